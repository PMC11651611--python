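"""stability_eigenmodes: steady states, spectral roots, proxy FC, mode fits."""

from dataclasses import replace

import numpy as np
import pytest

from ngnmm.model import IDX_RE, IDX_VE, M_LOCAL, NetworkRHS
from ngnmm.params import NetworkParameters
from ngnmm.stability import (
    SteadyStateError,
    dense_zero_delay_jacobian,
    eigenmode_fc_fit,
    find_hopf_crossing,
    jacobian_mode_basis,
    local_jacobian,
    network_jacobian_nm,
    rightmost_root,
    solve_network_steady_state,
    spectral_eigenvalues,
    structural_basis,
    structural_proxy_fc,
)


def filter_rates(node, net):
    return np.unique(np.concatenate([node.alpha.ravel(), [net.alpha_net]]))


def away_from_filters(lams, rates, radius=1e-2):
    lams = np.atleast_1d(np.asarray(lams))
    d = np.abs(lams[:, None] + np.asarray(rates)[None, :])
    return d.min(axis=1) > radius


class TestSteadyState:
    def test_residual_and_positivity(self, conn4, node, net_nonshunted):
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        assert ss.residual < 1e-9
        assert np.all(ss.R > 0)
        assert not ss.shunting

    def test_continuous_in_coupling(self, conn4, node, net_nonshunted):
        prev = None
        for k in (0.0, 0.02, 0.04, 0.06):
            ss = solve_network_steady_state(
                node, replace(net_nonshunted, k_ext=k), conn4
            )
            if prev is not None:
                assert np.linalg.norm(ss.xbar - prev) < 0.5
            prev = ss.xbar

    def test_implicit_function_slope(self, conn4, node, net_nonshunted):
        # d(xbar)/d(eta0_E) from the dense Jacobian matches the solver's
        # finite-difference slope (implicit function theorem)
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        rhs = NetworkRHS(conn4, node, net_nonshunted,
                         delays=np.zeros_like(conn4.distances))
        y0 = rhs.constant_state(ss.xbar)
        J = dense_zero_delay_jacobian(rhs, y0)
        b = np.zeros(y0.size)
        # layout: N contiguous 12-blocks of local states, edge states after
        b[IDX_VE:M_LOCAL * conn4.n_regions:M_LOCAL] = 1.0 / node.tau_E
        pred = -np.linalg.solve(J, b)[:M_LOCAL]  # node-0 local block

        h = 0.005
        hi = solve_network_steady_state(
            replace(node, eta0_E=node.eta0_E + h), net_nonshunted, conn4
        )
        lo = solve_network_steady_state(
            replace(node, eta0_E=node.eta0_E - h), net_nonshunted, conn4
        )
        slope = (hi.xbar - lo.xbar) / (2 * h)
        np.testing.assert_allclose(pred, slope, rtol=0.01, atol=1e-6)


class TestSpectralOracle:
    def test_roots_match_dense_jacobian(self, conn4, node, net_nonshunted):
        # zero-delay cross-validation: every converged spectral root away
        # from the synaptic filter rates (where the dense Jacobian carries
        # defective clusters with sqrt-conditioning) must coincide with a
        # dense finite-difference eigenvalue to 1e-6
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        rhs = NetworkRHS(conn4, node, net_nonshunted,
                         delays=np.zeros_like(conn4.distances))
        y0 = rhs.constant_state(ss.xbar)
        dense = np.linalg.eigvals(dense_zero_delay_jacobian(rhs, y0))
        roots = spectral_eigenvalues(
            ss, conn4, node, net_nonshunted,
            delays=np.zeros_like(conn4.distances),
        )
        rates = filter_rates(node, net_nonshunted)
        checked = 0
        for r in roots:
            if not r.converged or not away_from_filters(r.eigenvalue, rates)[0]:
                continue
            assert np.min(np.abs(dense - r.eigenvalue)) < 1e-6
            checked += 1
        assert checked >= 8  # the comparison must actually exercise roots

    def test_rightmost_root_matches_dense(self, conn4, node, net_nonshunted):
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        rhs = NetworkRHS(conn4, node, net_nonshunted,
                         delays=np.zeros_like(conn4.distances))
        y0 = rhs.constant_state(ss.xbar)
        dense = np.linalg.eigvals(dense_zero_delay_jacobian(rhs, y0))
        top = rightmost_root(conn4, node, net_nonshunted,
                             delays=np.zeros_like(conn4.distances))
        rm = dense[np.argmax(dense.real)]
        assert abs(top.eigenvalue.real - rm.real) < 1e-6
        assert abs(abs(top.eigenvalue.imag) - abs(rm.imag)) < 1e-6

    def test_gamma_consistency_at_zero_delay(self, conn4, node, net_nonshunted):
        # each root's transfer value must equal its structural eigenvalue
        # through the squared low-pass filter: gamma = nu / (1 + lam/a)^2
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        roots = spectral_eigenvalues(
            ss, conn4, node, net_nonshunted,
            delays=np.zeros_like(conn4.distances),
        )
        nus = structural_basis(conn4).eigenvalues
        a = net_nonshunted.alpha_net
        for r in roots:
            if not r.converged:
                continue
            expect = nus[r.mode] / (1.0 + r.eigenvalue / a) ** 2
            assert abs(r.gamma - expect) < 1e-8 * max(1.0, abs(expect))

    def test_hopf_bracket_required(self, conn4, node, net_nonshunted):
        with pytest.raises(ValueError, match="sign change"):
            find_hopf_crossing(conn4, node, net_nonshunted,
                               k_lo=0.0, k_hi=1e-4)


class TestProxyFC:
    def test_rank_one_unit_trace(self, conn6):
        basis = structural_basis(conn6)
        m = structural_proxy_fc(basis, 2)
        vals = m.values
        assert np.trace(vals) == pytest.approx(1.0, rel=1e-12)
        s = np.linalg.svd(vals, compute_uv=False)
        assert s[0] == pytest.approx(1.0, rel=1e-12)
        assert np.all(s[1:] < 1e-12)

    def test_perron_mode_is_uniform(self, conn6):
        # a row-normalised matrix has right eigenvector 1 with eigenvalue 1,
        # so the leading proxy FC is the constant matrix 1/N
        basis = structural_basis(conn6)
        assert basis.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        m = structural_proxy_fc(basis, 0)
        np.testing.assert_allclose(m.values, 1.0 / conn6.n_regions, atol=1e-10)

    def test_biorthonormality(self, conn6):
        basis = structural_basis(conn6)
        np.testing.assert_allclose(
            basis.left @ basis.right, np.eye(basis.n_modes), atol=1e-9
        )

    def test_three_node_hand_computation(self):
        from ngnmm.connectome import Connectome, row_normalize

        w = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        conn = row_normalize(Connectome(weights=w, distances=10 * np.ones((3, 3))))
        basis = structural_basis(conn)
        # row-normalised: [2/3,1/3;2/3,1/3;1/2,1/2] pattern; spectrum checked
        # against a direct eigensolve of the explicit matrix
        wn = w / w.sum(axis=1, keepdims=True)
        expect = np.sort(np.linalg.eigvals(wn).real)[::-1]
        np.testing.assert_allclose(np.sort(basis.eigenvalues)[::-1], expect,
                                   atol=1e-10)


class TestEigenmodeFit:
    def test_single_mode_target_recovered(self, conn6):
        basis = structural_basis(conn6)
        target = structural_proxy_fc(basis, 3).values
        order, coeffs, errs = eigenmode_fc_fit(basis, target, ordering="greedy")
        assert order[0] == 3
        assert errs[0] < 1e-8
        assert coeffs[0][0] == pytest.approx(1.0, rel=1e-6)

    def test_full_basis_orderings_agree(self, conn6, rng):
        basis = structural_basis(conn6)
        tgt = rng.standard_normal((6, 6))
        tgt = tgt + tgt.T
        finals = []
        for ordering in ("eigenvalue", "random", "greedy"):
            _, _, errs = eigenmode_fc_fit(basis, tgt, ordering=ordering, seed=5)
            finals.append(errs[-1])
        assert max(finals) - min(finals) < 1e-8

    def test_greedy_first_step_is_best_single_mode(self, conn6, rng):
        basis = structural_basis(conn6)
        tgt = rng.standard_normal((6, 6))
        tgt = tgt + tgt.T
        _, _, greedy_errs = eigenmode_fc_fit(basis, tgt, ordering="greedy")
        # brute force: restrict to each single mode via a one-column basis
        singles = []
        for m in range(basis.n_modes):
            _, _, e = eigenmode_fc_fit(basis.right[:, [m]], tgt,
                                       ordering="eigenvalue")
            singles.append(e[0])
        assert greedy_errs[0] <= min(singles) + 1e-12

    def test_constant_target_is_named_failure(self, conn6):
        basis = structural_basis(conn6)
        with pytest.raises(ValueError, match="constant"):
            eigenmode_fc_fit(basis, np.ones((6, 6)))


class TestJacobians:
    def test_local_jacobian_vs_finite_differences(self, node):
        from ngnmm.model import local_rhs

        rng = np.random.default_rng(2)
        x = np.abs(rng.standard_normal(M_LOCAL)) * 0.5
        x[2:4] = -1.0  # plausible voltages
        J = local_jacobian(x, node)
        eps = 1e-6
        for j in range(M_LOCAL):
            dx = np.zeros(M_LOCAL)
            dx[j] = eps * max(1.0, abs(x[j]))
            col = (local_rhs(x + dx, node) - local_rhs(x - dx, node)) / (2 * dx[j])
            np.testing.assert_allclose(J[:, j], col, rtol=1e-6, atol=1e-4)

    def test_network_jacobian_block_structure(self, conn4, node, net_nonshunted):
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        J = network_jacobian_nm(ss, conn4, node, net_nonshunted)
        N, M = conn4.n_regions, M_LOCAL
        assert J.shape == (N * M, N * M)
        Df = local_jacobian(ss.xbar, node)
        blk = J[:M, :M]  # diagonal block: local Jacobian (self weight is 0)
        np.testing.assert_allclose(blk, Df, atol=1e-12)
        # off-diagonal block couples source R_E into target dV_E/dt only
        off = J[:M, M:2 * M].copy()
        expect = np.zeros((M, M))
        expect[IDX_VE, IDX_RE] = (net_nonshunted.k_ext
                                  * net_nonshunted.v_syn_net / node.tau_E
                                  * conn4.weights[0, 1])
        np.testing.assert_allclose(off, expect, atol=1e-12)

    def test_jacobian_mode_basis_shape(self, conn4, node, net_nonshunted):
        ss = solve_network_steady_state(node, net_nonshunted, conn4)
        basis = jacobian_mode_basis(ss, conn4, node, net_nonshunted, n_modes=3)
        assert basis.shape == (4, 3)
        np.testing.assert_allclose(np.linalg.norm(basis, axis=0), 1.0,
                                   atol=1e-12)

    def test_steady_state_failure_is_named(self, conn4, node):
        # past the fold of the uniform branch (shunted convention) no
        # uniform steady state exists and the failure is a named error
        with pytest.raises(SteadyStateError):
            solve_network_steady_state(
                node, NetworkParameters(k_ext=0.5), conn4
            )
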