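"""Steady states, linear stability, and eigenmode proxies for network FC.

With a row-normalised structural matrix the delayed network admits a
uniform steady state in which every region sits at the same 12-vector.
Linearising around it and projecting onto the eigenvectors of the
structural matrix turns the (12 + 2N) N-dimensional spectral problem into N
scalar transcendental equations

    det[ lambda I - Df(xbar) - gamma_mu(lambda) K ] = 0,

where Df is the local Jacobian, K carries the long-range drive
(k_ext v_syn_net / tau_E into dV_E/dt from R_E), and

    gamma_mu(lambda) = sum_ij w_ij (1 + lambda/alpha_net)^-2
                       exp(-lambda T_ij) u_i^mu v_j^mu

mixes the synaptic filter and the conduction delays along structural mode
mu (right/left eigenvectors v^mu, u^mu). The projection onto fixed
structural eigenvectors is exact for uniform alpha_net and zero delays and
is the standard approximation otherwise. The rightmost root governs
stability; a complex pair crossing the imaginary axis marks a Hopf
bifurcation into network oscillations.

This module also builds proxy functional connectivity from eigenmodes
(outer products of eigenvectors) and fits combinations of such modes to a
target FC matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .connectome import Connectome, delays_from_distances
from .fc import FCMatrix, pearson_distance_vec
from .model import IDX_RE, IDX_VE, M_LOCAL, NetworkRHS, uncoupled_fixed_point
from .params import NetworkParameters, NodeParameters

__all__ = [
    "SteadyState",
    "SpectralRoot",
    "EigenmodeBasis",
    "SteadyStateError",
    "solve_network_steady_state",
    "local_jacobian",
    "spectral_eigenvalues",
    "rightmost_root",
    "find_hopf_crossing",
    "structural_basis",
    "jacobian_mode_basis",
    "structural_proxy_fc",
    "eigenmode_fc_fit",
    "dense_zero_delay_jacobian",
]


class SteadyStateError(RuntimeError):
    pass


@dataclass(frozen=True)
class SteadyState:
    """Uniform network steady state: the local 12-vector plus metadata."""

    xbar: np.ndarray          # (R_E, R_I, V_E, V_I, g_ab..., s_ab...)
    residual: float
    shunting: bool

    @property
    def R(self) -> np.ndarray:
        return self.xbar[0:2]

    @property
    def V(self) -> np.ndarray:
        return self.xbar[2:4]


def _steady_equations(
    z: np.ndarray, node: NodeParameters, net: NetworkParameters, ramp: float = 1.0
) -> np.ndarray:
    """The four nonlinear equations for (R_E, R_I, V_E, V_I).

    ``ramp`` scales all couplings (homotopy from the uncoupled closed form).
    The long-range drive on the excitatory population uses the explicit
    form k_ext * R_E * (v_syn_net - V_E) (shunted) or k_ext * v_syn_net *
    R_E (non-shunted), valid for row sums equal to one.
    """
    R = z[0:2]
    V = z[2:4]
    ks = ramp * node.kappa_s
    kv = ramp * node.kappa_v
    kx = ramp * net.k_ext
    gbar = ks * R[None, :]  # g_ab = kappa_s^ab R_b
    FR = (-R * (gbar.sum(axis=1) + kv.sum(axis=1)) + 2.0 * R * V
          + node.delta / (np.pi * node.tau))
    FV = (node.eta0 + V**2 - (np.pi * node.tau * R) ** 2
          + (gbar * (node.v_syn - V[:, None])).sum(axis=1)
          + (kv * (V[None, :] - V[:, None])).sum(axis=1))
    if net.shunting_network_input:
        FR[0] += -R[0] * kx * R[0]
        FV[0] += kx * R[0] * (net.v_syn_net - V[0])
    else:
        FV[0] += kx * net.v_syn_net * R[0]
    return np.concatenate([FR, FV])


def solve_network_steady_state(
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
    connectome: Connectome | None = None,
    *,
    tol: float = 1e-12,
) -> SteadyState:
    """Solve for the uniform steady state of the row-normalised network.

    Continuation from the uncoupled closed-form fixed point: couplings are
    ramped up in stages, each stage solved by a damped Newton method
    (scipy's hybrid scheme), which keeps the returned branch continuous in
    the parameters. Falls back to deterministic multi-starts if the
    homotopy stalls. Roots with non-positive rates are rejected.
    """
    node = node_params or NodeParameters()
    net = net_params or NetworkParameters()
    if connectome is not None and not connectome.is_row_normalized:
        raise SteadyStateError(
            "uniform steady state requires a row-normalised connectome"
        )
    RE, VE = uncoupled_fixed_point(node.eta0_E, node.delta_E, node.tau_E)
    RI, VI = uncoupled_fixed_point(node.eta0_I, node.delta_I, node.tau_I)
    z = np.array([RE, RI, VE, VI])

    for ramp in (0.25, 0.5, 0.75, 1.0):
        sol = optimize.root(
            _steady_equations, z, args=(node, net, ramp), method="hybr",
            tol=1e-13,
        )
        if sol.success:
            z = sol.x
    res = np.linalg.norm(_steady_equations(z, node, net, 1.0))
    if res > 1e-10 or np.any(z[0:2] <= 0):
        # deterministic multi-start fallback
        best = None
        for k, scale in enumerate((0.5, 1.0, 2.0, 4.0, 0.25, 8.0, 1.5, 3.0)):
            guess = np.array([RE * scale, RI * scale, VE, VI])
            sol = optimize.root(
                _steady_equations, guess, args=(node, net, 1.0), method="hybr",
                tol=1e-13,
            )
            r = np.linalg.norm(_steady_equations(sol.x, node, net, 1.0))
            if sol.success and np.all(sol.x[0:2] > 0) and (best is None or r < best[1]):
                best = (sol.x, r)
        if best is None:
            raise SteadyStateError(
                f"no positive-rate steady state found (residual {res:.3g})"
            )
        z, res = best
    if res > 1e-10:
        raise SteadyStateError(f"steady-state residual {res:.3g} exceeds 1e-10")

    R = z[0:2]
    gbar = node.kappa_s * R[None, :]
    xbar = np.concatenate([z[0:2], z[2:4], gbar.ravel(), gbar.ravel()])
    return SteadyState(xbar=xbar, residual=float(res), shunting=net.shunting_network_input)


def local_jacobian(xbar: np.ndarray, node: NodeParameters) -> np.ndarray:
    """Analytic 12x12 Jacobian of the local (within-region) flow at xbar."""
    R = xbar[0:2]
    V = xbar[2:4]
    g = xbar[4:8].reshape(2, 2)
    tau = node.tau
    J = np.zeros((12, 12))
    for a in range(2):
        rowR, rowV = a, 2 + a
        J[rowR, a] = (-(g[a].sum() + node.kappa_v[a].sum()) + 2.0 * V[a]) / tau[a]
        J[rowR, 2 + a] = 2.0 * R[a] / tau[a]
        J[rowV, a] = -2.0 * np.pi**2 * tau[a] * R[a]
        # the self gap term kappa_v^aa (V_a - V_a) vanishes identically, so
        # only the cross term contributes to d(dV_a)/dV_a
        J[rowV, 2 + a] = (2.0 * V[a] - g[a].sum() - node.kappa_v[a, 1 - a]) / tau[a]
        J[rowV, 2 + (1 - a)] += node.kappa_v[a, 1 - a] / tau[a]
        for b in range(2):
            colG = 4 + 2 * a + b
            colS = 8 + 2 * a + b
            J[rowR, colG] += -R[a] / tau[a]
            J[rowV, colG] += (node.v_syn[a, b] - V[a]) / tau[a]
            J[colG, colG] = -node.alpha[a, b]
            J[colG, colS] = node.alpha[a, b]
            J[colS, b] = node.alpha[a, b] * node.kappa_s[a, b]
            J[colS, colS] = -node.alpha[a, b]
    return J


# ---------------------------------------------------------------------------
# spectral problem


@dataclass(frozen=True)
class SpectralRoot:
    mode: int
    eigenvalue: complex
    gamma: complex
    residual: float
    converged: bool


@dataclass(frozen=True)
class EigenmodeBasis:
    """Eigenvalues with biorthonormal right/left eigenvectors (u . v = 1)."""

    eigenvalues: np.ndarray   # (k,)
    right: np.ndarray         # (N, k) columns v^mu
    left: np.ndarray          # (k, N) rows u^mu

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def structural_basis(connectome: Connectome) -> EigenmodeBasis:
    """Eigen-decomposition of the structural matrix, sorted by Re descending.

    A row-normalised symmetric-origin matrix is similar to a symmetric one,
    so its spectrum is real; tiny imaginary round-off is discarded.
    """
    vals, P = linalg.eig(connectome.weights)
    order = np.argsort(-vals.real)
    vals, P = vals[order], P[:, order]
    left = linalg.inv(P)
    if np.allclose(vals.imag, 0, atol=1e-9) and np.allclose(P.imag, 0, atol=1e-9):
        vals, P, left = vals.real, P.real, left.real
    return EigenmodeBasis(eigenvalues=vals, right=P, left=left)


def _coupling_matrix(node: NodeParameters, net: NetworkParameters) -> np.ndarray:
    """Single-entry drive matrix K: R_E of the source into dV_E/dt of the target."""
    K = np.zeros((M_LOCAL, M_LOCAL))
    K[IDX_VE, IDX_RE] = net.k_ext * net.v_syn_net / node.tau_E
    return K


def _zero_delay_block(
    Df: np.ndarray, K: np.ndarray, nu: complex, alpha_net: float
) -> np.ndarray:
    """14x14 delay-free block for one structural mode (seed eigenvalues).

    Augments the 12 local variables with the long-range synaptic filter
    pair (G, S); the transfer G = nu (1 + lambda/alpha)^-2 R_E is exact at
    zero delay.
    """
    B = np.zeros((14, 14), dtype=complex)
    B[:12, :12] = Df
    B[:12, 12] = K[:, IDX_RE]  # G drives the state where R_E would
    B[12, 12] = -alpha_net
    B[12, 13] = alpha_net
    B[13, IDX_RE] = alpha_net * nu
    B[13, 13] = -alpha_net
    return B


def spectral_eigenvalues(
    ss: SteadyState,
    connectome: Connectome,
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
    n_modes: int | None = None,
    *,
    delays: np.ndarray | None = None,
    scan_re: tuple[float, float] = (-200.0, 50.0),
    scan_im: tuple[float, float] = (0.0, 2 * np.pi * 120.0),
    scan_grid: tuple[int, int] = (5, 7),
    max_iter: int = 60,
    dedupe_tol: float = 1e-8,
) -> list[SpectralRoot]:
    """Solve the spectral equations for the linearised network.

    For each retained structural mode, Newton's method in the complex plane
    is run from (a) the eigenvalues of the exact delay-free block and (b) a
    coarse grid over the scan box, using the log-determinant derivative
    d log det A / d lambda = tr(A^-1 A'). Converged roots are deduplicated,
    conjugates added by spectral symmetry, and the list returned sorted by
    descending real part. Non-convergence of individual starts is not
    fatal.
    """
    node = node_params or NodeParameters()
    net = net_params or NetworkParameters()
    if net.shunting_network_input:
        net = NetworkParameters(
            k_ext=net.k_ext, alpha_net=net.alpha_net, v_syn_net=net.v_syn_net,
            speed=net.speed, shunting_network_input=False,
        )
    Df = local_jacobian(ss.xbar, node)
    K = _coupling_matrix(node, net)
    basis = structural_basis(connectome)
    T = delays if delays is not None else delays_from_distances(connectome, net.speed)
    w = connectome.weights
    rows, cols = np.nonzero(w)
    wv = w[rows, cols]
    Te = T[rows, cols]
    a = net.alpha_net
    n_modes = basis.n_modes if n_modes is None else min(n_modes, basis.n_modes)
    K_re = K[:, IDX_RE]

    roots: list[SpectralRoot] = []
    eye = np.eye(M_LOCAL)
    for mu in range(n_modes):
        u = basis.left[mu]
        v = basis.right[:, mu]
        ce = wv * u[rows] * v[cols]

        def gamma_and_deriv(lam: complex) -> tuple[complex, complex]:
            denom = 1.0 + lam / a
            if abs(denom) < 1e-13:
                # filter pole lambda = -alpha: no root here, abort this start
                raise FloatingPointError("gamma pole")
            filt = denom ** -2
            ex = np.exp(-lam * Te)
            s0 = np.sum(ce * ex)
            s1 = np.sum(ce * ex * Te)
            g = filt * s0
            dg = -filt * s1 - (2.0 / a) * (1.0 + lam / a) ** -3 * s0
            return g, dg

        seeds = list(
            np.linalg.eigvals(
                _zero_delay_block(Df, K, basis.eigenvalues[mu], a)
            )
        )
        re_grid = np.linspace(*scan_re, scan_grid[0])
        im_grid = np.linspace(*scan_im, scan_grid[1])
        seeds += [complex(r, i) for r in re_grid for i in im_grid]

        mode_roots: list[complex] = []
        for lam0 in seeds:
            lam = complex(lam0)
            ok = False
            for _ in range(max_iter):
                try:
                    g, dg = gamma_and_deriv(lam)
                except FloatingPointError:
                    break
                A = lam * eye - Df - g * K_re[:, None] @ np.eye(1, M_LOCAL, IDX_RE)
                Ap = np.eye(M_LOCAL, dtype=complex)
                Ap -= dg * K_re[:, None] @ np.eye(1, M_LOCAL, IDX_RE)
                try:
                    X = np.linalg.solve(A, Ap)
                except np.linalg.LinAlgError:
                    break
                tr = np.trace(X)
                if tr == 0:
                    break
                step = 1.0 / tr
                lam -= step
                if abs(step) < 1e-11 * (1.0 + abs(lam)):
                    ok = True
                    break
            if not ok or not np.isfinite(lam):
                continue
            if not (scan_re[0] - 50 <= lam.real <= scan_re[1] + 50):
                continue
            if abs(lam.imag) > scan_im[1] + 200:
                continue
            lam = complex(lam.real, abs(lam.imag))
            if any(abs(lam - r) <= max(dedupe_tol, 1e-8 * abs(lam)) for r in mode_roots):
                continue
            try:
                g, _ = gamma_and_deriv(lam)
            except FloatingPointError:
                continue
            A = lam * eye - Df - g * K_re[:, None] @ np.eye(1, M_LOCAL, IDX_RE)
            sv = np.linalg.svd(A, compute_uv=False)
            res = sv[-1] / max(sv[0], 1e-300)
            if res > 1e-8:
                continue
            mode_roots.append(lam)
            roots.append(
                SpectralRoot(mode=mu, eigenvalue=lam, gamma=g, residual=float(res),
                             converged=True)
            )
            if lam.imag > dedupe_tol:
                roots.append(
                    SpectralRoot(mode=mu, eigenvalue=lam.conjugate(),
                                 gamma=g.conjugate(), residual=float(res),
                                 converged=True)
                )
    roots.sort(key=lambda r: -r.eigenvalue.real)
    return roots


def rightmost_root(
    connectome: Connectome,
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
    **kwargs,
) -> SpectralRoot:
    """Steady state + spectral solve, returning the rightmost eigenvalue."""
    node = node_params or NodeParameters()
    net = net_params or NetworkParameters()
    ss = solve_network_steady_state(node, net, connectome)
    roots = spectral_eigenvalues(ss, connectome, node, net, **kwargs)
    if not roots:
        raise SteadyStateError("no spectral roots converged")
    return roots[0]


def find_hopf_crossing(
    connectome: Connectome,
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
    k_lo: float = 0.0,
    k_hi: float = 1.0,
    tol: float = 1e-4,
    **kwargs,
) -> tuple[float, SpectralRoot]:
    """Bisect the global coupling k_ext for the Hopf point Re(lambda) = 0.

    Requires the rightmost root to be stable at ``k_lo`` and unstable at
    ``k_hi``.
    """
    from dataclasses import replace as _replace

    node = node_params or NodeParameters()
    net = net_params or NetworkParameters()

    def re_at(k: float) -> float:
        return rightmost_root(
            connectome, node, _replace(net, k_ext=k), **kwargs
        ).eigenvalue.real

    f_lo, f_hi = re_at(k_lo), re_at(k_hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of Re(lambda) on [{k_lo}, {k_hi}] "
            f"(values {f_lo:.3g}, {f_hi:.3g})"
        )
    while k_hi - k_lo > tol:
        mid = 0.5 * (k_lo + k_hi)
        if re_at(mid) * f_lo <= 0:
            k_hi = mid
        else:
            k_lo, f_lo = mid, re_at(mid)
    k_c = 0.5 * (k_lo + k_hi)
    return k_c, rightmost_root(
        connectome, node, _replace(net, k_ext=k_c), **kwargs
    )


# ---------------------------------------------------------------------------
# dense Jacobian oracle and Jacobian modes


def dense_zero_delay_jacobian(
    rhs: NetworkRHS, y0: np.ndarray, eps: float = 1e-4
) -> np.ndarray:
    """Central finite-difference Jacobian of the full network flow at zero delay.

    Delayed lookups are fed the instantaneous state, so this is the exact
    Jacobian of the delay-free system — the brute-force oracle for the
    spectral equations. The flow is quadratic in the state, so central
    differences are exact up to roundoff and a moderately large step
    minimises the error.
    """
    comps = rhs.delay_components

    def f(y: np.ndarray) -> np.ndarray:
        return rhs(0.0, y, y[comps])

    n = y0.size
    J = np.empty((n, n))
    for j in range(n):
        dy = np.zeros(n)
        dy[j] = eps * max(1.0, abs(y0[j]))
        J[:, j] = (f(y0 + dy) - f(y0 - dy)) / (2.0 * dy[j])
    return J


def network_jacobian_nm(
    ss: SteadyState,
    connectome: Connectome,
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
) -> np.ndarray:
    """The NM x NM network Jacobian I_N (x) Df + w (x) K at lambda = 0."""
    node = node_params or NodeParameters()
    net = net_params or NetworkParameters()
    Df = local_jacobian(ss.xbar, node)
    K = _coupling_matrix(node, net)
    N = connectome.n_regions
    return np.kron(np.eye(N), Df) + np.kron(connectome.weights, K)


def jacobian_mode_basis(
    ss: SteadyState,
    connectome: Connectome,
    node_params: NodeParameters | None = None,
    net_params: NetworkParameters | None = None,
    n_modes: int | None = None,
) -> np.ndarray:
    """R_E-projected eigenmodes of the network Jacobian, by descending Re.

    Right eigenvectors of the lambda = 0 network Jacobian are reduced to
    their R_E components (one entry per region), realified and normalised.
    Conjugate pairs contribute a single vector. Returns an (N, k) array of
    unit vectors.
    """
    N = connectome.n_regions
    J = network_jacobian_nm(ss, connectome, node_params, net_params)
    vals, vecs = linalg.eig(J)
    order = np.argsort(-vals.real)
    vals, vecs = vals[order], vecs[:, order]
    keep = vals.imag >= -1e-12
    vals, vecs = vals[keep], vecs[:, keep]
    re_idx = M_LOCAL * np.arange(N) + IDX_RE
    k = N if n_modes is None else n_modes
    out = []
    for m in range(vecs.shape[1]):
        if len(out) >= k:
            break
        proj = vecs[re_idx, m]
        vec = proj.real if np.linalg.norm(proj.real) >= np.linalg.norm(proj.imag) \
            else proj.imag
        nrm = np.linalg.norm(vec)
        if nrm < 1e-12:
            continue
        vec = vec / nrm
        if any(abs(abs(vec @ o) - 1.0) < 1e-9 for o in out):
            continue  # duplicate direction (conjugate partner)
        out.append(vec)
    return np.column_stack(out)


# ---------------------------------------------------------------------------
# proxy FC and eigenmode fitting


def structural_proxy_fc(basis: EigenmodeBasis | np.ndarray, mode: int) -> FCMatrix:
    """Rank-one proxy FC: the outer product of one unit eigenvector."""
    vecs = basis.right if isinstance(basis, EigenmodeBasis) else np.asarray(basis)
    v = np.real(vecs[:, mode])
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("eigenvector has zero norm")
    v = v / nrm
    return FCMatrix(values=np.outer(v, v), metric="proxy", band=None)


def eigenmode_fc_fit(
    basis: EigenmodeBasis | np.ndarray,
    target: FCMatrix | np.ndarray,
    ordering: str = "greedy",
    seed: int = 0,
    n_modes: int | None = None,
) -> tuple[list[int], list[np.ndarray], np.ndarray]:
    """Fit a target FC by an incrementally grown combination of mode FCs.

    At step k the target's upper triangle is approximated in the least
    squares sense by sum_{m in S_k} c_m v^m (v^m)^T, refitting all
    coefficients at every step, and the misfit is recorded as the Pearson
    distance. Orderings: 'random' (seeded permutation), 'eigenvalue'
    (basis order, i.e. descending eigenvalue), 'greedy' (each step adds
    the mode whose inclusion minimises the refit error). A 'jacobian'
    ordering is the 'eigenvalue' ordering applied to a
    :func:`jacobian_mode_basis`.

    Returns (mode order, coefficient vectors per step, error curve).
    """
    vecs = basis.right if isinstance(basis, EigenmodeBasis) else np.asarray(basis)
    vecs = np.real(vecs)
    tgt = target.values if isinstance(target, FCMatrix) else np.asarray(target)
    N = tgt.shape[0]
    iu = np.triu_indices(N, k=1)
    b = tgt[iu]
    if np.ptp(b) == 0:
        raise ValueError("constant target FC: Pearson distance undefined")
    k = vecs.shape[1] if n_modes is None else min(n_modes, vecs.shape[1])
    A = np.empty((iu[0].size, k))
    for m in range(k):
        v = vecs[:, m] / np.linalg.norm(vecs[:, m])
        A[:, m] = np.outer(v, v)[iu]

    def refit(sel: list[int]) -> tuple[np.ndarray, float]:
        c, *_ = np.linalg.lstsq(A[:, sel], b, rcond=None)
        fit = A[:, sel] @ c
        return c, pearson_distance_vec(fit, b)

    if ordering in ("eigenvalue", "jacobian"):
        order = list(range(k))
    elif ordering == "random":
        order = list(np.random.default_rng(seed).permutation(k))
    elif ordering == "greedy":
        order = []
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    sel: list[int] = []
    coeffs: list[np.ndarray] = []
    errs: list[float] = []
    for step in range(k):
        if ordering == "greedy":
            best = None
            for cand in range(k):
                if cand in sel:
                    continue
                _, e = refit(sel + [cand])
                if best is None or e < best[1]:
                    best = (cand, e)
            sel.append(best[0])
            order.append(best[0])
        else:
            sel.append(order[step])
        c, e = refit(sel)
        coeffs.append(c)
        errs.append(e)
    return order, coeffs, np.asarray(errs)
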