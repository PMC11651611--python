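"""Right-hand side of the delayed E--I neural mass network.

Each region carries 12 local variables
``(R_E, R_I, V_E, V_I, g_EE, g_EI, g_IE, g_II, s_EE, s_EI, s_IE, s_II)``:
firing rates R_a (1/s), mean membrane potentials V_a (mV) and second-order
alpha-function synapse pairs (g_ab, s_ab) for each of the four within-region
pathways. Every structural edge (i, j) with w_ij > 0 additionally carries a
long-range synapse pair (g_ij, s_ij) driven by the delayed excitatory rate of
the source region, so a dense N-region network has (12 + 2N) N equations.

The local flow is, per population a in {E, I},

    tau_a dR_a/dt = -R_a sum_b (g_ab + kappa_v^ab) + 2 R_a V_a
                    + Delta_a / (pi tau_a)
    tau_a dV_a/dt = eta0_a + V_a^2 - pi^2 tau_a^2 R_a^2
                    + sum_b g_ab (v_syn^ab - V_a)
                    + sum_b kappa_v^ab (V_b - V_a)
    dg_ab/dt = alpha_ab (s_ab - g_ab)
    ds_ab/dt = alpha_ab (kappa_s^ab R_b - s_ab)

and each long-range synapse obeys (1 + alpha_net^-1 d/dt)^2 g_ij
= k_ext w_ij R_E^j(t - T_ij). Inter-node input enters the excitatory
population of node i as sum_j g_ij (v_syn_net - V_E^i) in tau_E dV_E/dt and
as -R_E sum_j g_ij in tau_E dR_E/dt when the input is shunted (the full
simulation convention); in the non-shunted convention used for linear
analysis the voltage drive is sum_j g_ij v_syn_net and the rate term is
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, delays_from_distances
from .params import NetworkParameters, NodeParameters

__all__ = [
    "StateLayout",
    "NetworkRHS",
    "local_rhs",
    "uncoupled_fixed_point",
    "kuramoto_from_RV",
    "rv_from_kuramoto",
    "KuramotoPoleError",
]

M_LOCAL = 12  # local variables per region

# offsets within a node block
IDX_RE, IDX_RI, IDX_VE, IDX_VI = 0, 1, 2, 3
IDX_G = slice(4, 8)   # g_EE, g_EI, g_IE, g_II (row-major [a][b])
IDX_S = slice(8, 12)


class KuramotoPoleError(ValueError):
    """Raised at the pole W = -1 of the conformal map."""


def uncoupled_fixed_point(eta0: float, delta: float, tau: float) -> tuple[float, float]:
    """Closed-form fixed point of an isolated population (no synapses).

    Setting dR/dt = dV/dt = 0 with all coupling off gives V = -Delta/(2 pi
    tau R) and, with r = pi tau R, the quartic r^4 - eta0 r^2 - Delta^2/4 = 0
    whose positive root is r^2 = (eta0 + sqrt(eta0^2 + Delta^2)) / 2.
    """
    r2 = 0.5 * (eta0 + np.hypot(eta0, delta))
    r = np.sqrt(r2)
    R = r / (np.pi * tau)
    V = -delta / (2.0 * r)
    return float(R), float(V)


def local_rhs(
    state: np.ndarray,
    params: NodeParameters,
    external_drive: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Time derivatives of one region's 12 local variables.

    ``external_drive = (gsum, current)``: ``gsum`` is the summed long-range
    conductance (adds -R_E * gsum inside tau_E dR_E/dt) and ``current`` is
    the long-range synaptic current added inside tau_E dV_E/dt.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (M_LOCAL,):
        raise ValueError(f"state must have {M_LOCAL} components")
    R = x[0:2]
    V = x[2:4]
    g = x[IDX_G].reshape(2, 2)
    s = x[IDX_S].reshape(2, 2)
    tau, eta0, delta = params.tau, params.eta0, params.delta
    gsum_ext, current_ext = external_drive

    gv = g.sum(axis=1) + params.kappa_v.sum(axis=1)
    dR = (-R * gv + 2.0 * R * V + delta / (np.pi * tau)) / tau
    dR[0] += -R[0] * gsum_ext / tau[0]

    syn = (g * (params.v_syn - V[:, None])).sum(axis=1)
    gap = (params.kappa_v * (V[None, :] - V[:, None])).sum(axis=1)
    dV = (eta0 + V**2 - (np.pi * tau * R) ** 2 + syn + gap) / tau
    dV[0] += current_ext / tau[0]

    dg = params.alpha * (s - g)
    ds = params.alpha * (params.kappa_s * R[None, :] - s)
    return np.concatenate([dR, dV, dg.ravel(), ds.ravel()])


@dataclass(frozen=True)
class StateLayout:
    """Packing map for the flat network state vector.

    Node-major blocks of 12 local variables, then the long-range g_ij for
    every structural edge in CSR order, then the matching s_ij block.
    """

    n_regions: int
    edge_rows: np.ndarray  # target node i per edge
    edge_cols: np.ndarray  # source node j per edge

    @property
    def n_edges(self) -> int:
        return self.edge_rows.size

    @property
    def size(self) -> int:
        return M_LOCAL * self.n_regions + 2 * self.n_edges

    @property
    def g_edge_offset(self) -> int:
        return M_LOCAL * self.n_regions

    @property
    def s_edge_offset(self) -> int:
        return M_LOCAL * self.n_regions + self.n_edges

    def node_index(self, node: int, component: int) -> int:
        return M_LOCAL * node + component

    def re_indices(self) -> np.ndarray:
        """Flat indices of every region's excitatory rate R_E."""
        return M_LOCAL * np.arange(self.n_regions) + IDX_RE

    @classmethod
    def from_connectome(cls, c: Connectome) -> "StateLayout":
        w = c.weights.copy()
        np.fill_diagonal(w, 0.0)
        rows, cols = np.nonzero(w)  # np.nonzero is row-major == CSR order
        return cls(n_regions=c.n_regions, edge_rows=rows, edge_cols=cols)


class NetworkRHS:
    """Vectorised derivative of the full delayed network state.

    The integrator supplies, at each evaluation, the delayed excitatory
    rates ``R_E^j(t - T_ij)`` for every structural edge (one value per edge,
    in layout edge order); :attr:`delay_components` and :attr:`delay_lags`
    declare which flat state components and lags those are.
    """

    def __init__(
        self,
        connectome: Connectome,
        node_params: NodeParameters | None = None,
        net_params: NetworkParameters | None = None,
        *,
        warn_unnormalized: bool = True,
        delays: np.ndarray | None = None,
    ):
        self.connectome = connectome
        self.node = node_params or NodeParameters()
        self.net = net_params or NetworkParameters()
        if warn_unnormalized and not connectome.is_row_normalized:
            import warnings

            warnings.warn(
                "connectome weights are not row-normalised; the uniform "
                "steady-state construction will not apply",
                stacklevel=2,
            )
        self.layout = StateLayout.from_connectome(connectome)
        lay = self.layout
        self.edge_w = connectome.weights[lay.edge_rows, lay.edge_cols]
        if delays is not None:
            T = np.asarray(delays, dtype=float)  # override (e.g. zero-delay oracles)
        else:
            T = delays_from_distances(connectome, self.net.speed)
        self.delay_lags = T[lay.edge_rows, lay.edge_cols]
        self.delay_components = M_LOCAL * lay.edge_cols + IDX_RE
        self.max_lag = float(self.delay_lags.max()) if lay.n_edges else 0.0

        # cached parameter arrays and layout offsets (hot path)
        p = self.node
        self._tau = p.tau
        self._eta0 = p.eta0
        self._delta_term = p.delta / (np.pi * p.tau)
        self._kv = p.kappa_v
        self._kvT = np.ascontiguousarray(p.kappa_v.T)
        self._kv_rowsum = p.kappa_v.sum(axis=1)
        self._alpha = p.alpha
        self._ks = p.kappa_s
        self._vsyn = p.v_syn
        self._pitau_sq = (np.pi * p.tau) ** 2
        self._goff = lay.g_edge_offset
        self._soff = lay.s_edge_offset
        self._ne = lay.n_edges
        self._kext_w = self.net.k_ext * self.edge_w
        self._anet = self.net.alpha_net
        self._anet_kw = self._anet * self._kext_w
        self._build_linear_part()

    def _build_linear_part(self) -> None:
        """Precompute the linear operator A and constant c of the flow.

        The full derivative is ``dy = A y + c + q(y) + input`` where ``q``
        collects the few genuinely quadratic terms (rate--conductance and
        rate--voltage products) evaluated per call; everything else --
        synaptic filter chains, gap-junction voltage coupling, the linear
        part of the synaptic currents and the edge filters -- is constant
        coefficient and folded into one sparse matrix--vector product.
        """
        from scipy import sparse

        lay = self.layout
        N = lay.n_regions
        p = self.node
        tau, alpha, ks, vsyn = p.tau, p.alpha, p.kappa_s, p.v_syn
        kv, kvr = p.kappa_v, self._kv_rowsum
        rows, cols, vals = [], [], []

        def add(r, c_, v):
            rows.append(r)
            cols.append(c_)
            vals.append(v)

        c = np.zeros(lay.size)
        for a in range(N):
            m0 = M_LOCAL * a
            for pp in range(2):
                # rate: gap-junction damping and the Lorentzian source
                add(m0 + pp, m0 + pp, -kvr[pp] / tau[pp])
                c[m0 + pp] = self._delta_term[pp] / tau[pp]
                # voltage: background drive, synaptic g * v_syn, gap coupling
                rv = m0 + 2 + pp
                c[rv] = self._eta0[pp] / tau[pp]
                for b in range(2):
                    add(rv, m0 + 4 + 2 * pp + b, vsyn[pp, b] / tau[pp])
                    add(rv, m0 + 2 + b, kv[pp, b] / tau[pp])
                add(rv, m0 + 2 + pp, -kvr[pp] / tau[pp])
                # filter pairs
                for b in range(2):
                    rg = m0 + 4 + 2 * pp + b
                    rs = m0 + 8 + 2 * pp + b
                    add(rg, rg, -alpha[pp, b])
                    add(rg, rs, alpha[pp, b])
                    add(rs, rs, -alpha[pp, b])
                    add(rs, m0 + b, alpha[pp, b] * ks[pp, b])
        a_net = self._anet
        for e in range(lay.n_edges):
            tgt = lay.edge_rows[e]
            # linear part of the network drive onto the target V_E (the
            # shunted convention adds its quadratic -g V_E part per call)
            add(M_LOCAL * tgt + IDX_VE, self._goff + e,
                self.net.v_syn_net / tau[0])
            add(self._goff + e, self._goff + e, -a_net)
            add(self._goff + e, self._soff + e, a_net)
            add(self._soff + e, self._soff + e, -a_net)
        self._A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(lay.size, lay.size)
        )
        self._c = c

    @property
    def size(self) -> int:
        return self.layout.size

    def __call__(
        self, t: float, y: np.ndarray, delayed_re: np.ndarray
    ) -> np.ndarray:
        """Full derivative vector. ``delayed_re[e] = R_E^{j(e)}(t - T_e)``."""
        lay = self.layout
        N = lay.n_regions
        nodes = y[: M_LOCAL * N].reshape(N, M_LOCAL)
        R = nodes[:, 0:2]
        V = nodes[:, 2:4]
        g = nodes[:, 4:8].reshape(N, 2, 2)
        g_edge = y[self._goff : self._soff]

        out = self._A @ y
        out += self._c
        dnodes = out[: M_LOCAL * N].reshape(N, M_LOCAL)

        # quadratic terms: rate--conductance / rate--voltage products
        gsum2 = g.sum(axis=2)
        dnodes[:, 0:2] += R * (2.0 * V - gsum2) / self._tau
        dnodes[:, 2:4] += (
            V * V - self._pitau_sq[None, :] * (R * R) - V * gsum2
        ) / self._tau

        if self.net.shunting_network_input:
            # conductance-based inter-node input: -g (R_E, V_E) products
            gsum = np.bincount(
                lay.edge_rows, weights=g_edge, minlength=N
            ) / self._tau[0]
            dnodes[:, 0] -= R[:, 0] * gsum
            dnodes[:, 2] -= V[:, 0] * gsum

        out[self._soff :] += self._anet_kw * delayed_re
        return out

    def call_with_lookup(self, t: float, y: np.ndarray, delayed_RE) -> np.ndarray:
        """Variant taking ``delayed_RE(j, lag) -> R_E^j(t - lag)``.

        Convenience for tests and method-of-steps checks; the integrator
        uses the array form.
        """
        lay = self.layout
        delayed = np.array(
            [
                delayed_RE(int(j), float(lag))
                for j, lag in zip(lay.edge_cols, self.delay_lags)
            ]
        )
        return self(t, y, delayed)

    def constant_state(self, xbar: np.ndarray, re_bar: float | None = None) -> np.ndarray:
        """Pack a uniform network state from a 12-vector plus edge equilibria.

        Edge synapses equilibrate at g_ij = s_ij = k_ext w_ij R_E; ``re_bar``
        defaults to ``xbar[0]``.
        """
        lay = self.layout
        if re_bar is None:
            re_bar = float(xbar[IDX_RE])
        y = np.empty(lay.size)
        y[: M_LOCAL * lay.n_regions] = np.tile(np.asarray(xbar, float), lay.n_regions)
        edge_eq = self.net.k_ext * self.edge_w * re_bar
        y[lay.g_edge_offset : lay.g_edge_offset + lay.n_edges] = edge_eq
        y[lay.s_edge_offset :] = edge_eq
        return y


def kuramoto_from_RV(R: float, V: float, tau: float) -> complex:
    """Kuramoto order parameter from (R, V) via the conformal map.

    Z = (1 - W*)/(1 + W*) with W = pi tau R + i V; |Z| <= 1 for R >= 0.
    """
    if R < 0:
        raise ValueError("firing rate must be non-negative")
    W = np.pi * tau * R + 1j * V
    denom = 1.0 + np.conj(W)
    if abs(denom) < 1e-300:
        raise KuramotoPoleError("conformal map pole at W = -1")
    return (1.0 - np.conj(W)) / denom


def rv_from_kuramoto(Z: complex, tau: float) -> tuple[float, float]:
    """Inverse conformal map: recover (R, V) from the order parameter."""
    denom = 1.0 + Z
    if abs(denom) < 1e-300:
        raise KuramotoPoleError("inverse map pole at Z = -1")
    W = np.conj((1.0 - Z) / denom)
    R = W.real / (np.pi * tau)
    return float(R), float(W.imag)
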