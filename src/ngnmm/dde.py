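"""Adaptive delay-differential-equation integration with Hermite dense output.

The integrator advances the network equations with an embedded
Bogacki--Shampine 3(2) Runge--Kutta pair and serves delayed state lookups
from a dynamically pruned history of (time, value, slope) knots covering
only the delayed components (the excitatory rates referenced by the
long-range synapses). Values between knots come from a third-order (cubic)
Hermite interpolant, matching the order of the step scheme. The history
buffer discards knots older than ``t - max_lag`` as integration proceeds,
so memory is bounded by the delay horizon rather than the run length.

Runs are deterministic: no step-size randomisation, all accumulation in
double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Trajectory",
    "HistoryBuffer",
    "hermite_eval",
    "integrate",
    "StepUnderflowError",
    "NonFiniteStateError",
    "HistoryRangeError",
]


class StepUnderflowError(RuntimeError):
    """Step size fell below the minimum allowed."""


class NonFiniteStateError(RuntimeError):
    """The integration produced NaN or infinite state values."""


class HistoryRangeError(RuntimeError):
    """A delayed lookup fell outside the stored history."""


def hermite_eval(t_query, knot_left, knot_right):
    """Cubic Hermite interpolation between two (t, y, f) knots.

    Exact at the knots and for all polynomials of degree <= 3. ``y`` and
    ``f`` may be scalars or arrays (interpolated componentwise).
    """
    ta, ya, fa = knot_left
    tb, yb, fb = knot_right
    if not (ta <= t_query <= tb):
        raise HistoryRangeError(
            f"query t={t_query} outside bracket [{ta}, {tb}]"
        )
    h = tb - ta
    if h == 0.0:
        return np.asarray(ya) if np.ndim(ya) else ya
    th = (t_query - ta) / h
    h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
    h10 = th * (1.0 - th) ** 2
    h01 = th * th * (3.0 - 2.0 * th)
    h11 = th * th * (th - 1.0)
    return h00 * ya + h * h10 * fa + h01 * yb + h * h11 * fb


class HistoryBuffer:
    """Knot store for the delayed components of the state.

    Keeps (t, value, slope) rows for the ``n_comp`` delayed components at
    every accepted step plus the initial-history segment, and evaluates
    many (time, component) queries at once by bracketing with searchsorted
    and applying the cubic Hermite formula vectorised.
    """

    def __init__(self, n_comp: int, capacity: int = 1024):
        self.n_comp = n_comp
        self._t = np.empty(capacity)
        # values and slopes interleaved per knot: row = [y_0..y_n, f_0..f_n],
        # so eval gathers one (knot, [comp, comp+n]) block instead of four
        # separate fancy-index reads
        self._v = np.empty((capacity, 2 * n_comp))
        self._start = 0
        self._len = 0
        self._cols_key: int | None = None
        self._cols: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self._t[self._start : self._start + self._len]

    def append(self, t: float, y: np.ndarray, f: np.ndarray) -> None:
        i = self._start + self._len
        if i == self._t.size:
            self._compact_or_grow()
            i = self._start + self._len
        self._t[i] = t
        n = self.n_comp
        self._v[i, :n] = y
        self._v[i, n:] = f
        self._len += 1

    def _compact_or_grow(self) -> None:
        n = self._len
        if self._start > 0:
            sl = slice(self._start, self._start + n)
            self._t[:n] = self._t[sl]
            self._v[:n] = self._v[sl]
            self._start = 0
        if n >= self._t.size:
            cap = 2 * self._t.size
            self._t = np.resize(self._t, cap)
            self._v.resize((cap, 2 * self.n_comp), refcheck=False)

    def prune(self, horizon: float) -> None:
        """Drop knots strictly older than the horizon, keeping one bracket knot."""
        t = self.times
        # keep the last knot at or before the horizon so [horizon, t_now]
        # stays fully bracketed
        k = int(np.searchsorted(t, horizon, side="right")) - 1
        if k > 0:
            self._start += k
            self._len -= k

    def eval(self, t_query: np.ndarray, comp: np.ndarray) -> np.ndarray:
        """Interpolated values of components ``comp`` at times ``t_query``."""
        t = self.times
        if self._len < 2:
            raise HistoryRangeError("history has fewer than two knots")
        idx = np.searchsorted(t, t_query, side="right") - 1
        t0 = t[0]
        t1 = t[self._len - 1]
        tol = 1e-9 * max(1.0, abs(t1))
        if t_query.min() < t0 - tol or t_query.max() > t1 + tol:
            raise HistoryRangeError(
                "delayed lookup outside stored history: history too short "
                f"(have [{t0}, {t1}])"
            )
        np.minimum(idx, self._len - 2, out=idx)
        np.maximum(idx, 0, out=idx)
        a = self._start + idx
        ta = self._t[a]
        tb = self._t[a + 1]
        if self._cols_key != id(comp):
            self._cols_key = id(comp)
            self._cols = np.column_stack((comp, comp + self.n_comp))
        va = self._v[a[:, None], self._cols]  # (m, 2) = (y_a, f_a)
        vb = self._v[(a + 1)[:, None], self._cols]
        ya, fa = va[:, 0], va[:, 1]
        yb, fb = vb[:, 0], vb[:, 1]
        h = tb - ta
        same = h <= 0
        h[same] = 1.0
        th = (t_query - ta) / h
        np.minimum(th, 1.0, out=th)
        np.maximum(th, 0.0, out=th)
        # Horner form of the cubic Hermite combination
        d = yb - ya
        hfa = h * fa
        hfb = h * fb
        c3 = hfa + hfb - 2.0 * d
        c2 = d - hfa - c3
        val = ya + th * (hfa + th * (c2 + th * c3))
        return np.where(same, ya, val)


@dataclass
class Trajectory:
    """Integration output: sample grid, states, and optional slope knots.

    When the integrator ran with ``t_eval`` the states hold dense-output
    samples of the recorded components on that grid and ``slopes`` is None;
    otherwise every accepted step knot is stored with its derivative, and
    :meth:`dense_eval` gives third-order interpolation anywhere in range.
    """

    times: np.ndarray
    states: np.ndarray
    slopes: np.ndarray | None = None
    components: np.ndarray | None = None
    stats: dict = field(default_factory=dict)

    def dense_eval(self, t: float) -> np.ndarray:
        if self.slopes is None:
            raise ValueError("dense output requires stored slope knots")
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        i = min(max(i, 0), len(self.times) - 2)
        return hermite_eval(
            t,
            (self.times[i], self.states[i], self.slopes[i]),
            (self.times[i + 1], self.states[i + 1], self.slopes[i + 1]),
        )

    def to_hdf5(self, path: str | Path, thin: int = 1, meta: dict | None = None) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times[::thin])
            fh.create_dataset("states", data=self.states[::thin])
            if self.slopes is not None:
                fh.create_dataset("slopes", data=self.slopes[::thin])
            if self.components is not None:
                fh.create_dataset("layout", data=self.components)
            for k, v in {**self.stats, **(meta or {})}.items():
                if isinstance(v, (int, float, str, np.integer, np.floating)):
                    fh.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Trajectory":
        with h5py.File(path, "r") as fh:
            return cls(
                times=fh["times"][()],
                states=fh["states"][()],
                slopes=fh["slopes"][()] if "slopes" in fh else None,
                components=fh["layout"][()] if "layout" in fh else None,
                stats=dict(fh.attrs),
            )


# Bogacki-Shampine 3(2) embedded pair (FSAL): third-order solution with a
# second-order error estimator and a matching cubic-Hermite dense output.
_C = np.array([0.0, 0.5, 0.75, 1.0])
_B3 = np.array([2.0 / 9.0, 1.0 / 3.0, 4.0 / 9.0, 0.0])
_B2 = np.array([7.0 / 24.0, 0.25, 1.0 / 3.0, 0.125])


def integrate(
    rhs,
    history,
    t_span: tuple[float, float],
    rtol: float = 1e-6,
    atol: float = 1e-9,
    *,
    delay_components: np.ndarray | None = None,
    delay_lags: np.ndarray | None = None,
    t_eval: np.ndarray | None = None,
    record_components: np.ndarray | None = None,
    max_step: float = np.inf,
    first_step: float | None = None,
    min_step: float = 1e-13,
    prune_history: bool = True,
) -> Trajectory:
    """Integrate a (delayed) ODE system adaptively from t0 to t1.

    Parameters
    ----------
    rhs
        Callable ``rhs(t, y, delayed) -> dy/dt`` where ``delayed[k]`` is the
        value of state component ``delay_components[k]`` at ``t -
        delay_lags[k]``. Objects exposing ``delay_components`` /
        ``delay_lags`` attributes (e.g. :class:`~ngnmm.model.NetworkRHS`)
        need no explicit arrays.
    history
        Initial data: a state vector (constant history) or a callable
        ``h(t) -> state`` defined on ``[t0 - max_lag, t0]``.
    t_eval
        Optional uniform output grid; when given, only
        ``record_components`` (default: all) are sampled there via the
        dense output and no per-step knots are stored.
    """
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")

    if delay_components is None:
        delay_components = np.asarray(
            getattr(rhs, "delay_components", np.empty(0, int)), dtype=int
        )
    if delay_lags is None:
        delay_lags = np.asarray(getattr(rhs, "delay_lags", np.empty(0)), dtype=float)
    delay_components = np.atleast_1d(delay_components)
    delay_lags = np.atleast_1d(delay_lags).astype(float)
    if np.any(delay_lags < 0):
        raise ValueError("delay lags must be non-negative")
    has_delays = delay_lags.size > 0
    pos = delay_lags[delay_lags > 0]
    max_lag = float(delay_lags.max()) if has_delays else 0.0
    min_pos_lag = float(pos.min()) if pos.size else np.inf

    if callable(history):
        y0 = np.array(history(t0), dtype=float)
    else:
        y0 = np.array(history, dtype=float)
    dim = y0.size

    # history buffer over the unique delayed components
    if has_delays:
        comps_unique, comp_pos = np.unique(delay_components, return_inverse=True)
        hist = HistoryBuffer(comps_unique.size)
        if max_lag > 0:
            t_pre = t0 - 1.01 * max_lag
            if callable(history):
                # sample the user history on a fine grid with numerical slopes
                ts = np.linspace(t_pre, t0, 65)
                dt = ts[1] - ts[0]
                vals = np.array([np.asarray(history(t), float)[comps_unique] for t in ts])
                slopes = np.gradient(vals, dt, axis=0)
                for t, v, s in zip(ts, vals, slopes):
                    hist.append(t, v, s)
            else:
                yd = y0[comps_unique]
                zero = np.zeros_like(yd)
                hist.append(t_pre, yd, zero)
                hist.append(t0, yd, zero)
        zero_lag = delay_lags == 0.0
        nonzero_lag = ~zero_lag
        any_zero, any_nonzero = bool(zero_lag.any()), bool(nonzero_lag.any())
        nz_lags = delay_lags[nonzero_lag]
        nz_pos = comp_pos[nonzero_lag]
        z_comps = delay_components[zero_lag]
    else:
        hist = None
        comps_unique = comp_pos = zero_lag = None

    def delayed_at(t_stage: float, y_stage: np.ndarray) -> np.ndarray:
        if not has_delays:
            return np.empty(0)
        if any_nonzero and not any_zero:
            return hist.eval(t_stage - nz_lags, nz_pos)
        out = np.empty(delay_lags.size)
        if any_nonzero:
            out[nonzero_lag] = hist.eval(t_stage - nz_lags, nz_pos)
        if any_zero:
            # zero-lag entries read the current stage state directly
            out[zero_lag] = y_stage[z_comps]
        return out

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(rhs(t, y, delayed_at(t, y)), dtype=float)

    # With h capped at the smallest positive lag, every stage query
    # t + c h - lag lies at or before t, so the three stage lookups of a
    # step attempt can be served by a single batched history evaluation.
    batch_stages = has_delays and any_nonzero and not any_zero
    if batch_stages:
        stage_c = np.array([0.5, 0.75, 1.0])
        nz_pos3 = np.tile(nz_pos, 3)

    # output bookkeeping
    recording = t_eval is not None
    if recording:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval.size and (t_eval[0] < t0 - 1e-12 or t_eval[-1] > t1 + 1e-12):
            raise ValueError("t_eval must lie within t_span")
        rec = (
            np.arange(dim)
            if record_components is None
            else np.atleast_1d(np.asarray(record_components, int))
        )
        out_states = np.empty((t_eval.size, rec.size))
        next_out = 0
    else:
        knot_t, knot_y, knot_f = [t0], [y0.copy()], []

    stats = {
        "n_accepted": 0,
        "n_rejected": 0,
        "n_fev": 0,
        "min_step": np.inf,
        "max_step": 0.0,
    }

    t = t0
    y = y0.copy()
    k1 = f(t, y)
    stats["n_fev"] += 1
    if has_delays and max_lag > 0:
        # duplicate knot at t0 with the true right-side slope: the first
        # integration segment must not inherit the history's left-side
        # slope (order would drop to 2 across the t0 derivative jump)
        hist.append(t0, y0[comps_unique], k1[comps_unique])
    if not recording:
        knot_f.append(k1.copy())
    if recording and t_eval.size and abs(t_eval[0] - t0) <= 1e-12:
        out_states[0] = y[rec]
        next_out = 1

    h = first_step if first_step is not None else min(1e-4, min_pos_lag / 4.0, t1 - t0)
    h = min(h, max_step, min_pos_lag, t1 - t0)
    safety, order = 0.9, 3.0
    err_prev = 1.0

    K = np.empty((4, dim))
    while t < t1 - 1e-14:
        h = min(h, max_step, min_pos_lag, t1 - t)
        if h < min_step:
            raise StepUnderflowError(f"step size underflow at t = {t:.6g}")
        K[0] = k1
        if batch_stages:
            tq = (t + h * stage_c)[:, None] - nz_lags[None, :]
            D = hist.eval(tq.ravel(), nz_pos3).reshape(3, -1)
            K[1] = rhs(t + 0.5 * h, y + (0.5 * h) * K[0], D[0])
            K[2] = rhs(t + 0.75 * h, y + (0.75 * h) * K[1], D[1])
            y_new = y + h * (_B3[0] * K[0] + _B3[1] * K[1] + _B3[2] * K[2])
            K[3] = rhs(t + h, y_new, D[2])
        else:
            K[1] = f(t + 0.5 * h, y + (0.5 * h) * K[0])
            K[2] = f(t + 0.75 * h, y + (0.75 * h) * K[1])
            y_new = y + h * (_B3[0] * K[0] + _B3[1] * K[1] + _B3[2] * K[2])
            K[3] = f(t + h, y_new)
        stats["n_fev"] += 3
        if not np.all(np.isfinite(y_new)):
            raise NonFiniteStateError(f"non-finite state at t = {t + h:.6g}")
        y_low = y + h * (K.T @ _B2)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        err = np.sqrt(np.mean(((y_new - y_low) / scale) ** 2))

        if err <= 1.0:
            t_new = t + h
            if recording:
                while next_out < t_eval.size and t_eval[next_out] <= t_new + 1e-14:
                    tv = min(t_eval[next_out], t_new)
                    out_states[next_out] = hermite_eval(
                        tv, (t, y[rec], K[0][rec]), (t_new, y_new[rec], K[3][rec])
                    )
                    next_out += 1
            else:
                knot_t.append(t_new)
                knot_y.append(y_new.copy())
                knot_f.append(K[3].copy())
            if has_delays and max_lag > 0:
                hist.append(t_new, y_new[comps_unique], K[3][comps_unique])
                if prune_history:
                    hist.prune(t_new - max_lag)
            stats["n_accepted"] += 1
            stats["min_step"] = min(stats["min_step"], h)
            stats["max_step"] = max(stats["max_step"], h)
            t, y, k1 = t_new, y_new, K[3].copy()  # FSAL
            # predictive PI controller (Gustafsson): damped response to the
            # error history keeps the step near the accept boundary without
            # the overshoot/reject cycling of the deadbeat rule
            if err > 0:
                factor = safety * err ** (-0.7 / order) * err_prev ** (0.4 / order)
                err_prev = err
            else:
                factor = 5.0
        else:
            stats["n_rejected"] += 1
            factor = min(1.0, safety * err ** (-1.0 / order))
        h *= min(5.0, max(0.2, factor))

    if recording:
        return Trajectory(
            times=t_eval, states=out_states, slopes=None, components=rec, stats=stats
        )
    return Trajectory(
        times=np.array(knot_t),
        states=np.array(knot_y),
        slopes=np.array(knot_f),
        components=None,
        stats=stats,
    )
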