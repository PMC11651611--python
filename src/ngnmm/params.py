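"""Model parameters for the next-generation neural mass network.

Each cortical region is an excitatory--inhibitory (E--I) pair of mean-field
populations derived exactly from networks of quadratic integrate-and-fire
neurons with conductance-based chemical synapses and ohmic gap junctions.
``NodeParameters`` holds all within-region constants; ``NetworkParameters``
holds the long-range (excitatory-to-excitatory) coupling constants; and
``BoldParameters`` the Balloon--Windkessel haemodynamic constants.

Defaults are the physiologically plausible reference set that places the
network steady state close to a Hopf bifurcation.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "NodeParameters",
    "NetworkParameters",
    "BoldParameters",
    "load_config",
    "default_config_path",
]

# Population index convention used everywhere: 0 = E, 1 = I.
POP_E = 0
POP_I = 1


def _mat(EE, EI, IE, II) -> np.ndarray:
    """2x2 array in [a][b] (target, source) order."""
    return np.array([[EE, EI], [IE, II]], dtype=float)


@dataclass(frozen=True)
class NodeParameters:
    """Constants of a single E--I neural mass (12 local equations).

    ``alpha[a][b]``, ``kappa_s[a][b]``, ``v_syn[a][b]`` and ``kappa_v[a][b]``
    are indexed target-population-first, ``a, b in {E=0, I=1}``; e.g.
    ``kappa_s[0][1]`` is the strength of the inhibitory-to-excitatory
    chemical synapse (kappa_s^EI).

    Units: time constants in seconds, synaptic rates in 1/s, reversal
    potentials in mV; drives, widths and coupling strengths dimensionless.
    """

    tau_E: float = 0.011
    tau_I: float = 0.012
    eta0_E: float = -2.5
    eta0_I: float = 3.0
    delta_E: float = 0.5
    delta_I: float = 0.5
    alpha: np.ndarray = field(default_factory=lambda: _mat(50.0, 40.0, 50.0, 40.0))
    kappa_s: np.ndarray = field(default_factory=lambda: _mat(0.5, 0.3, 0.7, 0.3))
    v_syn: np.ndarray = field(default_factory=lambda: _mat(10.0, -10.0, 10.0, -10.0))
    kappa_v: np.ndarray = field(default_factory=lambda: _mat(0.01, 0.0, 0.0, 0.025))

    def __post_init__(self):
        for name in ("alpha", "kappa_s", "v_syn", "kappa_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (2, 2):
                raise ValueError(f"{name} must be a 2x2 array")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("membrane time constants must be strictly positive")
        if self.delta_E <= 0 or self.delta_I <= 0:
            raise ValueError("drive half-widths must be strictly positive")
        if np.any(self.alpha <= 0):
            raise ValueError("synaptic rates alpha must be strictly positive")
        if np.any(self.kappa_s < 0) or np.any(self.kappa_v < 0):
            raise ValueError("coupling strengths must be non-negative")

    # convenience vectors in (E, I) order
    @property
    def tau(self) -> np.ndarray:
        return np.array([self.tau_E, self.tau_I])

    @property
    def eta0(self) -> np.ndarray:
        return np.array([self.eta0_E, self.eta0_I])

    @property
    def delta(self) -> np.ndarray:
        return np.array([self.delta_E, self.delta_I])

    def without_gap_junctions(self) -> "NodeParameters":
        return replace(self, kappa_v=np.zeros((2, 2)))


@dataclass(frozen=True)
class NetworkParameters:
    """Long-range coupling constants between excitatory populations.

    ``shunting_network_input`` selects whether inter-node synaptic currents
    depend on the local voltage (true, the full simulation convention) or are
    treated as pure current injections (false, the convention under which the
    network steady state and its linear stability are computed).
    """

    k_ext: float = 0.2
    alpha_net: float = 40.0
    v_syn_net: float = 10.0
    speed: float = 12.0  # conduction speed, m/s
    shunting_network_input: bool = True

    def __post_init__(self):
        if self.k_ext < 0:
            raise ValueError("k_ext must be non-negative")
        if self.alpha_net <= 0:
            raise ValueError("alpha_net must be strictly positive")
        if self.speed <= 0:
            raise ValueError("conduction speed must be strictly positive")


@dataclass(frozen=True)
class BoldParameters:
    """Balloon--Windkessel haemodynamic constants (time in seconds).

    rho: resting oxygen extraction fraction; tau_bold: haemodynamic transit
    time; k: signal decay rate; gamma: flow-dependent elimination rate;
    alpha_grubb: Grubb exponent. The read-out weights (V0, k1, k2, k3) are a
    3 T parameterisation and are configuration, not model structure.
    """

    rho: float = 0.34
    tau_bold: float = 2.0
    k: float = 0.65
    gamma: float = 0.41
    alpha_grubb: float = 0.32
    V0: float = 0.02
    k1: float = 3.72
    k2: float = 0.527
    k3: float = 0.53

    def __post_init__(self):
        if min(self.rho, self.tau_bold, self.k, self.gamma, self.alpha_grubb) <= 0:
            raise ValueError("Balloon-Windkessel parameters must be positive")


def default_config_path() -> Path:
    """Path of the shipped defaults TOML (the reference parameter set)."""
    return Path(str(resources.files("ngnmm") / "data" / "defaults.toml"))


def _node_from_dict(d: dict) -> NodeParameters:
    kw = {}
    for scalar in ("tau_E", "tau_I", "eta0_E", "eta0_I", "delta_E", "delta_I"):
        if scalar in d:
            kw[scalar] = float(d[scalar])
    for mat, prefix in (
        ("alpha", "alpha"),
        ("kappa_s", "kappa_s"),
        ("v_syn", "v_syn"),
        ("kappa_v", "kappa_v"),
    ):
        keys = [f"{prefix}_{ab}" for ab in ("EE", "EI", "IE", "II")]
        if any(k in d for k in keys):
            base = getattr(NodeParameters(), mat)
            vals = _mat(
                d.get(keys[0], base[0, 0]),
                d.get(keys[1], base[0, 1]),
                d.get(keys[2], base[1, 0]),
                d.get(keys[3], base[1, 1]),
            )
            kw[mat] = vals
    return NodeParameters(**kw)


def load_config(path: str | Path) -> dict:
    """Read a TOML run configuration.

    Returns a dict with keys ``node`` (NodeParameters), ``network``
    (NetworkParameters), ``bold`` (BoldParameters) and ``run`` (raw table of
    run options: durations, seeds, connectome source, observables).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    node = _node_from_dict(raw.get("node", {}))
    net_kw = {
        k: raw["network"][k]
        for k in ("k_ext", "alpha_net", "v_syn_net", "speed", "shunting_network_input")
        if "network" in raw and k in raw["network"]
    }
    network = NetworkParameters(**net_kw)
    bold_kw = {
        k: raw["bold"][k]
        for k in ("rho", "tau_bold", "k", "gamma", "alpha_grubb", "V0", "k1", "k2", "k3")
        if "bold" in raw and k in raw["bold"]
    }
    bold = BoldParameters(**bold_kw)
    return {"node": node, "network": network, "bold": bold, "run": raw.get("run", {}), "raw": raw}
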