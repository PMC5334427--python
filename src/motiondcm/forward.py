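"""Generative model: bilinear neuronal dynamics + hemodynamic observation.

Neuronal states x (one per region) follow the bilinear state equation

    dx/dt = (A + sum_i u_i B^(i)) x + C u

where A (n x n) holds the endogenous coupling, B^(i) the modulation of
coupling by input i, and C (n x m) the direct driving inputs. Inputs are
piecewise constant on the microtime grid, so the neuronal update over each
bin is computed *exactly* via the matrix exponential of the (affine-
augmented) bin dynamics.

Each region's neuronal activity drives a balloon-Windkessel hemodynamic
cascade (vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin
q), integrated with RK4 on the same grid:

    ds/dt = eps * x - kappa * s - gamma * (f - 1)
    df/dt = s
    dv/dt = (f - v^(1/alpha)) / tau
    dq/dt = (f * E(f, E0)/E0 - v^(1/alpha) * q / v) / tau,
    E(f, E0) = 1 - (1 - E0)^(1/f)

and BOLD (percent signal) is the standard nonlinear readout

    y = V0 * (k1 * (1 - q) + k2 * (1 - q/v) + k3 * (1 - v))

with 3T constants (TE = 30 ms): k1 = 4.3 * theta0 * E0 * TE,
k2 = eps_rho * r0 * E0 * TE, k3 = 1 - eps_rho.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .design import InputSet

__all__ = [
    "DCMSpec",
    "NeuralParams",
    "HemoParams",
    "DCMParams",
    "BOLDSeries",
    "default_hemo",
    "neural_derivative",
    "integrate_states",
    "predict_bold",
    "simulate_bold",
    "noise_sd_for_snr",
    "write_bold",
    "read_bold",
]

NODES = ("V1", "V5", "PPC")

# BOLD readout constants (3 Tesla, TE = 30 ms)
_TE = 0.03
_THETA0 = 80.6  # frequency offset at the outer surface of magnetized vessels, 1/s
_R0 = 110.0  # slope of intravascular relaxation rate with oxygenation, 1/s
_EPS_RHO = 0.47  # intra-/extravascular signal ratio
_V0 = 4.0  # resting venous volume fraction, percent signal units


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DCMSpec:
    """Structure of one model: which A/B/C entries are free."""

    a_mask: np.ndarray  # (n, n) bool; diagonal always True
    b_masks: np.ndarray  # (n, n, m) bool
    c_mask: np.ndarray  # (n, m) bool
    nodes: tuple[str, ...] = NODES
    input_names: tuple[str, ...] = ("MOTION", "UNPREDICTABLE", "ARBITRARY")
    family: str = ""
    gain_variant: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_mask", np.asarray(self.a_mask, dtype=bool))
        object.__setattr__(self, "b_masks", np.asarray(self.b_masks, dtype=bool))
        object.__setattr__(self, "c_mask", np.asarray(self.c_mask, dtype=bool))
        n, m = len(self.nodes), len(self.input_names)
        if self.a_mask.shape != (n, n):
            raise ValueError("a_mask must be (n, n)")
        if self.b_masks.shape != (n, n, m):
            raise ValueError("b_masks must be (n, n, m)")
        if self.c_mask.shape != (n, m):
            raise ValueError("c_mask must be (n, m)")
        if not np.all(np.diag(self.a_mask)):
            raise ValueError("self-connections (a_mask diagonal) must be present")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.input_names)

    @property
    def model_id(self) -> str:
        """Stable 12-hex-digit identifier of the mask triple."""
        payload = json.dumps(
            {
                "a": self.a_mask.astype(int).tolist(),
                "b": self.b_masks.astype(int).tolist(),
                "c": self.c_mask.astype(int).tolist(),
            },
            separators=(",", ":"),
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @property
    def mask_key(self) -> tuple:
        return (
            self.a_mask.tobytes(),
            self.b_masks.tobytes(),
            self.c_mask.tobytes(),
        )

    def to_dict(self) -> dict:
        return {
            "id": self.model_id,
            "nodes": list(self.nodes),
            "input_names": list(self.input_names),
            "a_mask": self.a_mask.astype(int).tolist(),
            "b_masks": self.b_masks.astype(int).tolist(),
            "c_mask": self.c_mask.astype(int).tolist(),
            "family": self.family,
            "gain_variant": self.gain_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMSpec":
        return cls(
            a_mask=np.array(d["a_mask"], dtype=bool),
            b_masks=np.array(d["b_masks"], dtype=bool),
            c_mask=np.array(d["c_mask"], dtype=bool),
            nodes=tuple(d.get("nodes", NODES)),
            input_names=tuple(d.get("input_names", ("MOTION", "UNPREDICTABLE", "ARBITRARY"))),
            family=d.get("family", ""),
            gain_variant=d.get("gain_variant", "none"),
        )


@dataclass
class NeuralParams:
    A: np.ndarray  # (n, n) Hz
    B: np.ndarray  # (n, n, m) Hz
    C: np.ndarray  # (n, m) Hz

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)


def default_hemo(n: int = 3) -> "HemoParams":
    return HemoParams(
        kappa=np.full(n, 0.64),
        gamma=np.full(n, 0.32),
        tau=np.full(n, 2.0),
        alpha=0.32,
        E0=0.4,
        epsilon=np.ones(n),
    )


@dataclass
class HemoParams:
    """Balloon-Windkessel parameters (per region unless scalar)."""

    kappa: np.ndarray  # signal decay, 1/s
    gamma: np.ndarray  # autoregulatory feedback, 1/s
    tau: np.ndarray  # mean transit time, s
    alpha: float  # vessel stiffness exponent
    E0: float  # resting oxygen extraction fraction
    epsilon: np.ndarray  # neuronal efficacy (drive gain)

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "epsilon"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (0 < self.alpha < 1 and 0 < self.E0 < 1):
            raise ValueError("alpha and E0 must lie in (0, 1)")
        if any(np.any(getattr(self, name) <= 0) for name in ("kappa", "gamma", "tau", "epsilon")):
            raise ValueError("hemodynamic rates must be positive")


@dataclass
class DCMParams:
    neural: NeuralParams
    hemo: HemoParams
    noise_sd: np.ndarray | float = 0.0  # additive scan noise, percent-signal units

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BOLDSeries:
    y: np.ndarray  # (T_scans, n) percent signal
    tr: float = 1.8
    nodes: tuple[str, ...] = NODES

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]


# ---------------------------------------------------------------------------
# dynamics


def neural_derivative(x: np.ndarray, u: np.ndarray, p: NeuralParams) -> np.ndarray:
    """Instantaneous dx/dt of the bilinear state equation."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(u)):
        raise ValueError("non-finite state or input")
    M = p.A + np.tensordot(p.B, u, axes=([2], [0]))
    return M @ x + p.C @ u


def _bold_constants(E0: float) -> tuple[float, float, float]:
    k1 = 4.3 * _THETA0 * E0 * _TE
    k2 = _EPS_RHO * _R0 * E0 * _TE
    k3 = 1.0 - _EPS_RHO
    return k1, k2, k3


def _hderiv_py(s, f, v, q, x, kappa, gamma, tau, ooa, E0, ln1mE0, eps):
    ds = eps * x - kappa * s - gamma * (f - 1.0)
    df = s
    # v**(1/alpha) and (1-E0)**(1/f) via exp/log (cheaper than pow, NaN-safe)
    fv = math.exp(ooa * math.log(v)) if v > 0 else np.nan
    dv = (f - fv) / tau
    if f > 0:
        E = 1.0 - math.exp(ln1mE0 / f)
    else:
        E = np.nan
    dq = (f * E / E0 - fv * q / v) / tau
    return ds, df, dv, dq


def _propagate_py(Ed, gd, Eh, gh, uidx, dt, kappa, gamma, tau, alpha, E0, eps, k1, k2, k3, V0):
    """Advance neuronal + hemodynamic states over all microtime bins.

    Ed/gd (Eh/gh): exact full-bin (half-bin) affine neuronal updates for
    each distinct input value. Returns neuronal states, hemodynamic states
    (s, f, v, q) and microtime BOLD, all sampled at bin *ends*. Written
    allocation-free in the hot loop so the numba-compiled version stays
    cheap enough for finite-difference Jacobians during inversion.
    """
    T = uidx.shape[0]
    n = Ed.shape[1]
    x = np.zeros(n)
    xm = np.zeros(n)
    x1 = np.zeros(n)
    h = np.zeros((n, 4))
    for r in range(n):
        h[r, 1] = 1.0
        h[r, 2] = 1.0
        h[r, 3] = 1.0
    x_all = np.empty((T, n))
    h_all = np.empty((T, n, 4))
    bold = np.empty((T, n))
    ooa = 1.0 / alpha
    ln1mE0 = math.log(1.0 - E0)
    for t in range(T):
        k = uidx[t]
        for j in range(n):
            am = gh[k, j]
            af = gd[k, j]
            for i in range(n):
                am += Eh[k, j, i] * x[i]
                af += Ed[k, j, i] * x[i]
            xm[j] = am
            x1[j] = af
        for r in range(n):
            s0, f0, v0, q0 = h[r, 0], h[r, 1], h[r, 2], h[r, 3]
            a1, b1, c1, d1 = _hderiv(s0, f0, v0, q0, x[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r])
            a2, b2, c2, d2 = _hderiv(
                s0 + 0.5 * dt * a1, f0 + 0.5 * dt * b1, v0 + 0.5 * dt * c1, q0 + 0.5 * dt * d1,
                xm[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            a3, b3, c3, d3 = _hderiv(
                s0 + 0.5 * dt * a2, f0 + 0.5 * dt * b2, v0 + 0.5 * dt * c2, q0 + 0.5 * dt * d2,
                xm[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            a4, b4, c4, d4 = _hderiv(
                s0 + dt * a3, f0 + dt * b3, v0 + dt * c3, q0 + dt * d3,
                x1[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            h[r, 0] = s0 + dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            h[r, 1] = f0 + dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            h[r, 2] = v0 + dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            h[r, 3] = q0 + dt / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            vq, qq = h[r, 2], h[r, 3]
            bold[t, r] = V0 * (k1 * (1.0 - qq) + k2 * (1.0 - qq / vq) + k3 * (1.0 - vq))
        for j in range(n):
            x[j] = x1[j]
            x_all[t, j] = x1[j]
            for c in range(4):
                h_all[t, j, c] = h[j, c]
    return x_all, h_all, bold


def _propagate_scan_py(
    Ed, gd, Eh, gh, uidx, dt, kappa, gamma, tau, alpha, E0, eps, k1, k2, k3, V0, bps
):
    """Same propagation as :func:`_propagate_py` but stores nothing except
    BOLD at scan ends (every ``bps``-th bin) — the inversion hot path."""
    T = uidx.shape[0]
    n = Ed.shape[1]
    x = np.zeros(n)
    xm = np.zeros(n)
    x1 = np.zeros(n)
    h = np.zeros((n, 4))
    for r in range(n):
        h[r, 1] = 1.0
        h[r, 2] = 1.0
        h[r, 3] = 1.0
    y = np.empty((T // bps, n))
    ooa = 1.0 / alpha
    ln1mE0 = math.log(1.0 - E0)
    for t in range(T):
        k = uidx[t]
        for j in range(n):
            am = gh[k, j]
            af = gd[k, j]
            for i in range(n):
                am += Eh[k, j, i] * x[i]
                af += Ed[k, j, i] * x[i]
            xm[j] = am
            x1[j] = af
        for r in range(n):
            s0, f0, v0, q0 = h[r, 0], h[r, 1], h[r, 2], h[r, 3]
            a1, b1, c1, d1 = _hderiv(s0, f0, v0, q0, x[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r])
            a2, b2, c2, d2 = _hderiv(
                s0 + 0.5 * dt * a1, f0 + 0.5 * dt * b1, v0 + 0.5 * dt * c1, q0 + 0.5 * dt * d1,
                xm[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            a3, b3, c3, d3 = _hderiv(
                s0 + 0.5 * dt * a2, f0 + 0.5 * dt * b2, v0 + 0.5 * dt * c2, q0 + 0.5 * dt * d2,
                xm[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            a4, b4, c4, d4 = _hderiv(
                s0 + dt * a3, f0 + dt * b3, v0 + dt * c3, q0 + dt * d3,
                x1[r], kappa[r], gamma[r], tau[r], ooa, E0, ln1mE0, eps[r],
            )
            h[r, 0] = s0 + dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            h[r, 1] = f0 + dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            h[r, 2] = v0 + dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            h[r, 3] = q0 + dt / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        for j in range(n):
            x[j] = x1[j]
        if (t + 1) % bps == 0:
            sc = (t + 1) // bps - 1
            for r in range(n):
                vq, qq = h[r, 2], h[r, 3]
                y[sc, r] = V0 * (k1 * (1.0 - qq) + k2 * (1.0 - qq / vq) + k3 * (1.0 - vq))
    return y


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    import numba

    # no fastmath: NaN propagation from unstable parameter draws must stay
    # well-defined so the inversion's step-halving can react to it
    _hderiv = numba.njit(cache=True, inline="always")(_hderiv_py)
    _propagate = numba.njit(cache=True)(_propagate_py)
    _propagate_scan = numba.njit(cache=True)(_propagate_scan_py)
except ImportError:  # pragma: no cover
    _hderiv = _hderiv_py
    _propagate = _propagate_py
    _propagate_scan = _propagate_scan_py


def _bin_updates(
    p: NeuralParams, u_unique: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact affine neuronal updates per distinct input value (full/half bin)."""
    K, m = u_unique.shape
    n = p.A.shape[0]
    Ed = np.empty((K, n, n))
    gd = np.empty((K, n))
    Eh = np.empty((K, n, n))
    gh = np.empty((K, n))
    for k in range(K):
        u = u_unique[k]
        M = p.A + np.tensordot(p.B, u, axes=([2], [0]))
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = M
        aug[:n, n] = p.C @ u
        full = expm(aug * dt)
        half = expm(aug * (dt / 2.0))
        Ed[k], gd[k] = full[:n, :n], full[:n, n]
        Eh[k], gh[k] = half[:n, :n], half[:n, n]
    return Ed, gd, Eh, gh


def _run_kernel(p: DCMParams, inputs: InputSet):
    u_unique, uidx = inputs.piecewise_constant()
    Ed, gd, Eh, gh = _bin_updates(p.neural, u_unique, inputs.dt_micro)
    k1, k2, k3 = _bold_constants(p.hemo.E0)
    n = p.neural.A.shape[0]
    hemo = p.hemo
    return _propagate(
        Ed,
        gd,
        Eh,
        gh,
        uidx,
        inputs.dt_micro,
        np.broadcast_to(hemo.kappa, (n,)).astype(float).copy(),
        np.broadcast_to(hemo.gamma, (n,)).astype(float).copy(),
        np.broadcast_to(hemo.tau, (n,)).astype(float).copy(),
        float(hemo.alpha),
        float(hemo.E0),
        np.broadcast_to(hemo.epsilon, (n,)).astype(float).copy(),
        k1,
        k2,
        k3,
        _V0,
    )


def _check_stable(A: np.ndarray) -> None:
    if np.max(np.linalg.eigvals(A).real) >= 0:
        raise ValueError("endogenous coupling matrix A is not stable (Re eig >= 0)")


def integrate_states(p: DCMParams, inputs: InputSet) -> dict[str, np.ndarray]:
    """Integrate neuronal and hemodynamic states on the microtime grid.

    Returns a dict with ``t`` (bin-end times), ``x`` (T, n) neuronal states,
    ``hemo`` (T, n, 4) hemodynamic states (s, f, v, q) and ``bold_micro``.
    Rejects an unstable A before integrating.
    """
    _check_stable(p.neural.A)
    x_all, h_all, bold = _run_kernel(p, inputs)
    t = (np.arange(inputs.n_micro) + 1) * inputs.dt_micro
    return {"t": t, "x": x_all, "hemo": h_all, "bold_micro": bold}


def _scan_indices(inputs: InputSet) -> np.ndarray:
    bps = inputs.bins_per_scan
    return np.arange(1, inputs.n_scans + 1) * bps - 1


def predict_bold(p: DCMParams, inputs: InputSet, check_stability: bool = True) -> BOLDSeries:
    """Noiseless BOLD prediction at scan times (end of each TR)."""
    if check_stability:
        _check_stable(p.neural.A)
    u_unique, uidx = inputs.piecewise_constant()
    Ed, gd, Eh, gh = _bin_updates(p.neural, u_unique, inputs.dt_micro)
    k1, k2, k3 = _bold_constants(p.hemo.E0)
    n = p.neural.A.shape[0]
    hemo = p.hemo
    y = _propagate_scan(
        Ed,
        gd,
        Eh,
        gh,
        uidx,
        inputs.dt_micro,
        np.broadcast_to(hemo.kappa, (n,)).astype(float).copy(),
        np.broadcast_to(hemo.gamma, (n,)).astype(float).copy(),
        np.broadcast_to(hemo.tau, (n,)).astype(float).copy(),
        float(hemo.alpha),
        float(hemo.E0),
        np.broadcast_to(hemo.epsilon, (n,)).astype(float).copy(),
        k1,
        k2,
        k3,
        _V0,
        inputs.bins_per_scan,
    )
    return BOLDSeries(y=y[: inputs.n_scans], tr=inputs.tr)


def simulate_bold(
    p: DCMParams, inputs: InputSet, seed: int | np.random.Generator = 0
) -> BOLDSeries:
    """Noisy synthetic BOLD: prediction + i.i.d. Gaussian scan noise."""
    pred = predict_bold(p, inputs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = np.broadcast_to(np.asarray(p.noise_sd, dtype=float), (pred.y.shape[1],))
    y = pred.y + rng.standard_normal(pred.y.shape) * sd
    return BOLDSeries(y=y, tr=pred.tr)


def noise_sd_for_snr(p: DCMParams, inputs: InputSet, snr: float = 3.0) -> np.ndarray:
    """Per-region noise SD giving the requested SNR (temporal SD of the
    noiseless signal divided by noise SD)."""
    pred = predict_bold(p, inputs)
    return pred.y.std(axis=0) / snr


# ---------------------------------------------------------------------------
# I/O


def write_bold(series: BOLDSeries, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(series.y, columns=list(series.nodes)).to_csv(path, index=False)
    sidecar = {"tr": series.tr, "nodes": list(series.nodes)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bold(path: str | Path) -> BOLDSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    y = pd.read_csv(path).to_numpy(dtype=float)
    return BOLDSeries(y=y, tr=meta["tr"], nodes=tuple(meta["nodes"]))
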