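"""Exogenous DCM inputs from a session design.

The three condition blocks are recoded into *nested* predictors:

* ``MOTION`` — on during every block (all moving stimuli),
* ``UNPREDICTABLE`` — on during RANDOM and ARBITRARY blocks,
* ``ARBITRARY`` — on during ARBITRARY blocks only,

so that ``ARBITRARY <= UNPREDICTABLE <= MOTION`` pointwise and each
predictor expresses the *additional* effect of one step down in
predictability. Inputs are unit boxcars on a microtime grid of
``tr / microtime_bins_per_scan`` seconds, zero during baselines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import Condition, SessionDesign

__all__ = ["InputSet", "build_inputs", "write_inputs", "read_inputs", "canonical_hrf"]

INPUT_NAMES = ("MOTION", "UNPREDICTABLE", "ARBITRARY")

#: conditions each nested predictor is "on" for
_PREDICTOR_CONDITIONS = {
    "MOTION": {Condition.PREDICTABLE, Condition.RANDOM, Condition.ARBITRARY},
    "UNPREDICTABLE": {Condition.RANDOM, Condition.ARBITRARY},
    "ARBITRARY": {Condition.ARBITRARY},
}


@dataclass
class InputSet:
    """m = 3 binary input functions on the microtime grid."""

    u: np.ndarray  # (T_micro, 3) in {0, 1}
    dt_micro: float  # s
    names: tuple[str, ...] = INPUT_NAMES
    n_scans: int = 512
    tr: float = 1.8

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2 or self.u.shape[1] != len(self.names):
            raise ValueError("u must be (T_micro, m)")

    @property
    def n_micro(self) -> int:
        return self.u.shape[0]

    @property
    def bins_per_scan(self) -> int:
        return int(round(self.tr / self.dt_micro))

    def on_seconds(self) -> np.ndarray:
        """Total 'on' time of each input (column sum x dt)."""
        return self.u.sum(axis=0) * self.dt_micro

    def piecewise_constant(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct input rows and the per-bin index into them (cached).

        The boxcar inputs take only a handful of distinct values, so
        integrators can precompute one exact update per distinct value.
        """
        cached = getattr(self, "_pwc", None)
        if cached is None:
            u_unique, uidx = np.unique(self.u, axis=0, return_inverse=True)
            cached = (u_unique, uidx.astype(np.int64).ravel())
            object.__setattr__(self, "_pwc", cached)
        return cached


def build_inputs(
    session: SessionDesign,
    dt_micro: float | None = None,
    n_scans: int = 512,
    tr: float = 1.8,
    microtime_bins_per_scan: int = 16,
) -> InputSet:
    """Rasterize a session into the nested boxcar inputs.

    A microtime bin is "on" when its midpoint falls inside a block. Blocks
    extending past the scan window (``n_scans * tr``) are truncated with a
    warning — with 30 blocks plus baselines the nominal session is slightly
    longer than the 512-scan acquisition window.
    """
    if dt_micro is None:
        dt_micro = tr / microtime_bins_per_scan
    bins_per_scan = tr / dt_micro
    if abs(bins_per_scan - round(bins_per_scan)) > 1e-9:
        raise ValueError("dt_micro must divide tr")
    t_total = n_scans * tr
    n_micro = n_scans * int(round(bins_per_scan))
    mid = (np.arange(n_micro) + 0.5) * dt_micro

    u = np.zeros((n_micro, 3))
    truncated = False
    for b in session.blocks:
        if b.onset + b.duration > t_total + 1e-9:
            truncated = True
        lo, hi = b.onset, min(b.onset + b.duration, t_total)
        if hi <= lo:
            continue
        on = (mid >= lo) & (mid < hi)
        for j, name in enumerate(INPUT_NAMES):
            if b.condition in _PREDICTOR_CONDITIONS[name]:
                u[on, j] = 1.0
    if truncated:
        warnings.warn(
            "session extends past the scan window; trailing block(s) truncated",
            stacklevel=2,
        )
    return InputSet(u=u, dt_micro=dt_micro, n_scans=n_scans, tr=tr)


def write_inputs(inputs: InputSet, path: str | Path) -> None:
    """Write u as CSV (T x 3) with a JSON sidecar next to it."""
    path = Path(path)
    pd.DataFrame(inputs.u, columns=list(inputs.names)).to_csv(path, index=False)
    sidecar = {
        "dt_micro": inputs.dt_micro,
        "names": list(inputs.names),
        "n_scans": inputs.n_scans,
        "tr": inputs.tr,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_inputs(path: str | Path) -> InputSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    u = pd.read_csv(path).to_numpy(dtype=float)
    return InputSet(
        u=u,
        dt_micro=meta["dt_micro"],
        names=tuple(meta["names"]),
        n_scans=meta["n_scans"],
        tr=meta["tr"],
    )


def canonical_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function sampled at dt.

    Peak at ~6 s with an undershoot at ~16 s; normalized to unit sum. Used
    only for GLM-style sanity plots — the DCM itself uses the nonlinear
    hemodynamic forward model.
    """
    from scipy.stats import gamma

    t = np.arange(0.0, length, dt)
    h = gamma.pdf(t, 6.0) - gamma.pdf(t, 16.0) / 6.0
    return h / h.sum()
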