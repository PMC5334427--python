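"""Group-level fixed-effects Bayesian model selection and parameter pooling.

Fixed-effects BMS assumes every subject's data arose from the same model
structure: group log-evidence of a model is the sum of its per-subject
free energies, and posterior model probabilities follow by softmax under a
uniform model prior. Occam's window keeps the models with non-negligible
posterior probability; their parameters are pooled by Bayesian parameter
averaging (precision-weighted fixed-effects combination of the Gaussian
subject posteriors), and credible intervals are corrected for multiplicity
by Bonferroni-adjusted quantiles of samples drawn from the averaged
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .invert import Posterior

__all__ = [
    "EvidenceTable",
    "BMSResult",
    "BPAResult",
    "ffx_bms",
    "occams_window",
    "bayesian_parameter_average",
    "corrected_intervals",
    "report_markdown",
]


@dataclass
class EvidenceTable:
    """Free energies, subjects x models."""

    F: np.ndarray  # (n_subjects, n_models)
    model_ids: list[str]
    families: list[str] | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.F.shape[1] != len(self.model_ids):
            raise ValueError("F columns must match model_ids")
        if self.families is not None and len(self.families) != len(self.model_ids):
            raise ValueError("families must match model_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, columns=self.model_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, families: list[str] | None = None) -> "EvidenceTable":
        return cls(df.to_numpy(dtype=float), list(df.columns), families)


@dataclass
class BMSResult:
    model_ids: list[str]
    group_log_evidence: np.ndarray  # column sums of F
    posterior_prob: np.ndarray  # normalized over all models
    family_prob: dict[str, float] | None = None
    occam_threshold: float = 0.01

    @property
    def winner(self) -> str:
        return self.model_ids[int(np.argmax(self.posterior_prob))]

    def occam_set(self) -> list[str]:
        return occams_window(self, self.occam_threshold)

    def window_renormalized(self) -> dict[str, float]:
        """Posterior probabilities renormalized within Occam's window."""
        ids = self.occam_set()
        idx = [self.model_ids.index(i) for i in ids]
        p = self.posterior_prob[idx]
        return dict(zip(ids, p / p.sum()))

    def to_dict(self) -> dict:
        out = {
            "model_ids": self.model_ids,
            "group_log_evidence": self.group_log_evidence.tolist(),
            "posterior_prob": self.posterior_prob.tolist(),
            "occam_threshold": self.occam_threshold,
            "occam_set": self.occam_set(),
            "occam_renormalized": self.window_renormalized(),
        }
        if self.family_prob is not None:
            out["family_prob"] = self.family_prob
        return out


def ffx_bms(
    ev: EvidenceTable, occam_threshold: float = 0.01, on_nan: str = "raise"
) -> BMSResult:
    """Fixed-effects BMS: sum free energies over subjects, softmax over
    models (uniform model prior).

    ``on_nan``: "raise" aborts on any non-finite evidence; "drop" discards
    subjects with non-finite rows (with a warning).
    """
    F = ev.F
    if F.shape[0] < 1 or F.shape[1] < 2:
        raise ValueError("need at least one subject and two models")
    finite_rows = np.all(np.isfinite(F), axis=1)
    if not np.all(finite_rows):
        if on_nan == "drop":
            import warnings

            warnings.warn(f"dropping {int((~finite_rows).sum())} subject(s) with non-finite F")
            F = F[finite_rows]
            if F.shape[0] == 0:
                raise ValueError("no subjects left after dropping non-finite rows")
        else:
            raise ValueError("non-finite free energies in evidence table")
    group = F.sum(axis=0)
    z = group - group.max()
    p = np.exp(z)
    p /= p.sum()
    family_prob = None
    if ev.families is not None:
        family_prob = {}
        for fam in sorted(set(ev.families)):
            family_prob[fam] = float(p[[f == fam for f in ev.families]].sum())
    return BMSResult(
        model_ids=list(ev.model_ids),
        group_log_evidence=group,
        posterior_prob=p,
        family_prob=family_prob,
        occam_threshold=occam_threshold,
    )


def occams_window(result: BMSResult, threshold: float = 0.01) -> list[str]:
    """Models whose posterior probability exceeds ``threshold`` (always at
    least the best model)."""
    ids = [
        mid
        for mid, p in zip(result.model_ids, result.posterior_prob)
        if p > threshold
    ]
    if not ids:
        ids = [result.winner]
    return ids


@dataclass
class BPAResult:
    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    n_sources: int

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def __getitem__(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.mean[i]), float(np.sqrt(self.cov[i, i]))

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "mean": self.mean.tolist(),
            "sd": self.sd().tolist(),
            "n_sources": self.n_sources,
        }


def bayesian_parameter_average(posteriors: list[Posterior]) -> BPAResult:
    """Precision-weighted fixed-effects combination of Gaussian posteriors.

    Combined precision is the sum of the source precisions; the combined
    mean is the precision-weighted average. All sources must describe the
    same parameter vector.
    """
    if not posteriors:
        raise ValueError("no posteriors to average")
    names = list(posteriors[0].names)
    for p in posteriors[1:]:
        if list(p.names) != names:
            raise ValueError("posteriors describe different parameter sets")
    P = len(names)
    Pi = np.zeros((P, P))
    eta = np.zeros(P)
    for p in posteriors:
        prec = np.linalg.inv(p.cov)
        Pi += prec
        eta += prec @ p.mean
    cov = np.linalg.inv(Pi)
    mean = cov @ eta
    return BPAResult(names=names, mean=mean, cov=0.5 * (cov + cov.T), n_sources=len(posteriors))


def corrected_intervals(
    bpa: BPAResult,
    k: int = 13,
    alpha: float = 0.05,
    n_samples: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multiplicity-corrected credible intervals by posterior sampling.

    Draws ``n_samples`` from the averaged Gaussian posterior and takes the
    Bonferroni-adjusted empirical quantiles (alpha/k)/2 and 1-(alpha/k)/2
    per parameter; flags parameters whose corrected interval contains zero.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_samples < 1000:
        import warnings

        warnings.warn("fewer than 1000 samples; quantiles will be unstable")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(bpa.mean, bpa.cov, size=n_samples, method="cholesky")
    q = (alpha / k) / 2.0
    lo = np.quantile(draws, q, axis=0)
    hi = np.quantile(draws, 1.0 - q, axis=0)
    return pd.DataFrame(
        {
            "mean": bpa.mean,
            "sd": bpa.sd(),
            "lower": lo,
            "upper": hi,
            "excludes_zero": (lo > 0) | (hi < 0),
        },
        index=bpa.names,
    )


def report_markdown(
    bms: BMSResult, bpa: BPAResult | None = None, intervals: pd.DataFrame | None = None
) -> str:
    """Human-readable summary: winner, Occam's window, averaged couplings."""
    lines = ["# Model selection report", ""]
    lines.append(f"Winning model: `{bms.winner}` "
                 f"(posterior {bms.posterior_prob.max():.4f})")
    lines.append("")
    lines.append(f"## Occam's window (threshold {bms.occam_threshold})")
    renorm = bms.window_renormalized()
    for mid in bms.occam_set():
        i = bms.model_ids.index(mid)
        lines.append(
            f"- `{mid}`: p = {bms.posterior_prob[i]:.4f} "
            f"(renormalized {renorm[mid]:.4f})"
        )
    if bms.family_prob:
        lines.append("")
        lines.append("## Family probabilities")
        for fam, p in bms.family_prob.items():
            lines.append(f"- {fam}: {p:.4f}")
    if bpa is not None:
        lines.append("")
        lines.append(f"## Averaged parameters ({bpa.n_sources} sessions pooled)")
        table = intervals if intervals is not None else None
        for i, name in enumerate(bpa.names):
            if table is not None:
                row = table.loc[name]
                star = "" if row["excludes_zero"] else " (n.s.)"
                lines.append(
                    f"- {name}: {bpa.mean[i]:+.3f} ± {bpa.sd()[i]:.3f} "
                    f"[{row['lower']:+.3f}, {row['upper']:+.3f}]{star}"
                )
            else:
                lines.append(f"- {name}: {bpa.mean[i]:+.3f} ± {bpa.sd()[i]:.3f}")
    return "\n".join(lines) + "\n"
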