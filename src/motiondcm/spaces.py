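"""Enumeration of the study's model spaces.

All models share the same endogenous skeleton over (V1, V5, PPC): self-
connections plus reciprocal V1<->V5 and V5<->PPC coupling (no direct
V1<->PPC edge), and every model carries the modulation of the V1->V5
connection by MOTION.

Three spaces are defined:

* the **main space** — three families of direct-input structures
  (A: MOTION->V1 + ARBITRARY->PPC; B: additionally MOTION->V5;
  C: additionally UNPREDICTABLE->V5 and ARBITRARY->V5), each crossed with
  the 2^(2x4) = 256 on/off combinations of UNPREDICTABLE and ARBITRARY
  modulating the four inter-node connections, and each of the resulting
  768 models replicated in three mutually exclusive synaptic-gain variants
  (no gain modulation, UNPREDICTABLE on the V5 self-connection, ARBITRARY
  on the V5 self-connection) — 2304 models;
* **pre-selection step 1** — 2^5 = 32 models varying the direct inputs
  MOTION->V1 and {UNPREDICTABLE, ARBITRARY}->{V5, PPC}, with all candidate
  modulations switched on;
* **pre-selection step 2** — the step-1 winner against the three variants
  that add MOTION->V5 and/or MOTION->PPC.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import DCMSpec

__all__ = [
    "ModelSpace",
    "skeleton_a_mask",
    "build_main_space",
    "build_preselect1_space",
    "build_preselect2_space",
    "build_demo_space",
    "exhaustive_count",
]

# node indices
V1, V5, PPC = 0, 1, 2
# input indices
MOTION, UNPRED, ARB = 0, 1, 2

#: the four inter-node connections, as (to, from) index pairs
EDGES = ((V5, V1), (PPC, V5), (V1, V5), (V5, PPC))

_FAMILY_DIRECT = {
    "A": ((V1, MOTION), (PPC, ARB)),
    "B": ((V1, MOTION), (V5, MOTION), (PPC, ARB)),
    "C": ((V1, MOTION), (V5, MOTION), (V5, UNPRED), (V5, ARB), (PPC, ARB)),
}

_GAIN_VARIANTS = {"none": None, "gain_unpredictable": UNPRED, "gain_arbitrary": ARB}


@dataclass
class ModelSpace:
    models: list[DCMSpec]
    description: str  # main | preselect1 | preselect2 | demo

    def __post_init__(self) -> None:
        keys = {m.mask_key for m in self.models}
        if len(keys) != len(self.models):
            raise ValueError("duplicate models in space")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def family_of(self, model_id: str) -> str:
        return next(m.family for m in self.models if m.model_id == model_id)

    def index(self) -> pd.DataFrame:
        """CSV-friendly index: id, family, gain variant, free-parameter counts."""
        rows = []
        for m in self.models:
            rows.append(
                {
                    "id": m.model_id,
                    "family": m.family,
                    "gain_variant": m.gain_variant,
                    "n_free_neural": int(
                        m.a_mask.sum() + m.b_masks.sum() + m.c_mask.sum()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.models:
                fh.write(json.dumps(m.to_dict(), separators=(",", ":")) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path, description: str = "") -> "ModelSpace":
        models = [DCMSpec.from_dict(json.loads(line)) for line in open(path)]
        return cls(models, description)


def skeleton_a_mask(n: int = 3) -> np.ndarray:
    """Endogenous structure: self-connections + reciprocal V1<->V5, V5<->PPC."""
    a = np.eye(n, dtype=bool)
    for to, frm in EDGES:
        a[to, frm] = True
    return a


def _base_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = skeleton_a_mask()
    b = np.zeros((3, 3, 3), dtype=bool)
    b[V5, V1, MOTION] = True  # mandatory: MOTION modulates V1 -> V5
    c = np.zeros((3, 3), dtype=bool)
    return a, b, c


def build_main_space() -> ModelSpace:
    """The 2304-model main space: 3 families x 256 modulation patterns x 3
    synaptic-gain variants."""
    models: list[DCMSpec] = []
    for fam, direct in _FAMILY_DIRECT.items():
        for pattern in itertools.product((False, True), repeat=2 * len(EDGES)):
            for gname, ginput in _GAIN_VARIANTS.items():
                a, b, c = _base_masks()
                for node, inp in direct:
                    c[node, inp] = True
                it = iter(pattern)
                for inp in (UNPRED, ARB):
                    for to, frm in EDGES:
                        if next(it):
                            b[to, frm, inp] = True
                if ginput is not None:
                    b[V5, V5, ginput] = True
                models.append(
                    DCMSpec(a_mask=a, b_masks=b, c_mask=c, family=fam, gain_variant=gname)
                )
    return ModelSpace(models, "main")


def build_preselect1_space() -> ModelSpace:
    """Step-1 pre-selection: all 32 combinations of the candidate direct
    inputs, with every candidate modulation switched on."""
    candidates = ((V1, MOTION), (V5, UNPRED), (V5, ARB), (PPC, UNPRED), (PPC, ARB))
    models: list[DCMSpec] = []
    for bits in itertools.product((False, True), repeat=len(candidates)):
        a, b, c = _base_masks()
        for inp in (UNPRED, ARB):
            for to, frm in EDGES:
                b[to, frm, inp] = True
        for on, (node, inp) in zip(bits, candidates):
            if on:
                c[node, inp] = True
        models.append(DCMSpec(a_mask=a, b_masks=b, c_mask=c, family="preselect1"))
    return ModelSpace(models, "preselect1")


def build_preselect2_space(winner: DCMSpec) -> ModelSpace:
    """Step-2 pre-selection: the step-1 winner vs. adding MOTION->V5 and/or
    MOTION->PPC as direct inputs."""
    models: list[DCMSpec] = []
    for v5_on, ppc_on in itertools.product((False, True), repeat=2):
        c = winner.c_mask.copy()
        if v5_on:
            c[V5, MOTION] = True
        if ppc_on:
            c[PPC, MOTION] = True
        models.append(
            replace(winner, c_mask=c, family="preselect2", gain_variant=winner.gain_variant)
        )
    return ModelSpace(models, "preselect2")


def build_demo_space() -> ModelSpace:
    """Desk-scale 16-model subspace for pipeline smoke tests and recovery
    experiments: family-B direct inputs, no gain variant, and the 2^4
    combinations of UNPREDICTABLE/ARBITRARY modulating the two forward
    connections (V1->V5, V5->PPC). Contains the winning model of the
    overt-response run."""
    forward_edges = ((V5, V1), (PPC, V5))
    models: list[DCMSpec] = []
    for pattern in itertools.product((False, True), repeat=4):
        a, b, c = _base_masks()
        for node, inp in _FAMILY_DIRECT["B"]:
            c[node, inp] = True
        it = iter(pattern)
        for inp in (UNPRED, ARB):
            for to, frm in forward_edges:
                if next(it):
                    b[to, frm, inp] = True
        models.append(DCMSpec(a_mask=a, b_masks=b, c_mask=c, family="B", gain_variant="none"))
    return ModelSpace(models, "demo")


def exhaustive_count(n: int, m: int) -> int:
    """Size of the exhaustive space of n-node, m-input bilinear models:
    2^((n*n)*(m+1) + m*n) on/off choices over A, the m B matrices and C."""
    if n < 1 or m < 0:
        raise ValueError("require n >= 1, m >= 0")
    return 2 ** ((n * n) * (m + 1) + m * n)
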