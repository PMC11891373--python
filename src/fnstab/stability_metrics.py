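"""The four fracture-stability metrics extracted from a mechanics solution.

* construct stiffness: applied load magnitude over the displacement of the
  load reference point projected on the load direction (N/mm);
* MIVS: maximum implant von Mises stress (MPa) — yield-risk proxy;
* MISS: maximum interfragmentary shear stress (MPa) — tangential traction
  peak on the fracture interface;
* MIG: maximum interfragmentary gap (mm) — peak normal-direction opening;
  compressed pairs contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mesh
from .construct_mechanics import SolutionField, LoadCase, interface_tractions

__all__ = [
    "MetricRecord",
    "MetricTable",
    "construct_stiffness",
    "max_implant_von_mises",
    "max_interfragmentary_shear",
    "max_interfragmentary_gap",
    "extract_metrics",
]

METRIC_COLUMNS = ["stiffness_N_mm", "mivs_MPa", "miss_MPa", "mig_mm"]


@dataclass(frozen=True)
class MetricRecord:
    model_label: str
    stiffness_N_mm: float
    mivs_MPa: float
    miss_MPa: float
    mig_mm: float

    def __post_init__(self):
        vals = [self.stiffness_N_mm, self.mivs_MPa, self.miss_MPa, self.mig_mm]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"{self.model_label}: non-finite metric")
        if self.stiffness_N_mm <= 0:
            raise ValueError(f"{self.model_label}: stiffness must be positive")
        if min(self.mivs_MPa, self.miss_MPa, self.mig_mm) < 0:
            raise ValueError(f"{self.model_label}: stresses and gap must be nonnegative")


@dataclass
class MetricTable:
    records: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [r.model_label for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate model labels in metric table")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_label": r.model_label,
                    **{c: getattr(r, c) for c in METRIC_COLUMNS},
                }
                for r in self.records
            ]
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "MetricTable":
        df = pd.read_csv(path_or_buf)
        missing = {"model_label", *METRIC_COLUMNS} - set(df.columns)
        if missing:
            raise ValueError(f"metric CSV missing columns: {sorted(missing)}")
        recs = [
            MetricRecord(
                model_label=str(r.model_label),
                stiffness_N_mm=float(r.stiffness_N_mm),
                mivs_MPa=float(r.mivs_MPa),
                miss_MPa=float(r.miss_MPa),
                mig_mm=float(r.mig_mm),
            )
            for r in df.itertuples()
        ]
        return cls(records=recs)


def construct_stiffness(load: LoadCase, solution: SolutionField) -> float:
    """Load magnitude divided by the load-direction displacement of the
    area-weighted load patch centroid."""
    if load.magnitude_N <= 0:
        raise ValueError("load magnitude must be positive")
    w = solution.meta.get("patch_weights")
    d = solution.meta.get("direction")
    if w is None or d is None:
        raise ValueError("solution does not carry a load patch (fixture drive?)")
    u_ref = w @ solution.u_mm
    delta = float(u_ref @ d)
    if delta <= 0:
        raise ValueError(f"non-physical load-point displacement {delta:.3g} mm")
    return load.magnitude_N / delta


def max_implant_von_mises(solution: SolutionField, implant_mask: np.ndarray):
    """Peak von Mises stress over implant elements, with its element id."""
    idx = np.flatnonzero(implant_mask)
    if idx.size == 0:
        raise ValueError("empty implant element set")
    vm = solution.von_mises_MPa[idx]
    k = int(np.argmax(vm))
    return float(vm[k]), int(idx[k])


def max_interfragmentary_shear(solution: SolutionField, pair_tag: str = "fracture"):
    """Peak tangential traction magnitude over the fracture pairs."""
    _, tau, _ = interface_tractions(solution, pair_tag)
    if len(tau) == 0:
        raise ValueError("fracture interface has no pairs")
    k = int(np.argmax(tau))
    return float(tau[k]), k


def max_interfragmentary_gap(solution: SolutionField, pair_tag: str = "fracture"):
    """Peak positive normal opening across the fracture pairs (compressed
    pairs contribute zero)."""
    _, _, gap = interface_tractions(solution, pair_tag)
    if len(gap) == 0:
        raise ValueError("fracture interface has no pairs")
    opening = np.maximum(gap, 0.0)
    k = int(np.argmax(opening))
    return float(opening[k]), k


def extract_metrics(
    label: str,
    mesh: _mesh.VolumeMesh,
    load: LoadCase,
    solution: SolutionField,
) -> MetricRecord:
    """All four metrics for one solved construct."""
    mivs, _ = max_implant_von_mises(solution, mesh.implant_mask())
    miss, _ = max_interfragmentary_shear(solution)
    mig, _ = max_interfragmentary_gap(solution)
    return MetricRecord(
        model_label=label,
        stiffness_N_mm=construct_stiffness(load, solution),
        mivs_MPa=mivs,
        miss_MPa=miss,
        mig_mm=mig,
    )
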