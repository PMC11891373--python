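"""FNS placement configurations and construct-frame geometry.

The Femoral Neck System (FNS) bolt is normally inserted along the femoral
neck axis.  Intraoperatively its placement can deviate in four ways: the
bolt length, a superior/inferior offset of the entry point along the shaft
axis, and the axis-bolt angle (ABA) measured in the anteroposterior view
(``alpha``, coronal plane) and the lateral view (``beta``, sagittal plane).
This module defines the standard placement, the 17-member positional grid
(standard + four single-factor families), and the mapping from a
configuration to a concrete bolt axis and fracture plane in construct
coordinates.

Coordinate convention (right-handed): shaft axis = +Z (proximal up),
anterior = +Y, lateral = +X.  The coronal (AP-view) plane is XZ, the
sagittal (lateral-view) plane is YZ.  Lengths in mm, angles in degrees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FNSConfiguration",
    "FracturePlane",
    "NeckAxis",
    "standard_configuration",
    "configuration_grid",
    "implant_axis",
    "aba_angles",
    "fracture_plane",
    "containment_report",
    "grid_to_csv",
    "grid_from_csv",
]

#: grid families (deltas from the standard model; one factor varies per model)
BOLT_LENGTHS_MM = (75.0, 80.0, 85.0, 90.0, 95.0)
OFFSETS_MM = (5.0, 0.0, -5.0, -10.0, -15.0)
ALPHAS_DEG = (3.0, 0.0, -3.0, -6.0, -9.0)
BETAS_DEG = (10.0, 5.0, 0.0, -5.0, -10.0)

STANDARD_BOLT_LENGTH_MM = 95.0
PRESLIDE_MM = 10.0


@dataclass(frozen=True)
class FNSConfiguration:
    """One FNS placement: bolt length plus three positional deltas.

    ``offset_mm`` moves the entry point along the shaft axis (positive =
    superior).  ``alpha_deg`` tilts the bolt in the AP view (positive =
    outward, i.e. steeper), ``beta_deg`` in the lateral view (positive =
    anterior).  ``preslide_mm`` is the fixed 10 mm presliding displacement
    of the bolt relative to the plate barrel.
    """

    label: str
    bolt_length_mm: float = STANDARD_BOLT_LENGTH_MM
    offset_mm: float = 0.0
    alpha_deg: float = 0.0
    beta_deg: float = 0.0
    preslide_mm: float = PRESLIDE_MM

    def deltas(self) -> dict:
        """Non-standard fields of this configuration."""
        out = {}
        if self.bolt_length_mm != STANDARD_BOLT_LENGTH_MM:
            out["bolt_length_mm"] = self.bolt_length_mm
        if self.offset_mm != 0.0:
            out["offset_mm"] = self.offset_mm
        if self.alpha_deg != 0.0:
            out["alpha_deg"] = self.alpha_deg
        if self.beta_deg != 0.0:
            out["beta_deg"] = self.beta_deg
        return out

    def __post_init__(self):
        if self.bolt_length_mm <= 0:
            raise ValueError("bolt length must be positive")


@dataclass(frozen=True)
class NeckAxis:
    """A line: entry point on the lateral cortex plus a unit direction
    toward the femoral head center."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("direction must be a nonzero finite vector")
        object.__setattr__(self, "direction", d / n)

    def point(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class FracturePlane:
    """Planar fracture cut: anchor point, unit normal, and the Pauwels
    angle the plane makes with the horizontal reference plane."""

    anchor_point: np.ndarray
    normal: np.ndarray
    pauwels_angle_deg: float

    def __post_init__(self):
        object.__setattr__(self, "anchor_point", np.asarray(self.anchor_point, float))
        n = np.asarray(self.normal, float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("zero normal")
        object.__setattr__(self, "normal", n / nn)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.anchor_point) @ self.normal


def validate_grid(grid: list[FNSConfiguration]) -> None:
    """Grid sanity: unique labels and one varied factor per member."""
    labels = [c.label for c in grid]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in configuration grid")
    for c in grid:
        if len(c.deltas()) > 1:
            raise ValueError(
                f"{c.label!r}: a grid member may vary at most one factor "
                f"from the standard model, got {c.deltas()}"
            )


def standard_configuration() -> FNSConfiguration:
    """The standard model: 95 mm bolt along the neck axis, 10 mm preslide."""
    return FNSConfiguration(label="standard")


def configuration_grid() -> list[FNSConfiguration]:
    """The 17-model positional grid: standard + 4 lengths + 4 offsets +
    4 alpha + 4 beta, each non-standard member varying exactly one factor."""
    grid = [standard_configuration()]
    for L in BOLT_LENGTHS_MM:
        if L != STANDARD_BOLT_LENGTH_MM:
            grid.append(FNSConfiguration(label=f"len{L:g}", bolt_length_mm=L))
    for off in OFFSETS_MM:
        if off != 0.0:
            grid.append(FNSConfiguration(label=f"off{off:+g}", offset_mm=off))
    for a in ALPHAS_DEG:
        if a != 0.0:
            grid.append(FNSConfiguration(label=f"alpha{a:+g}", alpha_deg=a))
    for b in BETAS_DEG:
        if b != 0.0:
            grid.append(FNSConfiguration(label=f"beta{b:+g}", beta_deg=b))
    assert len(grid) == 17
    validate_grid(grid)
    return grid


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector")
    return v


def implant_axis(
    config: FNSConfiguration,
    neck: NeckAxis,
    shaft_direction: np.ndarray,
    coronal_normal: np.ndarray,
) -> NeckAxis:
    """Bolt axis for a configuration: translate the entry point by the
    offset along the shaft axis, then tilt the neck direction by alpha in
    the AP view and beta in the lateral view.

    The view normal used for the alpha rotation is the coronal normal
    re-orthogonalized against the neck direction, so that the two ABA
    rotations decouple exactly: the AP-projected angle equals alpha and
    the out-of-coronal elevation equals beta, to machine precision, even
    for an anteverted neck.
    """
    s = _check_unit(shaft_direction, "shaft_direction")
    nc = _check_unit(coronal_normal, "coronal_normal")
    if abs(s @ nc) > 1e-9:
        raise ValueError("coronal_normal must be perpendicular to shaft_direction")
    d0 = neck.direction
    if np.linalg.norm(np.cross(s, d0)) < 1e-9:
        raise ValueError("shaft and neck directions are parallel (degenerate frame)")

    # effective AP-view normal, orthogonal to the neck axis
    n_eff = nc - (nc @ d0) * d0
    n_eff = n_eff / np.linalg.norm(n_eff)

    d_alpha = _rotation_matrix(n_eff, config.alpha_deg) @ d0
    # transverse axis in the (rotated) coronal plane; beta > 0 tips anterior
    t = np.cross(d_alpha, n_eff)
    t = t / np.linalg.norm(t)
    if np.cross(t, d_alpha) @ nc < 0:
        t = -t
    d = _rotation_matrix(t, config.beta_deg) @ d_alpha
    origin = neck.origin + config.offset_mm * s
    return NeckAxis(origin=origin, direction=d / np.linalg.norm(d))


def aba_angles(
    axis_direction: np.ndarray, neck: NeckAxis, coronal_normal: np.ndarray
) -> tuple[float, float]:
    """Recover (alpha, beta) in degrees from a bolt direction, inverting
    the construction in :func:`implant_axis`."""
    d = _check_unit(axis_direction, "axis_direction")
    d0 = neck.direction
    nc = _check_unit(coronal_normal, "coronal_normal")
    n_eff = nc - (nc @ d0) * d0
    n_eff = n_eff / np.linalg.norm(n_eff)
    beta = np.rad2deg(np.arcsin(np.clip(d @ n_eff, -1, 1)))
    dp = d - (d @ n_eff) * n_eff
    dp = dp / np.linalg.norm(dp)
    cosa = np.clip(dp @ d0, -1, 1)
    sina = np.cross(d0, dp) @ n_eff
    alpha = np.rad2deg(np.arctan2(sina, cosa))
    return float(alpha), float(beta)


def fracture_plane(
    head_center: np.ndarray,
    horizontal_normal: np.ndarray,
    pauwels_angle_deg: float = 70.0,
    anchor_offset_mm: float = 15.0,
    tilt_axis: np.ndarray | None = None,
) -> FracturePlane:
    """Pauwels fracture plane: the horizontal plane through the femoral
    head center tilted by the Pauwels angle about an in-plane axis, then
    shifted ``anchor_offset_mm`` along its own normal so the cut crosses
    the mid neck rather than bisecting the head.

    ``pauwels_angle_deg`` must lie in (0, 90]; the dihedral angle between
    the returned plane and the horizontal plane equals it to 1e-9.
    """
    if not (0.0 < pauwels_angle_deg <= 90.0):
        raise ValueError("Pauwels angle must be in (0, 90] degrees")
    h = np.asarray(horizontal_normal, float)
    if np.linalg.norm(h) == 0:
        raise ValueError("zero normal")
    h = h / np.linalg.norm(h)
    if tilt_axis is None:
        # default tilt about the anterior axis: the fracture trace runs
        # inferomedial to superolateral in the AP view
        t = np.array([0.0, 1.0, 0.0])
        t = t - (t @ h) * h
        if np.linalg.norm(t) < 1e-9:
            t = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ h) * h
    else:
        t = np.asarray(tilt_axis, float)
        t = t - (t @ h) * h
        if np.linalg.norm(t) < 1e-9:
            raise ValueError("tilt axis parallel to horizontal normal")
    t = t / np.linalg.norm(t)
    n = _rotation_matrix(t, pauwels_angle_deg) @ h
    c = np.asarray(head_center, float)
    anchor = c + anchor_offset_mm * n
    return FracturePlane(anchor_point=anchor, normal=n, pauwels_angle_deg=pauwels_angle_deg)


@dataclass(frozen=True)
class ContainmentReport:
    tip_to_subchondral_mm: float
    inside_head: bool
    cortical_breach: bool


def containment_report(axis: NeckAxis, config: FNSConfiguration, femur_spec) -> ContainmentReport:
    """Placement guard on the surrogate geometry.

    The bolt tip sits ``bolt_length - preslide`` along the axis from the
    entry point.  ``tip_to_subchondral_mm`` is the remaining distance along
    the axis to the far (subchondral) head surface; ``inside_head`` is
    False when the tip lies outside the head sphere, ``cortical_breach``
    True when the tip passes beyond the subchondral surface.
    """
    c = np.asarray(femur_spec.head_center(), float)
    r = float(femur_spec.head_radius_mm)
    o, d = axis.origin, axis.direction
    oc = o - c
    b = oc @ d
    disc = b * b - (oc @ oc - r * r)
    if disc <= 0:
        raise ValueError("implant axis misses the femoral head sphere")
    t_far = -b + np.sqrt(disc)
    t_tip = config.bolt_length_mm - config.preslide_mm
    tip = axis.point(t_tip)
    inside = bool(np.linalg.norm(tip - c) < r)
    breach = bool(t_tip > t_far)
    return ContainmentReport(
        tip_to_subchondral_mm=float(t_far - t_tip),
        inside_head=inside,
        cortical_breach=breach,
    )


_GRID_COLUMNS = ["label", "bolt_length_mm", "offset_mm", "alpha_deg", "beta_deg"]


def grid_to_csv(grid: list[FNSConfiguration], path_or_buf) -> None:
    df = pd.DataFrame(
        [
            {
                "label": c.label,
                "bolt_length_mm": c.bolt_length_mm,
                "offset_mm": c.offset_mm,
                "alpha_deg": c.alpha_deg,
                "beta_deg": c.beta_deg,
            }
            for c in grid
        ],
        columns=_GRID_COLUMNS,
    )
    df.to_csv(path_or_buf, index=False)


def grid_from_csv(path_or_buf) -> list[FNSConfiguration]:
    df = pd.read_csv(path_or_buf)
    missing = set(_GRID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
    return [
        FNSConfiguration(
            label=str(r.label),
            bolt_length_mm=float(r.bolt_length_mm),
            offset_mm=float(r.offset_mm),
            alpha_deg=float(r.alpha_deg),
            beta_deg=float(r.beta_deg),
        )
        for r in df.itertuples()
    ]
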