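"""Parametric surrogate proximal femur, implant embedding and test fixtures.

The surrogate replaces the patient CT geometry with an analytically
checkable union of primitives: a spherical head, a capsule neck and a
cylindrical shaft, each with a cortical shell (points within the cortical
thickness of the outer surface) over a cancellous core.  A per-element
Hounsfield field is drawn from region-specific normal distributions using
a counter-based hash of the element's grid address, so fields are
bit-reproducible and stable under re-meshing of unchanged cells.

The module also provides the planted-weight decision-matrix generator used
to exercise the entropy ranking stage, and small closed-form mechanics
fixtures (axial rod, cantilever, two-block gap) that serve as oracles for
the finite-element backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _mesh as M
from .config_grid import (
    FNSConfiguration,
    FracturePlane,
    NeckAxis,
    containment_report,
)

__all__ = [
    "SurrogateFemurSpec",
    "ImplantDims",
    "HUField",
    "SyntheticDecisionSpec",
    "ToyFixture",
    "generate_surrogate_femur",
    "hounsfield_field",
    "apply_fracture_cut",
    "embed_implant",
    "generate_metric_table",
    "toy_fixture_cases",
    "box_mesh",
]


@dataclass(frozen=True)
class ImplantDims:
    """FNS hardware dimensions (mm) used by the surrogate embedding."""

    bolt_radius_mm: float = 5.0
    ars_radius_mm: float = 2.0
    ars_offset_mm: float = 8.5  # perpendicular superior offset of the screw
    ars_shorten_mm: float = 15.0  # antirotation screw is this much shorter
    plate_thickness_mm: float = 4.0
    plate_halfspan_deg: float = 25.0
    plate_above_mm: float = 9.0
    plate_below_mm: float = 25.0
    lock_radius_mm: float = 2.0
    lock_length_mm: float = 28.0
    lock_drop_mm: float = 15.0  # locking screw sits this far below the entry


@dataclass(frozen=True)
class SurrogateFemurSpec:
    """Geometry, material field and meshing parameters of the surrogate.

    Defaults follow standard adult proximal-femur anatomy (head radius
    24 mm, neck-shaft angle 130 deg, anteversion 15 deg).  The default HU
    means (cortical 1500 +- 100, cancellous 300 +- 50) yield apparent
    densities on both sides of the 1.2 g/cm^3 elasticity branch point.
    ``target_edge_length_mm * size_factor`` is the grid spacing; 1.5 mm
    mirrors the converged mesh density of the reference workflow, while
    coarser factors give desk-scale meshes.
    """

    head_radius_mm: float = 24.0
    neck_length_mm: float = 55.0
    neck_radius_mm: float = 13.0
    neck_shaft_angle_deg: float = 130.0
    anteversion_deg: float = 15.0
    cortical_thickness_mm: float = 4.0
    shaft_length_mm: float = 120.0
    shaft_outer_radius_mm: float = 15.0
    neck_base_drop_mm: float = 15.0
    hu_cortical_mean_sd: tuple = (1500.0, 100.0)
    hu_cancellous_mean_sd: tuple = (300.0, 50.0)
    target_edge_length_mm: float = 1.5
    size_factor: float = 1.0
    element_order: int = 10
    seed: int = 0
    implant: ImplantDims = field(default_factory=ImplantDims)
    min_quality: float = 0.02

    def __post_init__(self):
        for name in (
            "head_radius_mm",
            "neck_length_mm",
            "neck_radius_mm",
            "cortical_thickness_mm",
            "shaft_length_mm",
            "shaft_outer_radius_mm",
            "target_edge_length_mm",
            "size_factor",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.cortical_thickness_mm >= self.shaft_outer_radius_mm:
            raise ValueError("cortical thickness must be below the shaft radius")
        if self.element_order not in (1, 2):
            # order is expressed as polynomial order: 1 -> TET4, 2 -> TET10
            if self.element_order in (4, 10):
                object.__setattr__(
                    self, "element_order", 1 if self.element_order == 4 else 2
                )
            else:
                raise ValueError("element_order must be 4/10 (or 1/2)")

    # ---- construct frame -------------------------------------------------
    @property
    def h(self) -> float:
        return self.target_edge_length_mm * self.size_factor

    def shaft_direction(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def coronal_normal(self) -> np.ndarray:
        return np.array([0.0, 1.0, 0.0])

    def horizontal_normal(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def neck_direction(self) -> np.ndarray:
        polar = np.deg2rad(180.0 - self.neck_shaft_angle_deg)
        d0 = np.array([-np.sin(polar), 0.0, np.cos(polar)])
        phi = np.deg2rad(-self.anteversion_deg)
        R = np.array(
            [[np.cos(phi), -np.sin(phi), 0], [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]]
        )
        return R @ d0

    def neck_base(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.shaft_length_mm - self.neck_base_drop_mm])

    def head_center(self) -> np.ndarray:
        return self.neck_base() + self.neck_length_mm * self.neck_direction()

    def entry_point(self) -> np.ndarray:
        """Where the neck axis, extended laterally from the head center,
        exits the shaft outer surface."""
        c, d = self.head_center(), self.neck_direction()
        R = self.shaft_outer_radius_mm
        a = d[0] ** 2 + d[1] ** 2
        b = -2.0 * (c[0] * d[0] + c[1] * d[1])
        cc = c[0] ** 2 + c[1] ** 2 - R * R
        disc = b * b - 4 * a * cc
        if disc <= 0 or a == 0:
            raise ValueError("neck axis does not reach the shaft surface")
        t = (-b + np.sqrt(disc)) / (2 * a)  # lateral-side root
        p = c - t * d
        if not (0.0 <= p[2] <= self.shaft_length_mm):
            raise ValueError("neck-axis entry point misses the shaft segment")
        return p

    def neck_axis(self) -> NeckAxis:
        return NeckAxis(origin=self.entry_point(), direction=self.neck_direction())


@dataclass(frozen=True)
class HUField:
    """Per-element Hounsfield values over the bone elements of a mesh."""

    values: np.ndarray
    element_ids: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite Hounsfield value")
        if len(self.values) != len(self.element_ids):
            raise ValueError("values/element_ids length mismatch")


# ---------------------------------------------------------------------------
# counter-based gaussian draws (stable under re-meshing)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _hash_standard_normal(keys: np.ndarray, seed: int) -> np.ndarray:
    """One N(0,1) draw per uint64 key via hashed uniforms + Box-Muller."""
    k = keys.astype(np.uint64) ^ _splitmix64(np.uint64(seed) * np.ones(1, np.uint64))
    u1 = (_splitmix64(k) >> np.uint64(11)).astype(float) * 2.0**-53
    u2 = (_splitmix64(k ^ np.uint64(0xDEADBEEFCAFEF00D)) >> np.uint64(11)).astype(
        float
    ) * 2.0**-53
    u1 = np.clip(u1, 1e-300, 1.0)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


def _element_keys(mesh: M.VolumeMesh) -> np.ndarray:
    """Grid-lattice address of every element as a uint64 key, independent
    of the particular bounding box used to mesh it."""
    h = mesh.meta["h"]
    origin = mesh.meta["origin"]
    shift = np.rint(origin / h).astype(np.int64)
    abs_cell = mesh.cell_index.astype(np.int64) + shift
    x = (abs_cell + np.int64(1 << 18)).astype(np.uint64)  # 19 bits per axis
    key = ((x[:, 0] << np.uint64(19)) | x[:, 1]) << np.uint64(19) | x[:, 2]
    return (key << np.uint64(3)) | mesh.cell_tet.astype(np.uint64)


def hounsfield_field(mesh: M.VolumeMesh, spec: SurrogateFemurSpec | None = None) -> HUField:
    """Draw the per-element HU field for the bone elements of ``mesh``."""
    if spec is None:
        spec = mesh.meta["spec"]
    bone_ids = np.flatnonzero(mesh.bone_mask())
    z = _hash_standard_normal(_element_keys(mesh)[bone_ids], spec.seed)
    cort = mesh.region[bone_ids] == M.CORTICAL
    mean = np.where(cort, spec.hu_cortical_mean_sd[0], spec.hu_cancellous_mean_sd[0])
    sd = np.where(cort, spec.hu_cortical_mean_sd[1], spec.hu_cancellous_mean_sd[1])
    return HUField(values=mean + sd * z, element_ids=bone_ids)


# ---------------------------------------------------------------------------
# geometry classification


def _bone_classify(spec: SurrogateFemurSpec, pts: np.ndarray):
    """(inside, depth-to-outer-surface, part) for bone primitives."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    R, L = spec.shaft_outer_radius_mm, spec.shaft_length_mm
    rho = np.hypot(x, y)
    shaft_in = (rho <= R) & (z >= 0.0) & (z <= L)
    shaft_depth = np.where(shaft_in, R - rho, -np.inf)

    c = spec.head_center()
    r_head = np.linalg.norm(pts - c, axis=1)
    head_in = r_head <= spec.head_radius_mm
    head_depth = np.where(head_in, spec.head_radius_mm - r_head, -np.inf)

    base, d = spec.neck_base(), spec.neck_direction()
    t = np.clip((pts - base) @ d, 0.0, spec.neck_length_mm)
    q = base + t[:, None] * d
    dn = np.linalg.norm(pts - q, axis=1)
    neck_in = dn <= spec.neck_radius_mm
    neck_depth = np.where(neck_in, spec.neck_radius_mm - dn, -np.inf)

    inside = shaft_in | head_in | neck_in
    depth = np.maximum(shaft_depth, np.maximum(head_depth, neck_depth))
    part = np.full(len(pts), M.NECK_PART, dtype=np.int8)
    part[head_in] = M.HEAD_PART
    part[shaft_in] = M.SHAFT_PART  # shaft wins at junctions: never cut
    return inside, depth, part


def _cylinder_mask(pts, origin, direction, s_min, s_max, radius):
    rel = pts - origin
    s = rel @ direction
    radial = rel - s[:, None] * direction
    return (s >= s_min) & (s <= s_max) & (np.linalg.norm(radial, axis=1) <= radius)


def _implant_classify(
    spec: SurrogateFemurSpec, config: FNSConfiguration, axis: NeckAxis, pts: np.ndarray
):
    """Region code per point (-1 where not inside any implant part).

    Thin parts (screws, plate shell) get a minimum effective thickness of
    about one grid cell so they stay resolved on coarse meshes."""
    dims = spec.implant
    d, o = axis.direction, axis.origin
    out = np.full(len(pts), -1, dtype=np.int8)
    h = spec.h
    r_ars = max(dims.ars_radius_mm, 0.6 * h)
    r_lock = max(dims.lock_radius_mm, 0.6 * h)
    th_plate = max(dims.plate_thickness_mm, 0.8 * h)

    entry_phi = np.arctan2(o[1], o[0])
    R = spec.shaft_outer_radius_mm
    rho = np.hypot(pts[:, 0], pts[:, 1])
    dphi = np.angle(np.exp(1j * (np.arctan2(pts[:, 1], pts[:, 0]) - entry_phi)))
    plate = (
        (rho > R)
        & (rho <= R + th_plate)
        & (np.abs(dphi) <= np.deg2rad(dims.plate_halfspan_deg))
        & (pts[:, 2] >= o[2] - dims.plate_below_mm)
        & (pts[:, 2] <= o[2] + dims.plate_above_mm)
    )
    out[plate] = M.PLATE

    lock_tip = np.array(
        [
            (R + th_plate) * np.cos(entry_phi),
            (R + th_plate) * np.sin(entry_phi),
            o[2] - dims.lock_drop_mm,
        ]
    )
    lock_dir = np.array([-np.cos(entry_phi), -np.sin(entry_phi), 0.0])
    lock = _cylinder_mask(pts, lock_tip, lock_dir, 0.0, dims.lock_length_mm, r_lock)
    out[lock] = M.LOCKSCREW

    sup = spec.shaft_direction() - (spec.shaft_direction() @ d) * d
    sup = sup / np.linalg.norm(sup)
    o_ars = o + dims.ars_offset_mm * sup
    L_ars = config.bolt_length_mm - dims.ars_shorten_mm
    ars = _cylinder_mask(
        pts, o_ars, d, -config.preslide_mm, L_ars - config.preslide_mm, r_ars
    )
    out[ars] = M.ARS

    bolt = _cylinder_mask(
        pts,
        o,
        d,
        -config.preslide_mm,
        config.bolt_length_mm - config.preslide_mm,
        dims.bolt_radius_mm,
    )
    out[bolt] = M.BOLT
    return out


def _implant_bbox(spec, config, axis):
    dims = spec.implant
    ends = [
        axis.point(-config.preslide_mm),
        axis.point(config.bolt_length_mm - config.preslide_mm),
    ]
    pad = dims.bolt_radius_mm + dims.ars_offset_mm + dims.ars_radius_mm
    lo = np.min(ends, axis=0) - pad
    hi = np.max(ends, axis=0) + pad
    R2 = spec.shaft_outer_radius_mm + dims.plate_thickness_mm
    lo = np.minimum(lo, [-R2, -R2, axis.origin[2] - dims.plate_below_mm])
    hi = np.maximum(hi, [R2, R2, axis.origin[2] + dims.plate_above_mm])
    return lo, hi


def _mesh_from_masks(spec: SurrogateFemurSpec, lo, hi, implant_ctx=None) -> M.VolumeMesh:
    h = spec.h
    origin = np.floor(np.asarray(lo) / h - 1.0) * h  # snapped to the h-lattice
    dims = np.ceil((np.asarray(hi) - origin) / h + 1.0).astype(int)

    def classify(pts):
        bone_in, depth, part = _bone_classify(spec, pts)
        # the articular head carries no resolvable cortical shell: the real
        # subchondral plate is sub-millimetre, far below the element scale,
        # so head elements are cancellous throughout
        region = np.where(
            (depth < spec.cortical_thickness_mm) & (part != M.HEAD_PART),
            M.CORTICAL,
            M.CANCELLOUS,
        ).astype(np.int8)
        inside = bone_in.copy()
        if implant_ctx is not None:
            config, axis = implant_ctx
            imp = _implant_classify(spec, config, axis, pts)
            hit = imp >= 0
            inside |= hit
            region = np.where(hit, imp, region).astype(np.int8)
            part = np.where(hit, M.IMPLANT_PART, part).astype(np.int8)
        return inside, region, part

    mesh = M.build_grid_mesh(origin, h, dims, classify)
    mesh.meta["spec"] = spec
    mesh.validate(min_quality=spec.min_quality)
    _tag_standard_sets(mesh, spec)
    return mesh


def _tag_standard_sets(mesh: M.VolumeMesh, spec: SurrogateFemurSpec) -> None:
    """Boundary facet/node sets every construct carries: distal end and
    head outer surface."""
    h = mesh.meta["h"]
    zmin = mesh.nodes[:, 2].min()
    bone = mesh.bone_mask()
    bf = M.boundary_facets(mesh.elems, bone)
    fc = mesh.nodes[bf].mean(axis=1)
    distal = bf[fc[:, 2] < zmin + 0.75 * h]
    mesh.facet_sets["distal_end"] = distal
    mesh.node_sets["distal_end"] = np.unique(distal)

    head_elems = bone & (mesh.part == M.HEAD_PART)
    if head_elems.any():
        hb = M.boundary_facets(mesh.elems, head_elems)
        c = spec.head_center()
        r = np.linalg.norm(mesh.nodes[hb].mean(axis=1) - c, axis=1)
        mesh.facet_sets["head_surface"] = hb[r > spec.head_radius_mm - 1.5 * h]


def generate_surrogate_femur(spec: SurrogateFemurSpec):
    """Mesh the intact surrogate femur and draw its Hounsfield field.

    Returns ``(VolumeMesh, HUField)``.  Pure function of the spec: the
    same spec (including seed) reproduces the output bit-for-bit.
    """
    c, rh = spec.head_center(), spec.head_radius_mm
    R, L = spec.shaft_outer_radius_mm, spec.shaft_length_mm
    lo = np.minimum(c - rh, [-R, -R, 0.0])
    hi = np.maximum(c + rh, [R, R, L])
    mesh = _mesh_from_masks(spec, lo, hi)
    return mesh, hounsfield_field(mesh, spec)


def embed_implant(
    mesh: M.VolumeMesh,
    config: FNSConfiguration,
    axis: NeckAxis,
    allow_breach: bool = False,
) -> M.VolumeMesh:
    """Embed the FNS construct: re-mesh the grid with the implant
    primitives added, turning overlapping bone cells into implant cells
    (drilling bone loss), and split the frictional interfaces
    (bolt-bone, plate-bolt, plate-screw) into penalty node pairs.

    The removed-bone volume is recorded in ``meta['bone_loss_volume_mm3']``.
    """
    spec: SurrogateFemurSpec = mesh.meta["spec"]
    rep = containment_report(axis, config, spec)
    if rep.cortical_breach and not allow_breach:
        raise ValueError("bolt tip breaches the subchondral surface (pass allow_breach=True to override)")

    c, rh = spec.head_center(), spec.head_radius_mm
    R, L = spec.shaft_outer_radius_mm, spec.shaft_length_mm
    lo = np.minimum(c - rh, [-R, -R, 0.0])
    hi = np.maximum(c + rh, [R, R, L])
    ilo, ihi = _implant_bbox(spec, config, axis)
    new = _mesh_from_masks(
        spec, np.minimum(lo, ilo), np.maximum(hi, ihi), implant_ctx=(config, axis)
    )
    if not (new.region == M.BOLT).any():
        raise ValueError("implant axis misses the meshed bone")

    # bone loss: old bone elements whose lattice address is now implant
    old_keys = _element_keys(mesh)[mesh.bone_mask()]
    new_imp_keys = _element_keys(new)[new.implant_mask()]
    lost = np.intersect1d(old_keys, new_imp_keys).size
    h = mesh.meta["h"]
    new.meta["bone_loss_volume_mm3"] = lost * h**3 / 6.0
    new.meta["config"] = config
    new.meta["axis"] = axis

    d, o = axis.direction, axis.origin

    def bolt_radial(pts):
        rel = pts - o
        rad = rel - (rel @ d)[:, None] * d
        n = np.linalg.norm(rad, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return rad / n

    bone = new.bone_mask()
    other_imp = np.unique(new.elems[new.region_mask("antirotation_screw", "plate", "locking_screw")])
    M.split_interface(
        new, "bolt_bone", bone, new.region == M.BOLT, bolt_radial, exclude_nodes=other_imp
    )
    M.split_interface(
        new, "plate_bolt", new.region == M.PLATE, new.region == M.BOLT, bolt_radial
    )
    sup = spec.shaft_direction() - (spec.shaft_direction() @ d) * d
    sup = sup / np.linalg.norm(sup)
    o_ars = o + spec.implant.ars_offset_mm * sup

    def ars_radial(pts):
        rel = pts - o_ars
        rad = rel - (rel @ d)[:, None] * d
        n = np.linalg.norm(rad, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return rad / n

    M.split_interface(
        new, "plate_screw", new.region == M.PLATE, new.region == M.ARS, ars_radial
    )

    # the plate presses on the lateral cortex but is not osseointegrated:
    # frictional pairs, anchored through the (bonded) locking screw
    entry_phi = np.arctan2(o[1], o[0])
    inward = -np.array([np.cos(entry_phi), np.sin(entry_phi), 0.0])  # plate -> bone
    lock_nodes = np.unique(new.elems[new.region == M.LOCKSCREW])
    M.split_interface(
        new,
        "plate_bone",
        new.bone_mask(),
        new.region == M.PLATE,
        lambda pts: inward[None, :],
        exclude_nodes=lock_nodes,
    )
    return new


def apply_fracture_cut(
    mesh: M.VolumeMesh, plane: FracturePlane, snap_tol_factor: float = 0.3
) -> M.VolumeMesh:
    """Partition the head/neck bone into head- and shaft-side fragments by
    the fracture plane, snap near-plane bone nodes onto the plane, and
    split the interface into paired penalty nodes (tag ``fracture``).

    The cut applies only to head/neck-part elements so the infinite plane
    never claims the medial shaft wall.  Element reassignment conserves
    volume exactly; node snapping perturbs it by a bounded amount that is
    checked against 0.5 %.
    """
    vol_before = mesh.element_volumes().sum()
    sd = plane.signed_distance(mesh.element_centroids())
    cuttable = mesh.bone_mask() & np.isin(mesh.part, (M.HEAD_PART, M.NECK_PART))
    head = cuttable & (sd < 0.0)
    if not head.any() or not (cuttable & (sd >= 0.0)).any():
        raise ValueError("fracture plane does not intersect the neck region")
    mesh.fragment[head] = 1

    implant_nodes = np.unique(mesh.elems[mesh.implant_mask()]) if mesh.implant_mask().any() else np.array([], int)

    # snap bone nodes onto the plane for a planar, pairable fracture face
    h = mesh.meta["h"]
    nsd = plane.signed_distance(mesh.nodes)
    cand = np.flatnonzero(np.abs(nsd) < snap_tol_factor * h)
    cand = np.setdiff1d(cand, implant_nodes)
    if cand.size:
        saved = mesh.nodes[cand].copy()
        mesh.nodes[cand] -= nsd[cand, None] * plane.normal
        vols = mesh.element_volumes()
        bad = vols < 0.05 * h**3 / 6.0
        if bad.any():
            bad_nodes = np.intersect1d(np.unique(mesh.elems[bad]), cand)
            pos = {n: i for i, n in enumerate(cand)}
            rows = [pos[n] for n in bad_nodes]
            mesh.nodes[bad_nodes] = saved[rows]
            if (mesh.element_volumes() < 0).any():
                mesh.nodes[cand] = saved  # give up snapping entirely

    shaft_side = mesh.bone_mask() & (mesh.fragment == 0)
    tris = M.shared_facets(mesh.elems, shaft_side, mesh.fragment == 1)
    mesh.facet_sets["fracture_face_shaft"] = tris
    M.split_interface(
        mesh,
        "fracture",
        shaft_side,
        mesh.fragment == 1,
        lambda pts: plane.normal[None, :],
        exclude_nodes=implant_nodes,
    )
    pairs = mesh.interfaces.get("fracture")
    if pairs is not None and len(pairs):
        remap = np.arange(mesh.n_nodes)
        remap[pairs.node_a] = pairs.node_b
        mesh.facet_sets["fracture_face_head"] = remap[tris]
    mesh.meta["plane"] = plane

    vol_after = mesh.element_volumes().sum()
    rel = abs(vol_after - vol_before) / vol_before
    if rel > 0.005:
        raise ValueError(f"fracture cut changed total volume by {rel:.2%}")
    return mesh


# ---------------------------------------------------------------------------
# synthetic decision matrices for the entropy-ranking stage


@dataclass(frozen=True)
class SyntheticDecisionSpec:
    """Planted-weight generator spec for 17-alternative, 4-metric tables."""

    n_alternatives: int = 17
    planted_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.planted_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("planted weights must be nonnegative and sum to 1")
        if self.n_alternatives < 2:
            raise ValueError("need at least 2 alternatives")


def generate_metric_table(spec: SyntheticDecisionSpec):
    """Decision matrix whose column dispersions are shaped so the entropy
    method recovers the planted weight ordering as noise -> 0.

    Each column's min-max-normalized profile is ``u**c_j`` on a uniform
    grid, with the exponent ``c_j`` increasing in the planted weight:
    more skew means lower Shannon entropy, hence more information and a
    larger recovered weight.  Equal planted weights give identical
    profiles and exactly equal recovered weights.  Columns are emitted on
    metric-like scales (stiffness as benefit, stresses/gap as cost) so the
    table round-trips through the full orientation + ranking pipeline.
    """
    from .stability_metrics import MetricRecord, MetricTable

    n = spec.n_alternatives
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.planted_weights, float)
    u = np.linspace(0.0, 1.0, n)
    cols = []
    for j, wj in enumerate(w):
        c = 1.0 + 10.0 * wj
        y = u**c
        y = y + spec.noise_sd * rng.standard_normal(n)
        cols.append(y)
    Y = np.column_stack(cols)
    perm = rng.permutation(n)
    Y = Y[perm]

    # map onto metric-like scales; orientation must invert back to Y
    scales = np.array([600.0, 150.0, 12.0, 1.2])
    offsets = np.array([300.0, 60.0, 5.0, 0.4])
    records = []
    for i in range(n):
        stiff = offsets[0] + scales[0] * Y[i, 0]  # benefit
        mivs = offsets[1] + scales[1] * (1.0 - Y[i, 1])  # cost
        miss = offsets[2] + scales[2] * (1.0 - Y[i, 2])
        mig = offsets[3] + scales[3] * (1.0 - Y[i, 3])
        records.append(
            MetricRecord(
                model_label=f"alt{i:02d}",
                stiffness_N_mm=float(stiff),
                mivs_MPa=float(max(mivs, 0.0)),
                miss_MPa=float(max(miss, 0.0)),
                mig_mm=float(max(mig, 0.0)),
            )
        )
    return MetricTable(records=records, metadata={"generator": "planted", "seed": spec.seed})


# ---------------------------------------------------------------------------
# closed-form mechanics fixtures


@dataclass
class ToyFixture:
    """A tiny mechanics problem with its analytic answer attached.

    ``dirichlet`` is a list of (node_ids, component, value); ``loads`` a
    dense (n_nodes, 3) nodal force array.  ``order`` is the recommended
    element polynomial order for the check.
    """

    name: str
    mesh: M.VolumeMesh
    E_MPa: float
    nu: float
    dirichlet: list
    loads: np.ndarray
    answer: dict
    order: int = 1


def box_mesh(lengths, h: float) -> M.VolumeMesh:
    """Kuhn-tet mesh of an axis-aligned box with corner at the origin."""
    lengths = np.asarray(lengths, float)
    dims = np.maximum(np.rint(lengths / h).astype(int), 1)
    hs = lengths / dims  # exact fit; mildly anisotropic cells are fine here

    # build on a unit lattice then scale per-axis
    def classify(pts):
        n = len(pts)
        return (
            np.ones(n, bool),
            np.full(n, M.CANCELLOUS, np.int8),
            np.full(n, M.SHAFT_PART, np.int8),
        )

    mesh = M.build_grid_mesh(np.zeros(3), 1.0, dims, classify)
    mesh.nodes = mesh.nodes * hs
    mesh.meta["h"] = float(np.max(hs))
    mesh.meta["box_lengths"] = lengths
    return mesh


def toy_fixture_cases(h: float = 2.5) -> list[ToyFixture]:
    """Axial rod (EA/L), tip-loaded cantilever (PL^3/3EI) and a two-block
    prescribed-gap pair, each with its closed-form answer."""
    fixtures = []

    # --- axial rod: 10 x 10 x 100, E = 1000, roller-free cross sections
    rod = box_mesh([10.0, 10.0, 100.0], h)
    zmax = rod.nodes[:, 2].max()
    bot = np.flatnonzero(rod.nodes[:, 2] < 1e-9)
    top = np.flatnonzero(rod.nodes[:, 2] > zmax - 1e-9)
    F = 1000.0
    loads = np.zeros((rod.n_nodes, 3))
    bf = M.boundary_facets(rod.elems)
    fc = rod.nodes[bf].mean(axis=1)
    top_faces = bf[fc[:, 2] > zmax - 1e-9]
    areas = M.triangle_areas(rod.nodes, top_faces)
    np.add.at(loads[:, 2], top_faces.reshape(-1), np.repeat(areas / 3.0, 3))
    loads[:, 2] *= F / loads[:, 2].sum()
    rod.node_sets["top"] = top
    fixtures.append(
        ToyFixture(
            name="axial_rod",
            mesh=rod,
            E_MPa=1000.0,
            nu=0.0,
            dirichlet=[(bot, 0, 0.0), (bot, 1, 0.0), (bot, 2, 0.0)],
            loads=loads,
            answer={"stiffness_N_mm": 1000.0 * 100.0 / 100.0, "force_N": F},
            order=1,
        )
    )

    # --- cantilever: 10 x 10 x 100 clamped at z=0, tip load P in x
    cant = box_mesh([10.0, 10.0, 100.0], h)
    zmax = cant.nodes[:, 2].max()
    bot = np.flatnonzero(cant.nodes[:, 2] < 1e-9)
    tip = np.flatnonzero(cant.nodes[:, 2] > zmax - 1e-9)
    P = 1.0
    loads = np.zeros((cant.n_nodes, 3))
    loads[tip, 0] = P / len(tip)
    cant.node_sets["tip"] = tip
    I = 10.0 * 10.0**3 / 12.0
    fixtures.append(
        ToyFixture(
            name="cantilever",
            mesh=cant,
            E_MPa=1000.0,
            nu=0.0,
            dirichlet=[(bot, 0, 0.0), (bot, 1, 0.0), (bot, 2, 0.0)],
            loads=loads,
            answer={"tip_deflection_mm": P * 100.0**3 / (3.0 * 1000.0 * I), "force_N": P},
            order=2,
        )
    )

    # --- two stacked blocks with a split interface, prescribed 0.5 mm gap
    blk = box_mesh([10.0, 10.0, 20.0], h)
    upper = blk.element_centroids()[:, 2] > 10.0
    M.split_interface(
        blk,
        "fracture",
        ~upper,
        upper,
        lambda pts: np.array([[0.0, 0.0, -1.0]]),  # b (upper) -> a (lower)
    )
    bot = np.flatnonzero(blk.nodes[:, 2] < 1e-9)
    upper_nodes = np.unique(blk.elems[upper])
    gap = 0.5
    diri = [(bot, k, 0.0) for k in range(3)]
    diri += [(upper_nodes, 0, 0.0), (upper_nodes, 1, 0.0), (upper_nodes, 2, gap)]
    fixtures.append(
        ToyFixture(
            name="two_block_gap",
            mesh=blk,
            E_MPa=1000.0,
            nu=0.0,
            dirichlet=diri,
            loads=np.zeros((blk.n_nodes, 3)),
            answer={"max_gap_mm": gap},
            order=1,
        )
    )
    return fixtures
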