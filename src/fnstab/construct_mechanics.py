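"""Mechanics of the fixed construct under single-leg stance.

Two backends solve the same question — how stiff is a given FNS placement
and how much does the fracture move:

* a small-strain linear-elastic finite-element solve (TET4/TET10) with
  penalty-regularized Coulomb friction at the split interfaces, driven by
  a fixed-point active-set/cap iteration around a sparse direct solver;
* a reduced-order beam-and-spring surrogate built from lever-arm
  geometry, used for fast sweeps and rank-order cross-checks.

The single-leg-stance load is 3x body weight (2100 N for the 70 kg
default, with g = 10 m/s^2 so the number is exact), applied over a small
patch of the femoral head, tilted 8 deg posteriorly in the sagittal plane
and 13 deg in the coronal plane; the distal shaft is fully fixed and a
224 N preload compresses the fracture along the antirotation screw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix

from . import _fem, _mesh
from .bone_materials import MaterialMap, hu_to_density, density_to_elasticity
from .config_grid import FNSConfiguration, NeckAxis, implant_axis, containment_report

log = logging.getLogger(__name__)

__all__ = [
    "LoadCase",
    "InterfaceSpec",
    "SolutionField",
    "ReducedOrderParams",
    "single_leg_load",
    "default_interfaces",
    "assemble_and_solve",
    "interface_tractions",
    "reduced_order_metrics",
    "convergence_study",
]

GRAVITY_M_S2 = 10.0  # 3 x 70 kg x 10 m/s^2 = 2100 N exactly


@dataclass(frozen=True)
class LoadCase:
    magnitude_N: float = 2100.0
    sagittal_angle_deg: float = 8.0
    coronal_angle_deg: float = 13.0
    preload_N: float = 224.0
    load_patch: str = "head_surface"
    constrained_surface: str = "distal_end"
    patch_radius_mm: float = 8.0
    coronal_sense: int = 1  # +1 = lateral tilt as printed; -1 flips medially

    def __post_init__(self):
        if not self.magnitude_N > 0:
            raise ValueError("load magnitude must be positive")
        for a in (self.sagittal_angle_deg, self.coronal_angle_deg):
            if not (0.0 <= a < 90.0):
                raise ValueError("tilt angles must lie in [0, 90) degrees")

    def direction(self) -> np.ndarray:
        """Unit load direction: -Z tilted posteriorly then laterally."""
        th = np.deg2rad(-self.sagittal_angle_deg)
        Rx = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        ph = np.deg2rad(-self.coronal_sense * self.coronal_angle_deg)
        Ry = np.array(
            [[np.cos(ph), 0, np.sin(ph)], [0, 1, 0], [-np.sin(ph), 0, np.cos(ph)]]
        )
        d = Ry @ Rx @ np.array([0.0, 0.0, -1.0])
        return d / np.linalg.norm(d)


def single_leg_load(body_mass_kg: float = 70.0, factor: float = 3.0, **kwargs) -> LoadCase:
    """Single-leg-stance load case: ``factor`` x body weight."""
    if body_mass_kg <= 0 or factor <= 0:
        raise ValueError("mass and factor must be positive")
    return LoadCase(magnitude_N=factor * body_mass_kg * GRAVITY_M_S2, **kwargs)


@dataclass(frozen=True)
class InterfaceSpec:
    pair_tag: str
    model: str  # "bonded" | "frictional"
    friction_coefficient: float = 0.0
    normal_penalty: float = 5.0e3  # N/mm^3
    tangential_penalty: float = 5.0e3

    def __post_init__(self):
        if self.model not in ("bonded", "frictional"):
            raise ValueError("model must be 'bonded' or 'frictional'")
        if self.model == "frictional" and not self.friction_coefficient > 0:
            raise ValueError("frictional interface needs a positive coefficient")
        if self.normal_penalty <= 0 or self.tangential_penalty <= 0:
            raise ValueError("penalties must be positive")


def default_interfaces() -> list[InterfaceSpec]:
    """The published contact set: fracture ends mu=0.46, bolt-bone mu=0.3,
    plate-bolt and plate-screw mu=0.2, screw-bone bonded."""
    return [
        InterfaceSpec("fracture", "frictional", 0.46),
        InterfaceSpec("bolt_bone", "frictional", 0.30),
        InterfaceSpec("plate_bolt", "frictional", 0.20),
        InterfaceSpec("plate_screw", "frictional", 0.20),
        InterfaceSpec("plate_bone", "frictional", 0.30),
        InterfaceSpec("screw_bone", "bonded"),
    ]


@dataclass
class SolutionField:
    u_mm: np.ndarray  # (n_corner_nodes, 3)
    stress_MPa: np.ndarray  # (M, 6) Voigt
    von_mises_MPa: np.ndarray  # (M,)
    solver_report: dict
    interface_state: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _assemble_springs(mesh, states, ndof):
    """Penalty spring matrix from the per-pair effective stiffnesses."""
    rows, cols, vals = [], [], []
    for tag, st in states.items():
        pairs = mesh.interfaces[tag]
        kn, kt = st["kn_eff"], st["kt_eff"]
        idx = np.flatnonzero((kn > 0) | (kt > 0))
        if idx.size == 0:
            continue
        n = pairs.normal[idx]
        A = pairs.area[idx]
        nnT = np.einsum("pi,pj->pij", n, n)
        S = (kn[idx] * A)[:, None, None] * nnT + (kt[idx] * A)[:, None, None] * (
            np.eye(3) - nnT
        )
        da = (3 * pairs.node_a[idx][:, None] + np.arange(3)[None, :]).reshape(-1)
        db = (3 * pairs.node_b[idx][:, None] + np.arange(3)[None, :]).reshape(-1)
        for r, c, sgn in ((da, da, 1.0), (db, db, 1.0), (da, db, -1.0), (db, da, -1.0)):
            rr = np.repeat(r.reshape(-1, 3), 3, axis=1).reshape(-1)
            cc = np.tile(c.reshape(-1, 3), (1, 3)).reshape(-1)
            rows.append(rr)
            cols.append(cc)
            vals.append(sgn * S.reshape(-1))
    if not rows:
        return None
    return coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()


def _pair_kinematics(pairs, u3):
    """Signed gap and tangential slip of every pair given displacements."""
    d = u3[pairs.node_a] - u3[pairs.node_b]
    g = np.einsum("pi,pi->p", d, pairs.normal)
    dt = d - g[:, None] * pairs.normal
    return g, np.linalg.norm(dt, axis=1)


def _head_patch(mesh, load: LoadCase):
    spec = mesh.meta["spec"]
    facets = mesh.facet_sets.get(load.load_patch)
    if facets is None or len(facets) == 0:
        raise ValueError(f"mesh has no '{load.load_patch}' facet set")
    d = load.direction()
    target = spec.head_center() - spec.head_radius_mm * d
    r = load.patch_radius_mm
    fc = mesh.nodes[facets].mean(axis=1)
    for _ in range(6):
        sel = facets[np.linalg.norm(fc - target, axis=1) <= r]
        if len(sel):
            break
        r *= 1.5
    else:
        raise ValueError("no head-surface facets near the load application point")
    areas = _mesh.triangle_areas(mesh.nodes, sel)
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, sel.reshape(-1), np.repeat(areas / 3.0, 3))
    return w / w.sum()


def _preload_forces(mesh, load: LoadCase) -> np.ndarray:
    """Equal-and-opposite preload along the antirotation screw axis."""
    f = np.zeros((mesh.n_nodes, 3))
    if load.preload_N == 0.0:
        return f
    ars = mesh.region_mask("antirotation_screw")
    if not ars.any():
        return f
    axis: NeckAxis = mesh.meta["axis"]
    nodes = np.unique(mesh.elems[ars])
    s = (mesh.nodes[nodes] - axis.origin) @ axis.direction
    span = s.max() - s.min()
    head_end = nodes[s > s.max() - 0.15 * span]
    plate_end = nodes[s < s.min() + 0.15 * span]
    f[head_end] -= load.preload_N * axis.direction / len(head_end)
    f[plate_end] += load.preload_N * axis.direction / len(plate_end)
    return f


def assemble_and_solve(
    construct: _mesh.VolumeMesh,
    materials: MaterialMap,
    interfaces: list[InterfaceSpec],
    load: LoadCase,
    order: int | None = None,
    tol: float = 1e-8,
    cap_tol: float = 1e-4,
    max_iter: int = 100,
    relaxation: float = 0.6,
    cap_model: str = "coulomb",
    external_forces: np.ndarray | None = None,
    dirichlet: list | None = None,
) -> SolutionField:
    """Solve the construct under the load case.

    Frictional interfaces are penalty springs solved by a relaxed secant
    (Picard) iteration: pairs that open lose their springs, and slipping
    pairs get an effective tangential stiffness mu*sigma_n/|slip| that
    caps the traction at the Coulomb limit (``cap_model='linear'`` keeps
    every spring closed and uncapped, making the operator exactly linear).
    ``external_forces``/``dirichlet`` allow fixture-style drive instead of
    the physiological load path.
    """
    construct.validate(min_quality=construct.meta.get("spec").min_quality if construct.meta.get("spec") else 0.02)
    if order is None:
        spec = construct.meta.get("spec")
        order = spec.element_order if spec is not None else 1

    K, info = _fem.assemble_stiffness(
        construct.nodes, construct.elems, materials.E_MPa, materials.nu, order=order
    )
    ndof = 3 * info["n_nodes"]

    # external forces
    if external_forces is not None:
        f3 = np.asarray(external_forces, float).copy()
    else:
        w = _head_patch(construct, load)
        f3 = load.magnitude_N * w[:, None] * load.direction()[None, :]
        f3 += _preload_forces(construct, load)
    f = np.zeros(ndof)
    f[: 3 * construct.n_nodes] = f3.reshape(-1)

    # Dirichlet
    if dirichlet is None:
        fixed_nodes = construct.node_sets.get(load.constrained_surface)
        if fixed_nodes is None or len(fixed_nodes) == 0:
            raise ValueError(f"no '{load.constrained_surface}' node set to constrain")
        dirichlet = [(fixed_nodes, k, 0.0) for k in range(3)]
    fd, fv = [], []
    for nodes_, comp, val in dirichlet:
        nodes_ = np.asarray(nodes_, int)
        fd.append(3 * nodes_ + comp)
        fv.append(np.full(len(nodes_), float(val)))
    fixed_dofs = np.concatenate(fd)
    fixed_vals = np.concatenate(fv)
    fixed_dofs, uidx = np.unique(fixed_dofs, return_index=True)
    fixed_vals = np.concatenate(fv)[uidx]
    fixed_dofs, fixed_vals = _fem.extend_dirichlet_to_midside(info, fixed_dofs, fixed_vals)

    specs_by_tag = {s.pair_tag: s for s in interfaces}
    active_tags = [
        t
        for t, p in construct.interfaces.items()
        if specs_by_tag.get(t) is not None
        and specs_by_tag[t].model == "frictional"
        and len(p)
    ]
    # effective secant stiffnesses per pair: full penalties while sticking,
    # mu*sigma_n/|slip| while slipping, zero when open
    states = {
        t: {
            "kn_eff": np.full(len(construct.interfaces[t]), specs_by_tag[t].normal_penalty),
            "kt_eff": np.full(len(construct.interfaces[t]), specs_by_tag[t].tangential_penalty),
        }
        for t in active_tags
    }

    def factor(system_K):
        try:
            return _fem.LinearSystem(system_K, fixed_dofs, fixed_vals).factor()
        except RuntimeError as e:  # singular factorization
            raise RuntimeError(
                "singular stiffness system — a fragment or implant part has an "
                "unconstrained rigid-body mode"
            ) from e

    it = 0
    if not active_tags:
        sys_ = factor(K)
        u = sys_.solve(f)
    else:
        converged = cap_model == "linear"
        S = _assemble_springs(construct, states, ndof)
        sys_ = factor(K + S if S is not None else K)
        u = sys_.solve(f)
        prev_tr = None
        omega = relaxation
        while not converged and it < max_iter:
            it += 1
            u3 = u[: 3 * construct.n_nodes].reshape(-1, 3)
            tractions = []
            for t in active_tags:
                pairs = construct.interfaces[t]
                spec_t = specs_by_tag[t]
                g, slip = _pair_kinematics(pairs, u3)
                open_ = g > 0.0
                sig_n = np.where(open_, 0.0, -spec_t.normal_penalty * g)
                kn_new = np.where(open_, 0.0, spec_t.normal_penalty)
                tau_allow = spec_t.friction_coefficient * sig_n
                kt_new = np.where(
                    open_,
                    0.0,
                    np.minimum(
                        spec_t.tangential_penalty,
                        np.where(slip > 1e-14, tau_allow / np.maximum(slip, 1e-14),
                                 spec_t.tangential_penalty),
                    ),
                )
                st = states[t]
                st["kn_eff"] += omega * (kn_new - st["kn_eff"])
                st["kt_eff"] += omega * (kt_new - st["kt_eff"])
                tractions.append(sig_n)
                tractions.append(st["kt_eff"] * slip)
            tr = np.concatenate(tractions)
            S = _assemble_springs(construct, states, ndof)
            sys_ = factor(K + S if S is not None else K)
            u = sys_.solve(f)
            if prev_tr is not None:
                scale = max(np.linalg.norm(tr), np.linalg.norm(prev_tr), 1e-12)
                dtr = np.linalg.norm(tr - prev_tr) / scale
                log.info("contact iteration %d: dtraction=%.3e", it, dtr)
                if dtr < cap_tol:
                    converged = True
            prev_tr = tr
        if not converged:
            res = sys_.residual(u, f)
            raise RuntimeError(
                f"frictional cap iteration did not converge in {max_iter} "
                f"iterations (last traction change {dtr:.3e}, residual {res:.3e})"
            )

    residual = _fem.LinearSystem.residual(sys_, u, f)
    if residual > tol:
        raise RuntimeError(f"equilibrium residual {residual:.3e} above tolerance {tol:g}")

    stress, vm = _fem.recover_stresses(info, u)
    u3 = u[: 3 * construct.n_nodes].reshape(-1, 3)

    sol = SolutionField(
        u_mm=u3,
        stress_MPa=stress,
        von_mises_MPa=vm,
        solver_report={"iterations": it, "residual": residual},
    )
    for t in active_tags:
        pairs = construct.interfaces[t]
        spec_t = specs_by_tag[t]
        g, slip = _pair_kinematics(pairs, u3)
        if cap_model == "linear":
            sig_n = -spec_t.normal_penalty * g
            tau = spec_t.tangential_penalty * slip
            open_ = np.zeros(len(pairs), bool)
        else:
            open_ = g > 0.0
            sig_n = np.where(open_, 0.0, -spec_t.normal_penalty * g)
            tau = states[t]["kt_eff"] * slip
        sol.interface_state[t] = {
            "gap_mm": g,
            "normal_traction_MPa": sig_n,
            "tangential_traction_MPa": tau,
            "open": open_,
        }
    if external_forces is None:
        sol.meta["load"] = load
        sol.meta["patch_weights"] = w
        sol.meta["direction"] = load.direction()
    sol.meta["order"] = order
    sol.meta["strain_energy_N_mm"] = 0.5 * float(u @ (K @ u))
    sol.meta["external_work_N_mm"] = float(f @ u)
    return sol


def interface_tractions(solution: SolutionField, pair_tag: str):
    """(normal traction, tangential traction, signed gap) per node pair."""
    st = solution.interface_state.get(pair_tag)
    if st is None:
        raise KeyError(f"no interface state for pair '{pair_tag}'")
    return st["normal_traction_MPa"], st["tangential_traction_MPa"], st["gap_mm"]


# ---------------------------------------------------------------------------
# reduced-order beam/lever surrogate


@dataclass(frozen=True)
class ReducedOrderParams:
    """Calibration of the beam-spring surrogate.

    ``E_implant`` and ``E_bone`` enter as a series spring pair, so the
    predicted stiffness is homogeneous of degree one in the moduli.  The
    lever arm grows with inferior offset and axis eccentricity (lever-
    hinge picture: a longer medial force arm means a softer, more varus-
    prone construct); the head support spring softens as the bolt tip
    retreats from the subchondral bone.
    """

    E_implant_MPa: float = 105_000.0
    E_bone_MPa: float = 1118.0  # cancellous default through the density law
    bolt_radius_mm: float = 5.0
    head_support_area_mm2: float = 300.0
    base_arm_mm: float = 20.0
    tip_regularization_mm: float = 5.0
    offset_arm_gain: float = 1.0
    eccentricity_arm_gain: float = 0.5
    misalignment_gain: float = 2.0


def reduced_order_metrics(
    config: FNSConfiguration,
    rom_params: ReducedOrderParams | None = None,
    femur_spec=None,
    load: LoadCase | None = None,
):
    """Closed-form stability metrics for one placement (< 1 ms).

    Returns a MetricRecord with stiffness and proxies for the maximum
    implant von Mises stress, interfragmentary shear and gap.
    """
    from .stability_metrics import MetricRecord
    from .synth_femur import SurrogateFemurSpec

    p = rom_params or ReducedOrderParams()
    spec = femur_spec or SurrogateFemurSpec()
    load = load or LoadCase()
    if p.E_implant_MPa <= 0 or p.E_bone_MPa <= 0 or p.head_support_area_mm2 <= 0:
        raise ValueError("invalid reduced-order calibration")

    neck = spec.neck_axis()
    axis = implant_axis(config, neck, spec.shaft_direction(), spec.coronal_normal())
    rep = containment_report(axis, config, spec)
    c = spec.head_center()
    e_off = float(np.linalg.norm(np.cross(c - axis.origin, axis.direction)))

    d_load = load.direction()
    cosg = float(np.clip(-d_load @ axis.direction, -1.0, 1.0))
    gamma = np.arccos(cosg)

    I = np.pi * p.bolt_radius_mm**4 / 4.0
    arm = (
        p.base_arm_mm
        + p.offset_arm_gain * max(0.0, -config.offset_mm)
        + p.eccentricity_arm_gain * e_off
    )
    k_head = p.E_bone_MPa * p.head_support_area_mm2 / (
        rep.tip_to_subchondral_mm + p.tip_regularization_mm
    )
    k_imp = 3.0 * p.E_implant_MPa * I / arm**3
    c_align = 1.0 + p.misalignment_gain * (1.0 - cosg)
    stiffness = 1.0 / (c_align * (1.0 / k_head + 1.0 / k_imp))

    F = load.magnitude_N
    F_t = F * np.sin(gamma)
    F_ax = F * abs(cosg)
    mivs = F_t * arm * p.bolt_radius_mm / I + F_ax / (np.pi * p.bolt_radius_mm**2)
    miss = F_t / (np.pi * spec.neck_radius_mm**2) * (1.0 + arm / 50.0) * 10.0
    mig = F_t * arm**3 / (3.0 * p.E_implant_MPa * I) + F_ax / k_head

    return MetricRecord(
        model_label=config.label,
        stiffness_N_mm=float(stiffness),
        mivs_MPa=float(mivs),
        miss_MPa=float(miss),
        mig_mm=float(mig),
    )


def convergence_study(
    femur_spec,
    config: FNSConfiguration,
    interfaces: list[InterfaceSpec],
    load: LoadCase,
    sizes,
    order: int | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Mesh refinement study on the maximum implant von Mises stress.

    Re-meshes the construct at each edge length (fine -> coarse), solves,
    and flags the coarsest size whose relative change against the next
    finer mesh is below the 5 % criterion.
    """
    from .pipeline_audit import build_construct, solve_construct

    sizes = sorted(float(s) for s in sizes)
    if len(sizes) < 2:
        raise ValueError("convergence study needs at least two mesh sizes")
    rows = []
    for s in sizes:
        spec_s = replace(femur_spec, target_edge_length_mm=s, size_factor=1.0)
        mesh, hu, axis, plane = build_construct(spec_s, config)
        sol, _ = solve_construct(mesh, hu, interfaces, load, order=order)
        imp = mesh.implant_mask()
        rows.append({"size_mm": s, "max_implant_von_mises_MPa": float(sol.von_mises_MPa[imp].max())})
    df = pd.DataFrame(rows)
    vm = df["max_implant_von_mises_MPa"].to_numpy()
    rel = np.full(len(df), np.nan)
    rel[1:] = np.abs(vm[1:] - vm[:-1]) / vm[:-1]
    df["relative_change"] = rel
    df["converged"] = rel < threshold
    flagged = df.index[df["converged"]].max() if df["converged"].any() else None
    df.attrs["coarsest_converged_size_mm"] = (
        float(df.loc[flagged, "size_mm"]) if flagged is not None else None
    )
    return df
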