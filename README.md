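# fnstab

Implant-position stability analysis for Femoral Neck System (FNS)
fixation of Pauwels type III femoral neck fractures.

Vertical (Pauwels III, ~70°) femoral neck fractures are shear-dominated
and notoriously unstable. The FNS — a lateral plate with a sliding bolt
and an antirotation screw — can be implanted at different bolt lengths,
entry heights and axis–bolt angles (ABA α in the AP view, β in the
lateral view), and the choice affects fixation stability. `fnstab` is a
research toolkit for exploring that question end to end:

* a **parametric surrogate proximal femur** (sphere + capsule + tube,
  cortical shell over cancellous core, reproducible per-element
  Hounsfield field) meshed into Kuhn tetrahedra;
* the standard **17-model placement grid** (standard + 4 lengths +
  4 offsets + 4 α + 4 β) with Boolean bone removal for the implant and a
  70° fracture cut;
* the CT-based **material mapping** ρ = 0.000968·HU + 0.5 g/cm³, then
  E = 2014·ρ^2.5 MPa (ν = 0.2) below 1.2 g/cm³ and E = 1763·ρ^3.2 MPa
  (ν = 0.32) above, with a Ti-6Al-7Nb implant card (105 GPa, ν = 0.34,
  yield 800 MPa);
* a **linear-elastic FE solver** (TET4/TET10, sparse direct, penalty
  Coulomb friction: fracture μ = 0.46, bolt–bone μ = 0.3, plate
  interfaces μ = 0.2, bonded screw–bone) under the single-leg-stance
  load: 2100 N (3 × 70 kg body weight) tilted 8° posteriorly and 13° in
  the coronal plane, with a 224 N antirotation-screw preload — plus a
  closed-form beam-spring backend for fast sweeps;
* the four **stability metrics**: construct stiffness (load / load-point
  displacement), maximum implant von Mises stress (MIVS), maximum
  interfragmentary shear stress (MISS) and maximum interfragmentary gap
  (MIG);
* **entropy-weight ranking**: min–max normalize the 17×4 table
  (stiffness = benefit, stresses/gap = cost), weight each metric by its
  information content w_j = (1 − e_j)/Σ(1 − e_k) with e_j the normalized
  Shannon entropy, and score each placement by the weighted sum;
* an **audit** of the published percent-change arithmetic that recovers
  the unprinted standard-model baselines.

See `docs/methods.md` for the full model description and limitations.

## Worked example

Check the published arithmetic (every printed percent change against a
single inferred baseline per metric):

```text
$ fns audit
model_label         metric  absolute_value  printed_percent  recomputed_percent ...  pass
   standard stiffness_N_mm          577.13              0.0                 0.0       True
      len75 stiffness_N_mm          539.85             -6.5                -6.5       True
     off-15 stiffness_N_mm          210.20            -63.6               -63.6       True
    ...
max discrepancy 0.081 pp — PASS
```

The largest disagreement across all twenty printed statements is
0.081 percentage points — pure rounding — and the inversion yields the
unprinted standard-model baselines MIVS = 67.81 MPa and MIG = 1.19 mm.

Reproduce the published metric weights from the printed utility column
and rank a synthetic study:

```python
>>> from fnstab import entropy_ranking as er
>>> wv = er.weights_from_utilities([0.037, 0.029, 0.054, 0.18])
>>> (100 * wv.weight_w).round(2)
array([12.33,  9.67, 18.  , 60.  ])
```

The interfragmentary gap dominates at 60.0 % (published: 60.04 %) — the
gap varies most across placements, so it carries the most information.

Run a small FE study and rank it:

```python
>>> from fnstab import SurrogateFemurSpec, PipelineConfig, run_pipeline
>>> cfg = PipelineConfig(
...     femur=SurrogateFemurSpec(target_edge_length_mm=5.0, element_order=4),
...     labels=("standard", "len75"), backend="fe")
>>> out = run_pipeline(cfg, "results/demo", write_vtu=False)
```

which writes `metrics.csv`, e.g.

```text
model_label,stiffness_N_mm,mivs_MPa,miss_MPa,mig_mm
standard,3847.59...,131.56...,0.568...,0.0318...
len75,3053.24...,187.71...,8.218...,0.2278...
```

— the shorter bolt loses ~20 % stiffness and opens the fracture gap
seven-fold, the same direction as the published length family. Absolute
values are surrogate-specific (a homogeneous synthetic femur fixed at
the proximal shaft), not patient values; see the methods note.

The CLI also exposes `fns simulate` (full 17-model study),
`fns rank --metrics table.csv`, `fns gen-femur` (VTU export) and
`fns converge` (mesh convergence on the implant von Mises stress with
the 5 % criterion).

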