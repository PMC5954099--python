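# glyx

Quantitative tools for **cell-surface glycocalyx engineering**: where along
the glycocalyx a grafted polymer sits, how macromolecular crowding collapses
the layer, and how much that placement improves the immunocamouflage of
membrane antigens.

The package is aimed at researchers who modify cell surfaces with
amine-reactive polymers (e.g. hyperbranched polyglycerol, HPG) and want to
analyze three kinds of measurement:

1. **Electrophoretic mobility** of polymer-grafted red blood cells, through a
   soft-layer electrokinetic model that predicts how grafting depth changes
   hydrodynamic drag;
2. **Confocal z-stacks** of probe-labelled endothelial glycocalyces, through
   quadrant (Q1–Q4) segmentation of the axial probe distribution plus layer
   height, density and photobleach-corrected concentration metrics;
3. **Flow-cytometry MFIs** of antibody binding, through relative-protection
   and fold-enhancement statistics with Welch t-tests.

A fully seeded synthetic-data module generates realistic inputs for all
three stages, so every analysis is testable end-to-end without microscope or
cytometer data.

## The model

The cell surface is a charged, hydrodynamically penetrable layer of
thickness β anchored to an impermeable membrane at z = 0 and characterized
by a surface charge density σ (spread through the layer), a segment Stokes
radius a, and a segment density n(z). Since both the Debye length κ⁻¹
(≈ 0.8 nm in 0.145 M saline) and β (7.8 nm for the red-cell glycocalyx) are
far smaller than the cell radius, the geometry is a flat plate. Two linear
boundary-value problems are solved on the half-line normal to the membrane:

```
ψ'' = κ²ψ − ρ_fix(z)/ε          ψ'(0) = −σ_m/ε,   ψ(L) = 0
η u'' − f(z) u = −ρ_e(z)        u(0) = 0,         u'(L) = 0
```

with Brinkman friction f(z) = 6πηa·n(z), mobile charge ρ_e = −εκ²ψ, and
electrophoretic mobility µ = −u(L) (cell frame; a negatively charged layer
gives µ < 0). Grafted polymer adds friction — but no charge — over a depth
interval: the whole layer (0–β, "uniform") or only its outer region
(2.7 nm–β, "outer"). Both problems are discretized with second-order finite
differences and validated against an independently derived closed form for
piecewise-constant layers and against the Smoluchowski limit εζ/η.

For imaging, the glycocalyx span from the membrane focus reference to the
detected top is split into four equal quadrants Q1 (basal) … Q4 (apical) and
each slice's median fluorescent intensity (MFI) is apportioned to quadrants
by geometric overlap. Immunocamouflage is summarized as
`protection = 100·(1 − MFI_modified/MFI_control)` per antigen.

## Worked example

Predict how 20 kDa HPG grafts reduce red-cell mobility when placed
uniformly versus on the outer glycocalyx:

```bash
$ glyx mobility --scenario outer --molecules "0,4.75e5,9.5e5"
molecules_per_cell,mobility,mobility_external
0.0,-1.0310846407365462e-08,-1.0310846407365462
475000.0,-9.248310229457246e-09,-0.9248310229457245
950000.0,-8.395079189792115e-09,-0.8395079189792115

$ glyx mobility --scenario uniform --molecules "0,4.75e5,9.5e5"
molecules_per_cell,mobility,mobility_external
0.0,-1.0310846407365462e-08,-1.0310846407365462
475000.0,-9.567669764278122e-09,-0.9567669764278122
950000.0,-8.931231456651183e-09,-0.8931231456651183
```

`mobility_external` is in µm·s⁻¹/(V·cm⁻¹). The ungrafted cell sits at
−1.03, in the physiological range for red cells in saline. At 9.5×10⁵
molecules per cell, outer-weighted grafting lowers the mobility magnitude to
0.840 versus 0.893 for uniform grafting — outer placement exerts ~6% more
hydrodynamic shielding at the same graft count, which is the signature used
to infer graft location from electrophoresis.

The camouflage analysis of a synthetic cytometry experiment (two antigens,
five replicates, 10 000 events each):

```bash
$ glyx run --config configs/camouflage.yaml
$ column -ts, results/camouflage/protection.csv
antigen  mfi_control   protection_noncrowded  protection_crowded  fold_enhancement  ...  p_value
CD47     1200.529992   15.02974899            26.69023355         1.775826966            1.791450391e-10
RhD      999.9145788   19.9578179             39.93575389         2.00100803             2.356333677e-12
```

Cells grafted under crowding protect RhD twice as well as cells grafted
without crowding (fold ≈ 2.0), with the Welch test confirming the crowded vs
non-crowded difference.

Other shipped demos: `configs/distribution.yaml` (quadrant shift of grafted
probe under crowding), `configs/collapse.yaml` (dose-dependent height
collapse, washout reversibility, Q4 dose response and dextran
concentration), `configs/mobility.yaml` (curves, synthetic measurements and
scenario fitting). Each run writes tidy CSVs, a provenance JSON and the
resolved configuration, and is bit-reproducible for a fixed seed.

## Layout

- `src/glyx/electrokinetics.py` — soft-layer model, solvers, scenario fits
- `src/glyx/analytic.py` — closed-form two-region reference solution
- `src/glyx/zstack.py` — quadrant, height, density and bleach metrics
- `src/glyx/camouflage.py` — protection, fold enhancement, Welch tests
- `src/glyx/synthetic.py` — seeded generators for stacks, mobility, cytometry
- `src/glyx/{config,io,pipeline,cli}.py` — YAML config, TIFF/CSV IO, `glyx` CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
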