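# Methods

## Soft-layer electrokinetic model

A cell carrying a glycocalyx is treated as a flat plate bearing a charged,
hydrodynamically penetrable surface layer. The flat-plate idealization is
justified by scale separation: the Debye length in 0.145 M saline is
κ⁻¹ ≈ 0.80 nm and the red-cell glycocalyx is β = 7.8 nm thick, both orders
of magnitude below the cell radius (~4 µm), so curvature and relaxation
corrections are negligible at the precision of mobility measurements. The
electrostatics are linearized (Debye–Hückel); surface potentials in the
physiological parameter range stay below ~25 mV where linearization is
accurate to a few percent, and nonlinear Poisson–Boltzmann is deliberately
out of scope.

Within the layer, segments of Stokes radius a at volume density n(z) exert
a Brinkman drag f(z) = 6πη·a·n(z) on the electroosmotic flow. Two linear
two-point boundary-value problems are solved at unit applied field on
[0, L], L = β + 10κ⁻¹:

* potential: ψ'' = κ²ψ − ρ_fix(z)/ε with ψ'(0) = −σ_membrane/ε (membrane
  charge, default 0) and ψ(L) = 0;
* flow: η·u'' − f(z)·u = −ρ_e(z) with ρ_e = −εκ²ψ, u(0) = 0 (no slip at the
  membrane) and u'(L) = 0 (free stream).

Frame and sign convention: in the cell frame the far-field electroosmotic
velocity is −µE, so µ ≔ −u(L) and a negatively charged layer gives µ < 0.
The convention is pinned by the Smoluchowski case (f ≡ 0, ζ = −25 mV →
µ = εζ/η ≈ −1.95×10⁻⁸ m²V⁻¹s⁻¹).

### Discretization and numerical checks

Both problems are discretized with second-order central differences on a
uniform grid (default 2000 nodes) and solved with a banded direct solver;
Neumann conditions use ghost nodes. Friction and charge profiles are stored
as cell averages so the trapezoid rule integrates the fixed charge to the
prescribed surface charge exactly. The discrete residual is checked against
a 10⁻⁸ tolerance; doubling the node count changes µ by < 0.1%. An
independent closed-form solution for a single piecewise-constant layer
(hyperbolic modes matched at z = β, `glyx.analytic`) agrees with the
finite-difference mobility to ~10⁻⁶ relative at default resolution, far
inside the 10⁻³ validation band used in the tests. The closed form is
singular where κ² = f₀/η; validation sweeps exclude a ±5% neighbourhood of
that resonance.

### Parameters

| parameter | default | meaning |
|---|---|---|
| ionic strength | 0.145 mol/L | physiological saline |
| temperature | 298.15 K | room-temperature electrophoresis |
| viscosity η | 8.9×10⁻⁴ Pa·s | water at 25 °C |
| relative permittivity | 78.5 | water at 25 °C |
| β | 7.8 nm | red-cell glycocalyx thickness |
| native segment radius a | 0.6 nm | Stokes radius of a glycocalyx element |
| native segment density | 1.4×10¹⁷ m⁻² | calibration input, see below |
| total surface charge σ | −0.0138 C/m² | sialic-acid charge, spread over [0, β] |
| cell area | 1.4×10⁻¹⁰ m² | converts molecules/cell to m⁻² |
| graft radius | 4.6×10⁻¹¹·M⁰·⁴ m | compact branched-polymer scaling, 2.4 nm at 20 kDa |
| outer interval | 2.7 nm – β | "outer" grafting scenario |

The native segment density and total charge are **inputs, not claims**:
they were calibrated once so that the ungrafted mobility lands in the
physiological range for red cells (−1.03×10⁻⁸ m²V⁻¹s⁻¹ ≡ −1.03 µm·s⁻¹ per
V·cm⁻¹ at the defaults). Grafts are treated as uncharged (polyglycerol is a
neutral polyol) and contribute one segment per molecule by default
(configurable).

### Scenario fitting and identifiability

`fit_scenario` performs weighted least squares of measured mobilities
against the model under each grafting scenario independently, optimizing
the selected free parameters in log space from a deterministic multi-start
grid, and selects the scenario with the lower SSE. If the two SSEs agree
within 1% (relative) the result is reported as "indistinguishable" rather
than forcing a winner.

The default free parameter is the **native segment density**, not the graft
radius. With the graft radius free, the two scenarios are nearly
observationally equivalent — a uniform-depth fit can absorb an
outer-weighted shift into a ≈1.5× larger radius because the flow barely
penetrates the basal layer, so the extra basal friction it implies is
almost invisible in µ. The graft radius is, in practice, known from polymer
characterization, while the native layer's friction density is the
genuinely uncalibrated input. With segment density free, Monte-Carlo
self-recovery at 2% measurement noise identifies the generating scenario in
≥ 95% of datasets and recovers the parameter within a few percent.

## Z-stack quantification

Coordinates: slice k spans [k·Δz, (k+1)·Δz) with Δz = 0.2 µm by default;
z = 0 is the bottom slice. Per-slice signal is the median fluorescent
intensity (MFI) over ROI pixels; an integrated-intensity mode (`stat="sum"`)
exists because published quadrant statistics are ambiguous between the two.

* **Membrane reference**: the slice with maximal within-ROI membrane MFI
  (ties to the lowest index). Probe measurements start one slice above it.
* **Top detection**: the highest slice at/above the start whose probe MFI
  exceeds a threshold that is the larger of (a) a noise background,
  tail mean + k_σ·SD (k_σ = 2) estimated over the top 10% of slices, with
  the SD floored by the pixel-level SD of that tail region — the SD across
  only 4–5 slice medians is too poorly estimated to threshold against — and
  (b) a half-maximum edge criterion, tail mean + 0.5·(peak − tail mean). A
  pure background threshold detects the faint axial-PSF tail of the layer
  edge and overestimates heights by ≈ 2.3·σ_PSF (20–30% error on strongly
  compressed layers); the half-maximum criterion places the detected edge
  of a blurred boundary at the true boundary, which is why it is the
  standard edge rule in profile-based thickness measurements.
  `signal_fraction=0` restores the pure background rule.
* **Quadrants**: the continuous span [z(start), z(top)+Δz) is divided into
  four equal intervals Q1…Q4; each slice's signal is apportioned by the
  overlap of its one-slice extent with each quadrant, so no slices are
  dropped for non-divisible spans and the fractions are unbiased for any
  span length. Fractions sum to 1 by construction and mirror correctly
  under axial flips.
* **Height**: (top − start + 1)·Δz.
* **Density ratio**: integrated probe intensity divided by integrated
  nuclei (Hoechst) intensity as a cell-number proxy. The probe integral
  runs from the membrane-reference slice (inclusive) upward: the layer is
  anchored at the membrane, so axial blur pushes part of the basal signal
  into the membrane slice, and truncating there loses proportionally more
  mass the more the layer is compressed (−8% apparent mass at compression
  0.4 versus −3% with the membrane slice included). Integrated intensity
  rather than nucleus counting keeps the proxy robust at fixture scale;
  connected-component counting is not implemented.
* **Photobleach normalization**: per-slice ratio of the in-glycocalyx
  profile to a free-dye profile outside the cell. Any per-slice
  multiplicative bleaching factor applied to both regions cancels exactly
  (machine precision), which is the point of the ratio.

One result is produced per ROI; field-level summaries average ROIs with
equal weights.

## Synthetic data

The generator emulates a spinning-disk confocal acquisition of a cultured
endothelial monolayer: a membrane channel with a Gaussian axial focus peak
(σ = 0.25 µm) at 2.1 µm, a probe channel occupying a 4 µm layer above it
(uniform, outer-weighted, or compressed toward the membrane), 48 slices at
0.2 µm, an axial Gaussian PSF of σ = 0.3 µm (axial FWHM ≈ 0.7 µm, typical
of high-NA spinning-disk systems), Poisson shot noise at an expected
plateau of 200 counts/pixel (plateau SNR ≈ 14), Gaussian read noise
(SD = 2), and optional geometric per-slice photobleaching applied to all
channels. Only axial blur is modelled: the quadrant analysis is purely
axial, so lateral realism would add nothing testable. All generators are
byte-deterministic for a fixed seed.

Two distinct crowder-series generators reflect two distinct experiments:

* `gen_collapse_series` renders the layer *during* crowding, compressed
  toward the membrane by a per-dose factor c with probe mass conserved
  (per-slice density ∝ 1/c), plus an uncompressed after-washout stack. This
  produces the height-collapse, density-conservation and
  dextran-concentration trends.
* `gen_graft_series` renders the grafted probe *after* washout: during
  crowding at compression c only the outer, solution-accessible part of
  the layer can be reached, so after re-extension the grafted probe
  occupies the outer interval [(1−c)·h, h]. c = 1 gives a uniform
  distribution; decreasing c shifts occupancy toward Q4. A compressed
  probe density cannot itself produce a rising Q4 through the quadrant
  pipeline — the detected span tracks the compressed signal and
  re-normalizes a uniform layer back to quarters — so the accessibility
  mapping is the mechanism that links dose to outward redistribution.

Cytometry events are log-normal with the median at the group truth and a
CV of 0.1 interpreted on the log scale; each replicate MFI is the median
of 10 000 events, following standard acquisition practice. Replicate MFIs
therefore vary only through event sampling; an optional replicate-level CV
(default 0) can add day-to-day variation.

What passing tests on these fixtures do **not** show: robustness to lateral
heterogeneity, cell morphology, segmentation error, optical aberrations
beyond a Gaussian axial PSF, autofluorescence, or cytometry gating and
compensation — real acquisitions need upstream handling of all of these.

## Camouflage metrics

Relative protection is the percent reduction of antibody-binding MFI
versus unmodified control cells, 100·(1 − MFI_mod/MFI_ctrl), computed from
condition-mean replicate MFIs; this is the standard immunocamouflage
readout, stated explicitly because the figure-level quantity depends on it.
Negative protection (binding above control) is reported and flagged, never
clipped — clipping would hide failed grafting. Fold enhancement is the
ratio of crowded to non-crowded protection. Group comparisons use the
two-tailed Welch t-test (scipy's unequal-variance t-test; Satterthwaite
degrees of freedom), cross-validated in the test suite against a direct
evaluation of the Welch formulas. Isotype background subtraction is not
modelled (the synthetic truths are background-free).

## Numerical and degenerate-input conventions

* Solver tolerance 10⁻⁸ on the scaled discrete residual; mobility solves
  require L ≥ β + 8κ⁻¹.
* Membrane-peak ties break to the lowest slice; a flat membrane profile, a
  probe profile at background, zero total quadrant signal, zero nuclei
  signal and zero outside-reference intensity are all hard errors rather
  than silent defaults.
* Fits with fewer points than free parameters raise; exactly-determined
  fits warn.
* Quadrant problem sizes: validation fixtures use 48-slice stacks (0.2 µm)
  for noisy round-trips and 200-slice fine grids (0.05 µm) for
  continuous-limit checks; Monte-Carlo validations use 20 mobility
  datasets and 3 stack seeds per condition. These sizes are chosen so the
  full validation suite runs in seconds while keeping Monte-Carlo
  uncertainty well inside the tolerances tested.

## Known limitations

* The electrokinetic model is linear, flat and quasi-static: no curvature
  (Henry) or relaxation corrections, no charged grafts, no field-induced
  layer deformation.
* Graft friction assumes uniformly distributed, non-interacting segments;
  excluded-volume effects between grafts at high density are not modelled.
* Top detection assumes the top ~10% of slices are signal-free; a layer
  reaching the top of the stack violates the background estimate.
* The accessibility mapping c → outer interval is a deliberately simple
  stand-in for grafting kinetics during collapse; it reproduces the
  direction and monotonicity of the dose response, not its quantitative
  shape.
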