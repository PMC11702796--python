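# Methods

## Two-state denaturation models

Both fit equations describe a reversible two-state equilibrium between a
native and an unfolded ensemble whose populations follow a Boltzmann factor
in the relevant driving variable:

* thermal: `y(T) = Yn + Yd·σ(u)`, `u = (ΔH_app/R)(1/Tm − 1/T)`, with σ the
  logistic function;
* chemical: `y(x) = Yn + Yd·σ(v)`, `v = −(ΔG_app − m·x)/(RT)` (linear
  extrapolation model), fitted at a fixed temperature of 298.15 K (room
  temperature).

`Yn` is the pre-transition baseline and `Yd` the transition amplitude, i.e.
the post-transition level is `Yn + Yd`.  The two symbols are often loosely
described as the "pre and post transition signal"; the algebra above is what
is implemented, and the model value at the fitted midpoint is exactly
`Yn + Yd/2` (a tested identity).  Baselines are condition-independent
constants — no sloped pre/post baselines — keeping the parameter count at
four.  Thermal unfolding of the motivating system is irreversible, so every
thermal parameter is labelled *apparent*; no reversible-thermodynamics
interpretation is attached to ΔH_app.

The gas constant is R = 1.9872×10⁻³ kcal/(mol·K); all energies in the
package are molar, so the Boltzmann constant is the same number and PMF/Cv
units are kcal/mol-based throughout.

### Observable channels

A spectra series is reduced to one scalar per condition by one of three
channels:

* `lambda_max` — wavelength of maximal emission, refined by a parabola
  through the maximal sample and its neighbours (sub-grid resolution;
  boundary maxima are flagged and returned unrefined);
* `peak_intensity` — parabola-refined height of the emission maximum;
* `integrated_intensity` — trapezoidal area under the spectrum.

For a spectrum that is a mixture `(1−fu)·Gn + fu·Gu` of two fixed bands,
only the integrated intensity is *affine* in the unfolded fraction `fu`;
λmax and the peak height are smooth but nonlinear functions of `fu`, which
biases absolute fitted parameters (apparent Tm from the peak-intensity
channel sits a few kelvin below the generating value) while largely
cancelling in wild-type-minus-mutant differences.  Default reporting
channels are `peak_intensity` (thermal) and `lambda_max` (chemical), the
observables the experiments emphasise; recovery-accuracy checks and the
analysis scripts use `integrated_intensity`.  Exact parameter recovery
(noise-free, 1×10⁻⁴ relative) is only claimed — and only possible — on the
affine channel.

### Fitting

Nonlinear least squares (`scipy.optimize.least_squares`) with deterministic
initialisation: `Yn` from the first three points, `Yn+Yd` from the last
three, the midpoint (Tm or D½) from the linear interpolation of the
half-amplitude crossing, ΔH_app starting at 50 kcal/mol and m at
2 kcal/(mol·M); five additional restarts jitter the initial vector by ±30%
(fixed RNG), and the lowest-RSS solution wins.  Tm is bounded to the
observed range ±20 K; ΔH_app and m are positive.  Standard errors come from
the Jacobian at the optimum (`cov = (JᵀJ)⁻¹·RSS/dof`).  Curves whose total
range does not exceed five times the median absolute successive difference
are rejected as transition-free before any fit is attempted.

### Stability deltas

`ΔTm = Tm(WT) − Tm(variant)` (positive = destabilising),
`ΔD½ = D½(unfolding) − D½(refolding)` per variant (hysteresis of the
irreversible chemical cycle), and `ΔΔD½ = ΔD½(WT) − ΔD½(variant)`.

## Synthetic fluorescence spectra

Each condition's clean spectrum is `(1−fu)·Gn(λ) + fu·Gu(λ)` with Gaussian
bands and `fu` given by the two-state model at that condition; i.i.d.
Gaussian noise (default σ = 1 a.u., 1% of the native amplitude) is added.
Defaults emulate tryptophan emission: native band 330 nm/width 12/amplitude
100, unfolded band 350 nm/width 14/amplitude 55 (red-shifted and weaker —
enforced invariants), wavelengths 290–360 nm at 1 nm, thermal conditions
293–363 K at 5 K, chemical conditions 0–4 M at 0.25 M.  What it does *not*
emulate: aggregation drift, sloped baselines, buffer background, lamp
fluctuations, or any three-state intermediate — so passing recovery tests
demonstrates estimator correctness, not robustness to those real-data
pathologies.  One consequence worth knowing: once the native band has fully
decayed, the spectrum maximum sits on the unfolded band and the
peak-intensity channel creeps back up toward that band's amplitude; the
monotone decay claimed for this channel holds through the transition
(up to ≈90% unfolded), not asymptotically.

## Zimm–Bragg replica-exchange system

The simulation stand-in is a helix/coil chain of N = 30 residues.  A
configuration's statistical weight at temperature T is
`σ_zb^(runs) · s(T)^(n_h)` with nucleation parameter σ_zb ∈ (0,1] (default
1: independent sites, keeping every closed form elementary) and propagation
weight

    s(T) = exp((ΔH_prop/R)(1/T − 1/T_ref)),

so helix is favoured below T_ref and melts on heating.  The per-frame
energy is `E = −ΔH_prop·n_h`, which makes the weight factor as
`g(x)·exp(−E/RT)` with g temperature-independent; the standard energy-based
replica-swap criterion `min(1, exp[(1/RT_i − 1/RT_j)(E_i − E_j)])` is
therefore exact, and WHAM's one-dimensional energy histograms capture the
full temperature dependence.  Defaults: ΔH_prop = 15 kcal/mol,
T_ref = 330 K (placing the melting midpoint on the wild-type experimental
scale), an 8-temperature ladder over 300–360 K, 20 000 frames per replica,
one sweep (N attempted single-residue flips) per frame, swap attempts every
10 frames alternating even/odd adjacent pairs.  The ladder count is kept at
8 (rather than the ~20 of large all-atom studies) with the span chosen so
adjacent-pair acceptance stays in the ~0.2–0.6 range.  Rg is an affine
readout `Rg_coil − (Rg_coil − Rg_helix)·n_h/N` plus Gaussian noise
(17 Å helix, 30 Å coil, σ = 0.5 Å); it carries no excluded-volume physics
and is not meant to reproduce any particular real domain's compaction.

The transfer matrix `[[s, 1], [σs, 1]]` with first-residue weights (σs, 1)
gives Z; propagating first and second derivatives with respect to ln s
yields ⟨n_h⟩ and Var(n_h), hence exact ⟨E⟩(T), helix fraction
θ = ⟨n_h⟩/N, and `Cv = ΔH_prop²·Var(n_h)/(RT²)`, which equals d⟨E⟩/dT
exactly for this family of weights (tested both ways).  For σ_zb = 1 the
chain reduces to independent units with `θ = e^u/(1+e^u)` and
`Cv = N·R·(ΔH_prop/RT)²·e^u/(1+e^u)²`, `u = (ΔH_prop/R)(1/T − 1/T_ref)` —
note the `(ΔH_prop/RT)²` prefactor: the factor u² sometimes quoted for
two-level systems applies only when the level populations are controlled by
`ΔH/RT` alone (T_ref → ∞).

All Monte-Carlo randomness flows through a single seeded stream inside the
compiled kernel (numba), making runs bit-reproducible for a given seed
regardless of platform threading; per-replica sub-streams were considered
and dropped since the single kernel is already deterministic.

## WHAM

Direct iteration of

    Ω(E_b) = Σ_k n_k(E_b) / Σ_k N_k·exp(f_k − E_b/(R·T_k))
    exp(−f_k) = Σ_b Ω(E_b)·exp(−E_b/(R·T_k))

with f₁ pinned to 0, log-sum-exp arithmetic everywhere, convergence at
max|Δf_k| ≤ 1×10⁻⁷ (default) within 10 000 iterations; non-convergence
returns the partial solution flagged.  Energies are histogrammed into 200
equal-width bins by default; each *occupied* bin is represented by the mean
energy of its samples rather than its geometric centre, which removes the
quantisation bias that coarse bins would otherwise impose on discrete-level
systems and changes nothing in the dense limit.  Empty bins carry zero
density and are never smoothed.  No autocorrelation or statistical-
inefficiency correction is applied — frames at one temperature enter with
uniform weight, exactly as sampled — so quoted statistical checks use
block-based standard errors that absorb the correlation; this is a
documented limitation, not an oversight.

Reweighted energy moments use the binned density of states; PMFs and Rg
melting curves use per-frame weights
`w_i(T) ∝ exp(−E_i/RT) / Σ_k N_k·exp(f_k − E_i/RT_k)`.  Cv grids default to
0.5 K steps across the ladder; the Cv peak (and hence Tm) is refined by a
parabola through the grid maximum and its neighbours.  Requesting
temperatures more than 25 K outside the ladder raises an extrapolation
error.  The melting enthalpy ΔH_m used by the impact conversion is the
trapezoidal area of the Cv peak above a flat baseline at half its maximum,
integrated between the two half-maximum crossings.

PMF landscapes default to (Rg, helix fraction) on 50×50 bins; the minimum
over finite bins is anchored at 0 and empty bins are +inf (unreachable),
never 0.

## Impact aggregation

Conversions: `ΔΔG ≈ ΔH_m·ΔTm/Tm` for melting-point shifts (simulation:
ΔH_m from the Cv-peak area and Tm from the wild-type Cv peak; experiment:
the wild-type fitted ΔH_app and Tm — the wild type is the common reference
in the denominator) and `ΔΔG ≈ m·ΔD½` for chemical shifts.  The pipeline
negates the melting-shift conversions so destabilising shifts carry
negative ΔΔG, matching the predictor-tool convention
(ΔΔG negative = destabilising); the standalone conversion functions
preserve the sign of the shift they are given.  The chemical component uses
`D½,unfolding(variant) − D½,unfolding(WT)` with the wild-type unfolding
m-value by default; the per-variant unfolding/refolding hysteresis is
reported separately and can be routed into the component instead via
configuration (`cd_convention: hysteresis`), since the symbol ΔD½ is used
for both quantities in the field.

Predictor tables (one ΔΔG per mutation×tool) reduce to one value per
mutation by the mean across tools by default; median or a single named tool
are selectable.  The four components enter as absolute values — a
stabilising shift is still a perturbation — and the per-mutation sum is
divided by the largest sum (the scaling factor), so the score is
scale-invariant, order-invariant, lies in [0, 1], and the most affected
mutation scores exactly 1.  Missing components must be opted into per
mutation and then count as zero, recorded in provenance.  Reference
agreement is the sample Pearson correlation over the shared mutation set
(≥3 mutations, non-zero variance required).

## Synthetic study conditions

The bundled study mirrors the motivating experiment's structure: WT plus
five variants, with ground truths on the experimentally reported scale —
WT apparent Tm 333 K and ΔH_app 50 kcal/mol; chemical m-value
2 kcal/(mol·M) with WT D½ = 2.0 M and 0.365 M unfolding/refolding
hysteresis; the three least stable variants (R1020S, K1047Q, G1063V)
averaging a 10 K Tm drop with R1020S worst in every channel; simulation
T_ref values making R1020S the only simulation-destabilised variant (the
others mildly stabilised); predictor ΔΔG drawn per tool around per-variant
means with 0.3 kcal/mol scatter; reference pathogenicity-style scores in
[0, 1] with 0.03 scatter.  Analysis scripts use 6 000 frames per replica
(the full 20 000-frame configuration is exercised by the validation suite);
the smaller runs change the statistical, not systematic, quality of the
WHAM estimates.

## Numerical and degenerate-input choices

* Logistic terms are evaluated with `scipy.special.expit`; WHAM uses
  log-sum-exp exclusively, so absolute energy offsets are harmless (a
  tested translation invariance).
* Parabolic refinements fall back to the raw grid point at boundaries or
  when curvature vanishes.
* Flat spectra (no unique maximum), transition-free curves, empty series,
  out-of-range helix fractions, duplicate predictor keys, and fewer than
  two replicas with exchanges enabled all raise named validation errors;
  an empty predictor table only warns.
* Equal-temperature ladder pairs are permitted (their swaps are always
  accepted) as a diagnostic; decreasing ladders are rejected.

## Known limitations

No three-state or sloped-baseline denaturation models; no MBAR, umbrella
biases, or autocorrelation analysis; no all-atom geometry behind the
helix-coil stand-in, so absolute simulated quantities (Tm ≈ 327 K, Rg
range) characterise the synthetic chain, not any real protein.  Variant
labels are opaque strings: the motivating literature uses both K1034Q and
K1047Q for the same lysine variant, and this package deliberately performs
no renumbering or validation of mutation nomenclature.
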