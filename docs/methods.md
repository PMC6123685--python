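# Methods

This note documents the models, estimators, numerical choices and
limitations of `ryrcicr`, in the order a user meets them in the pipeline.

## Biphasic CICR activity model

Channel activity on the B/Bmax scale is modeled as
`A = Amax · fA · (1 − fI)` with Hill occupancies `fA`, `fI` of an activating
and an inactivating Ca²⁺ site. Assumptions: equilibrium binding (no gating
kinetics), independent sites, and no Mg²⁺ competition — the assay media the
model targets either carry a fixed Mg²⁺ background absorbed into the
apparent constants or remove the low-affinity site altogether (1 M NaCl, no
Mg²⁺, handled by the monophasic `inactivation=off` fit mode).

Parameters and defaults:

* `Amax` (dimensionless gain, B/Bmax scale) — free in fits, initialized at
  the largest observed mean.
* `KA`, `KI` (mol/L) — free; stored in mol/L everywhere, written as pKA/pKI
  in files. Keeping a single internal unit prevents nM/M mix-ups between
  imaging and binding scales.
* `nA`, `nI` (Hill coefficients) — fixed during each fit; default 2.0 / 1.0,
  the pair a ΣR² grid search selects on panel data.

`pCa50` is defined as `−log10(KA)`, the half-point of `fA`: with the Hill
coefficients fixed, `fA = 0.5` exactly at `[Ca²⁺] = KA`, which makes the
fitted `KA` the natural sensitivity readout. The half-point of the composite
biphasic curve is a distinct, slightly larger number when `KI` is close to
`KA`; it is exposed as `pca50_composite` for users who prefer that reading,
and the default is the `KA`-based definition.

Numerics: Hill fractions are evaluated as logistic functions of
`n·ln(ca/K)` (`scipy.special.expit`), which is exact, monotone and immune to
overflow at any representable pCa; `1 − fI` is computed directly as the
complementary logistic to avoid cancellation. Property tests confirm
agreement with the naive power form to 1e−10 relative wherever the naive
form is finite.

The resting-activity extrapolation evaluates `A` at pCa 7 (100 nM, the
resting cytoplasmic level). For a pure A-site shift the mutant/wild-type
ratio approaches `(KA_wt/KA_mut)^nA` as Ca²⁺ → 0; with `nA = 2` an eightfold
affinity gain therefore yields a ~64-fold resting-activity increase — the
amplification that links modest pCa₅₀ shifts to arrhythmogenic leak.

## Curve fitting and panel selection

Fits are nonlinear least squares (lmfit, trust-region `least_squares`
backend) over `Amax`, `pKA` and, in biphasic mode, `pKI`, with the Hill pair
fixed. Optimization runs in pK space with bounds pKA ∈ [2, 9], pKI ∈ [0, 9],
Amax ∈ (0, 10]. Because biphasic least-squares surfaces are multimodal, each
fit is multi-started: `pKA` from every observed pCa grid point, `Amax` from
the largest observed mean, `pKI` one decade below the starting `pKA`; the
best start by SSE wins. Convergence ties below 1e−14 in SSE keep the first
(lowest-pKA-start) solution, making results independent of data-row order.

All replicate points enter the fit with equal weight (the replicate count is
information; a means-only mode exists for emulating published-figure fits
and, with balanced replicates, lands on the same optimum). Standard errors
come from the covariance of the single fit; R² is computed against the
points actually fitted.

Lost-binding rule: when the largest per-pCa mean is below 0.01 on the
B/Bmax scale, or below 3× the pooled replicate SD, the curve is reported
`not-determined` instead of fitted — mutations that abolish binding have no
meaningful pCa₅₀, and inventing one from noise would be worse than a flag.

Hill-pair selection fits every panel curve at every candidate `(nA, nI)` and
keeps the pair with the largest ΣR², ties broken toward the smaller
coefficients. On noiseless panels the generating pair is the exact maximum.
On noisy panels `nA` is well identified (the activation limb is densely
sampled on an 8→3 pCa grid) but `nI` is weakly identified whenever `KI`
lies near the low-pCa edge of the grid, where the descending limb is barely
sampled: ΣR² margins between adjacent `nI` grid values are then of order
1e−3 and the selected `nI` can wander at replicate-noise level. Tests
therefore pin the full pair only on noiseless data and the activating
coefficient on noisy data.

Scatchard analysis regresses `B/F` on `B` (slope `−1/Kd`, x-intercept
`Bmax`) by ordinary least squares; on noiseless single-site data the
Scatchard transform is exactly linear, so recovery is exact. A non-negative
slope (no saturable binding) is a hard error, not a number.

## Free-Ca²⁺ speciation

The buffer module solves 1:1 metal–chelator mass balance: free Ca²⁺ is the
root of `free + Σ bound_i(free) − total`, found by bracketed Brent iteration
on `[~0, total]`; the function is strictly monotone, so convergence is
guaranteed and the mass-balance residual at the solution is at machine
precision (tested to 1e−12 relative). Mg²⁺ competition is handled by a
nested inner solve of the Mg balance at each trial free-Ca value. The
inverse problem (total Ca needed for a target free Ca) is closed-form.

The module deliberately operates on *apparent* constants valid at the
user's pH/ionic strength/temperature; a pH correction from absolute
constants is available via the cumulative protonation polynomial
`Kd_app = Kd_abs(1 + Σ_j 10^(Σ_{i≤j} pKa_i − j·pH))`. Ionic-strength and
temperature corrections are out of scope: published chelator constants
disagree between databases, and shipping one set as ground truth would lend
it false authority. Any constants appearing in examples or tests are
illustrative.

## Trace analysis

Normalization is `(F − Fmin)/(Fmax − Fmin)` with per-cell calibration
anchors; when a cell lacks its own floor, the channel defaults apply — 0 for
cytoplasmic indicators and 7.655% of Fmax for the ER-luminal indicator,
whose calibration floor does not reach zero.

The oscillation detector is deterministic: the trace is smoothed with a
0.3 s moving average, a rolling 15 s median forms the baseline, and events
are excursions above baseline + 5 robust sigmas (1.4826·MAD of the smoothed
residual) with hysteresis (events close at 50% of the rise threshold) and a
2 s refractory merge. The short pre-smoothing step is what makes counting
reliable down to spike amplitudes of ~5 noise SDs: it shrinks the effective
noise by ~√3 while leaving second-scale spikes nearly intact, so the
5-sigma threshold sits well below the spike peaks without admitting false
positives. Requires ≥ 30 s of data at ≥ 1 Hz.

The "upper ER level" (the refilled envelope of the sawtooth store signal)
is the 95th percentile of the normalized ER trace within the analysis
window — percentile rather than maximum for noise robustness, configurable.
Which window to read (whole control period vs plateau) is a user choice;
the default is the full window passed in.

Caffeine dose–response is a four-parameter monotone Hill fit (floor,
ceiling, EC₅₀, hill) with EC₅₀ optimized in log space; fits whose EC₅₀
falls outside the tested dose range are flagged rather than rejected.
Box-plot summaries use linear-interpolation quartiles (not Tukey hinges) so
that the documented examples are exact.

## Structure comparison

Coordinates are read with gemmi from PDB or mmCIF; one protomer chain is
analyzed (first alphabetically unless specified — the channel is a
homotetramer, so the choice is a convention). Alternate locations keep the
highest-occupancy conformer; residues missing from either model are dropped
pairwise.

Domain displacement between two ligand states superposes state B onto state
A by Kabsch least squares on the Cα atoms of a reference selection, then
reports the mean per-Cα displacement and centroid shift of the target
domain. The default reference frame is the transmembrane + S6c region
(residues 4540–4956 in the RyR1 numbering) — the least mobile frame for
"upward/rightward" domain motions — and it is configurable because
published overlays do not state their frame. The Kabsch implementation is
cross-checked against gemmi's superposition in the test suite.

The binding-pocket gauge projects the metal-coordinating oxygens
(carboxylates of the two glutamates, the glutamine amide oxygen, the
threonine main-chain carbonyl) onto their best-fit plane and reports the
convex-hull area of the projection plus all pairwise distances. This is an
explicit *proxy* for pocket size — rotation/translation invariant, scaling
quadratically, suitable for ranking the same site across ligand states —
not a cavity-volume computation, and the absolute Å² values it produces are
not comparable to areas measured by other procedures.

## Synthetic data: what it emulates and what it does not

Generators draw every input forward from the models above: binding curves
as `A(truth) + N(0, σ)` truncated at zero (σ = 0.02 on the B/Bmax scale,
n = 4 replicates, 12-point pCa grid from 8 to 3 by default — the replicate
structure and noise scale of the emulated assays), single-site saturation
series, antiphase spike/sawtooth trace pairs with appended Fmin/Fmax
calibration segments, and two-domain coordinate fixtures whose rigid
displacement is known exactly. All generators are deterministic under a
fixed integer seed.

Truncation at zero introduces a small positive bias at near-zero activity
(mean ≈ 0.8% of scale at σ = 0.02); recovery tests show the resulting
pCa₅₀ bias is below 0.001 pCa units at the default noise, and bias
assertions are made only at σ ≤ 0.02.

What passing the round-trip tests shows: the estimators recover the
generating truths at the stated noise. What it does not show: robustness to
features real data have and the generators lack — pipetting-correlated
replicate errors, baseline drift and photobleaching in traces, partial
occupancy and model-building error in coordinate models, and chelator
constant uncertainty in buffer design. Genotype truth values not printed in
the source literature are tagged ILLUSTRATIVE in the generator manifest and
are never treated as published values.

## Problem sizes

Default test and acceptance runs use the study-scale problems directly:
48-point curve fits (12 pCa × 4 replicates), 6-curve selection panels over
a 5 × 4 Hill grid, 36-observation dose–response fits, 60-residue coordinate
fixtures, and 10³-draw property sweeps. These sizes are the conditions the
estimators are specified for, and every stage completes in seconds to a few
minutes.

## Known limitations

* Caffeine is a condition label, not a mechanism: ± caffeine curves are fit
  independently, with no shared-parameter or allosteric model.
* No kinetic (time-dependent) gating, no Mg²⁺-competition term, no Bayesian
  uncertainty; standard errors are single-fit covariances.
* `nI` selection is noise-limited when the inactivation limb is poorly
  sampled (see above).
* The pocket gauge ranks states; it does not measure cavities.
* The free-Ca²⁺ calculator is only as good as the constants supplied to it.
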