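# Methods

## Scope and data model

`pixelet` analyzes per-pixel hit tables (`x`, `y`, `toa_ns`, `energy_keV`;
0-based coordinates on a 256×256 matrix, per-pixel calibration assumed done
upstream) from a silicon pixel detector operated partially depleted in
proton and helium-ion beams behind PMMA absorbers. The package covers the
full measurement chain — clustering, saturation recalibration, ion
spectroscopy, LET spectra and averages, spectrum comparison, mMKM RBE — and
a synthetic generator that emulates the statistical structure of such data
so the chain can be validated without measurement files.

## Cluster formation

Connectivity is 8-adjacency (diagonals included; repeated firings of the
same pixel count as neighbors too), and the coincidence criterion — time
difference ≤ `dt_max_ns`, default 850 ns — applies to *adjacent pairs
chained transitively*, not to the global cluster span. The pairwise reading
matches how drift-time spreads accumulate across a large cluster: the first
and last pixel of a long ionization footprint may legitimately differ by
more than the window while every neighboring pair is close. The partition
is computed with union-find and is invariant under input permutation;
output clusters are ordered deterministically by (reference time, first-hit
x, y).

Cropped-cluster repair — a second pass merging spatially abutting clusters
whose reference times differ by less than `repair_window_ns` — is available
for data with corrupted timestamps but disabled by default (`None`): the
synthetic generator never produces such artifacts, and an unconditional
merge pass would join genuinely distinct ions that happen to land adjacent
within the repair window.

Noise rejection removes single-pixel clusters and clusters below
`cutoff_keV = 30` on the volume. The per-pixel 3 keV threshold is treated
as already applied upstream; the generator enforces it at rasterization.

## Volcano-effect recalibration

Measured volumes are corrected with `E_rec = −(1/k)·ln((p − E)/q)`,
defaults `k = 0.155 ± 0.007 /MeV`, `p = 6.39 ± 0.25 MeV`,
`q = 6.40 ± 0.25 MeV`. The parameters are interpreted in MeV: helium
Bragg-peak depositions of several MeV require `p ≈ 6.39 MeV` for the log
argument to stay positive. Cluster volumes (keV elsewhere throughout the
package) are converted at this boundary only.

The correction is applied over the full measured range; whether a lower
threshold should exempt small depositions is undocumented for the original
fit, so none is imposed (at 0 MeV the correction is a negligible
+0.010 MeV). Events measured at or above `p` are unrecoverable; they are
counted and reported (`n_saturated_`, fraction in the pipeline log) and
returned as NaN — never clipped, because clipping would bias LET_d, whose
weighting emphasizes exactly those high-deposition events.

Uncertainty scenarios: *upper*/*lower* shift (k, p, q) jointly by ±1σ. The
joint shift treats the fit parameters as fully positively correlated — the
conservative choice when the covariance has large off-diagonal entries —
and brackets the mean curve pointwise over the usable domain.

## Synthetic data generator

The generator is the package's stand-in for both measurements and
transport-code references; it contains **no transport physics**. What it
does and does not emulate:

* **Straggling law.** Per-ion depositions in the depleted thickness are
  Moyal-distributed — a closed-form, right-tailed stand-in for
  Landau–Vavilov with an analytic mean (`loc + scale·(γ + ln 2)`) used by
  the recovery tests. A Gaussian option exists for near-peak spectra, where
  the real distribution symmetrizes. Real Landau tails are heavier; the
  Moyal choice trades tail fidelity for testability.
* **Depth dependence.** The primary location follows a Bragg-like power law
  in residual range, `loc(z) = loc(42 mm)·((R−42)/(R−z))^0.45`, with
  R = 132 mm (proton) / 133 mm (helium) PMMA and entrance locations
  170 keV / 680 keV, capped at 2.2 / 5.0 MeV near the peak; the scale is
  6 % of the location (floor 8 keV), so spectra shift and broaden with
  depth. These are phenomenological knobs chosen once for realistic
  magnitudes, not fits to any published depth profile.
* **Fragments.** Helium scenarios add lighter projectile fragments
  (hydrogen, location = primary/4, i.e. the Z² ratio at equal velocity);
  proton scenarios add heavier target fragments at 3× the primary location
  with doubled width. The admixture is an exact count,
  `round(fragment_fraction · n_primaries)`, so gating recovery is testable
  against binomial statistics.
* **Saturation.** The forward volcano model `E_meas = p − q·exp(−k·E_true)`
  — the algebraic inverse of the recalibration, giving exact round-trip
  recovery (residual < 1e−9 MeV).
* **Charge sharing.** An isotropic Gaussian kernel integrated over pixel
  boundaries, centered at a random sub-pixel offset, with width
  `σ = 0.45 + 1.1·√(E/MeV)` pixels so cluster size grows with deposition —
  the correlation the (size, volume) gating exploits. Real charge sharing
  is anisotropic along the track and bias-dependent; none of that is
  modeled.
* **Noise.** Poisson-count single-pixel hits, energies uniform in
  (3, 29.9) keV, so the documented cutoff removes exactly this population.
* **Timing.** Events are spaced 20 µs apart with ≤ 100 ns intra-cluster
  jitter; pile-up (two ions inside one coincidence window on overlapping
  pixels) is therefore rare by construction, not handled.

Consequently, passing recovery tests demonstrates the *analysis chain* is
self-consistent (clustering finds the generated ions, recalibration inverts
the distortion, gating recovers species fractions, LET_d returns to truth
within its stated uncertainty); it does not validate transport physics,
beamline modeling, or detector response beyond these idealizations.

All samplers take explicit seeds (`numpy.random.default_rng`); a fixed seed
gives byte-identical datasets. No global random state is used.

## Ion spectroscopy

Gating operates in (size, log₁₀ volume) space — the log stabilizes the
four-decade dynamic range of cluster volumes. Default regions are derived
from the data: the log-volume histogram (60 bins, 3-bin moving average) is
searched for prominence-filtered modes (prominence ≥ 5 % of the maximum);
for helium beams the valley between the two principal modes separates
region I (below) from region II, and the point where the smoothed density
falls below 0.5 % of the main mode bounds region II from region III. A
valley is only accepted if it dips below half the smaller mode — counting
noise inside one physical locus must not read as a second species. Region I
exists only for helium scenarios. Explicit polygons can be supplied as
JSON (label + vertex list) instead.

Assignment is first-match in the fixed order I, II, III, boundary-inclusive
(overlaps are permitted and logged). The sensitivity check scales each
polygon about its centroid by a contraction/dilation pair (default
0.9/1.1) and reports per-label count deltas, mirroring the
smaller/larger-region protocol used with hand-drawn gates.

## LET spectra and averages

Energy spectra are histogrammed in half-open [lo, hi) bins with a
range-based width lookup: 1–30 keV for proton spectra and 10–400 keV for
helium spectra, stepping up with the spectrum's maximum so each spectrum
keeps a few hundred bins; only the ranges are fixed, the per-depth widths
are the package's own lookup.

LET_Si divides bin edges by the depleted thickness (137 ± 3 µm) — the
constant-track-length, straight-line approximation; angle-corrected track
lengths are out of scope. Water conversion multiplies by the single-value
factor 0.541 (a configured constant, not re-derived from stopping-power
tables). Averages use the arithmetic bin midpoint as representative;
unbinned event-list averages are exposed alongside (`track_avg_events`,
`dose_avg_events`) since binned-vs-unbinned is a genuine dialect choice —
both satisfy LET_d ≥ LET_t and agree to the binning resolution.

LET_cut separation smooths the fluence with a 3-bin moving average, finds
prominence-filtered peaks, and places the cut at the minimum strictly
between the two highest distinct modes (same valley-depth criterion as the
gater). Unimodal spectra raise a `SeparationError`; the caller falls back
to single-species treatment.

## Uncertainty budget

Following the propagation-of-uncertainty (GUM) framework, per average:
recalibration = half the upper−lower scenario spread (the scenarios are ±1σ
shifts, so the half-spread is already a standard uncertainty); thickness =
exactly relative, `u = LET·(3/137)`; an optional systematic term
`systematic_rel` (default 0) covers the unquantified error of applying a
mean-based nonlinear recalibration to single-ion values. Components combine
in quadrature. The Poisson/type A term (SE of the mean for LET_t; delta
method via the influence function `(L² − LET_d·L)/mean(L)` for LET_d) is
computed but reported *separately* — at realistic statistics it is
negligible against the type B sources, and folding it in would obscure the
budget.

## Gamma index

Point-to-point 1D gamma on shared uniform bins, both spectra
area-normalized first. δx defaults to 3 bin widths; δy to 3 % of the
maximum of the normalized *reference* (the global-gamma convention — the
tolerance base level is the package's dialect choice, as is the
no-interpolation point-to-point metric). The passing-rate denominator is
the set of bins with nonzero evaluated weight. The default search window of
±30 bins (10·δx) equals the exhaustive search whenever the best-matching
reference point lies within it; the exhaustive mode is retained and the
tests assert equality. Enlarging either tolerance can only decrease Γ
values, so passing rates are monotone in (δx, δy).

## mMKM RBE

α_mix is the fluence·LET-weighted average of per-species α(LET) with linear
interpolation inside the table support and a hard error outside (no silent
extrapolation); β_mix ≡ β_γ. Defaults α_γ = 0.05 Gy⁻¹, β_γ = 0.025 Gy⁻²
((α/β)_γ = 2 Gy), physical dose 1.8 Gy (proton) / 1.3 Gy (helium). RBE is
defined as the photon-isoeffective dose ratio at equal LQ survival — the
positive root of `β_γ·D_γ² + α_γ·D_γ = α_mix·D + β_γ·D²` divided by D;
this closed form matches a bisection solve to 1e−10 in the tests. For
mixed helium fields the spectrum is split at LET_cut into hydrogen and
helium components; region III events are assigned to the primary species
as an approximation.

Clinical α(LET) tables are not public; `synthetic_alpha_table` provides
clearly labeled synthetic monotone tables (a linear-in-LET ramp anchored at
α_γ with mild saturation, slope 0.016/0.012 Gy⁻¹ per keV/µm for
hydrogen/helium) for tests and examples. RBE values computed from them
characterize the machinery only.

## Numerical choices and degenerate inputs

* Half-open [lo, hi) bins throughout; 0-based pixel coordinates.
* Empty hit tables cluster to an empty list (not an error); zero-fluence
  spectra raise `UndefinedAverageError`; zero-area spectra raise
  `NormalizationError`; every pipeline stage re-raises with a stage tag.
* Scenario shifts that drive k, p or q non-positive raise a configuration
  error rather than producing a silently invalid curve.
* All defaults live in `RunConfig` (YAML schema version 1); computation
  paths never hard-code constants.

## Problem sizes

The bundled tests and the acceptance script run the generator at 10³–10⁴
primaries per scenario and 10⁴ random spectra for the moment-inequality
property — sizes at which binomial recovery bands and scenario spreads are
already decisive. Larger runs only tighten the type A terms, which the
budget reports separately anyway.

## Known limitations

No transport physics or beamline model; no per-event track-length
reconstruction from cluster morphology; no pile-up deconvolution; no
ToT-to-energy per-pixel calibration; Moyal tails are lighter than
Landau–Vavilov; the derived default gates assume the species loci are
separable along log-volume (true for the generator, approximate for real
mixed fields); printed clinical RBE ranges are not reproducible without the
clinical α(LET) tables and are not targeted.
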