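# pixelet

Per-ion LET spectroscopy and RBE estimation from silicon pixel-detector hit
data in therapeutic proton and helium-ion beams.

## The problem

Hybrid silicon pixel detectors (256×256 matrix, 55 µm pitch) operated in a
clinical beamline record every traversing ion as a *cluster* of fired
pixels, with simultaneous time-of-arrival and calibrated per-pixel energy.
From these single-ion signals one can measure, directly behind PMMA
absorbers along the Bragg curve:

* energy-deposition spectra in the partially depleted sensor volume,
* linear energy transfer (LET) spectra in silicon and — via a single-value
  stopping-power ratio — in water,
* track-averaged and dose-averaged LET with a propagated uncertainty budget,
* relative biological effectiveness (RBE) through the modified
  microdosimetric kinetic model (mMKM).

This is the quantity chain a particle-therapy QA physicist needs to verify
that planned LET and RBE distributions are actually delivered. `pixelet`
implements the full chain, plus a synthetic detector-data generator that
stands in for measurements and Monte-Carlo references so that every stage
is testable at desk scale.

## The method

**Clustering.** Two hits belong to one cluster iff they are connected by a
chain of 8-adjacent hits whose pairwise time differences are within a
coincidence window (default 850 ns). Cluster *size* is the pixel count,
cluster *volume* the summed energy in keV. Single-pixel signals and
clusters below a ~30 keV volume cutoff are rejected as noise.

**Volcano-effect recalibration.** High depositions saturate the per-pixel
response; measured volumes are corrected with the saturating-exponential
inverse

```
E_rec = -(1/k) · ln((p − E_meas)/q),   k = 0.155 /MeV, p = 6.39 MeV, q = 6.40 MeV
```

with mean/upper/lower parameter scenarios (joint ±1σ shifts of the
positively correlated fit constants) feeding the uncertainty budget.

**Ion spectroscopy.** Clusters are gated in (size, log₁₀ volume) space into
region II (primary ions), region I (secondary hydrogen from projectile
fragmentation; helium beams only) and region III (heavier target
fragments), with a contraction/dilation sensitivity check on the region
boundaries.

**LET.** Energy spectra are rescaled by the constant track length of the
137 µm partially depleted thickness (straight-line approximation), and
converted to water with LET_H2O = 0.541 · LET_Si. Averages:

```
LET_t = Σ φᵢ·Lᵢ / Σ φᵢ          (fluence-weighted, first moment)
LET_d = Σ φᵢ·Lᵢ² / Σ φᵢ·Lᵢ      (dose-weighted, emphasizes high-LET tail)
```

PMMA depths convert to water-equivalent depths with RSP = 1.158.

**Comparison.** Two area-normalized spectra are compared with a 1D gamma
index, Γ = min √((Δx/δx)² + (Δy/δy)²), δx = 3 bins, δy = 3 % — plus
weighted mean/median relative differences.

**RBE (mMKM).** α_mix = Σ αᵢ(L)·φᵢ·Lᵢ / Σ φᵢ·Lᵢ with per-species α(LET)
tables, β_mix = β_γ; survival S = exp(−α_mix·D − β_γ·D²); RBE is the
photon-isoeffective dose ratio, with α_γ = 0.05 Gy⁻¹, β_γ = 0.025 Gy⁻²,
D = 1.8 Gy (protons) / 1.3 Gy (helium). Mixed helium fields are split at
LET_cut, the valley between the hydrogen and helium fluence peaks. The
bundled α(LET) tables are **synthetic** examples, not clinical data.

## Worked example

```python
import pixelet as px

scenario = px.BeamScenario(species="helium", depth_pmma=85.0, n_primaries=5000,
                           fragment_fraction=0.12, noise_rate=0.1, seed=1)
hits, truth = px.generate_dataset(scenario)          # 227 838 hits, 5 600 ions
report = px.run_pipeline(px.RunConfig(scenario=scenario), hits, with_rbe=True)
```

The report (abridged) reads:

```
cluster : 6113 raw clusters -> 5600 after the 30 keV / single-pixel cutoff
gate    : region I 599, region II 4996, region III 5   (672 hydrogen ions generated)
depth   : 85.0 mm PMMA = 98.43 ± 0.68 mm water
LET     : LET_t = 3.363 ± 0.303 keV/µm, LET_d = 3.634 ± 0.328 keV/µm (water)
          type A (Poisson) contributions 0.013 / 0.008 keV/µm, reported separately
RBE     : alpha_mix = 0.0933 /Gy, LET_cut = 1.72 keV/µm, survival = 0.849,
          RBE = 1.343 at 1.3 Gy   (synthetic alpha tables)
```

Reading: of the 5 600 generated ions, all survive the noise cutoff (the
~51 000 sub-threshold noise hits do not form clusters); the gate recovers
the hydrogen-fragment admixture; the combined LET uncertainty is dominated
by the recalibration-scenario spread, with the counting term two orders of
magnitude smaller; and the mixed helium field at this depth is ~34 % more
effective than photons under the synthetic α tables.

The same chain is scriptable from the shell:

```
pixelet simulate --species helium -n 5000 --fragment-fraction 0.12 --seed 1 -o hits.csv
pixelet pipeline hits.csv --rbe --outdir run/
```

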