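"""Synthetic pixel-detector data with the statistical structure of ion beams.

The generator emulates, phenomenologically, what a 256x256 silicon pixel
detector records behind PMMA slabs in a therapeutic proton or helium-ion
beam:

* per-ion energy depositions in the partially depleted thickness drawn from
  a right-tailed straggling law (Moyal, a tractable stand-in for
  Landau-Vavilov; a Gaussian option is available near the Bragg peak where
  the spectrum symmetrizes),
* location and width of the deposition spectrum growing Bragg-like with
  PMMA depth,
* lighter projectile fragments (hydrogen from helium beams, at roughly a
  quarter of the primary deposition) or heavier target fragments (for
  proton beams, above the primary deposition) as a configurable admixture,
* time-over-threshold saturation of high depositions (the volcano effect,
  the exact forward model of the recalibration inverse),
* charge sharing across neighboring pixels (isotropic Gaussian kernel whose
  width grows with deposited energy), a 3 keV per-pixel threshold,
* uncorrelated single-pixel noise hits below 30 keV.

There is no transport physics here: spectra are stand-ins whose parameters
are free knobs, chosen to produce the qualitative depth trends and the
species separation the downstream analysis assumes.  Every sampler takes an
explicit seed; fixed seed means byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import KEV_PER_MEV, RecalibrationParams, saturate
from .datatypes import GRID_SIZE, hits_to_frame
from .errors import ConfigurationError, GeometryError

#: Euler-Mascheroni constant, for the closed-form Moyal mean.
EULER_GAMMA = 0.5772156649015329

SPECIES = ("proton", "helium")

#: Practical range (mm PMMA) used to scale depositions toward the Bragg peak.
RANGE_PMMA_MM = {"proton": 132.0, "helium": 133.0}

#: Entrance-channel (42 mm PMMA) primary deposition location, keV in 137 um Si.
ENTRANCE_LOC_KEV = {"proton": 170.0, "helium": 680.0}


@dataclass(frozen=True)
class BeamScenario:
    """One irradiation condition: species, depth, statistics, admixtures."""

    species: str = "proton"
    depth_pmma: float = 42.0
    n_primaries: int = 10_000
    fragment_fraction: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ConfigurationError(f"species must be one of {SPECIES}")
        if not 0.0 <= self.fragment_fraction <= 1.0:
            raise ConfigurationError("fragment_fraction must be in [0, 1]")
        if not self.n_primaries > 0:
            raise ConfigurationError("n_primaries must be positive")
        if self.depth_pmma < 0:
            raise ConfigurationError("depth_pmma must be >= 0")
        if self.noise_rate < 0:
            raise ConfigurationError("noise_rate must be >= 0")


@dataclass(frozen=True)
class SpectralModel:
    """Location/scale of the per-species deposition law (keV).

    ``law`` is 'moyal' (right-tailed, entrance channel) or 'gauss'
    (near-Bragg-peak option).  Fragments are a second component: for helium
    beams, lighter hydrogen fragments at ``fragment_loc < primary_loc``;
    for proton beams, heavier target fragments at ``fragment_loc >
    primary_loc``.
    """

    primary_loc: float
    primary_scale: float
    fragment_loc: float
    fragment_scale: float
    fragment_species: str
    law: str = "moyal"

    def __post_init__(self):
        if self.primary_loc <= 0 or self.primary_scale <= 0:
            raise ConfigurationError("primary location/scale must be positive")
        if self.fragment_loc <= 0 or self.fragment_scale <= 0:
            raise ConfigurationError("fragment location/scale must be positive")
        if self.law not in ("moyal", "gauss"):
            raise ConfigurationError("law must be 'moyal' or 'gauss'")

    def mean_primary(self) -> float:
        """Closed-form mean of the primary deposition law (keV)."""
        if self.law == "moyal":
            return self.primary_loc + self.primary_scale * (EULER_GAMMA + np.log(2.0))
        return self.primary_loc


def default_model(scenario: BeamScenario) -> SpectralModel:
    """Depth-dependent spectral parameters for a beam scenario.

    The primary location follows a Bragg-like power law in residual range,
    ``loc(z) = loc_42mm * ((R - 42) / (R - z))**0.45`` capped near the peak;
    the scale is a fixed fraction of the location (straggling broadens the
    spectrum as it shifts).  Purely phenomenological.
    """
    R = RANGE_PMMA_MM[scenario.species]
    loc0 = ENTRANCE_LOC_KEV[scenario.species]
    z = min(scenario.depth_pmma, R - 2.0)
    loc = loc0 * ((R - 42.0) / (R - z)) ** 0.45 if z > 42.0 else loc0
    cap = 2200.0 if scenario.species == "proton" else 5000.0
    loc = min(loc, cap)
    scale = max(0.06 * loc, 8.0)
    if scenario.species == "helium":
        # Lighter projectile fragments: hydrogen at ~ quarter deposition.
        return SpectralModel(loc, scale, fragment_loc=loc / 4.0,
                             fragment_scale=max(scale / 3.0, 6.0),
                             fragment_species="hydrogen")
    # Proton beams: heavier target fragments above the primary deposition.
    return SpectralModel(loc, scale, fragment_loc=3.0 * loc,
                         fragment_scale=2.0 * scale,
                         fragment_species="target_fragment")


def _sample_law(rng, law, loc, scale, n):
    if law == "moyal":
        vals = stats.moyal.rvs(loc=loc, scale=scale, size=n, random_state=rng)
    else:
        vals = rng.normal(loc, scale, size=n)
    # Depositions are physical energies: resample the negligible negative tail.
    bad = vals <= 0
    while bad.any():
        repl = (stats.moyal.rvs(loc=loc, scale=scale, size=int(bad.sum()), random_state=rng)
                if law == "moyal" else rng.normal(loc, scale, size=int(bad.sum())))
        vals[bad] = repl
        bad = vals <= 0
    return vals


def sample_true_events(scenario: BeamScenario,
                       model: SpectralModel | None = None) -> pd.DataFrame:
    """Draw ground-truth events (species, e_dep_true keV, track_angle deg).

    Returns ``n_primaries * (1 + fragment_fraction)`` events (fragment count
    rounded to the nearest integer): primaries first, then fragments, in a
    deterministic order under a fixed seed.
    """
    model = model or default_model(scenario)
    rng = np.random.default_rng(scenario.seed)
    n_prim = scenario.n_primaries
    n_frag = int(round(scenario.fragment_fraction * n_prim))
    e_prim = _sample_law(rng, model.law, model.primary_loc, model.primary_scale, n_prim)
    e_frag = _sample_law(rng, "moyal", model.fragment_loc, model.fragment_scale, n_frag)
    species = np.concatenate([
        np.repeat(scenario.species, n_prim),
        np.repeat(model.fragment_species, n_frag),
    ])
    e_dep = np.concatenate([e_prim, e_frag])
    # Perpendicular irradiation; small residual angular spread from scattering.
    angle = np.abs(rng.normal(0.0, 2.0, size=n_prim + n_frag))
    angle = np.minimum(angle, 89.9)
    return pd.DataFrame({
        "species": species,
        "e_dep_true": e_dep,
        "track_angle": angle,
    })


@dataclass(frozen=True)
class RasterParams:
    """Charge-sharing / pixelization parameters.

    ``sigma0_px`` and ``sigma_e_px`` set the Gaussian sharing width
    ``sigma = sigma0 + sigma_e * sqrt(E / 1 MeV)`` (larger depositions make
    larger clusters, which is what the size-volume gating exploits).
    ``threshold_keV`` is the per-pixel detection threshold: sub-threshold
    pixels are dropped before summation.  ``toa_jitter_ns`` bounds the
    arrival-time spread inside one cluster (well inside the coincidence
    window).
    """

    sigma0_px: float = 0.45
    sigma_e_px: float = 1.1
    threshold_keV: float = 3.0
    toa_jitter_ns: float = 100.0

    def sigma_px(self, energy_keV: float) -> float:
        return self.sigma0_px + self.sigma_e_px * np.sqrt(max(energy_keV, 0.0) / KEV_PER_MEV)


def rasterize_event(energy_keV: float, origin: tuple[int, int], t0_ns: float,
                    raster: RasterParams = RasterParams(),
                    rng: np.random.Generator | None = None,
                    sigma_px: float | None = None) -> pd.DataFrame:
    """Spread one event's energy over pixels around ``origin``.

    The deposition is centered at a random sub-pixel offset inside the
    origin pixel and integrated over pixel boundaries with an isotropic
    Gaussian kernel of width ``sigma_px`` (derived from the energy when not
    given).  Per-pixel energies below the threshold are dropped.  With
    ``sigma_px == 0`` the full energy lands on the origin pixel.

    Returns a hit table; may be empty if every shared pixel fell below
    threshold.
    """
    rng = rng or np.random.default_rng()
    ox, oy = origin
    if not (0 <= ox < GRID_SIZE and 0 <= oy < GRID_SIZE):
        raise GeometryError(f"origin {origin} outside the {GRID_SIZE}x{GRID_SIZE} matrix")
    sigma = raster.sigma_px(energy_keV) if sigma_px is None else sigma_px
    if sigma < 0:
        raise ConfigurationError("sharing width must be >= 0")
    if sigma == 0:
        if energy_keV < raster.threshold_keV:
            return hits_to_frame([])
        return hits_to_frame([{"x": ox, "y": oy, "toa_ns": t0_ns, "energy_keV": energy_keV}])

    cx = ox + rng.uniform(-0.5, 0.5)
    cy = oy + rng.uniform(-0.5, 0.5)
    half = max(1, int(np.ceil(3.0 * sigma)))
    xs = np.arange(max(ox - half, 0), min(ox + half, GRID_SIZE - 1) + 1)
    ys = np.arange(max(oy - half, 0), min(oy + half, GRID_SIZE - 1) + 1)
    # Separable Gaussian integral over pixel borders [i-0.5, i+0.5].
    fx = stats.norm.cdf(xs + 0.5, cx, sigma) - stats.norm.cdf(xs - 0.5, cx, sigma)
    fy = stats.norm.cdf(ys + 0.5, cy, sigma) - stats.norm.cdf(ys - 0.5, cy, sigma)
    w = np.outer(fx, fy)
    w /= w.sum()
    e = energy_keV * w
    keep = e >= raster.threshold_keV
    if not keep.any():
        return hits_to_frame([])
    xi, yi = np.nonzero(keep)
    n = len(xi)
    toa = t0_ns + rng.uniform(0.0, raster.toa_jitter_ns, size=n)
    return pd.DataFrame({
        "x": xs[xi].astype(np.int64),
        "y": ys[yi].astype(np.int64),
        "toa_ns": toa,
        "energy_keV": e[keep],
    })


#: Spacing between successive primaries' arrival times; far beyond the
#: coincidence window so overlapping footprints stay temporally resolvable.
EVENT_SPACING_NS = 20_000.0


def generate_dataset(scenario: BeamScenario,
                     model: SpectralModel | None = None,
                     raster: RasterParams = RasterParams(),
                     recal: RecalibrationParams | None = RecalibrationParams(),
                     margin_px: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full forward simulation: events -> saturation -> pixel hits (+ noise).

    Pipeline per event: draw the true deposition, distort it with the
    volcano-effect forward model (skipped when ``recal`` is None), then
    rasterize at a uniformly random origin away from the matrix edge.
    Events are spaced ``EVENT_SPACING_NS`` apart in time.  Noise is a
    Poisson number of independent single-pixel hits with energies in
    (threshold, 30) keV at uniformly random times.

    Returns ``(hits, truth)``: the hit table and the ground-truth event
    table (with the measured, saturation-distorted event energy added as
    ``e_dep_meas``).
    """
    truth = sample_true_events(scenario, model)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    e_true = truth["e_dep_true"].to_numpy()
    if recal is not None:
        e_meas = np.asarray(saturate(e_true / KEV_PER_MEV, recal)) * KEV_PER_MEV
    else:
        e_meas = e_true.copy()
    truth = truth.assign(e_dep_meas=e_meas)

    lo, hi = margin_px, GRID_SIZE - 1 - margin_px
    frames = []
    for i, e in enumerate(e_meas):
        origin = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        t0 = i * EVENT_SPACING_NS
        df = rasterize_event(float(e), origin, t0, raster, rng)
        if len(df):
            frames.append(df)

    n_noise = int(rng.poisson(scenario.noise_rate * scenario.n_primaries))
    if n_noise:
        t_max = len(e_meas) * EVENT_SPACING_NS
        noise = pd.DataFrame({
            "x": rng.integers(0, GRID_SIZE, size=n_noise),
            "y": rng.integers(0, GRID_SIZE, size=n_noise),
            "toa_ns": rng.uniform(0.0, t_max, size=n_noise),
            "energy_keV": rng.uniform(raster.threshold_keV, 29.9, size=n_noise),
        })
        frames.append(noise)

    hits = (pd.concat(frames, ignore_index=True) if frames else hits_to_frame([]))
    hits = hits.sort_values(["toa_ns", "x", "y"], kind="mergesort").reset_index(drop=True)
    return hits, truth
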