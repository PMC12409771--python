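"""Energy-deposition and LET spectra, averages, and uncertainty propagation.

LET spectra in silicon are obtained by linearly rescaling energy-deposition
spectra by a constant track length — the partially depleted detector
thickness — under the straight-line approximation (tracks straight and
parallel to the beam axis).  Conversion to water uses a single-value
average silicon-to-water stopping-power ratio (default 0.541).

Track- and dose-averaged LET are the first moment and second-moment ratio
of the fluence spectrum:

    LET_t = sum(phi_i * L_i) / sum(phi_i)
    LET_d = sum(phi_i * L_i**2) / sum(phi_i * L_i)

with L_i the bin midpoint (binned route) or the per-event LET value
(unbinned route); both are exposed.  LET_d >= LET_t always
(Cauchy-Schwarz), with equality only for single-valued support.

Uncertainty follows the propagation-of-uncertainty (GUM) recipe: the
dominant recalibration contribution is the half-spread of the upper/lower
volcano-recalibration scenarios, combined in quadrature with the depleted-
thickness term (u_t/t, exactly relative for a constant divisor) and an
optional configured systematic term.  The Poisson (type A) counting term is
computed but reported separately — with >1e6 ions per point it is
negligible against the type B sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .calibration import (KEV_PER_MEV, RecalibrationParams, SCENARIOS,
                          recalibrate, scenario_params)
from .datatypes import DetectorConfig, GeometryConfig
from .errors import (ConfigurationError, SeparationError, UndefinedAverageError,
                     UsageError)


@dataclass
class Spectrum:
    """A binned fluence spectrum: counts per half-open bin [lo, hi).

    ``quantity`` is 'energy' (keV) or 'let' (keV/um); LET spectra also carry
    a ``medium`` ('silicon' or 'water').  ``meta`` is free-form provenance
    (species, depth, scenario ...).
    """

    edges: np.ndarray
    weights: np.ndarray
    quantity: str = "energy"
    medium: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ConfigurationError("edges must be a 1-D array of >= 2 values")
        if not np.all(np.diff(self.edges) > 0):
            raise ConfigurationError("bin edges must be strictly increasing")
        if self.weights.shape != (self.edges.size - 1,):
            raise ConfigurationError("weights must have len(edges) - 1 entries")
        if np.any(self.weights < 0):
            raise ConfigurationError("weights must be >= 0")

    @property
    def midpoints(self) -> np.ndarray:
        """Arithmetic bin midpoints, the bin representatives for averaging."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def replace(self, **kw) -> "Spectrum":
        d = dict(edges=self.edges, weights=self.weights, quantity=self.quantity,
                 medium=self.medium, meta=dict(self.meta))
        d.update(kw)
        return Spectrum(**d)


def default_bin_width(species: str, vmax_keV: float) -> float:
    """Range-based histogram bin width lookup (keV).

    Proton energy spectra use widths from 1 keV (narrow entrance spectra) to
    30 keV (wide distal spectra); helium spectra from 10 to 400 keV.  The
    width grows stepwise with the spectrum range so each spectrum keeps a
    few hundred bins.
    """
    if species == "proton":
        for top, w in ((300.0, 1.0), (1500.0, 5.0), (4000.0, 10.0)):
            if vmax_keV <= top:
                return w
        return 30.0
    for top, w in ((2000.0, 10.0), (6000.0, 50.0), (12000.0, 100.0)):
        if vmax_keV <= top:
            return w
    return 400.0


def histogram_events(values, species: str = "proton", bin_width: float | None = None,
                     quantity: str = "energy", medium: str | None = None,
                     meta: dict | None = None) -> Spectrum:
    """Bin per-event values into a Spectrum with half-open [lo, hi) bins."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise UndefinedAverageError("no finite events to histogram")
    vmax = float(values.max())
    w = bin_width if bin_width is not None else default_bin_width(species, vmax)
    if not w > 0:
        raise ConfigurationError("bin width must be positive")
    n_bins = max(1, int(np.ceil((vmax + 0.5 * w) / w)))
    edges = np.arange(n_bins + 1, dtype=np.float64) * w
    weights, _ = np.histogram(values, bins=edges)
    return Spectrum(edges, weights.astype(np.float64), quantity=quantity,
                    medium=medium, meta=dict(meta or {}, species=species))


def edep_to_let(spec: Spectrum, det: DetectorConfig) -> Spectrum:
    """Energy-deposition spectrum -> silicon LET spectrum (keV/um).

    Every bin edge is divided by the constant track length (the depleted
    thickness); fluence weights are untouched.
    """
    if not det.depleted_thickness_um > 0:
        raise ConfigurationError("depleted thickness must be positive")
    if spec.quantity == "let":
        raise UsageError("input is already an LET spectrum")
    return spec.replace(edges=spec.edges / det.depleted_thickness_um,
                        quantity="let", medium="silicon")


def let_si_to_water(spec: Spectrum, det: DetectorConfig) -> Spectrum:
    """Silicon LET spectrum -> water LET spectrum via the single-value factor."""
    if spec.medium == "water":
        raise UsageError("spectrum is already in water")
    if spec.medium != "silicon" or spec.quantity != "let":
        raise UsageError("expected a silicon LET spectrum")
    return spec.replace(edges=spec.edges * det.si_to_water_factor, medium="water")


def let_track_avg(spec: Spectrum) -> float:
    """Fluence-weighted (first-moment) average of the spectrum."""
    phi, L = spec.weights, spec.midpoints
    tot = phi.sum()
    if not tot > 0:
        raise UndefinedAverageError("zero total fluence")
    return float((phi * L).sum() / tot)


def let_dose_avg(spec: Spectrum) -> float:
    """Dose-weighted average: second-moment over first-moment ratio."""
    phi, L = spec.weights, spec.midpoints
    m1 = (phi * L).sum()
    if not phi.sum() > 0 or not m1 > 0:
        raise UndefinedAverageError("zero total fluence")
    return float((phi * L**2).sum() / m1)


def track_avg_events(values) -> float:
    """Unbinned (event-list) first-moment average."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise UndefinedAverageError("empty event list")
    return float(v.mean())


def dose_avg_events(values) -> float:
    """Unbinned second-moment-ratio average."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0 or not v.sum() > 0:
        raise UndefinedAverageError("empty event list")
    return float((v**2).sum() / v.sum())


def separate_by_let_cut(spec: Spectrum, smooth_bins: int = 3):
    """Split a bimodal LET spectrum at the valley between its two peaks.

    Mixed helium fields show a hydrogen peak (projectile fragments) below
    the primary-helium peak; the cut LET_cut is the bin midpoint of the
    minimum of the (moving-average smoothed) fluence strictly between the
    two highest distinct modes.  Bins below the cut form the hydrogen
    component, bins at/above it the helium component; the two components
    partition the fluence exactly.

    Returns ``(hydrogen: Spectrum, helium: Spectrum, let_cut: float)``.

    Raises
    ------
    SeparationError if the (smoothed) spectrum is not bimodal.
    """
    if smooth_bins < 1:
        raise ConfigurationError("smooth_bins must be >= 1")
    w = spec.weights
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        sm = np.convolve(w, kernel, mode="same")
    else:
        sm = w.astype(np.float64)

    # Prominence-filtered modes: counting noise inside one physical peak
    # must not read as bimodality.
    idx, _ = signal.find_peaks(sm, prominence=0.05 * sm.max())
    if len(idx) < 2:
        raise SeparationError("spectrum is not bimodal after smoothing")
    peaks = sorted(idx, key=lambda i: sm[i], reverse=True)
    i1, i2 = sorted(peaks[:2])
    if i2 - i1 < 2:
        raise SeparationError("the two modes are not distinct")
    valley = i1 + 1 + int(np.argmin(sm[i1 + 1:i2]))
    # genuine bimodality: the valley must dip well below the smaller mode
    if sm[valley] > 0.5 * min(sm[i1], sm[i2]):
        raise SeparationError("no clear fluence valley between the modes")
    let_cut = float(spec.midpoints[valley])

    w_h = w.copy()
    w_he = w.copy()
    w_h[valley:] = 0.0
    w_he[:valley] = 0.0
    hyd = spec.replace(weights=w_h, meta=dict(spec.meta, component="hydrogen"))
    he = spec.replace(weights=w_he, meta=dict(spec.meta, component="helium"))
    return hyd, he, let_cut


def water_equivalent_depth(depth_pmma: float, geom: GeometryConfig) -> tuple[float, float]:
    """PMMA depth -> water-equivalent depth (mm) with standard uncertainty."""
    if depth_pmma < 0:
        raise ConfigurationError("depth must be >= 0")
    return depth_pmma * geom.rsp_pmma, depth_pmma * geom.u_rsp


@dataclass
class LETResult:
    """Track- and dose-averaged LET with combined (k=1) uncertainties.

    ``u_let_t``/``u_let_d`` combine the recalibration-scenario half-spread,
    the thickness term and any configured systematic term in quadrature.
    ``u_stat_t``/``u_stat_d`` are the Poisson/type A standard errors,
    reported separately.  ``components`` itemizes the budget.
    """

    let_t: float
    let_d: float
    u_let_t: float
    u_let_d: float
    u_stat_t: float = 0.0
    u_stat_d: float = 0.0
    medium: str = "water"
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.let_d < self.let_t - 1e-12:
            raise ConfigurationError("LET_d must be >= LET_t")


def _event_let(e_meas_keV, det, recal_pars, medium):
    """Measured event energies (keV) -> per-event LET after recalibration."""
    e_rec = np.asarray(recalibrate(np.asarray(e_meas_keV) / KEV_PER_MEV, recal_pars))
    let_si = e_rec * KEV_PER_MEV / det.depleted_thickness_um
    return let_si * det.si_to_water_factor if medium == "water" else let_si


def propagate_let_uncertainty(e_meas_keV, det: DetectorConfig,
                              recal: RecalibrationParams,
                              systematic_rel: float = 0.0,
                              medium: str = "water") -> LETResult:
    """GUM-style uncertainty budget for LET_t and LET_d from measured events.

    Central values come from the mean recalibration scenario (unbinned
    averages).  The budget per average:

    * recalibration: half the upper-lower scenario spread (the scenarios
      shift k, p, q jointly by +/-1 sigma, so the half-spread is already a
      standard uncertainty),
    * thickness: exactly relative, ``u = LET * u_t / t``,
    * systematic: ``u = LET * systematic_rel`` (the configured allowance for
      applying a mean-based nonlinear recalibration to single-ion values),

    combined in quadrature.  The Poisson/type A standard errors (delta
    method for LET_d) are computed and reported separately.
    """
    if systematic_rel < 0:
        raise ConfigurationError("systematic_rel must be >= 0")
    e_meas_keV = np.asarray(e_meas_keV, dtype=np.float64)
    if e_meas_keV.size == 0:
        raise UndefinedAverageError("no events")

    per_scenario = {}
    for mode in SCENARIOS:
        let_vals = _event_let(e_meas_keV, det, scenario_params(recal, mode), medium)
        per_scenario[mode] = (track_avg_events(let_vals), dose_avg_events(let_vals))
    let_t, let_d = per_scenario["mean"]

    u_recal_t = 0.5 * abs(per_scenario["upper"][0] - per_scenario["lower"][0])
    u_recal_d = 0.5 * abs(per_scenario["upper"][1] - per_scenario["lower"][1])
    rel_t = det.u_thickness_um / det.depleted_thickness_um
    u_thick_t = let_t * rel_t
    u_thick_d = let_d * rel_t
    u_sys_t = let_t * systematic_rel
    u_sys_d = let_d * systematic_rel
    u_t = float(np.sqrt(u_recal_t**2 + u_thick_t**2 + u_sys_t**2))
    u_d = float(np.sqrt(u_recal_d**2 + u_thick_d**2 + u_sys_d**2))

    # Type A (Poisson counting): SE of the mean; delta method for the ratio
    # LET_d = m2/m1 via its influence function.
    L = _event_let(e_meas_keV, det, recal, medium)
    n = L.size
    u_stat_t = float(L.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if n > 1:
        infl = (L**2 - let_d * L) / L.mean()
        u_stat_d = float(infl.std(ddof=1) / np.sqrt(n))
    else:
        u_stat_d = 0.0

    return LETResult(
        let_t=let_t, let_d=let_d, u_let_t=u_t, u_let_d=u_d,
        u_stat_t=u_stat_t, u_stat_d=u_stat_d, medium=medium,
        components={
            "recalibration": {"let_t": u_recal_t, "let_d": u_recal_d},
            "thickness": {"let_t": u_thick_t, "let_d": u_thick_d},
            "systematic": {"let_t": u_sys_t, "let_d": u_sys_d},
            "scenario_values": {m: {"let_t": v[0], "let_d": v[1]}
                                for m, v in per_scenario.items()},
        },
    )
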