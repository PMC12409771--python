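"""Mixed-field RBE via the modified microdosimetric kinetic model (mMKM).

For a mixed radiation field characterized by a fluence LET spectrum, the
linear-quadratic alpha of the mixture is the dose-weighted average of the
per-component monochromatic alpha(LET):

    alpha_mix = sum_i alpha_i(L_i) * phi_i * L_i / sum_i phi_i * L_i

(the microscopic-dose weights d_i reduce exactly to the fluence*LET
weighting), while beta is LET-independent: beta_mix = beta_gamma.  The
survival at physical dose D is S = exp(-alpha_mix D - beta_gamma D^2), and
RBE is the photon-isoeffective dose ratio: the photon dose D_gamma giving
the same survival solves

    alpha_gamma D_gamma + beta_gamma D_gamma^2 = alpha_mix D + beta_gamma D^2

(positive root), and RBE = D_gamma / D.

alpha(LET) tables are a required per-species input (two-column CSV: LET in
water keV/um, alpha 1/Gy); the tables shipped by
:func:`synthetic_alpha_table` are SYNTHETIC, monotone, physically plausible
placeholders for tests and examples — they are not clinical tables, and
RBE values computed from them characterize the machinery, not any clinic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ExtrapolationError, PixeletError
from .let import Spectrum

#: Default physical doses (Gy) per primary species for RBE assessment.
DEFAULT_DOSE_GY = {"proton": 1.8, "helium": 1.3}


@dataclass
class AlphaTable:
    """Monotone alpha(LET) lookup for one particle species.

    Linear interpolation inside the support [let[0], let[-1]]; querying
    outside raises — no silent extrapolation.
    """

    let: np.ndarray
    alpha: np.ndarray
    species: str = ""

    def __post_init__(self):
        self.let = np.asarray(self.let, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.let.ndim != 1 or self.let.size < 2 or self.alpha.shape != self.let.shape:
            raise ConfigurationError("alpha table needs matching 1-D LET/alpha arrays (>= 2 rows)")
        if not np.all(np.diff(self.let) > 0):
            raise ConfigurationError("alpha table LET grid must be strictly increasing")
        if not np.all(self.alpha > 0):
            raise ConfigurationError("alpha values must be strictly positive")

    def __call__(self, let_values):
        v = np.asarray(let_values, dtype=np.float64)
        if np.any(v < self.let[0]) or np.any(v > self.let[-1]):
            lo, hi = float(self.let[0]), float(self.let[-1])
            raise ExtrapolationError(
                f"LET value outside alpha-table support [{lo}, {hi}] keV/um "
                f"for species {self.species or '?'}")
        out = np.interp(v, self.let, self.alpha)
        return out if out.ndim else float(out)


def synthetic_alpha_table(species: str, let_max: float = 200.0) -> AlphaTable:
    """SYNTHETIC monotone alpha(LET) table for tests and worked examples.

    A linear-quadratic-in-LET ramp anchored at the photon alpha, with a
    slightly steeper slope for hydrogen than for helium at equal LET
    (lighter ions are more effective per unit LET at therapeutic energies).
    Not a clinical table.
    """
    slopes = {"proton": 0.016, "hydrogen": 0.016, "helium": 0.012,
              "target_fragment": 0.010}
    if species not in slopes:
        raise ConfigurationError(f"no synthetic table for species {species!r}")
    grid = np.linspace(0.01, let_max, 400)
    alpha = 0.05 + slopes[species] * grid * (1.0 - grid / (2.0 * let_max))
    return AlphaTable(grid, alpha, species=species)


@dataclass
class MmkmConfig:
    """Photon LQ parameters, physical dose, and per-species alpha tables."""

    alpha_gamma: float = 0.05
    beta_gamma: float = 0.025
    dose_phys: float = 1.8
    alpha_tables: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.alpha_gamma > 0 and self.beta_gamma > 0 and self.dose_phys > 0):
            raise ConfigurationError("alpha_gamma, beta_gamma, dose_phys must be positive")

    @property
    def alpha_beta_ratio(self) -> float:
        """(alpha/beta)_gamma in Gy."""
        return self.alpha_gamma / self.beta_gamma


def alpha_mix(spectra: dict, cfg: MmkmConfig) -> float:
    """Dose-weighted mixture alpha from per-species water LET spectra (1/Gy).

    ``spectra`` maps species -> Spectrum (medium 'water'); each species
    must have an alpha table in ``cfg.alpha_tables``.  Weights are
    phi_i * L_i per bin across all species.
    """
    if not spectra:
        raise ConfigurationError("no spectra supplied")
    num = 0.0
    den = 0.0
    for species, spec in spectra.items():
        if spec.medium != "water":
            raise ConfigurationError(f"spectrum for {species} is not in water")
        if species not in cfg.alpha_tables:
            raise ConfigurationError(f"no alpha table for species {species!r}")
        table = cfg.alpha_tables[species]
        phi, L = spec.weights, spec.midpoints
        nz = phi > 0
        if not nz.any():
            continue
        a = np.asarray(table(L[nz]))
        num += float((a * phi[nz] * L[nz]).sum())
        den += float((phi[nz] * L[nz]).sum())
    if not den > 0:
        raise ConfigurationError("total fluence*LET weight is zero")
    return num / den


@dataclass
class RBEResult:
    """Mixed-field LQ parameters, survival and RBE at the physical dose."""

    alpha_mix: float
    beta_mix: float
    dose_phys: float
    survival: float
    dose_photon_eq: float
    rbe: float

    def __post_init__(self):
        if not 0.0 < self.survival <= 1.0:
            raise ConfigurationError("survival must be in (0, 1]")
        if self.rbe < 0:
            raise ConfigurationError("RBE must be >= 0")


def rbe(alpha_mix_value: float, cfg: MmkmConfig, dose: float | None = None) -> RBEResult:
    """Survival and photon-isoeffective RBE for a given mixture alpha.

    The photon-equivalent dose is the positive root of
    beta_gamma x^2 + alpha_gamma x - E = 0 with effect
    E = alpha_mix D + beta_gamma D^2.
    """
    if not alpha_mix_value > 0:
        raise ConfigurationError("alpha_mix must be positive")
    D = cfg.dose_phys if dose is None else dose
    if not D > 0:
        raise ConfigurationError("dose must be positive")
    effect = alpha_mix_value * D + cfg.beta_gamma * D * D
    disc = cfg.alpha_gamma**2 + 4.0 * cfg.beta_gamma * effect
    if disc <= 0:  # impossible for valid inputs; numeric guard
        raise PixeletError("non-positive discriminant in photon-dose solve")
    d_gamma = (-cfg.alpha_gamma + np.sqrt(disc)) / (2.0 * cfg.beta_gamma)
    return RBEResult(
        alpha_mix=alpha_mix_value,
        beta_mix=cfg.beta_gamma,
        dose_phys=D,
        survival=float(np.exp(-effect)),
        dose_photon_eq=float(d_gamma),
        rbe=float(d_gamma / D),
    )


def rbe_from_spectra(spectra: dict, cfg: MmkmConfig, dose: float | None = None) -> RBEResult:
    """Convenience: alpha_mix then rbe in one call."""
    return rbe(alpha_mix(spectra, cfg), cfg, dose)
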