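"""Volcano-effect energy recalibration.

High per-pixel energy depositions saturate the time-over-threshold response
(the "volcano effect"), so measured cluster volumes underestimate the true
deposited energy.  The correction is a saturating-exponential inverse

    E_rec = -(1/k) * ln((p - E_meas) / q)

with fit constants ``k`` (1/MeV), ``p`` and ``q`` (MeV).  The forward model
(used by the synthetic generator) is the algebraic inverse

    E_meas = p - q * exp(-k * E_true),

so recalibrate(saturate(E)) == E exactly.  ``p`` is the hard asymptote of
the measured response: events measured at or above ``p`` are unrecoverable
and must be flagged, never clipped.

Uncertainty on (k, p, q) is handled through three scenarios — mean, upper,
lower — where upper/lower shift all three parameters jointly by +/-1 sigma.
The joint shift encodes the strong positive correlation of the fit
parameters and gives a conservative envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, SaturationError

KEV_PER_MEV = 1000.0

SCENARIOS = ("mean", "upper", "lower")


@dataclass(frozen=True)
class RecalibrationParams:
    """Saturating-exponential constants with standard uncertainties.

    Units: ``k`` in 1/MeV, ``p`` and ``q`` in MeV (MeV keeps the log
    argument positive for helium Bragg-peak depositions of several MeV).
    """

    k: float = 0.155
    p: float = 6.39
    q: float = 6.40
    u_k: float = 0.007
    u_p: float = 0.25
    u_q: float = 0.25

    def __post_init__(self):
        if not (self.k > 0 and self.p > 0 and self.q > 0):
            raise ConfigurationError("k, p, q must all be positive")
        if self.u_k < 0 or self.u_p < 0 or self.u_q < 0:
            raise ConfigurationError("uncertainties must be >= 0")


def scenario_params(params: RecalibrationParams, mode: str) -> RecalibrationParams:
    """Return the parameter triple for one recalibration scenario.

    ``mean`` returns the params unchanged; ``upper``/``lower`` shift
    (k, p, q) jointly by (+1σ, +1σ, +1σ) / (−1σ, −1σ, −1σ) — a fully
    correlated shift, the conservative treatment for strongly positively
    correlated fit parameters.
    """
    if mode == "mean":
        return params
    if mode == "upper":
        s = +1.0
    elif mode == "lower":
        s = -1.0
    else:
        raise ConfigurationError(f"unknown scenario mode {mode!r}; expected one of {SCENARIOS}")
    shifted = replace(
        params,
        k=params.k + s * params.u_k,
        p=params.p + s * params.u_p,
        q=params.q + s * params.u_q,
    )
    # replace() re-runs __post_init__, turning non-positive shifted values
    # into ConfigurationError as required.
    return shifted


def saturate(e_true_mev, params: RecalibrationParams = RecalibrationParams()):
    """Forward volcano-effect model: true deposited energy -> measured energy.

    Strictly increasing, bounded above by ``p``.  Operates in MeV.
    """
    e = np.asarray(e_true_mev, dtype=np.float64)
    if np.any(e < 0):
        raise ConfigurationError("true deposited energy must be >= 0")
    out = params.p - params.q * np.exp(-params.k * e)
    return out if out.ndim else float(out)


def recalibrate(e_meas_mev, params: RecalibrationParams = RecalibrationParams()):
    """Invert the volcano-effect saturation: measured -> recalibrated energy (MeV).

    Raises
    ------
    SaturationError
        If any measured energy is at or above the asymptote ``p``; such
        events are unrecoverable and the caller must flag them.
    """
    e = np.asarray(e_meas_mev, dtype=np.float64)
    n_sat = int(np.count_nonzero(e >= params.p))
    if n_sat:
        raise SaturationError(
            f"{n_sat} event(s) measured at or above the saturation asymptote "
            f"p = {params.p} MeV; recalibration undefined there"
        )
    out = -np.log((params.p - e) / params.q) / params.k
    return out if out.ndim else float(out)


class VolcanoRecalibrator(BaseEstimator, TransformerMixin):
    """Transformer applying the volcano-effect recalibration to cluster volumes.

    Operates on energies in keV (shape ``(n,)`` or ``(n, 1)``); the keV<->MeV
    conversion happens at this boundary only.  Events at or above the
    asymptote are returned as NaN and counted (``on_saturated='flag'``,
    the default) or raise (``on_saturated='raise'``) — never clipped, since
    silent clipping would bias the dose-averaged LET.

    Parameters
    ----------
    params : RecalibrationParams
    scenario : {'mean', 'upper', 'lower'}
    on_saturated : {'flag', 'raise'}

    Attributes
    ----------
    n_saturated_ : int — events at/above ``p`` seen by the last transform
    saturated_fraction_ : float
    """

    def __init__(self, params: RecalibrationParams = RecalibrationParams(),
                 scenario: str = "mean", on_saturated: str = "flag"):
        self.params = params
        self.scenario = scenario
        self.on_saturated = on_saturated

    def fit(self, X, y=None):
        if self.on_saturated not in ("flag", "raise"):
            raise ConfigurationError("on_saturated must be 'flag' or 'raise'")
        # Validates the scenario mode and the (possibly shifted) triple.
        self.scenario_params_ = scenario_params(self.params, self.scenario)
        return self

    def transform(self, X):
        if not hasattr(self, "scenario_params_"):
            self.fit(X)
        pars = self.scenario_params_
        e_kev = np.asarray(X, dtype=np.float64)
        squeeze = e_kev.ndim == 1
        e_mev = e_kev.reshape(-1) / KEV_PER_MEV
        sat = e_mev >= pars.p
        self.n_saturated_ = int(sat.sum())
        self.saturated_fraction_ = self.n_saturated_ / max(len(e_mev), 1)
        if self.n_saturated_ and self.on_saturated == "raise":
            recalibrate(e_mev, pars)  # raises SaturationError with the count
        out = np.full_like(e_mev, np.nan)
        out[~sat] = recalibrate(e_mev[~sat], pars)
        out *= KEV_PER_MEV
        return out if squeeze else out.reshape(np.shape(X))
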