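"""Exception hierarchy for the pixelet pipeline.

Every pipeline stage raises a subclass of :class:`PixeletError` so that the
CLI and :func:`pixelet.pipeline.run_pipeline` can abort with stage-tagged
diagnostics instead of leaking bare ValueErrors.
"""


class PixeletError(Exception):
    """Base class for all pixelet errors."""


class ConfigurationError(PixeletError):
    """Invalid or inconsistent configuration values."""


class GeometryError(PixeletError):
    """A coordinate fell outside the sensor geometry."""


class ParseError(PixeletError):
    """Malformed input file; carries offending row numbers.

    Parameters
    ----------
    message : str
    bad_rows : list of (line_number, reason) pairs, optional
    """

    def __init__(self, message, bad_rows=None):
        self.bad_rows = list(bad_rows or [])
        if self.bad_rows:
            detail = "; ".join(f"line {ln}: {why}" for ln, why in self.bad_rows[:10])
            if len(self.bad_rows) > 10:
                detail += f"; … ({len(self.bad_rows)} rows total)"
            message = f"{message} [{detail}]"
        super().__init__(message)


class SaturationError(PixeletError):
    """Measured energy at or above the recalibration asymptote ``p``.

    The saturating-exponential response cannot be inverted there; affected
    events must be flagged by the caller, never silently dropped or clipped.
    """


class AlignmentError(PixeletError):
    """Two spectra do not share bin edges."""


class NormalizationError(PixeletError):
    """A zero-area spectrum cannot be area-normalized."""


class SeparationError(PixeletError):
    """No valley between two modes: LET_cut separation impossible."""


class UndefinedAverageError(PixeletError):
    """Spectrum has zero total fluence; averages undefined."""


class ExtrapolationError(PixeletError):
    """LET value outside the support of an alpha(LET) table."""


class PropagationError(PixeletError):
    """Missing scenario results during uncertainty propagation."""


class UsageError(PixeletError):
    """An operation was applied to an object in the wrong state."""
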