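"""Core domain records: pixel hits, clusters, detector and geometry configs.

Hit collections are carried as :class:`pandas.DataFrame` tables with the
canonical columns ``x, y, toa_ns, energy_keV`` (0-based pixel coordinates on
a 256x256 matrix); :class:`PixelHit` is the single-record view used at API
boundaries.  A :class:`Cluster` stores its member hits as numpy arrays and
derives size / volume / reference time from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError

#: Sensor matrix dimension (pixels per side).
GRID_SIZE = 256

HIT_COLUMNS = ("x", "y", "toa_ns", "energy_keV")


@dataclass(frozen=True)
class PixelHit:
    """One fired pixel: coordinates, arrival time, calibrated energy."""

    x: int
    y: int
    toa_ns: float
    energy_keV: float

    def __post_init__(self):
        if not (0 <= self.x < GRID_SIZE and 0 <= self.y < GRID_SIZE):
            raise GeometryError(
                f"pixel ({self.x}, {self.y}) outside the {GRID_SIZE}x{GRID_SIZE} matrix"
            )
        if not self.energy_keV > 0:
            raise ConfigurationError(f"hit energy must be positive, got {self.energy_keV}")


def hits_to_frame(hits) -> pd.DataFrame:
    """Pack an iterable of :class:`PixelHit` (or dicts) into the canonical table."""
    rows = [
        (h.x, h.y, h.toa_ns, h.energy_keV) if isinstance(h, PixelHit) else
        (h["x"], h["y"], h["toa_ns"], h["energy_keV"])
        for h in hits
    ]
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS)).astype(
        {"x": np.int64, "y": np.int64, "toa_ns": np.float64, "energy_keV": np.float64}
    )


def validate_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Check the hit-table invariants; returns the table unchanged."""
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"hit table missing columns {missing}")
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if len(df) and (
        (x < 0).any() or (x >= GRID_SIZE).any() or (y < 0).any() or (y >= GRID_SIZE).any()
    ):
        raise GeometryError("hit coordinates outside the pixel matrix")
    if len(df) and not (df["energy_keV"].to_numpy() > 0).all():
        raise ConfigurationError("hit energies must be strictly positive")
    return df


class Cluster:
    """A connected, time-coincident group of pixel hits.

    Attributes
    ----------
    x, y : int arrays — pixel coordinates of the member hits
    toa_ns : float array — arrival times
    energy_keV : float array — per-pixel calibrated energies
    """

    __slots__ = ("x", "y", "toa_ns", "energy_keV")

    def __init__(self, x, y, toa_ns, energy_keV):
        self.x = np.asarray(x, dtype=np.int64)
        self.y = np.asarray(y, dtype=np.int64)
        self.toa_ns = np.asarray(toa_ns, dtype=np.float64)
        self.energy_keV = np.asarray(energy_keV, dtype=np.float64)
        if self.x.size == 0:
            raise ConfigurationError("a cluster needs at least one hit")

    @property
    def size(self) -> int:
        """Number of pixels in the cluster."""
        return int(self.x.size)

    @property
    def volume_keV(self) -> float:
        """Cluster volume: sum of the member energies in keV."""
        return float(self.energy_keV.sum())

    @property
    def t_ref_ns(self) -> float:
        """Earliest arrival time among the member hits."""
        return float(self.toa_ns.min())

    @property
    def centroid(self) -> tuple[float, float]:
        """Energy-weighted centroid (x, y) in pixel units."""
        w = self.energy_keV
        return float((self.x * w).sum() / w.sum()), float((self.y * w).sum() / w.sum())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Cluster(size={self.size}, volume_keV={self.volume_keV:.1f}, t_ref_ns={self.t_ref_ns:.0f})"


def cluster_table(clusters) -> pd.DataFrame:
    """Summarize clusters as a table (size, volume_keV, t_ref_ns, centroid)."""
    rows = []
    for c in clusters:
        cx, cy = c.centroid
        rows.append((c.size, c.volume_keV, c.t_ref_ns, cx, cy))
    return pd.DataFrame(rows, columns=["size", "volume_keV", "t_ref_ns", "cx", "cy"])


@dataclass
class DetectorConfig:
    """Sensor geometry entering the LET conversion.

    The sensor is operated partially depleted: only ``depleted_thickness_um``
    of silicon collects charge and defines the constant track length of the
    straight-line approximation.  ``si_to_water_factor`` is the single-value
    average silicon-to-water stopping-power ratio.
    """

    depleted_thickness_um: float = 137.0
    u_thickness_um: float = 3.0
    si_to_water_factor: float = 0.541

    def __post_init__(self):
        if not self.depleted_thickness_um > 0:
            raise ConfigurationError("depleted thickness must be positive")
        if not self.si_to_water_factor > 0:
            raise ConfigurationError("Si-to-water factor must be positive")
        if self.u_thickness_um < 0:
            raise ConfigurationError("thickness uncertainty must be >= 0")


@dataclass
class GeometryConfig:
    """PMMA-to-water depth bookkeeping via relative stopping power."""

    rsp_pmma: float = 1.158
    u_rsp: float = 0.008

    def __post_init__(self):
        if not self.rsp_pmma > 0:
            raise ConfigurationError("RSP must be positive")
        if self.u_rsp < 0:
            raise ConfigurationError("RSP uncertainty must be >= 0")
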