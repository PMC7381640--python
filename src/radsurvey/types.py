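"""Core containers shared across the survey pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ActivityTriplet:
    """Activity concentrations of the three natural series, Bq kg^-1.

    ``a_u`` is the 238U series (via 214Pb/214Bi progeny), ``a_th`` the 232Th
    series, ``a_k`` 40K.  Standard uncertainties default to zero (exact /
    synthetic truth).
    """

    a_u: float
    a_th: float
    a_k: float
    u_u: float = 0.0
    u_th: float = 0.0
    u_k: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_u", "a_th", "a_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative activity concentration: {name}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_u, self.a_th, self.a_k], dtype=float)

    def scaled(self, factor: float) -> "ActivityTriplet":
        return ActivityTriplet(
            self.a_u * factor, self.a_th * factor, self.a_k * factor,
            self.u_u * factor, self.u_th * factor, self.u_k * factor,
        )


@dataclass
class PulseHeightSpectrum:
    """Channel-indexed counts with live time and optional linear energy scale.

    The energy of channel ``c`` is ``offset_kev + gain_kev * c``.  Counts may
    be floats when they are noise-free expectations from the generator.
    """

    counts: np.ndarray
    live_time: float
    offset_kev: float | None = None
    gain_kev: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("negative channel counts")
        if self.live_time <= 0:
            raise ValueError("live time must be positive")
        if self.gain_kev is not None and self.gain_kev <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def is_calibrated(self) -> bool:
        return self.offset_kev is not None and self.gain_kev is not None

    def energies_kev(self) -> np.ndarray:
        if not self.is_calibrated:
            raise ValueError("spectrum has no energy calibration")
        return self.offset_kev + self.gain_kev * np.arange(self.n_channels)

    def energies_mev(self) -> np.ndarray:
        return self.energies_kev() / 1000.0

    def rates(self) -> np.ndarray:
        """Counts per second per channel."""
        return self.counts / self.live_time

    def copy_with(self, counts: np.ndarray) -> "PulseHeightSpectrum":
        return PulseHeightSpectrum(
            np.asarray(counts, dtype=float), self.live_time,
            self.offset_kev, self.gain_kev,
        )


@dataclass(frozen=True)
class CalibrationSet:
    """Survey calibration factors: the multipliers of the dose reconstruction
    D_air = C_in * SF_carbody * SF_asphalt * DCF."""

    sf_carbody: float
    sf_asphalt: float
    dcf: float
    u_sf_carbody: float = float("nan")
    u_sf_asphalt: float = float("nan")
    u_dcf: float = float("nan")
    n_carbody: int = 0
    n_asphalt: int = 0
    n_dcf: int = 0

    def __post_init__(self) -> None:
        for name in ("sf_carbody", "sf_asphalt", "dcf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"calibration factor must be positive: {name}")

    def product(self) -> float:
        return self.sf_carbody * self.sf_asphalt * self.dcf


@dataclass(frozen=True)
class DoseRecord:
    """Absorbed dose rate in air tagged by provenance and location."""

    d_air: float  # nGy h^-1
    provenance: str  # "direct" | "soil"
    site_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in ("direct", "soil"):
            raise ValueError("provenance must be 'direct' or 'soil'")
        if self.d_air < 0:
            raise ValueError("negative dose rate")


@dataclass
class HazardAssessment:
    """Risk surface for a site or region: doses, AEDs and hazard indices."""

    d_air_direct: float | None = None  # nGy h^-1
    d_air_soil: float | None = None
    oaed: float = math.nan  # mSv year^-1
    iaed: float = math.nan
    total_aed: float = math.nan
    ra_eq: float = math.nan  # Bq kg^-1
    h_ex: float = math.nan
    exceeds_limit: bool = False
    ratio_of_difference: float = math.nan
    within_reference_band: bool | None = None
    site_id: str = ""
    region: str = ""


@dataclass
class SurveyTrack:
    """Ordered 30-s car-borne records.

    ``records`` is a DataFrame with columns timestamp, lat, lon, cps,
    campaign and, after reconstruction, dose_ngy_h.
    """

    records: "object"  # pandas.DataFrame; kept loose to avoid import cycle

    def __post_init__(self) -> None:
        df = self.records
        required = {"timestamp", "lat", "lon", "cps", "campaign"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        if (df["cps"] < 0).any():
            raise ValueError("negative count rate in track")
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise ValueError("coordinates outside WGS84 ranges")
        ts = df["timestamp"].to_numpy()
        if ts.size > 1 and (ts[1:] < ts[:-1]).any():
            raise ValueError("track records not time-ordered")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SyntheticSite:
    """A fixed-point measurement / soil-sampling location with known truth."""

    site_id: str
    region: str
    lat: float
    lon: float
    activity: ActivityTriplet  # soil truth
    d_air_soil: float  # nGy h^-1, soil-dose formula on the soil truth
    builtup_factor: float = 1.0  # perturbs the direct-measurement truth only

    def __post_init__(self) -> None:
        if self.builtup_factor <= 0:
            raise ValueError("built-up multiplier must be positive")

    @property
    def d_air_direct(self) -> float:
        return self.d_air_soil * self.builtup_factor

    @property
    def direct_activity(self) -> ActivityTriplet:
        """Effective activity seen by an in-field detector at this site."""
        return self.activity.scaled(self.builtup_factor)


@dataclass
class DoseGrid:
    """Regular lon/lat grid of interpolated dose rates with a distance mask."""

    lons: np.ndarray  # cell-centre longitudes, ascending
    lats: np.ndarray  # cell-centre latitudes, ascending
    values: np.ndarray  # shape (n_lat, n_lon)
    mask: np.ndarray  # True where a cell is beyond the datum-distance radius
    spacing: float

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = np.nan
        return out
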