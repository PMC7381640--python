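"""Synthetic survey-campaign generator.

Generates complete campaigns — regional ground-truth activity fields, NaI(Tl)
field spectra, HPGe soil spectra, paired inside/outside and asphalt/bare
count measurements, and 30-s car-borne tracks — from a single truth
configuration, so that every downstream stage of the pipeline has a
recoverable known truth.

Activity concentrations are drawn from zero-truncated normal distributions
whose *truncated* mean and SD equal the configured regional values (the
parent normal parameters are solved by moment matching, feasible whenever
SD/mean < ~0.756).  The default regional structure mirrors a two-region
(north/south) national survey: northern soil 39/63/551 and southern soil
32/54/551 Bq kg^-1 for the U series / Th series / 40K, with the paired
shielding truths SF_carbody 2.01 (north) and 1.71 (south), SF_asphalt 0.96
(north) and 1.37 (south), and DCF 0.14 nGy h^-1 per cps.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import HPGE_PEAKS, NAI_LINE_LIBRARY, SERIES
from .dosimetry import dose_from_soil
from .forward import DetectorModel, expected_spectrum_rates
from .hpge import EfficiencyCurve, HpgeDetector
from .types import ActivityTriplet, PulseHeightSpectrum, SurveyTrack, SyntheticSite


@dataclass(frozen=True)
class RegionTruth:
    """Per-region generating truth: activity moments, geometry and shielding."""

    mean: tuple[float, float, float]  # (U, Th, K) Bq kg^-1
    sd: tuple[float, float, float]
    weight: float  # fraction of sites in this region
    bbox: tuple[float, float, float, float]  # lat_min, lat_max, lon_min, lon_max
    sf_carbody: float
    sf_asphalt: float

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mean):
            raise ValueError("regional means must be strictly positive")
        if any(s < 0 for s in self.sd):
            raise ValueError("regional SDs must be non-negative")
        if self.sf_carbody <= 0 or self.sf_asphalt <= 0:
            raise ValueError("shielding factors must be strictly positive")
        if not 0 < self.weight <= 1:
            raise ValueError("region weight must be in (0, 1]")


@dataclass(frozen=True)
class TruthConfig:
    """Generating truth for a whole campaign."""

    regions: dict[str, RegionTruth]
    dcf: float = 0.14  # nGy h^-1 per cps
    cosmic_cps_per_channel: float = 0.01
    detector: DetectorModel = field(default_factory=DetectorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one region is required")
        if self.dcf <= 0 or self.cosmic_cps_per_channel < 0:
            raise ValueError("DCF must be positive and cosmic rate non-negative")
        total = sum(r.weight for r in self.regions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("region weights must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def region_of(self, region_id: str) -> RegionTruth:
        try:
            return self.regions[region_id]
        except KeyError:
            raise KeyError(f"unknown region id: {region_id}") from None


def default_truth_config(seed: int = 0, **overrides) -> TruthConfig:
    """The study-condition campaign truth (two regions, 178:284 site split)."""
    regions = {
        "north": RegionTruth(
            mean=(39.0, 63.0, 551.0), sd=(25.0, 33.0, 259.0),
            weight=178 / 462, bbox=(20.0, 23.5, 102.0, 108.0),
            sf_carbody=2.01, sf_asphalt=0.96,
        ),
        "south": RegionTruth(
            mean=(32.0, 54.0, 551.0), sd=(19.0, 33.0, 389.0),
            weight=284 / 462, bbox=(8.5, 16.0, 104.0, 109.5),
            sf_carbody=1.71, sf_asphalt=1.37,
        ),
    }
    return TruthConfig(regions=regions, seed=seed, **overrides)


@functools.lru_cache(maxsize=128)
def _matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose zero-truncation has the given moments."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise ValueError(
            f"no zero-truncated normal has mean {mean} and SD {sd} "
            "(requires SD/mean below ~0.756)"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _draw_activity(mean: float, sd: float, rng: np.random.Generator, size: int):
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = _matched_truncnorm_params(mean, sd)
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng)


def _region_counts(config: TruthConfig, n_sites: int) -> dict[str, int]:
    names = list(config.regions)
    weights = np.array([config.regions[r].weight for r in names])
    counts = np.floor(weights * n_sites).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = weights * n_sites - counts
    for i in np.argsort(-frac)[: n_sites - counts.sum()]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def generate_sites(
    config: TruthConfig,
    n_sites: int,
    p_shielded: float | None = None,
    builtup_range: tuple[float, float] = (0.5, 2.1),
    rng: np.random.Generator | None = None,
) -> list[SyntheticSite]:
    """Draw ``n_sites`` fixed-point sites with known activity truth.

    When ``p_shielded`` is given, each site receives a built-up multiplier on
    its direct-measurement truth: with probability ``p_shielded`` a shielding
    factor uniform on (builtup_range[0], 1), otherwise a source factor uniform
    on (1, builtup_range[1]).  With ``p_shielded=None`` the direct and soil
    truths coincide.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rng is None:
        rng = config.rng()
    counts = _region_counts(config, n_sites)
    sites: list[SyntheticSite] = []
    k = 0
    for region_id, n_r in counts.items():
        if n_r == 0:
            continue
        region = config.regions[region_id]
        draws = np.column_stack([
            _draw_activity(region.mean[i], region.sd[i], rng, n_r) for i in range(3)
        ])
        lat = rng.uniform(region.bbox[0], region.bbox[1], size=n_r)
        lon = rng.uniform(region.bbox[2], region.bbox[3], size=n_r)
        if p_shielded is None:
            factors = np.ones(n_r)
        else:
            shielded = rng.random(n_r) < p_shielded
            factors = np.where(
                shielded,
                rng.uniform(builtup_range[0], 1.0, size=n_r),
                rng.uniform(1.0, builtup_range[1], size=n_r),
            )
        for i in range(n_r):
            triplet = ActivityTriplet(*draws[i])
            sites.append(
                SyntheticSite(
                    site_id=f"S{k:04d}",
                    region=region_id,
                    lat=float(lat[i]),
                    lon=float(lon[i]),
                    activity=triplet,
                    d_air_soil=dose_from_soil(triplet),
                    builtup_factor=float(factors[i]),
                )
            )
            k += 1
    return sites


# ---------------------------------------------------------------------------
# spectra


def nai_source_lines(activity: ActivityTriplet) -> list[tuple[float, float]]:
    """(energy MeV, incident flux) pairs for an activity triplet."""
    amounts = dict(zip(SERIES, activity.as_array()))
    lines = []
    for series in SERIES:
        for energy, prob, _nuc in NAI_LINE_LIBRARY[series]:
            lines.append((energy, amounts[series] * prob))
    return lines


def simulate_nai_spectrum(
    site: SyntheticSite,
    live_time: float,
    config: TruthConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> PulseHeightSpectrum:
    """Forward-model NaI(Tl) field spectrum at a site.

    The in-field spectrum reflects the site's *direct* truth (soil activity
    scaled by the built-up multiplier).  With ``noise=False`` the expected
    (unsampled) counts are returned.
    """
    if live_time <= 0:
        raise ValueError("live time must be positive")
    det = config.detector
    if det.e_max_mev < 3.2:
        raise ValueError("detector channel range cannot contain 3.2 MeV")
    rates = expected_spectrum_rates(
        det, nai_source_lines(site.direct_activity), config.cosmic_cps_per_channel
    )
    expected = rates * live_time
    if noise:
        if rng is None:
            rng = config.rng()
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    # measured spectra carry no energy scale; calibration recovers it
    return PulseHeightSpectrum(counts, live_time)


def simulate_hpge_spectrum(
    activity: ActivityTriplet,
    efficiency_curve: EfficiencyCurve,
    live_time: float = 30000.0,
    mass: float = 0.13,
    det: HpgeDetector | None = None,
    baseline_cps_per_channel: float = 0.002,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> PulseHeightSpectrum:
    """HPGe soil-sample spectrum: four assay photopeaks on a flat baseline.

    Expected net peak areas are activity x emission probability x
    efficiency(E) x live time x mass.
    """
    if live_time <= 0 or mass <= 0:
        raise ValueError("live time and sample mass must be positive")
    if det is None:
        det = HpgeDetector()
    energies = det.offset_kev + det.gain_kev * np.arange(det.n_channels)
    expected = np.full(det.n_channels, baseline_cps_per_channel * live_time)
    amounts = dict(zip(SERIES, activity.as_array()))
    sigma_ch = det.fwhm_kev / 2.3548200450309493 / det.gain_kev
    edges = np.arange(det.n_channels + 1) - 0.5
    for _nuclide, (e_kev, prob, series) in HPGE_PEAKS.items():
        area = amounts[series] * prob * efficiency_curve.efficiency_at(e_kev) * live_time * mass
        if area == 0:
            continue
        center_ch = (e_kev - det.offset_kev) / det.gain_kev
        cdf = stats.norm.cdf(edges, loc=center_ch, scale=sigma_ch)
        expected = expected + area * np.diff(cdf)
    if noise:
        if rng is None:
            rng = np.random.default_rng(0)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return PulseHeightSpectrum(counts, live_time, det.offset_kev, det.gain_kev)


# ---------------------------------------------------------------------------
# paired shielding measurements and tracks


def simulate_paired_counts(
    sites: list[SyntheticSite],
    config: TruthConfig,
    live_time: float = 30.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Paired inside/outside and asphalt/bare count rates at each site.

    Expectations: outside = D_air(direct)/DCF; inside = outside/SF_carbody;
    asphalt = outside (the outside measurement is made on asphalt);
    bare = asphalt x SF_asphalt.  Counts are Poisson over ``live_time``.
    """
    if not sites:
        raise ValueError("empty site list")
    if live_time <= 0:
        raise ValueError("live time must be positive")
    if rng is None:
        rng = config.rng()
    rows = []
    for site in sites:
        region = config.region_of(site.region)
        outside = site.d_air_direct / config.dcf
        inside = outside / region.sf_carbody
        asphalt = outside
        bare = asphalt * region.sf_asphalt
        cps = np.array([inside, outside, asphalt, bare])
        if noise:
            cps = rng.poisson(cps * live_time) / live_time
        rows.append(
            {
                "site_id": site.site_id,
                "region": site.region,
                "campaign": site.region,
                "inside_cps": cps[0],
                "outside_cps": cps[1],
                "asphalt_cps": cps[2],
                "bare_cps": cps[3],
                "d_air_true": site.d_air_direct,
            }
        )
    return pd.DataFrame(rows)


def linear_route(
    start: tuple[float, float], end: tuple[float, float], n_points: int
) -> list[tuple[float, float]]:
    """Straight-line route of ``n_points`` (lat, lon) vertices."""
    if n_points < 2:
        raise ValueError("a route needs at least 2 points")
    lats = np.linspace(start[0], end[0], n_points)
    lons = np.linspace(start[1], end[1], n_points)
    return list(zip(lats.tolist(), lons.tolist()))


def simulate_track(
    route: list[tuple[float, float]],
    sites: list[SyntheticSite],
    config: TruthConfig,
    campaign: str | None = None,
    interval_s: float = 30.0,
    start_time: str = "2015-08-01T00:00:00",
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> SurveyTrack:
    """Car-borne 30-s count-rate track along a route.

    The local true dose rate at each vertex is the direct truth of the
    nearest site; the inside-car count-rate expectation is
    D_air / (DCF x SF_carbody x SF_asphalt) for the local campaign.
    """
    if len(route) < 2:
        raise ValueError("a route needs at least 2 points")
    if not sites:
        raise ValueError("empty site list")
    if rng is None:
        rng = config.rng()
    site_lat = np.array([s.lat for s in sites])
    site_lon = np.array([s.lon for s in sites])
    times = pd.date_range(start=start_time, periods=len(route), freq=f"{int(interval_s)}s")
    rows = []
    for (lat, lon), ts in zip(route, times):
        nearest = int(np.argmin((site_lat - lat) ** 2 + (site_lon - lon) ** 2))
        site = sites[nearest]
        camp = campaign if campaign is not None else site.region
        region = config.region_of(camp)
        expected_cps = site.d_air_direct / (
            config.dcf * region.sf_carbody * region.sf_asphalt
        )
        cps = (
            rng.poisson(expected_cps * interval_s) / interval_s
            if noise
            else expected_cps
        )
        rows.append(
            {
                "timestamp": ts.isoformat(),
                "lat": lat,
                "lon": lon,
                "cps": cps,
                "campaign": camp,
            }
        )
    return SurveyTrack(pd.DataFrame(rows))
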