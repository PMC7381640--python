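"""HPGe soil assay by the absolute full-energy-peak efficiency method.

Soil activity concentrations are computed from net photopeak areas as

    A = N_net / (eps(E) * p_gamma * t_live * m)    [Bq kg^-1]

with eps the full-energy-peak efficiency interpolated log-log on a certified
multi-nuclide volume-source calibration, p_gamma the emission probability,
t_live the live time (30,000 s default) and m the sample mass.  The 238U
series combines the 214Pb (351.9 keV) and 214Bi (609.3 keV) results by
inverse-variance weighting; the 232Th series uses 228Ac (911.2 keV) and 40K
its 1460.8 keV line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import EFFICIENCY_SOURCE_LINES_KEV, HPGE_PEAKS
from .types import ActivityTriplet, PulseHeightSpectrum


class ExtrapolationWarning(UserWarning):
    """Efficiency queried slightly outside the calibrated span."""


class DegenerateWeightError(ValueError):
    """A weighted average received a zero uncertainty."""


@dataclass(frozen=True)
class HpgeDetector:
    """Channel grid and resolution of the soil-assay HPGe spectrometer."""

    n_channels: int = 2048
    gain_kev: float = 1.0
    offset_kev: float = 0.0
    fwhm_kev: float = 2.0
    relative_efficiency_pct: float = 17.5  # detector metadata; not used in math

    def channel_of(self, energy_kev: float) -> float:
        return (energy_kev - self.offset_kev) / self.gain_kev


@dataclass(frozen=True)
class EfficiencyCurve:
    """Full-energy-peak efficiency calibration points with log-log
    interpolation between them."""

    energies_kev: np.ndarray
    efficiencies: np.ndarray
    rel_uncertainty: float = 0.012  # relative standard uncertainty of eps

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        eff = np.asarray(self.efficiencies, dtype=float)
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "efficiencies", eff)
        if e.size < 2 or e.size != eff.size:
            raise ValueError("need >= 2 matching calibration points")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any((eff <= 0) | (eff >= 1)):
            raise ValueError("efficiencies must lie in (0, 1)")

    def efficiency_at(self, energy_kev: float) -> float:
        """Log-log linear interpolation; flags mild extrapolation, rejects
        queries far outside the calibrated span."""
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        if not lo * 0.8 <= energy_kev <= hi * 1.25:
            raise ValueError(
                f"energy {energy_kev} keV far outside calibrated span [{lo}, {hi}]"
            )
        if not lo <= energy_kev <= hi:
            warnings.warn(
                f"extrapolating efficiency at {energy_kev} keV", ExtrapolationWarning
            )
        log_eff = np.interp(
            np.log(energy_kev), np.log(self.energies_kev), np.log(self.efficiencies)
        )
        # np.interp clamps; extend the edge segments for mild extrapolation
        if energy_kev < lo or energy_kev > hi:
            if energy_kev < lo:
                x0, x1 = self.energies_kev[:2]
                y0, y1 = self.efficiencies[:2]
            else:
                x0, x1 = self.energies_kev[-2:]
                y0, y1 = self.efficiencies[-2:]
            slope = (np.log(y1) - np.log(y0)) / (np.log(x1) - np.log(x0))
            log_eff = np.log(y0) + slope * (np.log(energy_kev) - np.log(x0))
        return float(np.exp(log_eff))


def synthetic_efficiency_curve(
    eff_662: float = 0.05, exponent: float = -0.7, rel_uncertainty: float = 0.012
) -> EfficiencyCurve:
    """Synthetic stand-in for a certified nine-nuclide volume-source
    calibration: a power-law efficiency anchored at 661.7 keV, evaluated at
    the standard source line energies."""
    e = np.array(EFFICIENCY_SOURCE_LINES_KEV)
    eff = eff_662 * (e / 661.7) ** exponent
    return EfficiencyCurve(e, eff, rel_uncertainty)


@dataclass(frozen=True)
class PeakMeasurement:
    """One photopeak's net area and the assay conditions behind it."""

    nuclide: str
    energy_kev: float
    net_area: float
    u_net: float
    live_time: float = 30000.0
    mass_kg: float = 0.13
    emission_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.net_area < 0:
            raise ValueError("net area must be >= 0 (clamp before constructing)")
        if self.live_time <= 0 or self.mass_kg <= 0 or self.emission_prob <= 0:
            raise ValueError("live time, mass and emission probability must be positive")


def net_peak_area(
    spectrum: PulseHeightSpectrum,
    roi: tuple[int, int],
    n_flank: int = 3,
) -> tuple[float, float]:
    """Net area in a region of interest over a linear baseline.

    The baseline is the straight line through the mean counts of ``n_flank``
    channels on each flank of the half-open ROI ``[lo, hi)``; the net area is
    gross minus the baseline integral, clamped at zero (with a warning), and
    its uncertainty follows Poisson propagation through both terms.
    """
    lo, hi = roi
    counts = spectrum.counts
    if not (0 <= lo < hi <= counts.size):
        raise ValueError("ROI outside spectrum")
    if lo - n_flank < 0 or hi + n_flank > counts.size:
        raise ValueError("ROI too close to the spectrum edge for baseline flanks")
    left = counts[lo - n_flank : lo]
    right = counts[hi : hi + n_flank]
    m_left, m_right = float(left.mean()), float(right.mean())
    x_left = lo - (n_flank + 1) / 2.0
    x_right = hi - 1 + (n_flank + 1) / 2.0
    x = np.arange(lo, hi, dtype=float)
    w_right = (x - x_left) / (x_right - x_left)
    w_left = 1.0 - w_right
    baseline = w_left.sum() * m_left + w_right.sum() * m_right
    gross = float(counts[lo:hi].sum())
    net = gross - baseline
    var_base = (w_left.sum() ** 2) * m_left / n_flank + (w_right.sum() ** 2) * m_right / n_flank
    u = float(np.sqrt(max(gross, 0.0) + max(var_base, 0.0)))
    if net < 0:
        warnings.warn("negative net area clamped to zero", UserWarning)
        net = 0.0
    return net, u


def activity_from_peak(
    p: PeakMeasurement, curve: EfficiencyCurve
) -> tuple[float, float]:
    """Absolute-method activity concentration from one peak, with combined
    uncertainty over the net-area and efficiency terms."""
    eff = curve.efficiency_at(p.energy_kev)
    denom = eff * p.emission_prob * p.live_time * p.mass_kg
    if denom == 0:
        raise ValueError("zero denominator in absolute-method activity")
    a = p.net_area / denom
    if p.net_area > 0:
        rel = np.sqrt((p.u_net / p.net_area) ** 2 + curve.rel_uncertainty**2)
        u = a * float(rel)
    else:
        u = p.u_net / denom
    return a, u


def u238_weighted_average(
    a_pb: tuple[float, float], a_bi: tuple[float, float]
) -> tuple[float, float]:
    """Inverse-variance weighted mean of the 214Pb and 214Bi activities."""
    (v1, u1), (v2, u2) = a_pb, a_bi
    if u1 <= 0 or u2 <= 0:
        raise DegenerateWeightError("weighted average requires positive uncertainties")
    w1, w2 = 1.0 / u1**2, 1.0 / u2**2
    value = (w1 * v1 + w2 * v2) / (w1 + w2)
    return value, (w1 + w2) ** -0.5


def assay_soil(
    spectrum: PulseHeightSpectrum,
    curve: EfficiencyCurve,
    mass_kg: float,
    det: HpgeDetector | None = None,
    roi_sigmas: float = 3.0,
    n_flank: int = 3,
) -> ActivityTriplet:
    """Full soil assay: net areas of the four assay peaks, absolute-method
    activities and the 238U weighted average.  Returns an
    :class:`~radsurvey.types.ActivityTriplet` with standard uncertainties.
    """
    if det is None:
        det = HpgeDetector()
    if not spectrum.is_calibrated:
        raise ValueError("HPGe spectrum requires an energy calibration")
    sigma_ch = det.fwhm_kev / 2.3548200450309493 / spectrum.gain_kev
    results: dict[str, tuple[float, float]] = {}
    for nuclide, (e_kev, prob, _series) in HPGE_PEAKS.items():
        center = (e_kev - spectrum.offset_kev) / spectrum.gain_kev
        half = roi_sigmas * sigma_ch
        roi = (int(np.floor(center - half)), int(np.ceil(center + half)) + 1)
        net, u_net = net_peak_area(spectrum, roi, n_flank=n_flank)
        meas = PeakMeasurement(
            nuclide=nuclide,
            energy_kev=e_kev,
            net_area=net,
            u_net=u_net,
            live_time=spectrum.live_time,
            mass_kg=mass_kg,
            emission_prob=prob,
        )
        results[nuclide] = activity_from_peak(meas, curve)
    a_u, u_u = u238_weighted_average(results["Pb-214"], results["Bi-214"])
    a_th, u_th = results["Ac-228"]
    a_k, u_k = results["K-40"]
    return ActivityTriplet(a_u, a_th, a_k, u_u, u_th, u_k)
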