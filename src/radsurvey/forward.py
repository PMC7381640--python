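"""Simplified NaI(Tl) forward response model.

This model replaces a full detector Monte Carlo with three ingredients:

* a Gaussian full-energy peak at the line energy, with resolution
  FWHM(E) = r * sqrt(0.662 MeV * E) anchored at the conventional 0.662 MeV
  reference (``r`` is the fractional FWHM at 0.662 MeV);
* a flat per-line Compton continuum extending from zero to the line's
  Compton edge, carrying a fixed fraction of the peak counts;
* an energy-dependent full-energy-peak sensitivity
  eps(E) = eps0 * (0.662 / E)^p (counts s^-1 per unit incident line flux).

The same functions generate synthetic spectra and build the unfolding
response matrix, so the forward and inverse problems are consistent by
construction.  "Flux" throughout means the incident line photon rate in the
detector's reference geometry (arbitrary but fixed units); activity
concentrations map to flux through the emission probabilities of the line
library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .constants import compton_edge_mev


@dataclass(frozen=True)
class DetectorModel:
    """Channel grid and response parameters of the field NaI(Tl) spectrometer."""

    n_channels: int = 1024
    gain_kev: float = 3.2  # keV per channel
    offset_kev: float = 0.0
    resolution_fwhm_662: float = 0.075  # fractional FWHM at 0.662 MeV
    continuum_fraction: float = 0.30  # continuum counts per peak count
    efficiency_scale: float = 1.0  # eps0, cps per unit flux at 0.662 MeV
    efficiency_exponent: float = 0.4

    def __post_init__(self) -> None:
        if self.n_channels < 512:
            raise ValueError("channel count must be >= 512")
        if self.gain_kev <= 0:
            raise ValueError("gain must be positive")
        if self.resolution_fwhm_662 < 0 or self.continuum_fraction < 0:
            raise ValueError("resolution and continuum fraction must be >= 0")
        if self.efficiency_scale <= 0:
            raise ValueError("efficiency scale must be positive")

    @property
    def e_max_mev(self) -> float:
        return (self.offset_kev + self.gain_kev * self.n_channels) / 1000.0

    def channel_energies_mev(self) -> np.ndarray:
        """Energy at each channel index (the channel coordinate itself)."""
        return (self.offset_kev + self.gain_kev * np.arange(self.n_channels)) / 1000.0

    def channel_edges_mev(self) -> np.ndarray:
        """Energy bin edges of the channel grid (channel c spans c +- 1/2)."""
        edges = self.offset_kev + self.gain_kev * (np.arange(self.n_channels + 1) - 0.5)
        return edges / 1000.0

    def fwhm_mev(self, energy_mev: float) -> float:
        return self.resolution_fwhm_662 * np.sqrt(0.662 * energy_mev)

    def sigma_mev(self, energy_mev: float) -> float:
        return self.fwhm_mev(energy_mev) / 2.3548200450309493

    def efficiency(self, energy_mev) -> np.ndarray | float:
        return self.efficiency_scale * (0.662 / np.asarray(energy_mev, dtype=float)) ** self.efficiency_exponent


def line_expected_channels(det: DetectorModel, energy_mev: float, flux: float) -> np.ndarray:
    """Expected channel counts per second for one photon line at unit live time.

    The Gaussian peak integrates (over the channel edges) to
    ``flux * eps(E)``; the flat continuum carries
    ``flux * eps(E) * continuum_fraction`` spread uniformly over channels
    below the Compton edge.
    """
    if energy_mev <= 0:
        raise ValueError("line energy must be positive")
    if flux < 0:
        raise ValueError("flux must be non-negative")
    edges = det.channel_edges_mev()
    peak_rate = flux * det.efficiency(energy_mev)
    sigma = det.sigma_mev(energy_mev)
    if sigma > 0:
        cdf = norm.cdf(edges, loc=energy_mev, scale=sigma)
        peak = peak_rate * np.diff(cdf)
    else:  # perfect resolution: all counts in the containing channel
        peak = np.zeros(det.n_channels)
        idx = int(np.clip(np.searchsorted(edges, energy_mev) - 1, 0, det.n_channels - 1))
        peak[idx] = peak_rate
    out = peak
    if det.continuum_fraction > 0:
        edge = compton_edge_mev(energy_mev)
        centers = det.channel_energies_mev()
        in_cont = centers < edge
        n_cont = int(in_cont.sum())
        if n_cont > 0:
            cont = np.zeros(det.n_channels)
            cont[in_cont] = peak_rate * det.continuum_fraction / n_cont
            out = out + cont
    return out


def expected_spectrum_rates(
    det: DetectorModel,
    lines: list[tuple[float, float]],
    cosmic_cps_per_channel: float = 0.0,
) -> np.ndarray:
    """Expected counts per second per channel for a set of (energy MeV, flux)
    lines plus a flat cosmic floor over all channels."""
    rates = np.full(det.n_channels, float(cosmic_cps_per_channel))
    for energy, flux in lines:
        if flux > 0:
            rates = rates + line_expected_channels(det, energy, flux)
    return rates
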