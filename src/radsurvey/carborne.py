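"""Car-borne survey calibration and dose reconstruction.

The survey dosimetry model is multiplicative with no offset:

    D_air = C_in x SF_carbody x SF_asphalt x DCF

where C_in is the 30-s count rate inside the car, SF_carbody the car-body
shielding factor (outside/inside count ratio), SF_asphalt the asphalt-cover
shielding factor (bare/asphalt ratio; may fall below 1 where the roadbed is
itself a source), and DCF the count-rate-to-dose conversion (nGy h^-1 per
cps).  Each factor is fitted by through-origin least squares on paired
measurements; an optional intercept fit is available for diagnostics but is
never used in the reconstruction.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .types import CalibrationSet, SurveyTrack


class MissingCalibrationError(KeyError):
    """A paired table lacks the columns for one of the three factors."""

    def __init__(self, factor: str, columns):
        self.factor = factor
        super().__init__(f"cannot fit {factor}: missing columns {sorted(columns)}")


class UncertaintyUndefinedWarning(UserWarning):
    """A slope was fitted on a single pair; its uncertainty is undefined."""


def fit_proportional(
    x, y, intercept: bool = False
) -> tuple[float, float]:
    """Least-squares slope of y = beta * x (through the origin by default).

    Returns (slope, standard uncertainty of the slope); the uncertainty is
    derived from the residual variance.  With ``intercept=True`` an ordinary
    straight-line fit is performed and the slope/uncertainty of that line are
    returned (diagnostic only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.all(x == 0):
        raise ValueError("all x values are zero; slope undefined")
    n = x.size
    if intercept:
        if n < 3:
            raise ValueError("intercept fit needs >= 3 pairs")
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
        return float(coeffs[0]), float(np.sqrt(cov[0, 0]))
    sxx = float(x @ x)
    beta = float(x @ y) / sxx
    if n == 1:
        warnings.warn(
            "slope fitted on a single pair; uncertainty undefined",
            UncertaintyUndefinedWarning,
        )
        return beta, float("nan")
    resid = y - beta * x
    u = float(np.sqrt((resid @ resid) / ((n - 1) * sxx)))
    return beta, u


_FACTOR_COLUMNS = {
    "SF_carbody": ("inside_cps", "outside_cps"),
    "SF_asphalt": ("asphalt_cps", "bare_cps"),
    "DCF": ("outside_cps", "d_air"),
}


def estimate_calibration(
    paired: pd.DataFrame,
    dose_column: str = "d_air",
    intercept: bool = False,
) -> CalibrationSet:
    """Fit the three survey factors from a paired-measurement table.

    SF_carbody is the slope of outside vs inside counts, SF_asphalt the
    slope of bare-surface vs asphalt counts, DCF the slope of the unfolded
    absorbed dose rate (``dose_column``, nGy h^-1) vs outside counts.
    """
    needed = dict(_FACTOR_COLUMNS)
    needed["DCF"] = ("outside_cps", dose_column)
    fits = {}
    for factor, (xcol, ycol) in needed.items():
        missing = {c for c in (xcol, ycol) if c not in paired.columns}
        if missing:
            raise MissingCalibrationError(factor, missing)
        slope, u = fit_proportional(paired[xcol], paired[ycol], intercept=intercept)
        fits[factor] = (slope, u, len(paired))
    return CalibrationSet(
        sf_carbody=fits["SF_carbody"][0],
        sf_asphalt=fits["SF_asphalt"][0],
        dcf=fits["DCF"][0],
        u_sf_carbody=fits["SF_carbody"][1],
        u_sf_asphalt=fits["SF_asphalt"][1],
        u_dcf=fits["DCF"][1],
        n_carbody=fits["SF_carbody"][2],
        n_asphalt=fits["SF_asphalt"][2],
        n_dcf=fits["DCF"][2],
    )


def estimate_calibration_by_campaign(
    paired: pd.DataFrame, campaign_column: str = "campaign", **kwargs
) -> dict[str, CalibrationSet]:
    """Per-campaign calibration fits (car and roadbed differ by campaign)."""
    if campaign_column not in paired.columns:
        raise MissingCalibrationError("per-campaign calibration", {campaign_column})
    return {
        str(campaign): estimate_calibration(group, **kwargs)
        for campaign, group in paired.groupby(campaign_column, sort=True)
    }


def reconstruct_dose(
    track: SurveyTrack,
    calib: CalibrationSet | Mapping[str, CalibrationSet],
) -> SurveyTrack:
    """Reconstruct per-record absorbed dose rate in air along a track.

    ``calib`` may be a single calibration or a mapping from campaign id to
    calibration; each record uses its campaign's factors.  Adds a
    ``dose_ngy_h`` column.
    """
    df = track.records.copy()
    if (df["cps"] < 0).any():
        raise ValueError("negative count rate in track")
    if isinstance(calib, Mapping):
        missing = set(df["campaign"].unique()) - set(calib)
        if missing:
            raise KeyError(f"no calibration for campaigns: {sorted(missing)}")
        product = df["campaign"].map({k: v.product() for k, v in calib.items()})
    else:
        product = calib.product()
    df["dose_ngy_h"] = df["cps"] * product
    return SurveyTrack(df)
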