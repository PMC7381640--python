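"""Plain-text I/O: SPE-style spectra, track CSVs and input validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import PulseHeightSpectrum, SurveyTrack


def write_spe(spectrum: PulseHeightSpectrum, path) -> None:
    """Write a spectrum as an SPE-style text block ($MEAS_TIM, $DATA,
    optional $ENER_FIT)."""
    with open(path, "w") as fh:
        fh.write("$MEAS_TIM:\n")
        fh.write(f"{spectrum.live_time:.1f} {spectrum.live_time:.1f}\n")
        fh.write("$DATA:\n")
        fh.write(f"0 {spectrum.n_channels - 1}\n")
        for c in spectrum.counts:
            if float(c).is_integer():
                fh.write(f"{int(c)}\n")
            else:
                fh.write(f"{c:.6f}\n")
        if spectrum.is_calibrated:
            fh.write("$ENER_FIT:\n")
            fh.write(f"{spectrum.offset_kev:.6f} {spectrum.gain_kev:.6f}\n")


def read_spe(path) -> PulseHeightSpectrum:
    """Parse an SPE-style text spectrum."""
    live_time = None
    counts: list[float] = []
    offset = gain = None
    section = None
    expected = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("$"):
                section = line.rstrip(":").upper()
                continue
            if section == "$MEAS_TIM":
                live_time = float(line.split()[0])
            elif section == "$DATA":
                parts = line.split()
                if expected is None and len(parts) == 2:
                    first, last = int(parts[0]), int(parts[1])
                    expected = last - first + 1
                else:
                    for p in parts:
                        value = float(p)
                        if value < 0:
                            raise ValueError(
                                f"negative channel count at channel {len(counts)}"
                            )
                        counts.append(value)
            elif section == "$ENER_FIT":
                offset, gain = (float(p) for p in line.split()[:2])
    if live_time is None:
        raise ValueError("SPE file lacks $MEAS_TIM")
    if expected is not None and len(counts) != expected:
        raise ValueError(
            f"SPE $DATA declares {expected} channels but {len(counts)} present"
        )
    return PulseHeightSpectrum(np.array(counts), live_time, offset, gain)


def write_track_csv(track: SurveyTrack, path) -> None:
    track.records.to_csv(path, index=False)


def read_track_csv(path) -> SurveyTrack:
    return SurveyTrack(pd.read_csv(path))


def validate_track_frame(df: pd.DataFrame, name: str = "track") -> list[str]:
    """Schema / range / ordering checks for a track table; returns error
    strings (empty when valid)."""
    errors = []
    required = ["timestamp", "lat", "lon", "cps", "campaign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{name}: missing columns {missing}")
        return errors
    for i, row in df.iterrows():
        if not -90 <= row["lat"] <= 90:
            errors.append(f"{name} row {i}: latitude {row['lat']} outside [-90, 90]")
        if not -180 <= row["lon"] <= 180:
            errors.append(f"{name} row {i}: longitude {row['lon']} outside [-180, 180]")
        if row["cps"] < 0:
            errors.append(f"{name} row {i}: negative count rate")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        errors.append(f"{name}: unparseable timestamps")
    elif not ts.is_monotonic_increasing:
        errors.append(f"{name}: timestamps not monotone increasing")
    return errors
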