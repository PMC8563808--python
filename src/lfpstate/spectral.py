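"""Band-power feature extraction from 1-s signal segments.

Each segment is transformed with a plain (rectangular-window) FFT into a
one-sided periodogram normalized so that the power bins sum to the segment
variance (Parseval), then summed over inclusive band masks: theta 4-8 Hz,
alpha 9-12 Hz, beta 13-30 Hz. With 1-s segments the bin resolution is 1 Hz,
so the printed band edges map to exact bin sets. Per hemisphere this yields
three features, six per subject with a bilateral montage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import SegmentedEpoch
from .sigio import FEATURE_COLUMNS, validate_feature_table
from .simulate import DEFAULT_BANDS, BandSpec

__all__ = ["Periodogram", "periodogram", "band_power", "build_feature_table"]


@dataclass
class Periodogram:
    """One-sided power spectrum; ``power.sum()`` equals the segment variance."""

    freqs: np.ndarray
    power: np.ndarray


def periodogram(segment: np.ndarray, fs: float, segment_seconds: float = 1.0) -> Periodogram:
    """Parseval-normalized one-sided periodogram of one segment.

    The segment mean is removed before the transform, so the DC bin is zero
    and the remaining bins carry exactly the segment variance. Band masks
    start at 4 Hz, so the DC bin is reported but never enters a feature.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be a 1-D sample vector")
    expected = int(round(fs * segment_seconds))
    if segment.size != expected:
        raise ValueError(
            f"segment length {segment.size} != round(fs * segment_seconds) = {expected}"
        )
    n = segment.size
    x = segment - segment.mean()
    spec = np.fft.rfft(x)
    power = (np.abs(spec) ** 2) / n**2
    # One-sided doubling: every bin except DC and (for even n) Nyquist.
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return Periodogram(freqs=freqs, power=power)


def band_power(p: Periodogram, band: BandSpec) -> float:
    """Sum of periodogram bins with ``low_hz <= f <= high_hz`` (inclusive)."""
    nyq = p.freqs[-1]
    if band.low_hz < 0 or band.high_hz > nyq:
        raise ValueError(f"band {band.name!r} [{band.low_hz}, {band.high_hz}] outside [0, {nyq}]")
    mask = (p.freqs >= band.low_hz) & (p.freqs <= band.high_hz)
    if not mask.any():
        raise ValueError(f"band {band.name!r} contains no frequency bins at this resolution")
    return float(p.power[mask].sum())


def build_feature_table(
    segmented: Iterable[SegmentedEpoch],
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    segment_seconds: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-segment feature table from segmented hemisphere epochs.

    One row per (subject, epoch, segment); hemispheres absent from the input
    leave their three columns missing (NA). Column layout follows
    :data:`lfpstate.sigio.FEATURE_COLUMNS`.
    """
    suffix = {"left": "L", "right": "R"}
    rows: dict[tuple[str, str, int], dict] = {}
    for se in segmented:
        for idx in range(se.segments.shape[0]):
            key = (se.subject_id, se.epoch, idx)
            row = rows.setdefault(
                key, {"subject_id": se.subject_id, "epoch": se.epoch, "segment_index": idx}
            )
            p = periodogram(se.segments[idx], se.fs, segment_seconds)
            for band in bands:
                col = f"{band.name}_{suffix[se.hemisphere]}"
                if col in row:
                    raise ValueError(
                        f"duplicate feature {col} for (subject={se.subject_id}, "
                        f"epoch={se.epoch}, segment={idx})"
                    )
                row[col] = band_power(p, band)
    df = pd.DataFrame(list(rows.values()))
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[FEATURE_COLUMNS]
    df = df.sort_values(["subject_id", "epoch", "segment_index"]).reset_index(drop=True)
    return validate_feature_table(df)
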