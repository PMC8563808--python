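"""Signal conditioning: decimation, zero-phase bandpass, DC removal,
within-hemisphere contact averaging, and epoch segmentation.

The canonical chain (and the order the pipeline applies) is::

    decimate -> bandpass_zero_phase -> remove_dc -> average_hemisphere -> segment_epoch

Decimation uses polyphase FIR resampling with an anti-alias cutoff at
0.4 x the target rate; the bandpass is a Butterworth filter applied
forward-backward (zero phase). Epoch windows that touch the first or last
second of a recording are trimmed away from the boundary when possible, to
keep filter edge transients out of the analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .sigio import EPOCH_LABELS, LfpRecording, MontageError

__all__ = [
    "HemisphereSignal",
    "SegmentedEpoch",
    "decimate",
    "bandpass_zero_phase",
    "remove_dc",
    "average_hemisphere",
    "segment_epoch",
    "trim_epoch_edges",
    "preprocess_recording",
    "qc_screen_hemispheres",
]


@dataclass
class HemisphereSignal:
    """A single averaged-hemisphere trace with rescaled epoch windows."""

    subject_id: str
    hemisphere: str
    fs: float
    data: np.ndarray
    epochs: dict[str, tuple[int, int]]


@dataclass
class SegmentedEpoch:
    """Non-overlapping fixed-length segments of one epoch (rows = segments)."""

    subject_id: str
    hemisphere: str
    epoch: str
    fs: float
    segments: np.ndarray


def _rescale_epochs(
    epochs: dict[str, tuple[int, int]], fs_in: float, fs_out: float, n_out: int
) -> dict[str, tuple[int, int]]:
    out = {}
    for label, (start, end) in epochs.items():
        s = int(round(start * fs_out / fs_in))
        e = int(round(end * fs_out / fs_in))
        out[label] = (min(s, n_out), min(e, n_out))
    return out


def decimate(rec: LfpRecording, target_fs: float) -> LfpRecording:
    """Anti-aliased polyphase rate reduction to ``target_fs``.

    Handles non-integer ratios (e.g. 44000 -> 1000 and 2000 -> 1000 both
    work). The anti-alias FIR cutoff is 0.4 x target_fs.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    if target_fs > rec.fs:
        raise ValueError(f"target_fs ({target_fs}) exceeds recording rate ({rec.fs})")
    if abs(target_fs - rec.fs) < 1e-12:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    # 10 taps per polyphase branch on each side, matching common practice.
    half_len = 10 * max(up, down)
    cutoff_hz = 0.4 * target_fs
    taps = sps.firwin(2 * half_len + 1, cutoff_hz, fs=rec.fs * up)
    data = sps.resample_poly(rec.data, up, down, axis=1, window=taps * up)
    n_out = data.shape[1]
    return LfpRecording(
        subject_id=rec.subject_id,
        fs=float(target_fs),
        channels=list(rec.channels),
        data=data,
        epochs=_rescale_epochs(rec.epochs, rec.fs, target_fs, n_out),
    )


def bandpass_zero_phase(
    rec: LfpRecording, low_hz: float = 0.5, high_hz: float = 80.0, order: int = 4
) -> LfpRecording:
    """Forward-backward Butterworth bandpass (zero net phase shift).

    ``order`` is the design order of the underlying Butterworth prototype;
    the effective magnitude response is the squared single-pass response.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyq})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=rec.fs)
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return LfpRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channels=list(rec.channels),
        data=data,
        epochs=dict(rec.epochs),
    )


def remove_dc(rec: LfpRecording) -> LfpRecording:
    """Subtract each contact's whole-recording mean (contact-wise DC removal)."""
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return LfpRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channels=list(rec.channels),
        data=data,
        epochs=dict(rec.epochs),
    )


def average_hemisphere(rec: LfpRecording) -> list[HemisphereSignal]:
    """Pointwise mean of the four contacts within each present hemisphere."""
    out = []
    for hemi in rec.hemispheres:
        block = rec.hemisphere_data(hemi)
        if block.shape[0] != 4:
            raise MontageError(
                f"hemisphere {hemi!r} has {block.shape[0]} contacts; expected 4"
            )
        out.append(
            HemisphereSignal(
                subject_id=rec.subject_id,
                hemisphere=hemi,
                fs=rec.fs,
                data=block.mean(axis=0),
                epochs=dict(rec.epochs),
            )
        )
    return out


def trim_epoch_edges(rec: LfpRecording, guard_seconds: float = 1.0) -> LfpRecording:
    """Pull epoch windows off the recording boundaries by ``guard_seconds``.

    Windows already clear of the first/last guard interval are untouched; a
    window that would become empty is left as-is.
    """
    guard = int(round(guard_seconds * rec.fs))
    n = rec.n_samples
    epochs = {}
    for label, (start, end) in rec.epochs.items():
        s = max(start, guard)
        e = min(end, n - guard)
        epochs[label] = (s, e) if s < e else (start, end)
    return LfpRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channels=list(rec.channels),
        data=rec.data,
        epochs=epochs,
    )


def segment_epoch(
    sig: HemisphereSignal, epoch_label: str, segment_seconds: float = 1.0
) -> SegmentedEpoch:
    """Split one epoch into contiguous non-overlapping fixed-length rows.

    A trailing partial segment is discarded (floor rule).
    """
    if epoch_label not in sig.epochs:
        raise KeyError(f"epoch {epoch_label!r} not present (have {sorted(sig.epochs)})")
    start, end = sig.epochs[epoch_label]
    seg_len = int(round(segment_seconds * sig.fs))
    n_seg = (end - start) // seg_len
    if n_seg < 1:
        raise ValueError(
            f"epoch {epoch_label!r} shorter ({(end - start) / sig.fs:g} s) than one "
            f"{segment_seconds:g}-s segment"
        )
    segs = sig.data[start : start + n_seg * seg_len].reshape(n_seg, seg_len)
    return SegmentedEpoch(
        subject_id=sig.subject_id,
        hemisphere=sig.hemisphere,
        epoch=epoch_label,
        fs=sig.fs,
        segments=segs,
    )


def qc_screen_hemispheres(
    recordings: list[LfpRecording], rms_factor: float = 10.0
) -> dict[str, set[str]]:
    """Cohort-level hemisphere exclusion rule.

    A hemisphere is flagged when any of its contacts has RMS greater than
    ``rms_factor`` x the median contact RMS across the whole cohort. Returns
    ``{subject_id: {hemispheres to drop}}`` (empty sets omitted).
    """
    all_rms = np.concatenate([np.sqrt((r.data**2).mean(axis=1)) for r in recordings])
    threshold = rms_factor * np.median(all_rms)
    flagged: dict[str, set[str]] = {}
    for rec in recordings:
        rms = np.sqrt((rec.data**2).mean(axis=1))
        for (hemi, _), value in zip(rec.channels, rms):
            if value > threshold:
                flagged.setdefault(rec.subject_id, set()).add(hemi)
    return flagged


def preprocess_recording(
    rec: LfpRecording,
    target_fs: float = 1000.0,
    low_hz: float = 0.5,
    high_hz: float = 80.0,
    order: int = 4,
    drop_hemispheres: set[str] | None = None,
    guard_seconds: float = 1.0,
) -> tuple[list[HemisphereSignal], dict]:
    """Run the full conditioning chain on one recording.

    Returns the averaged hemisphere signals (excluding any in
    ``drop_hemispheres``) and a provenance dictionary recording every
    parameter and the step order.
    """
    if drop_hemispheres:
        keep = [i for i, (h, _) in enumerate(rec.channels) if h not in drop_hemispheres]
        if not keep:
            raise MontageError(f"all hemispheres of {rec.subject_id} excluded by QC")
        rec = LfpRecording(
            subject_id=rec.subject_id,
            fs=rec.fs,
            channels=[rec.channels[i] for i in keep],
            data=rec.data[keep],
            epochs=dict(rec.epochs),
        )
    rec = decimate(rec, target_fs)
    rec = bandpass_zero_phase(rec, low_hz=low_hz, high_hz=high_hz, order=order)
    rec = remove_dc(rec)
    rec = trim_epoch_edges(rec, guard_seconds=guard_seconds)
    signals = average_hemisphere(rec)
    provenance = {
        "steps": ["decimate", "bandpass_zero_phase", "remove_dc", "trim_epoch_edges", "average_hemisphere"],
        "target_fs": target_fs,
        "bandpass": {"low_hz": low_hz, "high_hz": high_hz, "order": order, "family": "butterworth", "zero_phase": True},
        "guard_seconds": guard_seconds,
        "dropped_hemispheres": sorted(drop_hemispheres) if drop_hemispheres else [],
    }
    return signals, provenance
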