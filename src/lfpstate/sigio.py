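"""Signal and table I/O: validated in-memory containers plus disk formats.

Two signal containers are supported:

* **EDF+** — the interchange format. Files are written by a minimal EDF+C
  writer (16-bit samples, 1-s data records, epoch windows stored as EDF+
  annotations) and read back through :mod:`mne`. EDF's 16-bit quantization
  makes it lossy.
* **internal** — the precision-bearing format: a raw little-endian float32
  matrix (``<stem>.f32``) next to a JSON sidecar (``<stem>.json``) holding
  sampling rate, channel montage and epoch windows.

Tables (clinical scores, spectral features) travel as TSV.

All sample indices are 0-based and epoch windows are half-open
``[start, end)`` intervals.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPOCH_LABELS",
    "HDRS_MAX",
    "FEATURE_COLUMNS",
    "LfpRecording",
    "ClinicalTable",
    "MontageError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
    "read_clinical_table",
    "write_clinical_table",
]

EPOCH_LABELS = ("PRE", "MID", "POST")
HDRS_MAX = 52.0
HEMI_PREFIX = {"left": "L", "right": "R"}
PREFIX_HEMI = {"L": "left", "R": "right"}

#: Exact column set (and order) of the on-disk feature table.
FEATURE_COLUMNS = [
    "subject_id",
    "epoch",
    "segment_index",
    "theta_L",
    "alpha_L",
    "beta_L",
    "theta_R",
    "alpha_R",
    "beta_R",
]
FEATURE_VALUE_COLUMNS = FEATURE_COLUMNS[3:]


class ValidationError(ValueError):
    """A container violated one of its declared invariants."""


class MontageError(ValidationError):
    """Channel layout does not match the expected bilateral 4-contact montage."""


@dataclass
class LfpRecording:
    """One subject's multi-contact continuous LFP signal.

    ``channels`` is an ordered list of ``(hemisphere, contact_index)`` pairs,
    normalized to L1-L4 then R1-R4; ``epochs`` maps epoch labels to half-open
    0-based sample windows.
    """

    subject_id: str
    fs: float
    channels: list[tuple[str, int]]
    data: np.ndarray
    epochs: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = [(str(h), int(c)) for h, c in self.channels]
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.data.ndim != 2:
            raise ValidationError("data must be a channels x samples matrix")
        if len(self.channels) != self.data.shape[0]:
            raise MontageError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        by_hemi: dict[str, list[int]] = {}
        for hemi, contact in self.channels:
            if hemi not in HEMI_PREFIX:
                raise MontageError(f"unknown hemisphere {hemi!r}")
            by_hemi.setdefault(hemi, []).append(contact)
        for hemi, contacts in by_hemi.items():
            if sorted(contacts) != [1, 2, 3, 4]:
                raise MontageError(
                    f"hemisphere {hemi!r} has contacts {sorted(contacts)}; expected [1, 2, 3, 4]"
                )
        if not 1 <= len(by_hemi) <= 2:
            raise MontageError("recording must contain 1 or 2 hemispheres")
        n = self.data.shape[1]
        seen = set()
        for label, (start, end) in self.epochs.items():
            if label not in EPOCH_LABELS:
                raise ValidationError(f"unknown epoch label {label!r}")
            if label in seen:
                raise ValidationError(f"duplicate epoch label {label!r}")
            seen.add(label)
            if not (0 <= start < end <= n):
                raise ValidationError(
                    f"epoch {label}: window [{start}, {end}) outside [0, {n})"
                )

    @property
    def hemispheres(self) -> list[str]:
        out = []
        for hemi, _ in self.channels:
            if hemi not in out:
                out.append(hemi)
        return out

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_labels(self) -> list[str]:
        return [f"{HEMI_PREFIX[h]}{c}" for h, c in self.channels]

    def hemisphere_data(self, hemisphere: str) -> np.ndarray:
        idx = [i for i, (h, _) in enumerate(self.channels) if h == hemisphere]
        if not idx:
            raise MontageError(f"hemisphere {hemisphere!r} not present")
        return self.data[idx]

    def sorted_copy(self) -> "LfpRecording":
        """Channels reordered to the canonical L1-L4, R1-R4 order."""
        order = sorted(
            range(len(self.channels)),
            key=lambda i: (self.channels[i][0] != "left", self.channels[i][1]),
        )
        return LfpRecording(
            subject_id=self.subject_id,
            fs=self.fs,
            channels=[self.channels[i] for i in order],
            data=self.data[order],
            epochs=dict(self.epochs),
        )


class ClinicalTable:
    """Per-subject baseline and post-operative HDRS-17 scores.

    Wraps a DataFrame with columns ``subject_id``, ``hdrs_baseline``,
    ``hdrs_post`` (optional extras such as ``age`` are carried through) and
    enforces score range and subject uniqueness on construction.
    """

    REQUIRED = ["subject_id", "hdrs_baseline", "hdrs_post"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject_id: {dups}")
        for col in ("hdrs_baseline", "hdrs_post"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"non-numeric value in column {col}")
            if ((vals < 0) | (vals > HDRS_MAX)).any():
                raise ValidationError(f"column {col} has scores outside [0, {HDRS_MAX}]")
            df[col] = vals.astype(float)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClinicalTable) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# Internal float container
# ---------------------------------------------------------------------------


def _write_internal(rec: LfpRecording, stem: Path) -> None:
    data32 = np.ascontiguousarray(rec.data, dtype="<f4")
    stem.with_suffix(".f32").write_bytes(data32.tobytes())
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "channels": [[h, c] for h, c in rec.channels],
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "epochs": {k: [int(a), int(b)] for k, (a, b) in rec.epochs.items()},
        "dtype": "<f4",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _read_internal(path: Path) -> LfpRecording:
    meta = json.loads(path.read_text())
    raw = path.with_suffix(".f32").read_bytes()
    data = np.frombuffer(raw, dtype=meta.get("dtype", "<f4")).reshape(
        meta["n_channels"], meta["n_samples"]
    )
    return LfpRecording(
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
        channels=[(h, int(c)) for h, c in meta["channels"]],
        data=np.asarray(data, dtype=float),
        epochs={k: (int(a), int(b)) for k, (a, b) in meta["epochs"].items()},
    ).sorted_copy()


# ---------------------------------------------------------------------------
# EDF+ writer / reader
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767
_EDF_DIG_MIN = -32768


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # Trim numeric fields from the right; header fields must fit.
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _annotation_tals(rec: LfpRecording) -> list[bytes]:
    """Per-record annotation byte strings: timekeeping TAL + epoch TALs."""
    n_records = rec.n_samples // int(rec.fs)
    tals = []
    for r in range(n_records):
        chunk = f"+{r}\x14\x14\x00".encode("ascii")
        if r == 0:
            for label in EPOCH_LABELS:
                if label in rec.epochs:
                    start, end = rec.epochs[label]
                    onset = start / rec.fs
                    dur = (end - start) / rec.fs
                    chunk += f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("ascii")
        tals.append(chunk)
    return tals


def _write_edf(rec: LfpRecording, path: Path) -> None:
    rec = rec.sorted_copy()
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF export requires an integer sampling rate")
    fs_i = int(round(fs))
    if rec.n_samples % fs_i != 0:
        raise ValidationError(
            "EDF export requires a whole number of seconds of data; "
            "use the internal container for arbitrary lengths"
        )
    n_records = rec.n_samples // fs_i
    tals = _annotation_tals(rec)
    ann_bytes = max(max(len(t) for t in tals), 16)
    ann_samples = (ann_bytes + 1) // 2 + 4

    labels = rec.channel_labels()
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    n_sig = len(labels) + 1  # + annotation channel

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(f"subject {rec.subject_id}", 80)
    header += _edf_field("lfpstate synthetic LFP", 80)
    header += _edf_field("01.01.01", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_sig + 1), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_sig, 4)

    def sig_fields(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += sig_fields(labels + ["EDF Annotations"], 16)
    header += sig_fields([""] * n_sig, 80)
    header += sig_fields(["uV"] * len(labels) + [""], 8)
    header += sig_fields([f"{-pm:.6g}"[:8] for pm in phys_max] + ["-1"], 8)
    header += sig_fields([f"{pm:.6g}"[:8] for pm in phys_max] + ["1"], 8)
    header += sig_fields([_EDF_DIG_MIN] * n_sig, 8)
    header += sig_fields([_EDF_DIG_MAX] * n_sig, 8)
    header += sig_fields([""] * n_sig, 80)
    header += sig_fields([fs_i] * len(labels) + [ann_samples], 8)
    header += sig_fields([""] * n_sig, 32)
    assert len(header) == 256 * (n_sig + 1)

    # Physical -> digital with symmetric range: dig = x / phys_max * DIG_MAX.
    scale = _EDF_DIG_MAX / phys_max
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * fs_i, (r + 1) * fs_i)
            for ch in range(len(labels)):
                dig = np.clip(
                    np.round(rec.data[ch, sl] * scale[ch]), _EDF_DIG_MIN, _EDF_DIG_MAX
                ).astype("<i2")
                fh.write(dig.tobytes())
            fh.write(tals[r].ljust(2 * ann_samples, b"\x00"))


def _read_edf(path: Path, subject_id: str | None = None) -> LfpRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    channels = []
    keep = []
    for i, name in enumerate(raw.ch_names):
        name = name.strip()
        if name and name[0] in PREFIX_HEMI and name[1:].isdigit():
            channels.append((PREFIX_HEMI[name[0]], int(name[1:])))
            keep.append(i)
        else:
            raise MontageError(f"unrecognized channel label {name!r}")
    data = raw.get_data(picks=keep)
    # mne converts EDF physical dimension uV to volts; undo for native units.
    data = data * 1e6
    epochs = {}
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if desc in EPOCH_LABELS:
            start = int(round(onset * fs))
            epochs[desc] = (start, start + int(round(dur * fs)))
    missing = [lbl for lbl in EPOCH_LABELS if lbl not in epochs]
    if missing:
        raise ValidationError(f"EDF file lacks epoch annotations: {missing}")
    sid = subject_id or path.stem
    return LfpRecording(
        subject_id=sid, fs=fs, channels=channels, data=data, epochs=epochs
    ).sorted_copy()


def write_recording(rec: LfpRecording, path: str | Path) -> None:
    """Write a recording; ``.edf`` suffix selects EDF+, anything else internal."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        _write_internal(rec, path.with_suffix(""))


def read_recording(path: str | Path, subject_id: str | None = None) -> LfpRecording:
    """Read and validate a recording from EDF+ or the internal container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, subject_id=subject_id)
    if path.suffix == "":
        path = path.with_suffix(".json")
    return _read_internal(path)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, non-negativity and key uniqueness of a feature table."""
    if list(df.columns) != FEATURE_COLUMNS:
        raise ValidationError(
            f"feature table columns {list(df.columns)} != expected {FEATURE_COLUMNS}"
        )
    df = df.copy()
    for col in FEATURE_VALUE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric power in column {col}, row {int(np.flatnonzero(bad)[0])}"
            )
        if (vals.dropna() < 0).any():
            row = int(vals.index[vals < 0][0])
            raise ValidationError(f"negative power in column {col}, row {row}")
        df[col] = vals
    keys = df[["subject_id", "epoch", "segment_index"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate (subject, epoch, segment) key: {dup}")
    unknown = set(df["epoch"]) - set(EPOCH_LABELS)
    if unknown:
        raise ValidationError(f"unknown epoch labels: {sorted(unknown)}")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_feature_table(df)
    out = df.copy()
    for col in FEATURE_VALUE_COLUMNS:
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.17g}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"subject_id": str}
        )
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValidationError(f"failed to parse feature table {path}: {exc}") from exc
    return validate_feature_table(df)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return ClinicalTable(df)
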