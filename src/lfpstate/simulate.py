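"""Synthetic LFP cohorts with known ground truth.

Generates multi-contact subcallosal-cingulate-style local field potential
recordings (two hemispheres, four contacts each) plus a coupled clinical
outcome table, emulating an intraoperative deep-brain-stimulation study
design: three 60-s epochs (PRE, MID, POST), band-limited theta/alpha/beta
oscillations riding on 1/f background noise, a left-hemisphere beta power
decrease from PRE to POST, a right-hemisphere alpha increase, one subject
with a noise-corrupted hemisphere, and a depression-score change linearly
coupled to the left-beta change.

Every random draw is derived from one master seed through fixed
``numpy.random.SeedSequence`` substreams, so identical (spec, seed) pairs
give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sigio import EPOCH_LABELS, HDRS_MAX, ClinicalTable, LfpRecording

__all__ = [
    "BandSpec",
    "SubjectSpec",
    "CohortSpec",
    "GroundTruth",
    "DEFAULT_BANDS",
    "generate_lfp_epoch",
    "generate_clinical_scores",
    "generate_cohort",
    "reference_cohort_spec",
]

HEMISPHERES = ("left", "right")
N_CONTACTS = 4

#: Amplitude-modulation depth of each oscillation (dimensionless).
MODULATION_DEPTH = 0.3
#: Range of the slow random amplitude-modulation frequency (Hz).
MODULATION_BAND = (0.1, 1.0)
#: Broadband-noise multiplier applied to a flagged "bad" hemisphere, relative
#: to the per-contact white-noise scale. Healthy contacts carry oscillatory
#: and 1/f power well above the white-noise floor, so the factor is set high
#: enough that the corrupted contacts dwarf the cohort's contact-RMS
#: distribution, tripping any reasonable QC rule.
BAD_HEMISPHERE_NOISE_FACTOR = 40.0


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, optionally carrying an oscillation amplitude.

    The same type serves two roles: frequency-range definitions for spectral
    binning (amplitude irrelevant) and oscillation specifications for the
    simulator (amplitude in the same arbitrary microvolt-like units as the
    signal).
    """

    name: str
    low_hz: float
    high_hz: float
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: low_hz ({self.low_hz}) must be < high_hz ({self.high_hz})"
            )
        if self.amplitude < 0:
            raise ValueError(f"band {self.name!r}: amplitude must be >= 0")

    @property
    def center_hz(self) -> float:
        """Integer-rounded band centre, used as the oscillation carrier."""
        return float(round((self.low_hz + self.high_hz) / 2.0))


#: Canonical bands: theta 4-8 Hz, alpha 9-12 Hz, beta 13-30 Hz.
DEFAULT_BANDS = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 9.0, 12.0),
    BandSpec("beta", 13.0, 30.0),
)

BAND_RANGES = {b.name: (b.low_hz, b.high_hz) for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class SubjectSpec:
    """Generative description of one synthetic subject.

    ``amplitudes`` maps epoch label -> hemisphere -> band name -> oscillation
    amplitude. ``noise_scale`` is the RMS of the independent per-contact white
    noise; the 1/f background RMS defaults to the same value unless
    ``background_scale`` is given. ``bad_hemisphere`` marks a hemisphere whose
    contacts receive large broadband noise (emulating an unusable lead).
    """

    subject_id: str
    amplitudes: Mapping[str, Mapping[str, Mapping[str, float]]]
    one_over_f_exponent: float = 1.0
    noise_scale: float = 1.0
    background_scale: Optional[float] = None
    bad_hemisphere: Optional[str] = None
    hdrs_baseline: float = 22.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hdrs_baseline <= HDRS_MAX:
            raise ValueError(
                f"subject {self.subject_id!r}: hdrs_baseline must be in [0, {HDRS_MAX}]"
            )
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.bad_hemisphere is not None and self.bad_hemisphere not in HEMISPHERES:
            raise ValueError(f"bad_hemisphere must be one of {HEMISPHERES}")
        for epoch, per_hemi in self.amplitudes.items():
            if epoch not in EPOCH_LABELS:
                raise ValueError(f"unknown epoch label {epoch!r}")
            for hemi in per_hemi:
                if hemi not in HEMISPHERES:
                    raise ValueError(f"unknown hemisphere {hemi!r}")

    @property
    def effective_background_scale(self) -> float:
        return self.noise_scale if self.background_scale is None else self.background_scale


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: subjects plus shared acquisition settings."""

    subjects: tuple[SubjectSpec, ...]
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    fs: float = 2000.0
    epoch_seconds: float = 60.0
    pad_seconds: float = 2.0
    coupling_slope: float = 0.6
    outcome_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort spec")
        if len(self.subjects) < 2:
            raise ValueError("a cohort needs at least 2 subjects")


@dataclass
class GroundTruth:
    """Injected effect sizes stored alongside every generated cohort.

    ``beta_left_pct_change`` / ``alpha_right_pct_change`` are the percent
    changes in oscillatory *power* (amplitude squared) from PRE to POST implied
    by the subject specs — the quantities the downstream correlation analysis
    tries to recover.
    """

    amplitudes: dict[str, dict[str, dict[str, dict[str, float]]]]
    beta_left_pct_change: dict[str, float]
    alpha_right_pct_change: dict[str, float]
    coupling_slope: float
    outcome_noise_sd: float
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _substream(seed: int, *path: int) -> np.random.Generator:
    """Deterministic child generator at a fixed counter offset."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(path)))


def _one_over_f_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Synthesized by shaping a white complex spectrum, then rescaled to the
    requested RMS (so ``rms`` is the standard deviation of the output).
    """
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _hemisphere_oscillation(
    bands: Sequence[BandSpec],
    amplitudes: Mapping[str, float],
    t: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared oscillatory signal for one hemisphere in one epoch.

    Each band contributes a sinusoid at the band centre with uniformly random
    phase, slowly amplitude-modulated by a random 0.1-1 Hz sinusoid.
    """
    sig = np.zeros_like(t)
    for band in bands:
        amp = float(amplitudes.get(band.name, 0.0))
        if amp == 0.0:
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi)
        mod_freq = rng.uniform(*MODULATION_BAND)
        mod_phase = rng.uniform(0.0, 2.0 * np.pi)
        envelope = 1.0 + MODULATION_DEPTH * np.sin(2.0 * np.pi * mod_freq * t + mod_phase)
        sig += amp * envelope * np.sin(2.0 * np.pi * band.center_hz * t + phase)
    return sig


def generate_lfp_epoch(
    spec: SubjectSpec,
    epoch: str,
    duration: float,
    fs: float,
    seed: int,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
) -> np.ndarray:
    """Simulate one epoch of 8-contact LFP for one subject.

    Returns a ``(8, round(duration * fs))`` array ordered L1-L4, R1-R4. Each
    contact carries its hemisphere's shared oscillation plus independent 1/f
    background and white noise; a flagged bad hemisphere receives large
    broadband noise instead of usable signal on top.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    max_high = max(b.high_hz for b in bands)
    if fs <= 2.0 * max_high:
        raise ValueError(f"fs={fs} is below the Nyquist requirement for a {max_high} Hz band edge")
    if epoch not in EPOCH_LABELS:
        raise ValueError(f"unknown epoch label {epoch!r}")

    epoch_idx = EPOCH_LABELS.index(epoch)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    per_epoch = spec.amplitudes.get(epoch, {})

    out = np.empty((2 * N_CONTACTS, n))
    for h, hemi in enumerate(HEMISPHERES):
        osc_rng = _substream(seed, epoch_idx, h, 0)
        shared = _hemisphere_oscillation(bands, per_epoch.get(hemi, {}), t, osc_rng)
        for c in range(N_CONTACTS):
            contact_rng = _substream(seed, epoch_idx, h, 1 + c)
            x = shared + _one_over_f_noise(
                n, fs, spec.one_over_f_exponent, spec.effective_background_scale, contact_rng
            )
            if spec.noise_scale > 0:
                x = x + contact_rng.normal(0.0, spec.noise_scale, size=n)
            if spec.bad_hemisphere == hemi:
                bad_sd = BAD_HEMISPHERE_NOISE_FACTOR * max(spec.noise_scale, 1e-12)
                x = x + contact_rng.normal(0.0, bad_sd, size=n)
            out[h * N_CONTACTS + c] = x
    return out


def generate_clinical_scores(
    truth: GroundTruth,
    beta_pct_change: Mapping[str, float],
    baselines: Mapping[str, float],
    seed: int,
) -> ClinicalTable:
    """Post-operative depression scores coupled to the left-beta power change.

    ``hdrs_post = baseline * (1 + slope * beta_pct_change / 100) + N(0, sd)``,
    clamped to the valid HDRS-17 range [0, 52].
    """
    rng = _substream(seed, 9000)
    rows = []
    for i, (subject_id, baseline) in enumerate(baselines.items()):
        if subject_id not in beta_pct_change:
            raise KeyError(f"missing left-beta percent change for subject {subject_id!r}")
        noise = rng.normal(0.0, truth.outcome_noise_sd) if truth.outcome_noise_sd > 0 else 0.0
        post = baseline * (1.0 + truth.coupling_slope * beta_pct_change[subject_id] / 100.0) + noise
        rows.append(
            {
                "subject_id": subject_id,
                "hdrs_baseline": float(baseline),
                "hdrs_post": float(np.clip(post, 0.0, HDRS_MAX)),
            }
        )
    return ClinicalTable(pd.DataFrame(rows))


def _power_pct_change(amp_pre: float, amp_post: float) -> float:
    """Percent change in oscillatory power implied by an amplitude change."""
    if amp_pre == 0:
        return 0.0
    return 100.0 * (amp_post**2 - amp_pre**2) / amp_pre**2


def generate_cohort(
    cohort: CohortSpec, seed: int
) -> tuple[list[LfpRecording], ClinicalTable, GroundTruth]:
    """Generate one full synthetic cohort: recordings, outcomes, ground truth.

    Each recording is a continuous signal with PRE/MID/POST epoch annotations
    separated (and flanked) by ``pad_seconds`` of signal-free padding so that
    filter-transient trimming never eats into the epochs.
    """
    fs = cohort.fs
    n_epoch = int(round(cohort.epoch_seconds * fs))
    n_pad = int(round(cohort.pad_seconds * fs))
    n_total = n_pad + len(EPOCH_LABELS) * (n_epoch + n_pad)

    truth = GroundTruth(
        amplitudes={
            s.subject_id: {
                e: {h: dict(s.amplitudes.get(e, {}).get(h, {})) for h in HEMISPHERES}
                for e in EPOCH_LABELS
            }
            for s in cohort.subjects
        },
        beta_left_pct_change={},
        alpha_right_pct_change={},
        coupling_slope=cohort.coupling_slope,
        outcome_noise_sd=cohort.outcome_noise_sd,
        seed=int(seed),
    )

    recordings = []
    for si, sub in enumerate(cohort.subjects):
        sub_seed = int(np.random.SeedSequence(entropy=int(seed), spawn_key=(si,)).entropy) % (
            2**31 - 1
        )
        data = np.zeros((2 * N_CONTACTS, n_total))
        epochs = {}
        cursor = n_pad
        for epoch in EPOCH_LABELS:
            block = generate_lfp_epoch(
                sub, epoch, cohort.epoch_seconds, fs, sub_seed, bands=cohort.bands
            )
            data[:, cursor : cursor + n_epoch] = block
            epochs[epoch] = (cursor, cursor + n_epoch)
            cursor += n_epoch + n_pad
        channels = [(h, c + 1) for h in HEMISPHERES for c in range(N_CONTACTS)]
        recordings.append(
            LfpRecording(
                subject_id=sub.subject_id, fs=fs, channels=channels, data=data, epochs=epochs
            )
        )

        def _amp(epoch: str, hemi: str, band: str) -> float:
            return float(sub.amplitudes.get(epoch, {}).get(hemi, {}).get(band, 0.0))

        truth.beta_left_pct_change[sub.subject_id] = _power_pct_change(
            _amp("PRE", "left", "beta"), _amp("POST", "left", "beta")
        )
        truth.alpha_right_pct_change[sub.subject_id] = _power_pct_change(
            _amp("PRE", "right", "alpha"), _amp("POST", "right", "alpha")
        )

    baselines = {s.subject_id: s.hdrs_baseline for s in cohort.subjects}
    clinical = generate_clinical_scores(truth, truth.beta_left_pct_change, baselines, seed)
    return recordings, clinical, truth


# ---------------------------------------------------------------------------
# Reference preset
# ---------------------------------------------------------------------------

#: Per-subject baseline HDRS-17 scores of the eight-patient intraoperative
#: DBS cohort this package models (4-week pre-surgical averages).
REFERENCE_HDRS_BASELINES = (23.5, 20.5, 23.25, 23.5, 20.5, 23.25, 22.75, 24.75)


def reference_cohort_spec(
    n_subjects: int = 8,
    fs: float = 2000.0,
    epoch_seconds: float = 60.0,
    post_beta_scale: Optional[Sequence[float]] = None,
    post_alpha_scale: float = 1.5,
    noise_scale: float = 1.0,
    bad_hemisphere_subject: Optional[int] = 7,
    coupling_slope: float = 0.6,
    outcome_noise_sd: float = 1.0,
) -> CohortSpec:
    """The default "scc-8" study-regime preset.

    Eight subjects, bilateral 4-contact montage, three epochs. PRE and MID
    share identical band amplitudes (no injected mid-procedure effect); POST
    halves the left-hemisphere beta amplitude on average (per-subject scale
    ramp 0.35-0.65, giving a spread of power drops for the outcome
    correlation) and raises right-hemisphere alpha by ``post_alpha_scale``.
    Subject ``bad_hemisphere_subject`` (0-based; default the last) carries a
    noise-corrupted right hemisphere. Baseline HDRS values follow the
    reference clinical cohort, cycled if ``n_subjects`` exceeds eight.

    Subject-to-subject amplitude heterogeneity is a deterministic ramp, not a
    random draw, so the spec itself pins the ground truth; the seed passed to
    :func:`generate_cohort` only drives noise realizations.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if post_beta_scale is None:
        post_beta_scale = np.linspace(0.35, 0.65, n_subjects)
    elif len(post_beta_scale) != n_subjects:
        raise ValueError("post_beta_scale must have one entry per subject")

    base = {"theta": 2.0, "alpha": 2.0, "beta": 2.0}
    # Deterministic per-subject overall amplitude ramp (+/-20%).
    overall = np.linspace(0.8, 1.2, n_subjects)

    subjects = []
    for i in range(n_subjects):
        pre = {
            hemi: {name: amp * overall[i] for name, amp in base.items()} for hemi in HEMISPHERES
        }
        post = {hemi: dict(pre[hemi]) for hemi in HEMISPHERES}
        post["left"]["beta"] = pre["left"]["beta"] * float(post_beta_scale[i])
        post["right"]["alpha"] = pre["right"]["alpha"] * post_alpha_scale
        subjects.append(
            SubjectSpec(
                subject_id=f"S{i + 1:02d}",
                amplitudes={"PRE": pre, "MID": {h: dict(pre[h]) for h in HEMISPHERES}, "POST": post},
                noise_scale=noise_scale,
                bad_hemisphere="right" if i == bad_hemisphere_subject else None,
                hdrs_baseline=REFERENCE_HDRS_BASELINES[i % len(REFERENCE_HDRS_BASELINES)],
            )
        )
    return CohortSpec(
        subjects=tuple(subjects),
        fs=fs,
        epoch_seconds=epoch_seconds,
        coupling_slope=coupling_slope,
        outcome_noise_sd=outcome_noise_sd,
    )
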