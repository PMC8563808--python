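"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import warnings

import pytest

from lfpstate import preprocess, spectral
from lfpstate.simulate import CohortSpec, generate_cohort, reference_cohort_spec


def cohort_to_features(recordings, qc: bool = True):
    """Preprocess a cohort and build its feature table (QC on by default)."""
    drops = preprocess.qc_screen_hemispheres(recordings) if qc else {}
    segmented = []
    for rec in recordings:
        signals, _ = preprocess.preprocess_recording(
            rec, drop_hemispheres=drops.get(rec.subject_id)
        )
        for sig in signals:
            for epoch in sig.epochs:
                segmented.append(preprocess.segment_epoch(sig, epoch))
    return spectral.build_feature_table(segmented)


def build_cohort(spec: CohortSpec, seed: int, qc: bool = True):
    """Generate a cohort and return recordings, features, clinical, truth."""
    recordings, clinical, truth = generate_cohort(spec, seed)
    features = cohort_to_features(recordings, qc=qc)
    return {
        "recordings": recordings,
        "features": features,
        "clinical": clinical,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def preset_seed1():
    """The default 8-subject study-regime preset at seed 1, fully processed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_cohort(reference_cohort_spec(), seed=1)
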