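"""Shared fixtures: small synthetic cohorts exercising the full pipeline."""

import warnings

import numpy as np
import pytest

import wormid as w


@pytest.fixture(scope="session")
def truth_small():
    """Compact ground-truth map (80 cells) used across test modules."""
    return w.make_ground_truth(n_cells=80, seed=3)


@pytest.fixture(scope="session")
def dye_landmarks(truth_small):
    rng = np.random.default_rng(0)
    dye = set(rng.choice(truth_small.names, 14, replace=False))
    return dye, {n: truth_small.base_positions[n] for n in dye}


@pytest.fixture(scope="session")
def noisefree_pipeline(truth_small, dye_landmarks):
    """Noise-free cohort (rigid placement only) corrected and atlased.

    All biological variation sources are off: zero jitter, full detection,
    no bend.  Random rigid placement remains, so posture correction is
    still exercised end to end.  The ground-truth table acts as the
    reference atlas for the fill-in of names no promoter covers.
    """
    dye, lm = dye_landmarks
    model = w.VariationModel(
        iid_sd=np.zeros(3), detection_rate=1.0, bend_coeff_range=0.0
    )
    promoters = w.default_promoters(
        truth_small, n_promoters=4, expressed_fraction=0.6, positive_ratio=1.0, seed=5
    )
    cohort = w.make_cohort(truth_small, model, n_animals=8, seed=9, promoters=promoters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = [w.correct_posture(s, landmarks=lm)[0] for s in cohort.raw]
    reference = w.ReferenceAtlas(entries=truth_small.base_positions, source="truth")
    atlases = w.generate_atlases(
        corrected, n_atlases=6, seed=11, min_first_annotated=40, reference=reference
    )
    return cohort, corrected, atlases


@pytest.fixture(scope="session")
def noisy_pipeline(truth_small, dye_landmarks):
    """Noisy cohort: iid jitter comparable to the nearest-neighbour spacing."""
    from scipy.spatial.distance import pdist, squareform

    dye, lm = dye_landmarks
    D = squareform(pdist(truth_small.positions()))
    np.fill_diagonal(D, np.inf)
    spacing = float(np.median(D.min(axis=1)))
    model = w.VariationModel(iid_sd=np.full(3, spacing), detection_rate=0.97)
    promoters = w.default_promoters(
        truth_small, n_promoters=5, expressed_fraction=0.5, positive_ratio=0.9, seed=5
    )
    cohort = w.make_cohort(truth_small, model, n_animals=24, seed=9, promoters=promoters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = [w.correct_posture(s, landmarks=lm)[0] for s in cohort.raw]
    reference = w.ReferenceAtlas(entries=truth_small.base_positions, source="truth")
    atlases = w.generate_atlases(
        corrected, n_atlases=40, seed=11, min_first_annotated=40, reference=reference
    )
    return cohort, corrected, atlases
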