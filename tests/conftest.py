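"""Shared fixtures: tiny hand-built volumes and two synthetic cohorts.

The zero-variability cohort (10 identical subjects, noiseless) probes
exact recovery; the clustered cohort (60 subjects, 4 mm centre
displacement, two latent prototypes) is the regime where atlas
encoding and selection earn their keep.  Both are session-scoped: the
expensive encoder training is shared across test modules.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import froimal as fm

LABELS = {1, 2}


@pytest.fixture(scope="session")
def zero_var():
    spec = fm.PopulationSpec(
        n_subjects=10,
        translation_sd_mm=0.0,
        scale_sd=0.0,
        shape_jitter_sd=0.0,
        z_peak_sd=0.0,
        background_noise_sd=0.0,
        seed=11,
    )
    db, truths = fm.generate_population(spec)
    return SimpleNamespace(spec=spec, db=db, truths=truths, labels=LABELS)


@pytest.fixture(scope="session")
def clustered():
    spec = fm.PopulationSpec(
        n_subjects=60,
        translation_sd_mm=4.0,
        scale_sd=0.1,
        shape_jitter_sd=0.1,
        n_prototypes=2,
        z_peak_sd=0.5,
        seed=7,
    )
    with np.errstate(all="ignore"):
        db, truths = fm.generate_population(spec)
    mask = fm.build_collective_mask(db, LABELS)
    cfg = fm.ExperimentConfig(n_selected_atlases=0)
    encoders = fm.train_all_encoders(db, mask, LABELS, cfg)
    return SimpleNamespace(
        spec=spec, db=db, truths=truths, mask=mask, cfg=cfg,
        encoders=encoders, labels=LABELS,
    )
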