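import dataclasses

import pytest

from uit.pipeline import run_pipeline
from uit.synthdata import StudyDesign, make_study, predict_pipeline_outputs

#: seeds for the multi-seed parameter-recovery checks
RECOVERY_SEEDS = (101, 102, 103, 104, 105)


def _run(design: StudyDesign):
    study = make_study(design)
    lexicon = study.build_lexicon()
    result = run_pipeline(study.corpus, lexicon, design.selection_config)
    expected = predict_pipeline_outputs(study, design.selection_config)
    return study, result, expected


@pytest.fixture(scope="session")
def study_run():
    """One synthetic study at the default design, run end to end."""
    return _run(StudyDesign(seed=11))


@pytest.fixture(scope="session")
def noise_free_run():
    design = dataclasses.replace(
        StudyDesign(seed=12), duplicate_sentence_rate=0.0, misspelling_rate=0.0
    )
    return _run(design)


@pytest.fixture(scope="session")
def recovery_runs():
    """Five seeded noisy studies (2% misspellings) for recall checks."""
    return [_run(StudyDesign(seed=s)) for s in RECOVERY_SEEDS]
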