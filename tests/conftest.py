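"""Shared fixtures: synthetic studies at several scales.

The small study keeps unit tests fast; the error-free study isolates
QC/search logic from sequencing noise; the default study (59 samples x 5000
reads, the study design) backs the end-to-end recovery checks and is
generated once per session.
"""

import pytest

from otupipe.pipeline import pipeline_config_for_study, simulate_and_run
from otupipe.search import ReferenceIndex
from otupipe.simulate import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(n_per_group=(4, 3, 3), reads_per_sample=600, seed=11,
                       biomarker_n_per_group=(3, 3, 3))


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def ref_index(small_study):
    return ReferenceIndex(small_study.db)


@pytest.fixture(scope="session")
def small_run(small_config):
    """Full pipeline over the small study at rarefaction depth 300."""
    pcfg = pipeline_config_for_study(small_config, depth=300)
    return simulate_and_run(small_config, pcfg)


@pytest.fixture(scope="session")
def clean_study():
    """Error-free, chimera-free, high-quality study: ground truth is exact."""
    cfg = StudyConfig(n_per_group=(2, 2, 2), reads_per_sample=200, seed=3,
                      error_rate=0.0, homopolymer_indel_rate=0.0,
                      chimera_rate=0.0, low_quality_fraction=0.0,
                      biomarker_n_per_group=(2, 2, 2))
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_run():
    """The full-size default study run end to end (59 x 5000 reads)."""
    import time

    t0 = time.perf_counter()
    study, result, report = simulate_and_run(StudyConfig(seed=1))
    report["elapsed_seconds"] = time.perf_counter() - t0
    return study, result, report
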