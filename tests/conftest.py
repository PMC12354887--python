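"""Shared fixtures.

The two expensive fixtures (a trained copy-task transformer and a full
desk-preset pipeline run) are session-scoped and shared between unit and
acceptance tests.
"""

import numpy as np
import pytest

from cohortvec import code2vec, seq_model
from cohortvec.pipeline import PipelineConfig, run_all
from cohortvec.synthetic_ehr import (
    SimConfig,
    generate_cohort,
    generate_copy_cohort,
    generate_phecode_map,
)

PIPELINE_SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_patients=200, seed=7)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """(events, demographics, survival, truth) of the standard test cohort."""
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def phecode_map(sim_config):
    return generate_phecode_map(sim_config)


@pytest.fixture(scope="session")
def copy_task():
    """Deterministic-rule cohort and a transformer trained on it.

    Every patient repeats a fixed 5-code set each year, so next-year
    prediction is exactly solvable and the trained model doubles as a
    learnability oracle.
    """
    events = generate_copy_cohort(n_patients=200, n_years=6, vocab_size=30,
                                  codes_per_patient=5, seed=0)
    vocab = code2vec.filter_vocabulary(events, 5)
    corpus = seq_model.build_year_sentences(events, vocab, max_len=32)
    pairs = seq_model.make_nextyear_pairs(corpus)
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(pairs))
    held_out = [pairs[i] for i in idx[:150]]
    train = [pairs[i] for i in idx[150:]]
    model, history = seq_model.train_transformer(
        train, None, seq_model.desk_transformer_config(seed=0), vocab=vocab)
    return {"events": events, "vocab": vocab, "corpus": corpus,
            "train": train, "held_out": held_out, "model": model,
            "history": history}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full desk-preset pipeline run on the 3-subtype synthetic cohort."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=str(out), seed=PIPELINE_SEED,
                            preset="desk", n_patients=500)
    manifest = run_all(config)
    return {"dir": out, "manifest": manifest, "config": config}
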