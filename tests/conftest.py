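"""Shared fixtures: one small synthetic two-species dataset per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lecif.model import Hyperparameters, TrainingConfig, train_ensemble
from lecif.synthetic import SyntheticConfig, simulate_dataset
from lecif.workflow import prepare_paired_data

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth(tmp_path_factory):
    """A small planted-concordance fixture (rho = 0.9)."""
    cfg = SyntheticConfig(n_records=300, rho=0.9, seed=5)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def paired(synth):
    """The full data pipeline run on the session fixture."""
    return prepare_paired_data(
        synth.axt,
        synth.chrom_sizes_b,
        synth.manifest_a,
        synth.manifest_b,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_ensemble(paired):
    """A tiny trained ensemble (K=2) for scoring-path tests."""
    tr = paired.datasets["train"]
    va = paired.datasets["validation"]
    cfg = TrainingConfig(
        ensemble_size=2,
        n_pos=min(1500, tr.n_pos),
        n_neg=min(1500, tr.n_neg),
        seed=3,
        max_epochs=20,
    )
    scheme = paired.scheme
    return train_ensemble(
        tr,
        va,
        Hyperparameters(),
        cfg,
        train_chroms=(
            scheme.roles["train"][0] | scheme.roles["validation"][0],
            scheme.roles["train"][1] | scheme.roles["validation"][1],
        ),
        a_schema=paired.a_schema,
        b_schema=paired.b_schema,
    )
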