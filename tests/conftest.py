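"""Shared fixtures: small seeded synthetic corpora and fitted artifacts.

Expensive artifacts (fitted tokenizer) are session-scoped so the suite pays
for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from structok.synthetic import SyntheticConfig, generate_dataset
from structok.tokenizer import StructureTokenizer


@pytest.fixture(scope="session")
def small_dataset():
    """20 mixed-task proteins with labels (deterministic)."""
    cfg = SyntheticConfig(n_proteins=20, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_proteins(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def fitted_tokenizer(small_proteins):
    """Tokenizer with a 16-word codebook fit on the small corpus."""
    tok = StructureTokenizer(n_tokens=16, pretrain_epochs=1, seed=3)
    tok.fit(small_proteins)
    return tok


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
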