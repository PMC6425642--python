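"""Shared fixtures: synthetic study bundles and derived pipeline stages.

Everything is generated programmatically and seeded; the heavier fixtures
are session-scoped so the label/feature/classification chain is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from phageminer import features, ground_truth, simdata


@pytest.fixture(scope="session")
def easy_bundle():
    """The 'easy' preset study: 10 subjects x 6 timepoints, seed 42."""
    return simdata.generate_study(simdata.preset("easy", rng_seed=42))


@pytest.fixture(scope="session")
def easy_labels(easy_bundle):
    return ground_truth.label_contigs(
        easy_bundle.alignments,
        easy_bundle.contig_lengths,
        [c.id for c in easy_bundle.contigs],
    )


@pytest.fixture(scope="session")
def easy_features(easy_bundle):
    return features.build_feature_table(
        easy_bundle.contigs,
        easy_bundle.gene_calls,
        easy_bundle.hits,
        easy_bundle.mappings,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
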