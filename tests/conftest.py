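"""Shared fixtures: deterministic model corpora built from the generator."""

from __future__ import annotations

import itertools

import pytest

from rxnscript import GeneratorConfig, generate_model

FEATURE_FLAGS = ("events", "rules", "constraints", "fbc", "distrib",
                 "layout", "annotations", "named_stoich", "substance_only")


def make_corpus(n: int, base_seed: int = 0) -> list[str]:
    """n deterministic model texts spanning the feature-flag lattice."""
    subsets = ([()] + [(f,) for f in FEATURE_FLAGS]
               + list(itertools.combinations(FEATURE_FLAGS, 2))
               + [FEATURE_FLAGS])
    sizes = [(3, 2), (5, 4), (6, 5), (2, 1)]
    corpus = []
    for i in range(n):
        combo = subsets[i % len(subsets)]
        n_sp, n_rxn = sizes[(i // len(subsets)) % len(sizes)]
        cfg = GeneratorConfig(seed=base_seed + i, n_species=n_sp,
                              n_reactions=n_rxn,
                              **{f: True for f in combo})
        corpus.append(generate_model(cfg))
    return corpus


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    return make_corpus(60)
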