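"""Shared fixtures.

The two end-to-end pipeline fixtures are session-scoped because they
take a couple of minutes each; every test that inspects the trained
model, the clustering or the held-out evaluation reuses the same run.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

from phagehost.pipeline import RunConfig, run_pipeline
from phagehost.synthetic import SyntheticSpec, generate_corpus

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@dataclasses.dataclass
class EndToEnd:
    spec: SyntheticSpec
    genomes: list
    labels: object
    truth: dict
    result: object


def _run(spec: SyntheticSpec) -> EndToEnd:
    genomes, labels, truth = generate_corpus(spec)
    cfg = RunConfig(seed=spec.seed, top_n_genera=spec.n_genera)
    result = run_pipeline(genomes, labels, cfg)
    return EndToEnd(spec=spec, genomes=genomes, labels=labels, truth=truth, result=result)


@pytest.fixture(scope="session")
def default_run() -> EndToEnd:
    """Full pipeline on the default synthetic corpus (mutation 0.02, seed 42)."""
    return _run(SyntheticSpec())


@pytest.fixture(scope="session")
def clean_run() -> EndToEnd:
    """Full pipeline on the mutation-free corpus (exact family recovery)."""
    return _run(SyntheticSpec(mutation_rate=0.0))


@pytest.fixture(scope="session")
def small_corpus():
    """A small, fast corpus for tests that only need a plausible input."""
    spec = SyntheticSpec(n_genera=2, phages_per_genus=6, markers_per_genus=2,
                         background_pool_size=6, background_genes_per_phage=2,
                         mutation_rate=0.0, seed=11)
    return generate_corpus(spec)
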