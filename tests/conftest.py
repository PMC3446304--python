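"""Shared fixtures: small synthetic datasets and one full default run."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from decaymap.io import read_tsv
from decaymap.pipeline import PipelineConfig, run_pipeline
from decaymap.simulate import (
    SimConfig,
    assign_decay_params,
    make_genome,
    simulate_coverage,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_operons=20, seed=3)


@pytest.fixture(scope="session")
def small_genome(small_config):
    genes, sequences, spans = make_genome(small_config)
    return genes, sequences, spans


@pytest.fixture(scope="session")
def small_params(small_config, small_genome):
    genes, _, _ = small_genome
    return assign_decay_params(genes, small_config)


@pytest.fixture()
def noise_free_config() -> SimConfig:
    """Deterministic coverage: no Poisson draw, depth factors applied as-is."""
    return SimConfig(n_operons=20, seed=3, noise="none", depth_mode="explicit",
                     n_replicates=1)


def exact_config(**overrides) -> SimConfig:
    base = SimConfig(n_operons=20, seed=3, noise="none", depth_mode="explicit",
                     n_replicates=1)
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic genome (default conditions).

    ~1,000 genes, Poisson noise, qPCR-anchored normalization; returns the
    output directory, manifest, and joined truth/estimate tables.
    """
    out = tmp_path_factory.mktemp("default_run")
    sim = SimConfig(seed=7)
    config = PipelineConfig(outdir=str(out), sim=sim, seed=7,
                            use_kmer_fusing=False)
    manifest = run_pipeline(config)
    truth = read_tsv(out / "sim" / "truth.tsv").set_index("gene_id")
    halflives = read_tsv(out / "halflives.tsv").set_index("gene_id")
    directions = read_tsv(out / "direction_calls.tsv").set_index("gene_id")
    return {
        "outdir": out,
        "sim": sim,
        "manifest": manifest,
        "truth": truth,
        "halflives": halflives,
        "directions": directions,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
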