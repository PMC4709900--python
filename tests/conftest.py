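"""Shared fixtures: a small simulated GBS experiment run end to end once."""

from __future__ import annotations

import pytest

from gbsnp import pipeline
from gbsnp.evaluation import evaluate_against_truth
from gbsnp.synthetic_data import SimulationConfig, simulate


SMALL_CONFIG = SimulationConfig(
    n_fragments=40, n_genotypes=6, n_snps=20, mean_depth=30, seed=7
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return simulate(SMALL_CONFIG, outdir=outdir)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    workdir = tmp_path_factory.mktemp("work")
    result = pipeline.run_all(
        small_sim.r1_path, small_sim.r2_path, small_sim.barcode_path, workdir
    )
    return small_sim, result


@pytest.fixture(scope="session")
def small_eval(small_run):
    sim, result = small_run
    return sim, result, evaluate_against_truth(result, sim)
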