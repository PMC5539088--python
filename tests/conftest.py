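"""Shared fixtures: one full synthetic scenario and its screen run.

The scenario is generated once per session at the study-condition
defaults (445 samples, 127 epigenomes with 27 blood/immune flagged,
planted TE classes for every funnel stage) and shared by the pipeline
and end-to-end tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from tescreen import pipeline, synthetic_data

SCENARIO_SEED = 1234


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario")
    paths, truth = synthetic_data.generate_scenario(out, seed=SCENARIO_SEED)
    return paths, truth


@pytest.fixture(scope="session")
def scenario_config(scenario, tmp_path_factory):
    paths, _ = scenario
    out = tmp_path_factory.mktemp("screen_out")
    return pipeline.RunConfig(
        te_vcf=str(paths["te_vcf"]),
        snp_vcf=str(paths["snp_vcf"]),
        cohort_tsv=str(paths["cohort"]),
        gwas_tsv=str(paths["gwas"]),
        manifest_tsv=str(paths["manifest"]),
        enhancer_dir=str(paths["enhancer_dir"]),
        expression_tsv=str(paths["expression"]),
        gene_models_bed=str(paths["gene_models"]),
        allow_list_tsv=str(paths["allow_list"]),
        out_dir=str(out),
        group="both",
    )


@pytest.fixture(scope="session")
def screen_results(scenario_config):
    return pipeline.run(scenario_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
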