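"""Shared fixtures: a small two-genome scenario and the worked toy bundle.

Everything is generated programmatically at test time; nothing is downloaded
and no binary fixtures exist.
"""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from uest.config import FilterConfig
from uest.pipeline import GenomeInputs, RunInputs
from uest.synthetic_data import (
    DEFAULT_CLASSES,
    ScenarioConfig,
    generate_scenario,
    generate_worked_toy,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

EXCLUDE = ("chr6_*hap*",)


def small_config(seed: int = 11, **overrides) -> ScenarioConfig:
    """A fast scenario: 1 chromosome, 6 genes, 60 gene plants + 6 IGR."""
    base = dict(
        seed=seed,
        n_chromosomes=1,
        chrom_length_nt=400_000,
        genes_per_chrom=6,
        n_decoy_spliced=20,
        n_decoy_mismatch=10,
        n_decoy_numt=5,
        n_decoy_haplotype=3,
        uarna_count=4,
        b_only_genes_per_chrom=3,
        n_conserved=20,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def genome_inputs(paths: dict, full: bool = True) -> GenomeInputs:
    kwargs = dict(
        psl=paths["psl"],
        genepred=paths["genepred"],
        numts=paths["numts"],
        exclude_chroms=EXCLUDE,
    )
    if full:
        kwargs.update(
            cage=paths["cage"],
            cells_dir=paths["cells_dir"],
            chromatin=paths["chromatin"],
            rnaseq=tuple(sorted(Path(paths["rnaseq_dir"]).glob("*.bedgraph"))),
            conservation=paths["conservation"],
            chrom_sizes=paths["chrom_sizes"],
        )
    return GenomeInputs(**kwargs)


def run_inputs(scenario) -> RunInputs:
    inputs = RunInputs(genome_a=genome_inputs(scenario.paths["genome_a"]))
    if "genome_b" in scenario.paths:
        inputs.genome_b = genome_inputs(scenario.paths["genome_b"], full=False)
        inputs.chains_ab = scenario.paths["chains_ab"]
        inputs.chains_ba = scenario.paths["chains_ba"]
    return inputs


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    return generate_scenario(small_config(), tmp_path_factory.mktemp("small"))


@pytest.fixture(scope="session")
def toy_scenario(tmp_path_factory):
    return generate_worked_toy(tmp_path_factory.mktemp("toy"))


@pytest.fixture()
def config() -> FilterConfig:
    return FilterConfig()
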