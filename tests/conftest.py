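"""Shared fixtures: one seeded desk-scale synthetic study per session."""

import pytest

from pbscan.pipeline import PipelineConfig, run_pipeline
from pbscan.scan import ComparisonSpec
from pbscan.simulate import default_fixture

FIXTURE_SEED = 1

# the desk-scale scan yields ~1,190 windows per comparison; retaining 2%
# keeps >= 20 windows, the desk-scale analogue of the genome-wide 0.1%
RECOVERY_FRACTION = 0.02


def standard_comparisons() -> dict[str, list[ComparisonSpec]]:
    """Three comparisons per focal population, mirroring the study design:
    focal x close with each distant reference, plus focal x alternative
    close with the first reference."""
    return {
        "FOC": [
            ComparisonSpec("FOC", "CLO", "WAF"),
            ComparisonSpec("FOC", "CLO", "EUR"),
            ComparisonSpec("FOC", "CL2", "WAF"),
        ],
        "CLO": [
            ComparisonSpec("CLO", "FOC", "WAF"),
            ComparisonSpec("CLO", "FOC", "EUR"),
            ComparisonSpec("CLO", "CL2", "WAF"),
        ],
    }


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Default synthetic study: 3 chromosomes x 2,000 SNPs, 5 populations,
    10 loci planted at +0.5 in FOC."""
    return default_fixture(tmp_path_factory.mktemp("study"), seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def study_config(study, tmp_path_factory):
    return PipelineConfig(
        vcf=str(study.vcf),
        popmap=str(study.popmap),
        gene_models=str(study.bed),
        gmt=str(study.gmt),
        trait_votes=str(study.votes_tsv),
        comparisons=standard_comparisons(),
        out_dir=str(tmp_path_factory.mktemp("pipeline_out")),
        top_fraction=RECOVERY_FRACTION,
        pairs=[("FOC", "CLO")],
        seed=FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def study_result(study_config):
    return run_pipeline(study_config)


def planted_recovery(study, result, focal: str = "FOC") -> int:
    """Number of planted loci inside any retained window of the focal scans."""
    recovered = 0
    for rec in study.truth.planted.itertuples():
        inside = any(
            (
                (s.retained["chrom"] == rec.chrom)
                & (s.retained["start_pos"] <= rec.pos)
                & (s.retained["end_pos"] >= rec.pos)
            ).any()
            for s in result.focal_results[focal].scans.values()
        )
        recovered += inside
    return recovered
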