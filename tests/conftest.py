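import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_scenario():
    """A down-scaled synthetic study: 6 samples, 3 short regions."""
    from synthcn.simulate import SyntheticScenario

    return SyntheticScenario(
        seed=11,
        n_samples=6,
        lineage_sizes={"broad-leaf": 2, "narrow-leaf": 2, "hemp": 2, "unassigned": 0},
        n_regions=3,
        region_length=300,
        n_tips=6,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario, tmp_path_factory):
    """The small scenario written out in the pipeline's input dialects."""
    from synthcn.simulate import write_study_files

    outdir = tmp_path_factory.mktemp("study")
    write_study_files(small_scenario, outdir)
    return outdir


@pytest.fixture
def study_config(small_study, tmp_path):
    from synthcn.pipeline import RunConfig

    return RunConfig(
        output_dir=str(tmp_path / "run"),
        depth_dir=str(small_study / "depth"),
        bed=str(small_study / "regions.bed"),
        sample_sheet=str(small_study / "samples.tsv"),
        tree=str(small_study / "cultivars.nwk"),
        chemotype=str(small_study / "chemotypes.tsv"),
        fasta=str(small_study / "family.fasta"),
        counts=str(small_study / "counts.tsv"),
        library_sizes=str(small_study / "library_sizes.tsv"),
    )
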