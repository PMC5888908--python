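import pytest

from virosift.pipeline import PipelineConfig, run_pipeline
from virosift.synthetic import default_scenario, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study, generated once per session."""
    return generate_dataset(default_scenario())


@pytest.fixture(scope="session")
def dataset_paths(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic_data")
    return default_dataset.write(outdir)


@pytest.fixture(scope="session")
def pipeline_report(default_dataset, dataset_paths, tmp_path_factory):
    """Full pipeline run on the default synthetic study."""
    out = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        out_dir=str(out),
        contigs=str(dataset_paths["contigs"]),
        hits=str(dataset_paths["hits"]),
        counts=str(dataset_paths["counts"]),
        samples=str(dataset_paths["samples"]),
        coi=str(dataset_paths["coi"]),
        detection=str(dataset_paths["detection"]),
        genome_classes=str(dataset_paths["genome_classes"]),
        co_sequenced=(("Japan2016", "UK2016"),),
    )
    return run_pipeline(config)
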