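import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tillermir.pipeline import PipelineConfig, run_pipeline
from tillermir.synthetic import generate_full_dataset

DATASET_SEED = 1


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One full synthetic dataset (default study conditions), written to disk."""
    outdir = tmp_path_factory.mktemp("dataset")
    return generate_full_dataset(seed=DATASET_SEED, outdir=outdir), outdir


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """The full pipeline executed on the session dataset."""
    ds, indir = dataset
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        gene_matrix=str(indir / "gene_fpkm.tsv"),
        gene_design=str(indir / "gene_design.tsv"),
        mirna_matrix=str(indir / "mirna_counts.tsv"),
        mirna_design=str(indir / "mirna_design.tsv"),
        transcripts=str(indir / "transcripts.fasta"),
        mirnas=str(indir / "mirnas.fasta"),
        annotations=str(indir / "annotations.tsv"),
        tf_list=str(indir / "tf_list.txt"),
        seed=DATASET_SEED,
    )
    return run_pipeline(config, outdir), config
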