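from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nexon.pipeline import PipelineConfig, run_pipeline
from nexon.simulate import SimulationConfig, default_cohort_design, generate_cohort

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort: 20 genes, 15 true plants, 5 decoys, 8 samples."""
    out = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig()
    design = default_cohort_design(depth=100)
    locus, files = generate_cohort(config, design, out, seed=COHORT_SEED)
    return locus, files, design


@pytest.fixture(scope="session")
def pipeline_result(cohort, tmp_path_factory):
    locus, _, _ = cohort
    out = tmp_path_factory.mktemp("pipeline_out")
    base = locus.genome_path.parent
    config = PipelineConfig(
        annotation_gtf=str(locus.gtf_path),
        genome_fasta=str(locus.genome_path),
        alignments_dir=str(base / "samples"),
        models_dir=str(base / "samples"),
        elements_bed=str(base / "elements.bed"),
        per_base_bedgraph=str(base / "phylo.bedgraph"),
        design_tsv=str(base / "design.tsv"),
        out_dir=str(out),
    )
    return run_pipeline(config)
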