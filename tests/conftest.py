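"""Shared fixtures: synthetic cohorts generated fresh at test time."""

from __future__ import annotations

import numpy as np
import pytest

import tfact
from tfact import pipeline, simulate

SEED = 1


@pytest.fixture(scope="session")
def small_world():
    """Seconds-scale synthetic cohort with regulome and cis scenario."""
    cfg = tfact.SimConfig.small(SEED)
    counts, samples, models, truth = tfact.simulate_cohort(cfg)
    genome, pwm, peaks = tfact.simulate_regulome(cfg, models, truth)
    allele, cnv, tads = tfact.simulate_cis_case(cfg, models, truth)
    return dict(
        cfg=cfg, counts=counts, samples=samples, models=models, truth=truth,
        genome=genome, pwm=pwm, peaks=peaks, allele=allele, cnv=cnv, tads=tads,
    )


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default-scale cohort run end to end once per session (~20 s)."""
    outdir = tmp_path_factory.mktemp("full_run")
    cfg = tfact.SimConfig(seed=SEED)
    counts, samples, models, truth = tfact.simulate_cohort(cfg)
    genome, pwm, peaks = tfact.simulate_regulome(cfg, models, truth)
    allele, cnv, tads = tfact.simulate_cis_case(cfg, models, truth)
    panels = simulate.default_marker_panels(truth)
    acfg = pipeline.AnalysisConfig(focal_tf=cfg.tf_gene, seed=SEED)
    report = pipeline.run_all(
        acfg, counts, samples, models, genome=genome, pwm=pwm, peaks=peaks,
        panels=panels, allele_counts=allele, cnv_segments=cnv, tads=tads,
        outdir=outdir,
    )
    return dict(
        cfg=cfg, counts=counts, samples=samples, models=models, truth=truth,
        genome=genome, pwm=pwm, peaks=peaks, allele=allele, cnv=cnv, tads=tads,
        report=report, outdir=outdir,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def tiny_files(tmp_path):
    """Hand-written 3-gene × 2-sample input triple on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\tsA\tsB\n"
        "g1\t10\t0\n"
        "g2\t5\t40\n"
        "g3\t0\t7\n"
    )
    samples = tmp_path / "samples.tsv"
    samples.write_text(
        "sample_id\tlineage\tsubtype\tfusion\tbatch\n"
        "sA\tB-ALL\tETV\t\t\n"
        "sB\tB-ALL\tETV\t\t\n"
    )
    models = tmp_path / "gene_models.tsv"
    models.write_text(
        "gene_id\tchrom\tstart\tend\tstrand\texonic_length_bp\tbiotype\n"
        "g1\tchr1\t0\t1000\t+\t1000\tprotein_coding\n"
        "g2\tchr1\t2000\t2500\t+\t500\tprotein_coding\n"
        "g3\tchr1\t3000\t5000\t-\t2000\tprotein_coding\n"
    )
    return dict(counts=counts, samples=samples, models=models, dir=tmp_path)
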