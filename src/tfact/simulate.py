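"""Seeded synthetic-cohort generator with planted ground truth.

Emulates the structure of a multi-subtype B-ALL RNA-seq cohort: per-gene
negative-binomial counts with subtype offsets, a focal transcription factor
that is near-silent in the background (median FPKM < 1) and strongly
activated in a handful of planted outlier samples, planted up/down targets
shifted only in those samples, a small random genome with consensus motifs
planted in target promoters, ChIP-like peaks concentrated at TSSs, a
beta-binomially skewed allele-count table, and a focal deletion spanning a
TAD boundary downstream of the TF.

Defaults mirror the printed cohort bookkeeping: 629 subtype-annotated
samples across 11 subtypes, 13 outliers in 7 of them (5/2/2/1/1/1/1),
~10,505 expressed protein-coding genes, 33 up / 13 down planted targets,
313 motif-bearing promoters, and a 101 kb deletion 285 kb downstream of
the TF's TSS.

Everything is driven by one integer seed; the same seed reproduces every
emitted file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cis import CnvSegment
from .io import (
    GeneModel,
    write_bed,
    write_fasta,
    write_gene_models,
    write_gmt,
)
from .motif import Pwm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SUBTYPE_SIZES = {
    "ETV": 190,
    "HYPER": 155,
    "PHL": 70,
    "DUX4": 60,
    "MLL": 45,
    "PH": 41,
    "HYPO": 23,
    "E2A": 20,
    "PAX5": 11,
    "MEF2D": 8,
    "ZNF384": 6,
}  # sums to 629; the first seven (584 samples) carry the planted outliers

DEFAULT_OUTLIERS = {"HYPER": 5, "MLL": 2, "ETV": 2, "DUX4": 1, "HYPO": 1, "PH": 1, "PHL": 1}


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory."""

    seed: int
    subtype_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_SIZES))
    outliers_per_subtype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_OUTLIERS))
    n_genes: int = 12_000
    n_noncoding: int = 1_000
    n_expressed: int = 10_560  # expressed-regime coding genes; ~10,505 pass the filter
    # chosen so E[sum fpkm*length] ~ 1e9: realized FPKM (with in-matrix library
    # sizes) then matches the intended FPKM scale to within a few percent
    expressed_log2_fpkm_mean: float = 3.7
    expressed_log2_fpkm_sd: float = 1.5
    silent_log2_fpkm_mean: float = -4.0
    silent_log2_fpkm_sd: float = 1.0
    dispersion_median: float = 0.08
    dispersion_log_sd: float = 0.5
    subtype_effect_sd_log2: float = 0.1
    library_size_mean: float = 3.0e7
    library_size_cv: float = 0.2
    length_min_bp: int = 200
    length_max_bp: int = 20_000
    # focal transcription factor
    tf_gene: str = "GENE_TF"
    tf_background_fpkm: float = 0.3
    tf_dispersion: float = 0.05
    tf_activation_fold: float = 30.0
    # planted direct targets (shifted in outlier samples only)
    n_up_targets: int = 33
    n_down_targets: int = 13
    target_fold_min: float = 1.5
    target_fold_max: float = 4.0
    # regulome
    motif_consensus: str = "AGATAAGA"
    n_motif_genes: int = 313
    promoter_half_window: int = 100
    peak_sigma_bp: float = 50.0
    n_peaks_near: int = 1000
    n_peaks_decoy: int = 200
    peak_width: int = 500
    # cis scenario
    ase_allele_fraction: float = 0.95
    ase_n_markers: int = 6
    ase_marker_depth: int = 30
    ase_overdispersion_rho: float = 0.02
    deletion_length: int = 101_000
    deletion_tss_offset: int = 285_000
    tad_size: int = 400_000
    deletion_log2_ratio: float = -0.75
    deletion_loh: float = 0.32
    # layout
    n_contigs: int = 8
    tss_spacing: int = 400
    batch_effect_log2: float = 0.0  # optional additive batch offset (off)

    @classmethod
    def small(cls, seed: int) -> "SimConfig":
        """A seconds-scale preset (same structure, ~1/20 size) for tests."""
        return cls(
            seed=seed,
            subtype_sizes={"A": 40, "B": 35, "C": 30, "D": 30, "E": 25, "F": 25, "G": 20, "H": 12},
            outliers_per_subtype={"A": 2, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1},
            n_genes=600,
            n_noncoding=50,
            n_expressed=480,
            # keep sum(fpkm*length) ~ 1e9 with 22x fewer expressed genes
            expressed_log2_fpkm_mean=3.7 + float(np.log2(10_560 / 480)),
            n_up_targets=12,
            n_down_targets=6,
            n_motif_genes=60,
            n_peaks_near=200,
            n_peaks_decoy=40,
            n_contigs=4,
        )


@dataclass
class SimTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    tf_gene: str
    outlier_samples: list[str]
    outliers_by_subtype: dict[str, list[str]]
    up_targets: list[str]
    down_targets: list[str]
    fold_by_gene: dict[str, float]
    motif_genes: list[str] = field(default_factory=list)
    planted_fraction_core: float = float("nan")
    cis: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _validate(config: SimConfig) -> None:
    for subtype, k in config.outliers_per_subtype.items():
        if subtype not in config.subtype_sizes:
            raise ValueError(f"outliers requested for unknown subtype {subtype!r}")
        if k > config.subtype_sizes[subtype]:
            raise ValueError(
                f"subtype {subtype!r}: {k} outliers requested but only "
                f"{config.subtype_sizes[subtype]} samples"
            )
    if config.n_expressed + config.n_noncoding > config.n_genes:
        raise ValueError("n_expressed + n_noncoding exceeds n_genes")
    if config.tf_activation_fold <= 1 or config.target_fold_min <= 1:
        raise ValueError("activation/target folds must be > 1")


def _gene_layout(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place genes on contigs with TSSs on a fixed grid.

    The TF gene sits alone near the start of chr1 (TSS 100,000, + strand);
    the remaining chr1 genes start at 1 Mb, leaving room for the TAD /
    deletion geometry of the cis scenario.  TSSs (not starts) sit on the
    grid so promoter windows of neighbours never overlap.
    """
    n_other = config.n_genes - 1
    ids = [f"G{i + 1:05d}" for i in range(n_other)]
    biotypes = np.array(["protein_coding"] * n_other, dtype=object)
    if config.n_noncoding:
        noncoding_idx = rng.choice(n_other, size=config.n_noncoding, replace=False)
        biotypes[noncoding_idx] = "lncRNA"
    lengths = np.exp(
        rng.uniform(np.log(config.length_min_bp), np.log(config.length_max_bp), n_other)
    ).astype(int)
    strands = rng.choice(["+", "-"], size=n_other)

    per_contig = int(np.ceil(n_other / config.n_contigs))
    models = [
        GeneModel(config.tf_gene, "chr1", 100_000, 102_000, "+", 2_000, "protein_coding")
    ]
    for i in range(n_other):
        contig = i // per_contig
        j = i % per_contig
        chrom = f"chr{contig + 1}"
        base = 1_000_000 if contig == 0 else 10_000
        tss = base + j * config.tss_spacing
        span = int(lengths[i])
        if strands[i] == "+":
            start, end = tss, tss + span
        else:
            start = max(tss + 1 - span, 0)
            end = tss + 1
            span = end - start
        models.append(
            GeneModel(ids[i], chrom, start, end, strands[i], min(int(lengths[i]), span), str(biotypes[i]))
        )
    return models


def contig_lengths(models: list[GeneModel], tail_pad: int = 30_000) -> dict[str, int]:
    """Contig sizes implied by the gene layout (gene-free tail for decoys)."""
    lengths: dict[str, int] = {}
    for m in models:
        lengths[m.chrom] = max(lengths.get(m.chrom, 0), m.end)
    return {c: int(np.ceil((e + tail_pad) / 1000) * 1000) for c, e in lengths.items()}


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneModel], SimTruth]:
    """Generate (counts, sample sheet, gene models, truth) for one cohort."""
    _validate(config)
    rng = np.random.default_rng([config.seed, 1])
    models = _gene_layout(config, rng)
    gene_ids = [m.gene_id for m in models]
    lengths = np.array([m.exonic_length_bp for m in models], dtype=float)
    coding = np.array([m.biotype == "protein_coding" for m in models])

    # samples, grouped by subtype in config order
    subtype_of: list[str] = []
    for subtype, n in config.subtype_sizes.items():
        subtype_of.extend([subtype] * n)
    n_samples = len(subtype_of)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lineage": "B-ALL",
            "subtype": subtype_of,
            "fusion": pd.NA,
            "batch": pd.NA,
        }
    ).set_index("sample_id", drop=False)

    # baseline per-gene expression (FPKM scale) and dispersions
    n_genes = len(models)
    base_log2_fpkm = rng.normal(config.silent_log2_fpkm_mean, config.silent_log2_fpkm_sd, n_genes)
    non_tf = np.arange(1, n_genes)  # index 0 is the TF
    coding_non_tf = non_tf[coding[non_tf]]
    expressed_idx = rng.choice(coding_non_tf, size=config.n_expressed, replace=False)
    base_log2_fpkm[expressed_idx] = rng.normal(
        config.expressed_log2_fpkm_mean, config.expressed_log2_fpkm_sd, config.n_expressed
    )
    base_log2_fpkm[0] = np.log2(config.tf_background_fpkm)
    dispersion = np.exp(
        rng.normal(np.log(config.dispersion_median), config.dispersion_log_sd, n_genes)
    )
    dispersion[0] = config.tf_dispersion

    # subtype offsets (log2, per gene x subtype)
    subtypes = list(config.subtype_sizes)
    sub_effect = rng.normal(0.0, config.subtype_effect_sd_log2, (n_genes, len(subtypes)))
    sub_index = np.array([subtypes.index(s) for s in subtype_of])

    library_sizes = np.exp(
        rng.normal(
            np.log(config.library_size_mean) - config.library_size_cv**2 / 2,
            config.library_size_cv,
            n_samples,
        )
    )

    # planted outliers per subtype
    outliers_by_subtype: dict[str, list[str]] = {}
    outlier_mask = np.zeros(n_samples, dtype=bool)
    for subtype, k in config.outliers_per_subtype.items():
        pool = np.flatnonzero(np.array(subtype_of) == subtype)
        chosen = rng.choice(pool, size=k, replace=False)
        outlier_mask[chosen] = True
        outliers_by_subtype[subtype] = sorted(sample_ids[i] for i in chosen)

    # planted targets among solidly expressed coding genes (mid-range FPKM)
    m = config.expressed_log2_fpkm_mean
    solid = expressed_idx[
        (base_log2_fpkm[expressed_idx] >= m - 1.5) & (base_log2_fpkm[expressed_idx] <= m + 2.5)
    ]
    n_targets = config.n_up_targets + config.n_down_targets
    target_idx = rng.choice(solid, size=n_targets, replace=False)
    up_idx = target_idx[: config.n_up_targets]
    down_idx = target_idx[config.n_up_targets :]
    folds = rng.uniform(config.target_fold_min, config.target_fold_max, n_targets)
    fold_by_gene = {
        gene_ids[g]: (float(f) if i < config.n_up_targets else float(1.0 / f))
        for i, (g, f) in enumerate(zip(target_idx, folds))
    }

    # expected counts and NB sampling
    fpkm_mean = 2.0 ** (base_log2_fpkm[:, None] + sub_effect[:, sub_index])
    mu = fpkm_mean * lengths[:, None] * library_sizes[None, :] / 1e9
    mu[0, outlier_mask] *= config.tf_activation_fold
    mu[up_idx[:, None], np.flatnonzero(outlier_mask)[None, :]] *= folds[
        : config.n_up_targets, None
    ]
    mu[down_idx[:, None], np.flatnonzero(outlier_mask)[None, :]] /= folds[
        config.n_up_targets :, None
    ]
    mu = np.maximum(mu, 1e-8)
    lam = rng.gamma(1.0 / dispersion[:, None], dispersion[:, None] * mu)
    counts = rng.poisson(lam).astype("int64")

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = SimTruth(
        tf_gene=config.tf_gene,
        outlier_samples=sorted(s for ss in outliers_by_subtype.values() for s in ss),
        outliers_by_subtype=outliers_by_subtype,
        up_targets=sorted(gene_ids[g] for g in up_idx),
        down_targets=sorted(gene_ids[g] for g in down_idx),
        fold_by_gene=fold_by_gene,
    )
    return counts_df, samples, models, truth


def simulate_regulome(
    config: SimConfig,
    models: list[GeneModel],
    truth: SimTruth | None = None,
) -> tuple[dict[str, str], Pwm, pd.DataFrame]:
    """Generate (genome, PWM, peaks) matching the cohort's gene layout.

    Consensus motif instances are planted inside the promoter windows of
    the planted targets plus random fillers (``n_motif_genes`` total);
    ``n_peaks_near`` peaks are centred Normal(0, σ) around random TSSs and
    ``n_peaks_decoy`` decoys are dropped in the gene-free contig tails.
    ``truth`` (when given) is updated in place with the motif gene list and
    the planted near-TSS core fraction.
    """
    rng = np.random.default_rng([config.seed, 17])
    sizes = contig_lengths(models)
    genome_codes = {c: rng.integers(0, 4, size=n, dtype=np.int8) for c, n in sizes.items()}

    by_id = {m.gene_id: m for m in models}
    coding = [m for m in models if m.biotype == "protein_coding"]
    planted = set(truth.up_targets) | set(truth.down_targets) if truth else set()
    fillers = [m.gene_id for m in coding if m.gene_id not in planted and m.gene_id != config.tf_gene]
    n_fill = max(config.n_motif_genes - len(planted), 0)
    motif_genes = sorted(planted) + sorted(
        rng.choice(np.array(sorted(fillers)), size=n_fill, replace=False).tolist()
    )

    consensus = config.motif_consensus.upper()
    motif_codes = np.array(["ACGT".index(b) for b in consensus], dtype=np.int8)
    w = len(consensus)
    hw = config.promoter_half_window
    for gene_id in motif_genes:
        m = by_id[gene_id]
        offset = int(rng.integers(-hw, hw - w + 1))
        start = m.tss + offset
        genome_codes[m.chrom][start : start + w] = motif_codes

    genome = {c: _BASES[codes].tobytes().decode() for c, codes in genome_codes.items()}
    pwm = Pwm.from_consensus(consensus, nsites=1000)

    # peaks: near-TSS with Gaussian offsets, plus distal decoys in contig tails
    tss_pool = np.array([m.tss for m in coding])
    chrom_pool = np.array([m.chrom for m in coding])
    pick = rng.choice(len(coding), size=config.n_peaks_near, replace=False)
    offsets = np.round(rng.normal(0.0, config.peak_sigma_bp, config.n_peaks_near)).astype(int)
    centers = tss_pool[pick] + offsets
    half = config.peak_width // 2
    rows = [
        (chrom_pool[i], int(c - half), int(c + half))
        for i, c in zip(pick, centers)
    ]
    max_end = {c: max(m.end for m in models if m.chrom == c) for c in sizes}
    tail_chroms = rng.choice(np.array(sorted(sizes)), size=config.n_peaks_decoy)
    for chrom in tail_chroms:
        lo = max_end[chrom] + 5_000
        hi = sizes[chrom] - half - 10
        c = int(rng.integers(lo, hi))
        rows.append((chrom, c - half, c + half))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)

    if truth is not None:
        truth.motif_genes = list(motif_genes)
        truth.planted_fraction_core = float(np.mean(np.abs(offsets) <= 100))
    return genome, pwm, peaks


def simulate_cis_case(
    config: SimConfig,
    models: list[GeneModel],
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, list[CnvSegment], pd.DataFrame]:
    """Generate the cis-activation scenario for one outlier sample.

    Beta-binomially skewed allele counts at markers inside the TF gene
    (balanced controls at two other genes), one focal deletion of the
    configured length/offset downstream of the TF's TSS, and a TAD grid
    whose boundary falls inside the deletion.
    """
    rng = np.random.default_rng([config.seed, 29])
    by_id = {m.gene_id: m for m in models}
    tf = by_id[config.tf_gene]
    tss = tf.tss

    # allele counts
    rows = []
    concentration = 1.0 / config.ase_overdispersion_rho - 1.0
    af = config.ase_allele_fraction

    def _markers(gene: GeneModel, n_markers: int, fraction: float, tag: str) -> None:
        positions = np.sort(
            rng.choice(np.arange(gene.start + 1, gene.end - 1), size=n_markers, replace=False)
        )
        for i, pos in enumerate(positions):
            if 0 < fraction < 1:
                p_alt = rng.beta(fraction * concentration, (1 - fraction) * concentration)
            else:
                p_alt = fraction
            depth = config.ase_marker_depth
            alt = int(rng.binomial(depth, p_alt))
            rows.append((f"{tag}_{i + 1}", gene.chrom, int(pos), gene.gene_id, depth - alt, alt))

    _markers(tf, config.ase_n_markers, af, "mk_tf")
    controls = [m for m in models if m.gene_id != config.tf_gene][:2]
    for j, gene in enumerate(controls):
        _markers(gene, 4, 0.5, f"mk_ctl{j + 1}")
    allele_counts = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos", "gene_id", "ref_count", "alt_count"]
    )

    deletion = CnvSegment(
        chrom=tf.chrom,
        start=tss + config.deletion_tss_offset,
        end=tss + config.deletion_tss_offset + config.deletion_length,
        log2_ratio=config.deletion_log2_ratio,
        loh_segment_mean=config.deletion_loh,
    )

    tad_rows = []
    for chrom, size in sorted(contig_lengths(models).items()):
        edges = list(range(0, size, config.tad_size)) + [size]
        for lo, hi in zip(edges, edges[1:]):
            if hi > lo:
                tad_rows.append((chrom, lo, hi))
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    if truth is not None:
        truth.cis = {
            "sample": truth.outlier_samples[0] if truth.outlier_samples else None,
            "gene": config.tf_gene,
            "deletion_start": deletion.start,
            "deletion_end": deletion.end,
            "deletion_length": deletion.length,
            "tss_offset": deletion.start - tss,
            "expected_verdict": "cis-candidate",
        }
    return allele_counts, [deletion], tads


def default_marker_panels(truth: SimTruth, rng_seed: int = 101) -> dict[str, set[str]]:
    """Clinical-style marker panels over the synthetic cohort.

    The 'myeloid' panel holds 12 genes of which 7 are planted up-targets
    (mirroring the printed 7-of-12 overlap); the 'b_lineage' panel holds 10
    genes of which 6 are planted down-targets.
    """
    rng = np.random.default_rng([rng_seed, 7])
    up = list(truth.up_targets)
    down = list(truth.down_targets)
    other = [g for g in truth.motif_genes if g not in set(up) | set(down)]
    myeloid = set(up[:7]) | set(rng.choice(np.array(sorted(other)), 5, replace=False))
    b_lineage = set(down[:6]) | set(rng.choice(np.array(sorted(other)), 4, replace=False))
    return {"myeloid": myeloid, "b_lineage": b_lineage}


def write_inputs(
    outdir: str | Path,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    models: list[GeneModel],
    truth: SimTruth,
    genome: Mapping[str, str] | None = None,
    pwm: Pwm | None = None,
    peaks: pd.DataFrame | None = None,
    allele_counts: pd.DataFrame | None = None,
    cnv: list[CnvSegment] | None = None,
    tads: pd.DataFrame | None = None,
    panels: Mapping[str, set[str]] | None = None,
) -> dict[str, Path]:
    """Write every pipeline input the generator produced; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    paths["samples"] = outdir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["gene_models"] = outdir / "gene_models.tsv"
    write_gene_models(paths["gene_models"], models)
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    if genome is not None:
        paths["genome"] = outdir / "genome.fa"
        write_fasta(paths["genome"], genome)
    if pwm is not None:
        paths["pwm"] = outdir / "motif.meme"
        pwm.to_meme(paths["pwm"])
    if peaks is not None:
        paths["peaks"] = outdir / "peaks.bed"
        write_bed(paths["peaks"], peaks)
    if allele_counts is not None:
        paths["allele_counts"] = outdir / "allele_counts.tsv"
        allele_counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    if cnv is not None:
        paths["cnv"] = outdir / "cnv.seg"
        pd.DataFrame(
            [(s.chrom, s.start, s.end, s.log2_ratio, s.loh_segment_mean) for s in cnv],
            columns=["chrom", "start", "end", "log2_ratio", "loh_segment_mean"],
        ).to_csv(paths["cnv"], sep="\t", index=False)
    if tads is not None:
        paths["tads"] = outdir / "tads.bed"
        write_bed(paths["tads"], tads)
    if panels is not None:
        paths["panels"] = outdir / "panels.gmt"
        write_gmt(paths["panels"], panels)
    return paths
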