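"""End-to-end orchestration: normalize → outliers → DE → motif → nominate → cis.

``run_all`` composes the stages in analysis order, writes each stage's
output as a plain file (so any stage can be re-run standalone on hand-made
fixtures), and returns a :class:`RunReport` whose tallies are checked
against the emitted files.  The run is fully determined by the inputs and
the configuration; no timestamps enter the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cis as cis_mod
from . import diffexp, expression, motif, outliers
from .io import GeneModel, gene_models_frame

logger = logging.getLogger(__name__)


def format_percent(numerator: float, denominator: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage string, e.g. 13/629 → ``"2.07"``."""
    if denominator == 0:
        return "nan"
    return f"{100.0 * numerator / denominator:.{decimals}f}"


@dataclass
class AnalysisConfig:
    """Every pipeline threshold, echoed into the report for provenance."""

    focal_tf: str = "GENE_TF"
    k: float = 3.0
    min_subtype_n: int = 3
    expressed_threshold: float = 1.0
    expressed_min_fraction: float = 0.30
    biotype: str = "protein_coding"
    deg_fc: float = 1.5
    deg_p: float = 0.05
    motif_half_window: int = 100
    motif_p: float = 1e-4
    near: int = 2000
    core: int = 100
    ase_min_coverage: int = 10
    ase_alpha: float = 0.05
    cis_flank: int = 5000
    cis_max_distance: int = 500_000
    log2_cut: float = -0.4
    loh_cut: float = 0.2
    cis_sample: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        return cls.from_dict(values)


@dataclass
class RunReport:
    status: str
    config: dict
    tallies: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _write(outdir: Path | None, name: str, frame: pd.DataFrame, files: dict) -> int:
    if outdir is not None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        files[name] = str(path)
    return len(frame)


def run_all(
    config: AnalysisConfig,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | str | None = None,
    pwm: motif.Pwm | None = None,
    peaks: pd.DataFrame | None = None,
    panels: Mapping[str, set[str]] | None = None,
    gene_sets: Mapping[str, set[str]] | None = None,
    allele_counts: pd.DataFrame | None = None,
    cnv_segments: Sequence[cis_mod.CnvSegment] | None = None,
    tads: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis; optional inputs switch their stages on."""
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(status="ok", config=config.to_dict())
    tall, files = report.tallies, report.files
    frame = gene_models_frame(models)

    # --- normalize and filter ------------------------------------------------
    fpkm = expression.compute_fpkm(counts, frame["exonic_length_bp"])
    expressed = expression.filter_expressed(
        fpkm,
        frame["biotype"],
        threshold=config.expressed_threshold,
        min_fraction=config.expressed_min_fraction,
        biotype=config.biotype,
    )
    tall["n_genes"] = int(counts.shape[0])
    tall["n_samples"] = int(counts.shape[1])
    tall["n_expressed"] = len(expressed)
    if outdir is not None:
        _write(
            outdir,
            "expressed_genes.tsv",
            pd.DataFrame({"gene_id": sorted(expressed)}),
            files,
        )

    # --- outlier activation --------------------------------------------------
    if config.focal_tf not in fpkm.fpkm.index:
        raise KeyError(f"focal TF {config.focal_tf!r} absent from counts")
    subtyped = samples[samples["subtype"].notna() & (samples["subtype"].astype(str) != "")]
    calls = outliers.call_subtype_outliers(
        fpkm.fpkm.loc[config.focal_tf, subtyped["sample_id"]],
        subtyped,
        gene_id=config.focal_tf,
        k=config.k,
        min_subtype_n=config.min_subtype_n,
    )
    groups = outliers.assign_groups(calls, subtyped)
    n_out = int((groups == "outlier").sum())
    tall["n_subtyped"] = int(len(subtyped))
    tall["outliers_per_subtype"] = {
        c.subtype: len(c.outlier_samples) for c in calls if c.outlier_samples
    }
    tall["n_outliers"] = n_out
    tall["n_normal"] = int((groups == "normal").sum())
    tall["n_excluded"] = int((groups == "excluded").sum())
    report.percentages["outliers_of_subtyped"] = format_percent(n_out, len(subtyped))
    if outdir is not None:
        _write(outdir, "outlier_calls.tsv", outliers.outlier_calls_frame(calls), files)
        _write(
            outdir,
            "groups.tsv",
            groups.rename_axis("sample_id").reset_index(),
            files,
        )
    if n_out == 0:
        report.status = "no_outliers"
        if outdir is not None:
            report.to_json(outdir / "report.json")
        return report

    # --- differential expression --------------------------------------------
    offsets = pd.Series(
        np.log(fpkm.library_sizes.to_numpy(dtype=float)), index=fpkm.library_sizes.index
    )
    de = diffexp.fit_nb_glm_many(
        counts.loc[sorted(expressed)],
        subtyped,
        groups,
        offsets=offsets,
        covariates=("subtype", "batch"),
    )
    degs = diffexp.call_degs(de, fc=config.deg_fc, p=config.deg_p)
    tall["n_de_tested"] = int(len(de))
    tall["n_up"] = len(degs.up)
    tall["n_down"] = len(degs.down)
    tall["n_deg"] = len(degs.up) + len(degs.down)
    if outdir is not None:
        _write(outdir, "de_results.tsv", de.rename_axis("gene_id").reset_index(), files)
        deg_frame = pd.DataFrame(
            [(g, "up") for g in sorted(degs.up)] + [(g, "down") for g in sorted(degs.down)],
            columns=["gene_id", "direction"],
        )
        _write(outdir, "degs.tsv", deg_frame, files)

    # --- enrichment ----------------------------------------------------------
    if panels:
        for name, members in panels.items():
            panel = diffexp.MarkerPanel(name, set(members))
            for direction in ("up", "down"):
                try:
                    res = diffexp.marker_enrichment(degs, panel, expressed, direction)
                except ValueError as exc:
                    report.warnings.append(f"panel {name}/{direction}: {exc}")
                    continue
                report.enrichment[f"{name}_{direction}"] = {
                    "table": res.table.tolist(),
                    "p_one_sided": res.p_one_sided,
                    "p_two_sided": res.p_two_sided,
                }
    if gene_sets:
        for direction, genes in (("up", degs.up), ("down", degs.down)):
            ora = diffexp.overrepresentation(genes, gene_sets, expressed)
            if outdir is not None:
                _write(outdir, f"ora_{direction}.tsv", ora, files)
            report.enrichment[f"ora_{direction}_top"] = (
                ora.iloc[0]["set"] if len(ora) else None
            )

    # --- motif scan and nomination ------------------------------------------
    candidates = []
    if genome is not None and pwm is not None:
        coding = [m for m in models if m.biotype == config.biotype]
        promoters = motif.extract_promoters(coding, genome, config.motif_half_window)
        hits = motif.best_hits(promoters, pwm, p_threshold=config.motif_p)
        tall["n_promoters_scanned"] = len(promoters)
        tall["n_motif_genes"] = len(hits)
        if peaks is not None:
            profile = motif.peak_tss_profile(peaks, coding, near=config.near, core=config.core)
            tall["n_peaks_within_near"] = profile.n_within_near
            tall["n_peaks_within_core"] = profile.n_within_core
            report.percentages["peaks_core_of_near"] = format_percent(
                profile.n_within_core, max(profile.n_within_near, 1), decimals=1
            )
        in_scope = list(groups.index[groups != "excluded"])
        candidates = motif.nominate_targets(
            hits,
            degs,
            fpkm.fpkm,
            config.focal_tf,
            in_scope,
            de_pvalues=de["p_value"],
        )
        tall["n_candidates_up"] = sum(c.deg_direction == "up" for c in candidates)
        tall["n_candidates_down"] = sum(c.deg_direction == "down" for c in candidates)
        tall["n_candidates"] = len(candidates)
        if outdir is not None:
            hit_frame = pd.DataFrame(
                [
                    (h.gene_id, h.offset, h.strand, h.score, h.p_value)
                    for h in hits.values()
                ],
                columns=["gene_id", "offset", "strand", "score", "p_value"],
            ).sort_values("gene_id", kind="mergesort")
            _write(outdir, "motif_hits.tsv", hit_frame, files)
            cand_frame = pd.DataFrame(
                [
                    (c.gene_id, c.deg_direction, c.pearson_r, c.pearson_p, c.de_p)
                    for c in candidates
                ],
                columns=["gene_id", "direction", "pearson_r", "pearson_p", "de_p"],
            )
            _write(outdir, "candidates.tsv", cand_frame, files)

    # --- cis evidence --------------------------------------------------------
    if allele_counts is not None and cnv_segments is not None and tads is not None:
        by_id = {m.gene_id: m for m in models}
        gene = by_id[config.focal_tf]
        ase_all = cis_mod.ase_test(
            allele_counts, min_coverage=config.ase_min_coverage, alpha=config.ase_alpha
        )
        ase = ase_all.get(config.focal_tf, cis_mod.AseResult(gene_id=config.focal_tf))
        same_chrom = [s for s in cnv_segments if s.chrom == gene.chrom]
        deletion = min(same_chrom, key=lambda s: s.log2_ratio) if same_chrom else None
        deletion_class = (
            cis_mod.classify_deletion(deletion, config.log2_cut, config.loh_cut)
            if deletion is not None
            else None
        )
        if deletion is not None and deletion_class.classification == "focal_deletion":
            disruption = cis_mod.boundary_disruption(
                deletion, tads, gene, flank=config.cis_flank, max_distance=config.cis_max_distance
            )
        else:
            disruption = (False, None)
        sample = config.cis_sample
        if sample is None:
            flagged = sorted(groups.index[groups == "outlier"])
            sample = flagged[0] if flagged else ""
        cis_report = cis_mod.integrate_cis(
            config.focal_tf,
            sample,
            outlier_flag=bool(groups.get(sample, "") == "outlier"),
            ase=ase,
            deletion=deletion,
            deletion_class=deletion_class,
            disruption=disruption,
        )
        tall["cis_verdict"] = cis_report.verdict
        tall["cis_ase_call"] = ase.gene_call
        tall["cis_boundary_disrupted"] = cis_report.boundary_disrupted
        if outdir is not None:
            path = outdir / "cis_report.json"
            with open(path, "w") as fh:
                json.dump(dataclasses.asdict(cis_report), fh, indent=1, default=str)
            files["cis_report.json"] = str(path)

    _verify_tallies(report)
    if outdir is not None:
        report.to_json(outdir / "report.json")
        files["report.json"] = str(outdir / "report.json")
    return report


def _verify_tallies(report: RunReport) -> None:
    """Internal consistency: file row counts must match report tallies."""
    t = report.tallies
    if "n_candidates" in t:
        assert t["n_candidates"] == t["n_candidates_up"] + t["n_candidates_down"]
    if "n_deg" in t:
        assert t["n_deg"] == t["n_up"] + t["n_down"]
    for name, expected in (
        ("expressed_genes.tsv", t.get("n_expressed")),
        ("degs.tsv", t.get("n_deg")),
        ("candidates.tsv", t.get("n_candidates")),
        ("motif_hits.tsv", t.get("n_motif_genes")),
        ("de_results.tsv", t.get("n_de_tested")),
    ):
        path = report.files.get(name)
        if path is None or expected is None:
            continue
        n_rows = sum(1 for _ in open(path)) - 1  # header
        if n_rows != expected:
            raise AssertionError(
                f"{name}: {n_rows} rows but report tally says {expected}"
            )
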