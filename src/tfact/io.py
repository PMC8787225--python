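"""Plain-text I/O for the cohort pipeline.

Formats are deliberately minimal and text-only: TSV tables for counts,
samples, gene models, allele counts and copy-number segments; BED for
intervals; FASTA for sequence; GMT for gene sets.  All genomic coordinates
are 0-based half-open (BED convention) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

VALID_STRANDS = ("+", "-")

SAMPLE_COLUMNS = ("sample_id", "lineage", "subtype", "fusion", "batch")
GENE_MODEL_COLUMNS = (
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "exonic_length_bp",
    "biotype",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with the fields the pipeline needs.

    ``start``/``end`` are 0-based half-open genomic coordinates of the gene
    span; ``exonic_length_bp`` is the summed exon length used as the FPKM
    denominator (it may be shorter than the span, never longer).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exonic_length_bp: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.exonic_length_bp < 1:
            raise ValueError(
                f"gene {self.gene_id}: exonic_length_bp must be >= 1, "
                f"got {self.exonic_length_bp}"
            )
        if self.exonic_length_bp > self.end - self.start:
            raise ValueError(
                f"gene {self.gene_id}: exonic_length_bp ({self.exonic_length_bp}) "
                f"exceeds gene span ({self.end - self.start})"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on −."""
        return self.start if self.strand == "+" else self.end - 1


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the 7-column gene model TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model file {path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"gene model file {path}: duplicate gene ids {dups[:5]}")
    for col in ("start", "end", "exonic_length_bp"):
        bad = df[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"gene model file {path}: missing {col} for gene "
                f"{bad['gene_id'].iloc[0]!r}"
            )
    return [
        GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            exonic_length_bp=int(row.exonic_length_bp),
            biotype=row.biotype,
        )
        for row in df.itertuples(index=False)
    ]


def gene_models_frame(models: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate GeneModels (adds a derived ``tss`` column)."""
    rows = [
        (m.gene_id, m.chrom, m.start, m.end, m.strand, m.exonic_length_bp, m.biotype, m.tss)
        for m in models
    ]
    return pd.DataFrame(rows, columns=list(GENE_MODEL_COLUMNS) + ["tss"]).set_index(
        "gene_id", drop=False
    )


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    gene_models_frame(models).drop(columns="tss").to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV; ``fusion`` and ``batch`` are optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "lineage", "subtype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"sample sheet {path}: duplicate sample ids {dups[:5]}")
    if df["lineage"].isna().any():
        bad = df.loc[df["lineage"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample sheet {path}: sample {bad!r} has no lineage")
    for opt in ("fusion", "batch"):
        if opt not in df.columns:
            df[opt] = pd.NA
    return df.set_index("sample_id", drop=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read the counts TSV (first column gene_id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"counts file {path}: duplicate gene ids {dups[:5]}")
    if (df.values < 0).any():
        raise ValueError(f"counts file {path}: negative count entries")
    return df.astype("int64")


def read_counts(
    counts_path: str | Path,
    sample_path: str | Path,
    gene_model_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneModel]]:
    """Read and cross-validate the counts / sample-sheet / gene-model triple.

    Returns ``(counts, samples, models)`` where counts is genes × samples.
    Genes in the counts matrix must all be present in the gene models, and
    every counts column must appear in the sample sheet.
    """
    counts = read_count_matrix(counts_path)
    samples = read_sample_sheet(sample_path)
    models = read_gene_models(gene_model_path)
    known = {m.gene_id for m in models}
    unknown = [g for g in counts.index if g not in known]
    if unknown:
        raise KeyError(
            f"counts gene {unknown[0]!r} absent from gene models "
            f"({len(unknown)} such genes)"
        )
    missing_samples = [s for s in counts.columns if s not in samples.index]
    if missing_samples:
        raise ValueError(
            f"sample {missing_samples[0]!r} present in counts but absent from "
            f"sample sheet ({len(missing_samples)} such samples)"
        )
    samples = samples.loc[list(counts.columns)]
    return counts, samples, models


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end [, name ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path}: fewer than 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols
    df["chrom"] = df["chrom"].astype(str)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"BED file {path}: interval with start >= end")
    return df


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like TSV: chrom, start, end, log2_ratio [, loh_segment_mean]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SEG file {path}: missing columns {sorted(missing)}")
    if "loh_segment_mean" not in df.columns:
        df["loh_segment_mean"] = pd.NA
    return df


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read RNA allele counts at heterozygous markers."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "gene_id": str})
    required = {"marker_id", "chrom", "pos", "gene_id", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele count file {path}: missing columns {sorted(missing)}")
    if (df[["ref_count", "alt_count"]].values < 0).any():
        raise ValueError(f"allele count file {path}: negative counts")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory, uppercased."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
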