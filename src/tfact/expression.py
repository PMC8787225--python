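"""FPKM normalization and the expressed-gene filter.

FPKM (fragments per kilobase of exonic length per million library
fragments) is computed directly from the count matrix:

    fpkm[g, s] = counts[g, s] * 1e9 / (exonic_length_bp[g] * library_size[s])

Library size defaults to the in-matrix column sum, which keeps the
normalization self-contained and reproducible from the counts file alone.
A protein-coding gene is called *expressed* when its FPKM exceeds 1
(strictly) in at least 30% of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import GeneModel, gene_models_frame


@dataclass
class FpkmMatrix:
    """Normalized expression with the quantities that produced it."""

    fpkm: pd.DataFrame  # genes x samples
    library_sizes: pd.Series  # per sample
    gene_lengths: pd.Series  # exonic length per gene, bp

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    @property
    def samples(self) -> pd.Index:
        return self.fpkm.columns


def compute_fpkm(
    counts: pd.DataFrame,
    models: Sequence[GeneModel] | pd.Series,
    library_sizes: pd.Series | None = None,
) -> FpkmMatrix:
    """Compute FPKM from raw counts.

    Parameters
    ----------
    counts
        Integer matrix, genes × samples.
    models
        Gene models (or a Series of exonic lengths indexed by gene id)
        covering every gene in ``counts``.
    library_sizes
        Per-sample total fragment counts.  Defaults to the column sums of
        ``counts``.
    """
    if isinstance(models, pd.Series):
        lengths = models
    else:
        frame = gene_models_frame(models)
        lengths = frame["exonic_length_bp"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no exonic length for gene {missing[0]!r}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"gene {bad!r}: exonic length must be >= 1 bp")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.loc[counts.columns].astype(float)
    zero = library_sizes.index[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has library size 0")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    return FpkmMatrix(fpkm=fpkm, library_sizes=library_sizes, gene_lengths=lengths)


def filter_expressed(
    fpkm: FpkmMatrix | pd.DataFrame,
    models: Sequence[GeneModel] | pd.Series | None = None,
    threshold: float = 1.0,
    min_fraction: float = 0.30,
    biotype: str | None = "protein_coding",
) -> set[str]:
    """Genes with FPKM strictly > ``threshold`` in ≥ ``min_fraction`` of samples.

    When ``biotype`` is given (default ``protein_coding``), only genes of
    that biotype are eligible; pass ``biotype=None`` to keep all biotypes.
    Returns the set of expressed gene ids (empty for an empty matrix).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    matrix = fpkm.fpkm if isinstance(fpkm, FpkmMatrix) else fpkm
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        return set()
    if biotype is not None:
        if models is None:
            raise ValueError("models required when filtering on biotype")
        if isinstance(models, pd.Series):
            biotypes = models
        else:
            biotypes = gene_models_frame(models)["biotype"]
        keep = biotypes.reindex(matrix.index) == biotype
        matrix = matrix.loc[keep[keep].index]
    frac = (matrix.values > threshold).mean(axis=1)
    return set(matrix.index[frac >= min_fraction])
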