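"""Promoter PWM scanning with exact p-values and target nomination.

The scanner scores every window of the promoter (TSS ±100 bp by default)
with a log-odds position weight matrix and converts the score to an exact
p-value: the probability, under an i.i.d. background, that a random window
scores at least as high.  The tail is computed once per matrix by a
dynamic-programming convolution of the per-column score distributions on an
integer grid (default granularity: 1/1000 of a log2 odds unit), so the
lookup is exact for the discretized scores the scanner itself uses.

Peak–TSS distance profiling motivates the ±100 bp window: the fraction of
ChIP peaks (with a TSS within 2 kb) whose midpoint lies within ±100 bp of
that TSS.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    gene_id: str
    offset: int  # window start within the scanned sequence
    strand: str  # strand of the match relative to the scanned sequence
    score: float  # log2-odds
    p_value: float


@dataclass
class DistanceProfile:
    distances: np.ndarray  # signed midpoint-to-nearest-TSS distances
    n_within_near: int
    n_within_core: int
    n_skipped: int  # peaks on chroms with no gene

    @property
    def fraction_core(self) -> float:
        if self.n_within_near == 0:
            return float("nan")
        return self.n_within_core / self.n_within_near


@dataclass
class TargetCandidate:
    gene_id: str
    best_hit: MotifHit | None
    deg_direction: str  # "up" | "down"
    pearson_r: float
    pearson_p: float
    de_p: float = float("nan")


class Pwm:
    """A position weight matrix with exact score-to-p-value lookup.

    Parameters
    ----------
    matrix
        4 × width array over (A, C, G, T): probabilities or counts.
        A pseudocount (default 0.1 per cell) is added before column
        normalization, so every probability is strictly positive.
    background
        Length-4 background distribution (default uniform).
    granularity
        Integer grid step for the exact-p dynamic program, in log2-odds
        units.
    """

    def __init__(
        self,
        matrix,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.1,
        granularity: float = 1e-3,
    ) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("matrix must be 4 x width")
        if (m < 0).any():
            raise ValueError("matrix cells must be non-negative")
        m = m + pseudocount
        self.probs = m / m.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be a positive length-4 distribution")
        self.background = bg / bg.sum()
        self.granularity = float(granularity)
        self.log_odds = np.log2(self.probs / self.background[:, None])
        self.int_scores = np.round(self.log_odds / self.granularity).astype(np.int64)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    @cached_property
    def _tail(self) -> tuple[np.ndarray, int]:
        """Survival function of the integer window score under the background.

        Returns (sf, min_total): sf[k] = P(S >= min_total + k).
        """
        col_min = self.int_scores.min(axis=0)
        col_max = self.int_scores.max(axis=0)
        min_total = int(col_min.sum())
        size = int((col_max - col_min).sum()) + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0
        reach = 1  # occupied prefix length
        for j in range(self.width):
            shifts = self.int_scores[:, j] - col_min[j]
            span = int(shifts.max())
            new = np.zeros(reach + span)
            for b in range(4):
                new[shifts[b] : shifts[b] + reach] += self.background[b] * pmf[:reach]
            reach += span
            pmf[:reach] = new
            pmf[reach:] = 0.0
        sf = np.cumsum(pmf[::-1])[::-1]
        return np.minimum(sf, 1.0), min_total

    def pvalue_int(self, int_score) -> np.ndarray:
        """Exact tail probability of integer window score(s)."""
        sf, min_total = self._tail
        idx = np.asarray(int_score, dtype=np.int64) - min_total
        idx = np.clip(idx, 0, len(sf) - 1)
        return sf[idx]

    def pvalue(self, score: float) -> float:
        """Exact p-value for a log2-odds score (discretized to the grid)."""
        return float(self.pvalue_int(np.round(score / self.granularity)))

    def reverse_complemented(self) -> "Pwm":
        rc = Pwm.__new__(Pwm)
        rc.probs = self.probs[::-1, ::-1].copy()
        rc.background = self.background.copy()
        rc.granularity = self.granularity
        rc.log_odds = self.log_odds[::-1, ::-1].copy()
        rc.int_scores = self.int_scores[::-1, ::-1].copy()
        return rc

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_consensus(
        cls, consensus: str, nsites: int = 1000, off_rate: float = 0.0, **kwargs
    ) -> "Pwm":
        """A near-consensus matrix: ``nsites`` observations per column."""
        counts = np.full((4, len(consensus)), nsites * off_rate / 3.0)
        for j, base in enumerate(consensus.upper()):
            counts[:, j][_CODE[ord(base)]] = nsites * (1.0 - off_rate)
        return cls(counts, **kwargs)

    @classmethod
    def from_meme(cls, path: str | Path, **kwargs) -> "Pwm":
        """Read the first motif of a MEME minimal-format motif file.

        When the matrix header carries ``nsites=``, probabilities are
        converted back to counts before the pseudocount is applied, so a
        written matrix round-trips.
        """
        rows: list[list[float]] = []
        in_matrix = False
        nsites = 1.0
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                if stripped.lower().startswith("letter-probability matrix"):
                    in_matrix = True
                    m = re.search(r"nsites=\s*([0-9.]+)", stripped)
                    if m:
                        nsites = float(m.group(1))
                    continue
                if in_matrix:
                    parts = stripped.split()
                    if len(parts) >= 4:
                        try:
                            rows.append([float(x) for x in parts[:4]])
                        except ValueError:
                            break
                    elif rows:
                        break
        if not rows:
            raise ValueError(f"no letter-probability matrix found in {path}")
        return cls(np.asarray(rows).T * nsites, **kwargs)

    def to_meme(self, path: str | Path, name: str = "motif1", nsites: int = 1000) -> None:
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(_BASES, self.background)) + "\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.width} nsites= {nsites}\n"
            )
            for j in range(self.width):
                fh.write(" ".join(f"{self.probs[b, j]:.6f}" for b in range(4)) + "\n")


def background_from_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Base composition of a sequence collection (pseudocount 1 per base)."""
    counts = np.ones(4)
    for seq in seqs:
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = codes[codes >= 0]
        counts += np.bincount(valid, minlength=4)
    return counts / counts.sum()


def _window_scores(codes: np.ndarray, pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores and validity mask for every window of a coded sequence."""
    w = pwm.width
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = pwm.int_scores[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    gene_id: str = "",
) -> list[MotifHit]:
    """Scan a sequence for PWM hits with exact p-value < ``p_threshold``.

    Windows containing N are skipped.  Reported offsets are window starts
    in the scanned sequence; minus-strand hits are matches of the reverse
    complement at that window.  Sequences shorter than the matrix width
    yield an empty list.
    """
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    hits: list[MotifHit] = []
    matrices = [("+", pwm)]
    if both_strands:
        matrices.append(("-", pwm.reverse_complemented()))
    for strand, matrix in matrices:
        scores, valid = _window_scores(codes, matrix)
        if scores.size == 0:
            continue
        pvals = pwm.pvalue_int(scores)
        keep = valid & (pvals < p_threshold)
        for offset in np.flatnonzero(keep):
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    offset=int(offset),
                    strand=strand,
                    score=float(scores[offset] * pwm.granularity),
                    p_value=float(pvals[offset]),
                )
            )
    hits.sort(key=lambda h: (h.p_value, h.offset, h.strand))
    return hits


def extract_promoters(
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | str | Path,
    half_window: int = 100,
) -> dict[str, str]:
    """Extract TSS-centred promoter windows (2·half_window bp).

    The window is [TSS − half_window, TSS + half_window) on the reference
    strand; minus-strand genes are reverse-complemented so the promoter
    reads 5'→3' with respect to the gene.  Genes whose window would run off
    the contig, or whose chromosome is missing, are skipped with a warning.
    """
    if not isinstance(genome, Mapping):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome), sequence_always_upper=True)
        genome = {name: fasta[name] for name in fasta.keys()}
        lengths = {name: len(seq) for name, seq in genome.items()}
    else:
        lengths = {name: len(seq) for name, seq in genome.items()}
    promoters: dict[str, str] = {}
    for m in models:
        if m.chrom not in lengths:
            logger.warning("gene %s: chromosome %s missing from genome", m.gene_id, m.chrom)
            continue
        lo, hi = m.tss - half_window, m.tss + half_window
        if lo < 0 or hi > lengths[m.chrom]:
            logger.warning("gene %s: promoter window truncated at contig edge", m.gene_id)
            continue
        seq = str(genome[m.chrom][lo:hi]).upper()
        promoters[m.gene_id] = reverse_complement(seq) if m.strand == "-" else seq
    return promoters


def peak_tss_profile(
    peaks: pd.DataFrame,
    models: Sequence[GeneModel],
    near: int = 2000,
    core: int = 100,
) -> DistanceProfile:
    """Signed distance from each peak midpoint to the nearest protein-coding TSS.

    ``fraction_core`` is computed only over peaks with |distance| ≤ near.
    Peaks on chromosomes without any gene are skipped and counted.
    A ``summit`` column, when present, overrides the midpoint.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for m in models:
        if m.biotype != "protein_coding":
            continue
        tss_by_chrom.setdefault(m.chrom, []).append(m.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    distances: list[int] = []
    skipped = 0
    for row in peaks.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in tss_by_chrom:
            skipped += 1
            continue
        if hasattr(row, "summit") and not pd.isna(row.summit):
            point = int(row.start) + int(row.summit)
        else:
            point = (int(row.start) + int(row.end)) // 2
        tss = tss_by_chrom[chrom]
        i = np.searchsorted(tss, point)
        best = min(
            (abs(point - tss[j]), point - tss[j])
            for j in (max(i - 1, 0), min(i, len(tss) - 1))
        )[1]
        distances.append(int(best))
    dist = np.asarray(distances, dtype=np.int64)
    if skipped:
        logger.warning("%d peak(s) on chromosomes with no gene were skipped", skipped)
    within_near = np.abs(dist) <= near
    within_core = np.abs(dist) <= core
    return DistanceProfile(
        distances=dist,
        n_within_near=int(within_near.sum()),
        n_within_core=int((within_near & within_core).sum()),
        n_skipped=skipped,
    )


def best_hits(
    promoters: Mapping[str, str],
    pwm: Pwm,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> dict[str, MotifHit]:
    """Best (lowest-p) hit per promoter; genes without a hit are absent."""
    out: dict[str, MotifHit] = {}
    for gene_id, seq in promoters.items():
        hits = scan_pwm(seq, pwm, p_threshold=p_threshold, both_strands=both_strands, gene_id=gene_id)
        if hits:
            out[gene_id] = hits[0]
    return out


def motif_positive_genes(
    promoters: Mapping[str, str],
    pwm: Pwm,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> set[str]:
    """Genes with ≥1 sub-threshold hit anywhere in their promoter window."""
    return set(best_hits(promoters, pwm, p_threshold, both_strands))


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value (n−2 df).

    Raises on length mismatch, n < 3, or zero variance in either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def nominate_targets(
    motif_hits: Mapping[str, MotifHit] | set[str],
    degs,
    fpkm: pd.DataFrame,
    tf_gene: str,
    samples_in_scope: Sequence[str],
    de_pvalues: Mapping[str, float] | None = None,
) -> list[TargetCandidate]:
    """Nominate direct targets: motif-positive DEGs with TF co-expression.

    Candidates are the intersection of the motif-positive genes and the
    up/down DEG sets, each annotated with its best motif hit and the
    Pearson correlation (on log2(FPKM+1)) between the TF and the candidate
    across ``samples_in_scope``.  Sorted by DE p-value when provided.
    """
    if tf_gene not in fpkm.index:
        raise KeyError(f"TF gene {tf_gene!r} absent from FPKM matrix")
    if isinstance(motif_hits, Mapping):
        hit_of = dict(motif_hits)
    else:
        hit_of = {g: None for g in motif_hits}
    samples_in_scope = list(samples_in_scope)
    tf_values = np.log2(fpkm.loc[tf_gene, samples_in_scope].to_numpy(dtype=float) + 1.0)
    candidates: list[TargetCandidate] = []
    for gene in sorted(hit_of):
        if gene in degs.up:
            direction = "up"
        elif gene in degs.down:
            direction = "down"
        else:
            continue
        if gene not in fpkm.index:
            logger.warning("candidate %s absent from FPKM matrix; skipped", gene)
            continue
        g_values = np.log2(fpkm.loc[gene, samples_in_scope].to_numpy(dtype=float) + 1.0)
        try:
            r, p = pearson(tf_values, g_values)
        except ValueError:
            logger.warning("candidate %s: zero-variance expression; r set to 0", gene)
            r, p = 0.0, 1.0
        candidates.append(
            TargetCandidate(
                gene_id=gene,
                best_hit=hit_of[gene],
                deg_direction=direction,
                pearson_r=r,
                pearson_p=p,
                de_p=float(de_pvalues[gene]) if de_pvalues is not None else float("nan"),
            )
        )
    candidates.sort(key=lambda c: (c.de_p if not math.isnan(c.de_p) else 1.0, c.gene_id))
    return candidates
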