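"""Cis-activation evidence: allele-specific expression, focal deletions, and
TAD-boundary disruption.

An outlier sample is a *cis-candidate* when three independent lines of
evidence line up: the gene is an expression outlier, the RNA shows
allele-specific expression (ASE — a same-allele lesion drives one
haplotype), and a structural lesion disrupts a boundary of the
topologically associating domain (TAD) containing the gene, which can
rewire enhancer–promoter contacts.

ASE is tested per heterozygous marker with a two-sided exact binomial test
against 0.5; the gene-level call requires more than half of the covered
markers to be individually significant and skewed in the same direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

from .io import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class MarkerTest:
    marker_id: str
    n: int
    ref_fraction: float
    p_binomial: float


@dataclass
class AseResult:
    gene_id: str
    markers: list[MarkerTest] = field(default_factory=list)
    gene_call: str = "insufficient"  # ASE | balanced | insufficient
    direction: str = "mixed"  # ref | alt | mixed


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    log2_ratio: float
    loh_segment_mean: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNV segment start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DeletionCall:
    classification: str  # focal_deletion | neutral
    loh_supported: bool
    length: int


@dataclass
class CisEvidenceReport:
    gene_id: str
    sample_id: str
    outlier: bool
    ase: AseResult
    deletion: CnvSegment | None
    deletion_class: DeletionCall | None
    boundary_disrupted: bool
    distance_to_tss: int | None
    verdict: str  # cis-candidate | insufficient


def ase_test(
    table: pd.DataFrame,
    min_coverage: int = 10,
    alpha: float = 0.05,
) -> dict[str, AseResult]:
    """Allele-specific-expression call per gene from RNA allele counts.

    ``table`` columns: marker_id, chrom, pos, gene_id, ref_count, alt_count.
    Markers with ref+alt below ``min_coverage`` are ignored.  A gene is
    called ASE when strictly more than half of its covered markers have a
    two-sided binomial p < ``alpha`` *and* all those significant markers
    share the same skew direction; genes with no covered marker are
    ``insufficient``, the rest ``balanced``.
    """
    results: dict[str, AseResult] = {}
    for gene_id, rows in table.groupby("gene_id", sort=True):
        res = AseResult(gene_id=str(gene_id))
        sig_dirs: list[str] = []
        for row in rows.itertuples(index=False):
            ref, alt = int(row.ref_count), int(row.alt_count)
            n = ref + alt
            if n < min_coverage:
                continue
            p = float(stats.binomtest(ref, n, 0.5).pvalue)
            res.markers.append(
                MarkerTest(str(row.marker_id), n, ref / n, min(p, 1.0))
            )
            if p < alpha and ref != alt:
                sig_dirs.append("ref" if ref > alt else "alt")
        if not res.markers:
            res.gene_call = "insufficient"
        else:
            n_sig = len(sig_dirs)
            same_dir = len(set(sig_dirs)) == 1
            if n_sig * 2 > len(res.markers) and same_dir:
                res.gene_call = "ASE"
                res.direction = sig_dirs[0]
            else:
                res.gene_call = "balanced"
                res.direction = sig_dirs[0] if same_dir and sig_dirs else "mixed"
        results[str(gene_id)] = res
    return results


def classify_deletion(
    segment: CnvSegment,
    log2_cut: float = -0.4,
    loh_cut: float = 0.2,
) -> DeletionCall:
    """Classify a copy-number segment as focal deletion or neutral.

    ``focal_deletion`` iff log2 ratio ≤ ``log2_cut`` (inclusive); the call
    is LOH-supported when the accompanying LOH segment mean (an opaque
    annotated score) is ≥ ``loh_cut``.
    """
    is_del = segment.log2_ratio <= log2_cut
    loh_ok = (
        is_del
        and segment.loh_segment_mean is not None
        and not (isinstance(segment.loh_segment_mean, float) and math.isnan(segment.loh_segment_mean))
        and segment.loh_segment_mean >= loh_cut
    )
    return DeletionCall(
        classification="focal_deletion" if is_del else "neutral",
        loh_supported=bool(loh_ok),
        length=segment.length,
    )


def _tad_intervals(tads: pd.DataFrame | Iterable, chrom: str) -> list[tuple[int, int]]:
    if isinstance(tads, pd.DataFrame):
        rows = tads[tads["chrom"].astype(str) == chrom][["start", "end"]].itertuples(index=False)
        intervals = [(int(s), int(e)) for s, e in rows]
    else:
        intervals = [(int(s), int(e)) for c, s, e in tads if str(c) == chrom]
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping TADs on {chrom}: [{s1},{e1}) and [{s2},{e2})")
    return intervals


def boundary_disruption(
    deletion: CnvSegment,
    tads: pd.DataFrame,
    gene: GeneModel,
    flank: int = 5000,
    max_distance: int = 500_000,
) -> tuple[bool, int]:
    """Does the deletion disrupt a TAD boundary near the gene?

    True iff the deletion intersects ``[b − flank, b + flank)`` for some
    boundary ``b`` of the TAD containing the gene's TSS or of an adjacent
    TAD, and the deletion lies within ``max_distance`` of the TSS
    (distance 0 when the deletion overlaps the gene).  Returns
    ``(disrupted, distance_to_tss)``.
    """
    tss = gene.tss
    if deletion.chrom != gene.chrom:
        return False, 2**62
    intervals = _tad_intervals(tads, gene.chrom)
    home = next((i for i, (s, e) in enumerate(intervals) if s <= tss < e), None)
    if home is None:
        logger.warning("gene %s TSS not inside any TAD", gene.gene_id)
        return False, _deletion_tss_distance(deletion, gene)
    boundaries: set[int] = set()
    for i in (home - 1, home, home + 1):
        if 0 <= i < len(intervals):
            boundaries.update(intervals[i])
    distance = _deletion_tss_distance(deletion, gene)
    touches = any(
        deletion.start < b + flank and deletion.end > b - flank for b in boundaries
    )
    return bool(touches and distance <= max_distance), distance


def _deletion_tss_distance(deletion: CnvSegment, gene: GeneModel) -> int:
    """Min distance (bp) from the deletion to the TSS; 0 if it overlaps the gene."""
    if deletion.start < gene.end and deletion.end > gene.start:
        return 0
    tss = gene.tss
    if tss < deletion.start:
        return deletion.start - tss
    if tss >= deletion.end:
        return tss - deletion.end + 1
    return 0


def integrate_cis(
    gene_id: str,
    sample_id: str,
    outlier_flag: bool,
    ase: AseResult,
    deletion: CnvSegment | None = None,
    deletion_class: DeletionCall | None = None,
    disruption: tuple[bool, int] | None = None,
) -> CisEvidenceReport:
    """Combine the three evidence lines into a per-sample verdict.

    ``cis-candidate`` requires outlier expression AND an ASE gene call AND
    a disrupted TAD boundary; anything less is ``insufficient``.
    """
    disrupted, distance = disruption if disruption is not None else (False, None)
    verdict = (
        "cis-candidate"
        if outlier_flag and ase.gene_call == "ASE" and disrupted
        else "insufficient"
    )
    return CisEvidenceReport(
        gene_id=gene_id,
        sample_id=sample_id,
        outlier=bool(outlier_flag),
        ase=ase,
        deletion=deletion,
        deletion_class=deletion_class,
        boundary_disrupted=bool(disrupted),
        distance_to_tss=distance,
        verdict=verdict,
    )
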