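"""Per-subtype outlier-activation calling and nonparametric group comparisons.

A sample is called an outlier for the focal gene when its FPKM strictly
exceeds ``mean + k * sd`` of the gene's FPKM within the sample's molecular
subtype (k = 3 by default; sd uses the n−1 denominator).  Calling within
subtypes absorbs the strong baseline differences between subtypes.  The
subtype mean/sd include the candidate sample itself by default — the
conservative choice — with a leave-one-out variant behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OutlierCall:
    """Outlier threshold and flagged samples for one subtype."""

    gene_id: str
    subtype: str
    n_samples: int
    mean_fpkm: float
    sd_fpkm: float
    threshold: float
    outlier_samples: list[str] = field(default_factory=list)


@dataclass
class RankTestResult:
    statistic: float  # rank-sum W of group A
    n_a: int
    n_b: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


def call_subtype_outliers(
    fpkm_row: pd.Series,
    samples: pd.DataFrame,
    gene_id: str = "",
    k: float = 3.0,
    min_subtype_n: int = 3,
    leave_one_out: bool = False,
) -> list[OutlierCall]:
    """Call outlier samples for the focal gene, one call per subtype.

    Subtypes with fewer than ``min_subtype_n`` samples are skipped with a
    logged warning (a sample sd is meaningless there).  With
    ``leave_one_out=True`` each sample is compared against the mean/sd of
    the *other* samples of its subtype; the reported threshold is still the
    all-sample one.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    calls: list[OutlierCall] = []
    for subtype, sub in samples.groupby("subtype", sort=True):
        ids = [s for s in sub["sample_id"] if s in fpkm_row.index]
        if len(ids) < min_subtype_n:
            logger.warning(
                "subtype %s has %d samples (< %d); skipped", subtype, len(ids), min_subtype_n
            )
            continue
        values = fpkm_row.loc[ids].to_numpy(dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        threshold = mean + k * sd
        if leave_one_out:
            flagged = []
            n = len(values)
            total, total_sq = values.sum(), (values**2).sum()
            for i, sid in enumerate(ids):
                m = (total - values[i]) / (n - 1)
                var = (total_sq - values[i] ** 2 - (n - 1) * m**2) / max(n - 2, 1)
                s = math.sqrt(max(var, 0.0))
                if values[i] > m + k * s:
                    flagged.append(sid)
        else:
            flagged = [sid for sid, v in zip(ids, values) if v > threshold]
        calls.append(
            OutlierCall(
                gene_id=gene_id,
                subtype=str(subtype),
                n_samples=len(ids),
                mean_fpkm=mean,
                sd_fpkm=sd,
                threshold=threshold,
                outlier_samples=flagged,
            )
        )
    return calls


def assign_groups(calls: list[OutlierCall], samples: pd.DataFrame) -> pd.Series:
    """Partition samples into outlier / normal / excluded.

    Samples of subtypes with at least one outlier call are partitioned into
    the outlier and normal groups; samples of all other subtypes (including
    subtypes skipped during calling) are excluded.
    """
    outliers = {s for c in calls for s in c.outlier_samples}
    active_subtypes = {c.subtype for c in calls if c.outlier_samples}
    labels = {}
    for sid, subtype in zip(samples["sample_id"], samples["subtype"]):
        if str(subtype) not in active_subtypes:
            labels[sid] = "excluded"
        elif sid in outliers:
            labels[sid] = "outlier"
        else:
            labels[sid] = "normal"
    return pd.Series(labels, name="group")


def rank_sum_test(values_a, values_b, exact_limit: int = 12) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    The exact null distribution (enumeration over rank assignments) is used
    when ``n_a + n_b <= exact_limit`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.  Identical
    constant data in both groups yields p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return RankTestResult(w, a.size, b.size, 1.0, "exact")
    if a.size + b.size <= exact_limit and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    p = float(min(res.pvalue, 1.0))
    if math.isnan(p):  # zero tie-corrected variance
        p = 1.0
    return RankTestResult(w, a.size, b.size, p, method)


def group_expression_summary(fpkm_row: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    """Per-group n / median / mean FPKM for an arbitrary sample labelling.

    Labels must cover the samples of ``fpkm_row``; empty groups are omitted.
    """
    grouping = grouping.reindex(fpkm_row.index)
    if grouping.isna().any():
        missing = fpkm_row.index[grouping.isna()][0]
        raise ValueError(f"sample {missing!r} has no group label")
    rows = []
    for label, values in fpkm_row.groupby(grouping):
        if len(values) == 0:
            continue
        rows.append((label, len(values), float(values.median()), float(values.mean())))
    return pd.DataFrame(rows, columns=["group", "n", "median_fpkm", "mean_fpkm"]).set_index(
        "group"
    )


def outlier_calls_frame(calls: list[OutlierCall]) -> pd.DataFrame:
    """Tabulate outlier calls for the TSV stage output."""
    return pd.DataFrame(
        [
            (
                c.gene_id,
                c.subtype,
                c.n_samples,
                c.mean_fpkm,
                c.sd_fpkm,
                c.threshold,
                ";".join(c.outlier_samples),
            )
            for c in calls
        ],
        columns=["gene_id", "subtype", "n", "mean_fpkm", "sd_fpkm", "threshold", "outliers"],
    )
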