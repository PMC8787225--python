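"""Covariate-adjusted negative-binomial differential expression and enrichment.

The group contrast (outlier vs normal) is fitted per gene with a
log-link NB GLM::

    y_i ~ NB(mu_i, alpha),   log mu_i = offset_i + x_i' beta

where the offset is the log library size, the design holds an intercept,
the group indicator, and one-hot subtype (and optionally batch) covariates.
The per-gene dispersion ``alpha`` is estimated by method of moments
(Pearson chi-square matching against a Poisson fit, floored at 1e-8), the
coefficients by iteratively reweighted least squares, and the group effect
is tested with a Wald z on its coefficient.  No shrinkage of dispersions or
fold changes is applied, and DEGs are called on raw p-values
(|fold change| > 1.5 and p < 0.05 by default), both thresholds strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
_MIN_ALPHA = 1e-8


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2_fc: float  # outlier vs normal
    p_value: float
    converged: bool
    dispersion: float = float("nan")


@dataclass
class DEGSets:
    up: set[str]
    down: set[str]
    fc: float = 1.5
    p: float = 0.05


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float


@dataclass
class MarkerPanel:
    name: str
    gene_ids: set[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"marker panel {self.name!r} is empty")


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    samples: pd.DataFrame,
    groups: pd.Series,
    covariates: Sequence[str] = ("subtype",),
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the model matrix for the outlier-vs-normal contrast.

    Returns (X, column names, sample ids in design order).  Samples labelled
    "excluded" are dropped.  Each covariate is one-hot encoded with its most
    frequent level as the reference; constant covariates are dropped.
    """
    in_scope = groups[groups.isin(["outlier", "normal"])]
    if (in_scope == "outlier").sum() < 2 or (in_scope == "normal").sum() < 2:
        raise ValueError("need at least 2 samples in each of the outlier/normal groups")
    ids = list(in_scope.index)
    sub = samples.loc[ids]
    cols = [np.ones(len(ids)), (in_scope == "outlier").to_numpy(float)]
    names = ["intercept", "group_outlier"]
    for cov in covariates:
        if cov not in sub.columns:
            continue
        values = sub[cov].astype(str)
        levels = values.value_counts()
        if len(levels) < 2 or values.isna().all():
            continue
        reference = levels.index[0]
        for level in sorted(l for l in levels.index if l != reference):
            cols.append((values == level).to_numpy(float))
            names.append(f"{cov}_{level}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names, ids


# ---------------------------------------------------------------------------
# vectorized NB GLM


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    beta0: np.ndarray,
    alpha: np.ndarray | None,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for Poisson (alpha None) or NB log-link GLMs.

    Y: (G, n) counts; X: (n, p); beta0: (G, p); alpha: (G,) dispersions.
    Returns (beta, XtWX at the optimum, converged mask).
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = beta0.copy()
    converged = np.zeros(G, dtype=bool)
    A = np.zeros((G, p, p))
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta + offsets)
        mu = np.maximum(mu, 1e-10)
        if alpha is None:
            W = mu
        else:
            W = mu / (1.0 + alpha[:, None] * mu)
        Z = eta + (Y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
        b = np.einsum("ni,gn,gn->gi", X, W, Z, optimize=True)
        # ridge jitter keeps near-singular systems solvable; flagged below
        A_reg = A + 1e-10 * np.eye(p)
        try:
            new = np.linalg.solve(A_reg, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.stack(
                [np.linalg.lstsq(A_reg[g], b[g], rcond=None)[0] for g in range(G)]
            )
        new = np.clip(new, -30.0, 30.0)
        delta = np.abs(new - beta).max(axis=1)
        beta = new
        converged = delta < max(tol, 1e-8)
        if converged.all():
            break
    return beta, A, converged


def _estimate_dispersion(Y: np.ndarray, mu: np.ndarray, p: int) -> np.ndarray:
    """Method-of-moments dispersion: solve the Pearson chi-square equation.

    For each gene find alpha >= 0 with
    ``sum (y-mu)^2 / (mu + alpha mu^2) = n - p`` (monotone decreasing in
    alpha); alpha is floored at 1e-8 when even alpha=0 over-disperses.
    """
    G, n = Y.shape
    dof = max(n - p, 1)
    resid_sq = (Y - mu) ** 2

    def pearson(alpha: np.ndarray) -> np.ndarray:
        return (resid_sq / (mu + alpha[:, None] * mu**2)).sum(axis=1) - dof

    lo = np.full(G, 0.0)
    hi = np.full(G, 1.0)
    at_zero = pearson(lo)
    needs = at_zero > 0  # over-dispersed relative to Poisson
    for _ in range(60):  # grow hi until bracketing
        still = needs & (pearson(hi) > 0) & (hi < 1e4)
        if not still.any():
            break
        hi[still] *= 4.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        high = pearson(mid) > 0
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
    alpha = 0.5 * (lo + hi)
    alpha[~needs] = 0.0
    return np.maximum(alpha, _MIN_ALPHA)


def fit_nb_glm_many(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    groups: pd.Series,
    offsets: pd.Series | None = None,
    covariates: Sequence[str] = ("subtype",),
    alpha: float | None = None,
) -> pd.DataFrame:
    """Fit the NB GLM for every gene (row) of ``counts`` at once.

    ``offsets`` are log library sizes (defaults to log column sums of the
    full matrix passed in).  Returns a DataFrame indexed by gene with
    columns base_mean, log2_fc, p_value, converged, dispersion.
    ``alpha`` fixes the dispersion for every gene (used for limit tests);
    by default it is estimated per gene.
    """
    X, names, ids = build_design(samples, groups, covariates)
    Y = counts.loc[:, ids].to_numpy(dtype=float)
    if offsets is None:
        offsets_arr = np.log(counts.loc[:, ids].sum(axis=0).to_numpy(dtype=float))
    else:
        offsets_arr = offsets.loc[ids].to_numpy(dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    group_idx = names.index("group_outlier")

    nonzero = Y.sum(axis=1) > 0
    log2_fc = np.zeros(G)
    p_value = np.ones(G)
    converged = np.ones(G, dtype=bool)
    dispersion = np.full(G, np.nan)
    norm = np.exp(offsets_arr.mean() - offsets_arr)
    base_mean = (Y * norm).mean(axis=1)

    if nonzero.any():
        Ynz = Y[nonzero]
        # init from a log-linear least squares fit
        z0 = np.log(Ynz + 0.5) - offsets_arr
        beta0 = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
        # Poisson fit for the dispersion estimate
        beta_pois, _, _ = _irls(Ynz, X, offsets_arr, beta0, alpha=None, max_iter=30)
        mu_pois = np.exp(np.clip(beta_pois @ X.T, -30, 30) + offsets_arr)
        if alpha is None:
            alpha_vec = _estimate_dispersion(Ynz, mu_pois, p)
        else:
            alpha_vec = np.full(Ynz.shape[0], max(alpha, _MIN_ALPHA))
        beta, A, conv = _irls(Ynz, X, offsets_arr, beta_pois, alpha=alpha_vec)
        cov = np.linalg.inv(A + 1e-10 * np.eye(p))
        se = np.sqrt(np.maximum(cov[:, group_idx, group_idx], 1e-300))
        z = beta[:, group_idx] / se
        # Wald test against t with residual df: with moment-estimated
        # dispersions the normal reference is anticonservative at small n
        dof = n - p
        if dof > 0:
            pvals = 2.0 * stats.t.sf(np.abs(z), dof)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals[~conv] = 1.0
        log2_fc[nonzero] = beta[:, group_idx] / LN2
        p_value[nonzero] = pvals
        converged[nonzero] = conv
        dispersion[nonzero] = alpha_vec
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "p_value": p_value,
            "converged": converged,
            "dispersion": dispersion,
        },
        index=counts.index,
    )


def fit_nb_glm(
    counts_gene: pd.Series,
    samples: pd.DataFrame,
    groups: pd.Series,
    offsets: pd.Series | None = None,
    covariates: Sequence[str] = ("subtype",),
    alpha: float | None = None,
    gene_id: str = "",
) -> DEResult:
    """Fit the NB GLM for a single gene (thin wrapper over the batched fit)."""
    frame = counts_gene.to_frame().T
    frame.index = [gene_id or (counts_gene.name or "gene")]
    if offsets is None:
        raise ValueError("offsets (log library sizes) are required for a single gene")
    res = fit_nb_glm_many(
        frame, samples, groups, offsets=offsets, covariates=covariates, alpha=alpha
    ).iloc[0]
    return DEResult(
        gene_id=frame.index[0],
        base_mean=float(res["base_mean"]),
        log2_fc=float(res["log2_fc"]),
        p_value=float(res["p_value"]),
        converged=bool(res["converged"]),
        dispersion=float(res["dispersion"]),
    )


# ---------------------------------------------------------------------------
# DEG calling and enrichment


def call_degs(
    results: pd.DataFrame | Iterable[DEResult], fc: float = 1.5, p: float = 0.05
) -> DEGSets:
    """Call DEGs at |fold change| > fc and p < p-threshold (both strict)."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [(r.gene_id, r.log2_fc, r.p_value) for r in results],
            columns=["gene_id", "log2_fc", "p_value"],
        ).set_index("gene_id")
    log2_cut = math.log2(fc)
    sig = results["p_value"] < p
    up = set(results.index[sig & (results["log2_fc"] > log2_cut)])
    down = set(results.index[sig & (results["log2_fc"] < -log2_cut)])
    return DEGSets(up=up, down=down, fc=fc, p=p)


def fisher_exact(table) -> ContingencyResult:
    """Fisher's exact test on a 2×2 table.

    One-sided p is the hypergeometric upper tail at the observed top-left
    cell (enrichment); two-sided p sums all margin-fixed tables whose point
    probability does not exceed the observed one (minimum-likelihood rule).
    A zero margin yields p = 1 for both.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    a, b_, c, d = t.ravel()
    n_total = t.sum()
    row1, col1 = a + b_, a + c
    if 0 in (row1, col1, n_total - row1, n_total - col1):
        odds = float("nan")
        return ContingencyResult(t, odds, 1.0, 1.0)
    odds = float("inf") if b_ * c == 0 else (a * d) / (b_ * c)
    p_one = float(stats.hypergeom.sf(a - 1, n_total, row1, col1))
    p_two = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return ContingencyResult(t, odds, min(p_one, 1.0), min(p_two, 1.0))


def marker_enrichment(
    degs: DEGSets,
    panel: MarkerPanel,
    universe: set[str],
    direction: str = "up",
) -> ContingencyResult:
    """Fisher test of a marker panel against one DEG direction.

    The 2×2 table is [[panel∩DEG, panel∖DEG], [nonpanel∩DEG, nonpanel∖DEG]]
    over ``universe``.  Panel members missing from the universe are logged
    and dropped; a panel disjoint from the universe is an error.
    """
    if not universe:
        raise ValueError("universe is empty")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    in_universe = panel.gene_ids & universe
    missing = panel.gene_ids - universe
    if missing:
        logger.warning(
            "panel %s: %d member(s) absent from universe: %s",
            panel.name,
            len(missing),
            sorted(missing)[:5],
        )
    if not in_universe:
        raise ValueError(f"panel {panel.name!r} is disjoint from the universe")
    deg = (degs.up if direction == "up" else degs.down) & universe
    a = len(in_universe & deg)
    b = len(in_universe - deg)
    c = len(deg - in_universe)
    d = len(universe) - a - b - c
    return fisher_exact([[a, b], [c, d]])


def overrepresentation(
    genes: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each gene set.

    Per set: overlap k, upper-tail hypergeometric p, and Benjamini–Hochberg
    q over the tested sets; sorted by ascending p.
    """
    if not universe:
        raise ValueError("universe is empty")
    genes = genes & universe
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(genes)))
        rows.append((name, len(members), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)
    return out
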