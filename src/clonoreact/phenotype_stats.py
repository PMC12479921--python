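"""Group-wise expression statistics.

Cell-level differential expression between two groups uses the two-sided
Wilcoxon rank-sum test per gene on log-normalized values, after removal of
TCR-alpha/beta genes, with Benjamini-Hochberg FDR control and an average
log2 fold-change cutoff.  Donor-level analysis aggregates raw counts into
pseudobulk profiles normalized to counts per million.  Small paired
comparisons use an exact signed-rank test by enumeration.

The fold change reported per gene is
``log2((mean(expm1(x_g1)) + 1) / (mean(expm1(x_g2)) + 1))`` over the
log-normalized values ``x``: means are taken on the back-transformed
(de-logged) scale with a pseudocount of 1.

Sample-level differential testing here is a rank test on per-million
pseudobulk values across donors — a deliberate simplification of a
negative-binomial GLM, adequate for the small donor cohorts this package
targets; its output tables say so in their header.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG
from .errors import UndefinedStatisticError, ValidationError
from .io_formats import CountsMatrix

logger = logging.getLogger("clonoreact")

TCR_GENE_PREFIXES = ("TRAV", "TRAJ", "TRAC", "TRBV", "TRBD", "TRBJ", "TRBC")

EXACT_RANKSUM_MAX_N = 25  # exact enumeration below this per-group size
EXACT_SIGNED_RANK_MAX_N = 20


@dataclass
class DEResult:
    gene: str
    avg_log2fc: float
    p_value: float
    adj_p_value: float
    pct_expr_group1: float
    pct_expr_group2: float
    significant_up: bool
    significant_down: bool


@dataclass
class PseudobulkMatrix:
    """Donor-level sums of single-cell counts, with per-million values."""

    sample_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray  # genes x samples, integer
    per_million: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Gene stripping and normalization
# ---------------------------------------------------------------------------


def strip_tcr_genes(gene_ids: Sequence[str]) -> list[str]:
    """Drop TCR-alpha/beta segment genes (TRAV/TRAJ/TRAC/TRBV/TRBD/TRBJ/
    TRBC prefixes); order of the remainder is preserved."""
    return [
        g for g in gene_ids if not any(g.startswith(p) for p in TCR_GENE_PREFIXES)
    ]


def normalize_cells(
    matrix: CountsMatrix, scale: float = DEFAULT_CONFIG.normalize_scale
) -> np.ndarray:
    """Library-size normalize and log-transform:
    ``ln(1 + count * scale / library_size)`` per entry (dense output)."""
    lib = matrix.library_sizes.astype(float)
    if np.any(lib == 0):
        bad = matrix.barcodes[int(np.flatnonzero(lib == 0)[0])]
        raise ValidationError(f"cell {bad}: zero library size")
    dense = np.asarray(matrix.values.todense(), dtype=float)
    return np.log1p(dense * (scale / lib)[None, :])


# ---------------------------------------------------------------------------
# Rank-sum DE
# ---------------------------------------------------------------------------


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p via scipy's exact method (tie-free
    inputs); falls back to the asymptotic form when ties are present."""
    pooled = np.concatenate([x, y])
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_de(
    normalized: np.ndarray,
    gene_ids: Sequence[str],
    labels: Sequence[str],
    group1: str,
    group2: str,
    *,
    fc_cutoff: float = DEFAULT_CONFIG.fc_cutoff,
    alpha: float = DEFAULT_CONFIG.alpha,
    min_pct: float = DEFAULT_CONFIG.min_pct,
) -> list[DEResult]:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    ``normalized`` is genes x cells (output of :func:`normalize_cells`,
    with TCR genes already stripped).  Genes are tested only when expressed
    in at least ``min_pct`` of cells in at least one group.  P-values use
    exact enumeration when both groups have <= 25 cells (tie-free),
    otherwise the normal approximation with tie and continuity correction.
    Positive ``avg_log2fc`` means higher in ``group1``.
    """
    labels = np.asarray(labels)
    mask1 = labels == group1
    mask2 = labels == group2
    if not mask1.any() or not mask2.any():
        raise ValidationError(
            f"both groups must be non-empty (got {int(mask1.sum())} vs "
            f"{int(mask2.sum())} cells)"
        )
    x1 = normalized[:, mask1]
    x2 = normalized[:, mask2]
    n1, n2 = x1.shape[1], x2.shape[1]

    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)
    testable = (pct1 >= min_pct) | (pct2 >= min_pct)
    if not testable.any():
        logger.warning("no gene passes the min_pct filter; empty DE result")
        return []

    idx = np.flatnonzero(testable)
    if n1 <= EXACT_RANKSUM_MAX_N and n2 <= EXACT_RANKSUM_MAX_N:
        pvals = np.array(
            [_exact_ranksum_p(x1[i], x2[i]) for i in idx]
        )
    else:
        res = scipy.stats.mannwhitneyu(
            x1[idx], x2[idx], alternative="two-sided", method="asymptotic", axis=1
        )
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)

    mean_bt1 = np.expm1(x1[idx]).mean(axis=1)
    mean_bt2 = np.expm1(x2[idx]).mean(axis=1)
    log2fc = np.log2((mean_bt1 + 1.0) / (mean_bt2 + 1.0))

    adj = bh_adjust(list(pvals))
    results: list[DEResult] = []
    for k, i in enumerate(idx):
        up = log2fc[k] > fc_cutoff and adj[k] < alpha
        down = log2fc[k] < -fc_cutoff and adj[k] < alpha
        results.append(
            DEResult(
                gene=gene_ids[i],
                avg_log2fc=float(log2fc[k]),
                p_value=float(pvals[k]),
                adj_p_value=float(adj[k]),
                pct_expr_group1=float(pct1[i]),
                pct_expr_group2=float(pct2[i]),
                significant_up=bool(up),
                significant_down=bool(down),
            )
        )
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in np.clip(adj, 0.0, 1.0)]


# ---------------------------------------------------------------------------
# Pseudobulk
# ---------------------------------------------------------------------------


def pseudobulk(
    matrix: CountsMatrix, sample_labels: Sequence[Optional[str]]
) -> PseudobulkMatrix:
    """Sum raw counts per (gene, sample).  Every cell must carry a sample
    label; total mass is conserved exactly (integer arithmetic)."""
    if len(sample_labels) != len(matrix.barcodes):
        raise ValidationError("one sample label per cell is required")
    for bc, lab in zip(matrix.barcodes, sample_labels):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            raise ValidationError(f"cell {bc}: missing sample label")
    sample_ids = sorted(set(str(l) for l in sample_labels))
    col_of = {s: j for j, s in enumerate(sample_ids)}
    indicator = sp.csr_matrix(
        (
            np.ones(len(sample_labels), dtype=np.int64),
            (np.arange(len(sample_labels)), [col_of[str(l)] for l in sample_labels]),
        ),
        shape=(len(sample_labels), len(sample_ids)),
    )
    summed = np.asarray((matrix.values @ indicator).todense(), dtype=np.int64)
    pb = PseudobulkMatrix(
        sample_ids=sample_ids,
        gene_ids=list(matrix.gene_ids),
        counts=summed,
    )
    pb.per_million = fpm_normalize(pb)
    return pb


def fpm_normalize(pb: PseudobulkMatrix) -> np.ndarray:
    """Per-million scaling of pseudobulk counts: each sample column sums
    to 1e6."""
    totals = pb.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = pb.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValidationError(f"sample {bad}: zero pseudobulk total")
    return pb.counts * (1e6 / totals)[None, :]


def pseudobulk_rank_de(
    pb: PseudobulkMatrix,
    sample_groups: Sequence[str],
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Donor-level rank-sum test per gene on per-million pseudobulk values
    (a declared simplification of a count-model fit; see module docstring).
    Returns a DataFrame with per-gene p and BH-adjusted p."""
    groups = np.asarray(sample_groups)
    if len(groups) != len(pb.sample_ids):
        raise ValidationError("one group label per pseudobulk sample required")
    fpm = pb.per_million if pb.per_million is not None else fpm_normalize(pb)
    x1 = fpm[:, groups == group1]
    x2 = fpm[:, groups == group2]
    if x1.shape[1] == 0 or x2.shape[1] == 0:
        raise ValidationError("both donor groups must be non-empty")
    pvals = [
        exact_rank_sum(x1[i], x2[i])
        if x1.shape[1] <= EXACT_RANKSUM_MAX_N
        and x2.shape[1] <= EXACT_RANKSUM_MAX_N
        else _exact_ranksum_p(x1[i], x2[i])
        for i in range(fpm.shape[0])
    ]
    return pd.DataFrame(
        {
            "gene": pb.gene_ids,
            "mean_fpm_group1": x1.mean(axis=1),
            "mean_fpm_group2": x2.mean(axis=1),
            "p_value": pvals,
            "adj_p_value": bh_adjust(pvals),
        }
    )


# ---------------------------------------------------------------------------
# Exact small-n tests
# ---------------------------------------------------------------------------


def exact_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p (Mann-Whitney) for small
    groups, with ties handled by mid-ranks over the full enumeration of
    group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n + m), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def exact_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped; |differences| are mid-ranked and the
    positive-rank sum is referred to the full enumeration of the 2^n sign
    assignments.  The two-sided p doubles the smaller tail (inclusive),
    capped at 1 — the convention of R's ``wilcox.test`` exact path.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedStatisticError(
            "signed-rank test undefined: all paired differences are zero"
        )
    if n > EXACT_SIGNED_RANK_MAX_N:
        raise ValidationError(
            f"exact signed-rank enumeration limited to "
            f"{EXACT_SIGNED_RANK_MAX_N} non-zero pairs (got {n})"
        )
    ranks = scipy.stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    sums = np.zeros(1)
    # incremental enumeration of all 2^n sign assignments
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    p_low = np.mean(sums <= t_obs + 1e-12)
    p_high = np.mean(sums >= t_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def de_results_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "avg_log2fc": r.avg_log2fc,
                "p_value": r.p_value,
                "adj_p_value": r.adj_p_value,
                "pct_expr_group1": r.pct_expr_group1,
                "pct_expr_group2": r.pct_expr_group2,
                "significant_up": r.significant_up,
                "significant_down": r.significant_down,
            }
            for r in results
        ]
    )
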