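"""Single-cell QC, clonotype/cluster linkage and candidate selection.

Cells pass QC when they carry exactly one productive TCR-beta chain, at
most 10% mitochondrial reads and at least 100 detected genes; genes are
kept when detected in at least 10 retained cells.  Clonotypes are defined
by identity of the TCR-beta CDR3 amino-acid sequence, scoped per donor.
Per clonotype the distribution of its cells over expression clusters is
tabulated; a clonotype becomes a reactivity-testing candidate when it has
at least 10 cells in the target cluster and more than 60% of its cells
reside there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG
from .errors import ValidationError
from .io_formats import CellRecord, CountsMatrix, Group

logger = logging.getLogger("clonoreact")


@dataclass
class RemovedCell:
    barcode: str
    reason: str


@dataclass
class ClonotypeClusterProfile:
    """Cluster composition of one donor-scoped clonotype."""

    cdr3b_aa: str
    donor_id: str
    group: Group
    total_cells: int
    cells_per_cluster: dict[int, int]
    fraction_per_cluster: dict[int, float]
    exvivo_expanded: bool  # >= 2 cells sharing the clonotype ex vivo


@dataclass
class CandidateSelection:
    cdr3b_aa: str
    donor_id: str
    cells_in_target_cluster: int
    fraction_in_target_cluster: float
    selected: bool


@dataclass
class GroupClusterStats:
    """Per-cohort accounting of clonotypes/cells in the target cluster."""

    group: Group
    n_clonotypes: int
    n_cells: int
    n_donors: int
    mean_clonotypes_per_donor: float  # one decimal
    pct_expanded_clonotypes: float  # one decimal
    pct_cells_from_expanded: float  # one decimal


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

REASON_MULTI_TRB = "not exactly one productive TRB chain"
REASON_MITO = "mitochondrial fraction above threshold"
REASON_GENES = "too few genes detected"


def filter_cells(
    cells: Sequence[CellRecord],
    *,
    max_pct_mito: float = DEFAULT_CONFIG.max_pct_mito,
    min_genes: int = DEFAULT_CONFIG.min_genes,
    require_single_trb: bool = DEFAULT_CONFIG.require_single_trb,
) -> tuple[list[CellRecord], list[RemovedCell]]:
    """Apply the cell-level QC filters.

    A cell is kept when it has exactly one productive TRB chain (if
    required), ``pct_mito <= max_pct_mito`` and
    ``n_genes_detected >= min_genes``.  Removed cells carry the first
    failing reason in the fixed order TRB -> mito -> genes.
    """
    kept: list[CellRecord] = []
    removed: list[RemovedCell] = []
    for cell in cells:
        if require_single_trb and cell.n_productive_trb != 1:
            removed.append(RemovedCell(cell.barcode, REASON_MULTI_TRB))
        elif cell.pct_mito > max_pct_mito:
            removed.append(RemovedCell(cell.barcode, REASON_MITO))
        elif cell.n_genes_detected < min_genes:
            removed.append(RemovedCell(cell.barcode, REASON_GENES))
        else:
            kept.append(cell)
    return kept, removed


def filter_genes(
    matrix: CountsMatrix, min_cells: int = DEFAULT_CONFIG.min_cells_per_gene
) -> CountsMatrix:
    """Keep genes detected (nonzero count) in at least ``min_cells`` cells.
    Apply after the cell filter, so presence is counted over kept cells."""
    cells_per_gene = np.asarray((matrix.values > 0).sum(axis=1)).ravel()
    keep = cells_per_gene >= min_cells
    if not keep.any():
        logger.warning("gene filter removed every gene")
    return matrix.subset_genes(keep)


def pct_mito_from_counts(
    matrix: CountsMatrix, mito_prefix: str = DEFAULT_CONFIG.mito_prefix
) -> np.ndarray:
    """Percent mitochondrial reads per cell, from gene-identifier prefix."""
    is_mito = np.array(
        [g.startswith(mito_prefix) for g in matrix.gene_ids], dtype=bool
    )
    lib = matrix.library_sizes.astype(float)
    if np.any(lib == 0):
        bad = matrix.barcodes[int(np.flatnonzero(lib == 0)[0])]
        raise ValidationError(f"cell {bad}: zero library size")
    mito = np.asarray(matrix.values[is_mito, :].sum(axis=0)).ravel()
    return 100.0 * mito / lib


# ---------------------------------------------------------------------------
# Clonotype-cluster linkage
# ---------------------------------------------------------------------------


def build_cluster_profiles(
    cells: Sequence[CellRecord],
) -> list[ClonotypeClusterProfile]:
    """Tabulate cluster composition per (donor, CDR3b) clonotype.

    Cells lacking a clonotype or a cluster label are excluded (their count
    is logged): upstream clustering is an input here and its gaps must not
    silently distort the fractions.
    """
    usable = [
        c for c in cells if c.cdr3b_aa is not None and c.cluster_id is not None
    ]
    n_dropped = len(cells) - len(usable)
    if n_dropped:
        logger.info(
            "build_cluster_profiles: excluded %d cell(s) lacking a clonotype "
            "or cluster label",
            n_dropped,
        )
    grouped: dict[tuple[str, str], list[CellRecord]] = {}
    for c in usable:
        grouped.setdefault((c.donor_id, c.cdr3b_aa), []).append(c)

    profiles: list[ClonotypeClusterProfile] = []
    for (donor, cdr3), members in grouped.items():
        counts: dict[int, int] = {}
        for m in members:
            counts[m.cluster_id] = counts.get(m.cluster_id, 0) + 1
        total = len(members)
        profiles.append(
            ClonotypeClusterProfile(
                cdr3b_aa=cdr3,
                donor_id=donor,
                group=members[0].group,
                total_cells=total,
                cells_per_cluster=dict(sorted(counts.items())),
                fraction_per_cluster={
                    k: v / total for k, v in sorted(counts.items())
                },
                exvivo_expanded=total >= 2,
            )
        )
    profiles.sort(key=lambda p: (p.donor_id, -p.total_cells, p.cdr3b_aa))
    return profiles


def select_candidates(
    profiles: Sequence[ClonotypeClusterProfile],
    target_cluster: int,
    *,
    min_cells: int = DEFAULT_CONFIG.target_min_cells,
    min_fraction: float = DEFAULT_CONFIG.target_min_fraction,
) -> list[CandidateSelection]:
    """Select reactivity-testing candidates within the target cluster.

    A clonotype is selected when it has ``>= min_cells`` cells in the
    target cluster and strictly more than ``min_fraction`` of its cells
    there.  Sorted by descending target-cluster cell count, ties by CDR3b.
    """
    if profiles and all(
        target_cluster not in p.cells_per_cluster for p in profiles
    ):
        logger.warning(
            "target cluster %s absent from every profile; nothing selected",
            target_cluster,
        )
    out: list[CandidateSelection] = []
    for p in profiles:
        in_target = p.cells_per_cluster.get(target_cluster, 0)
        frac = p.fraction_per_cluster.get(target_cluster, 0.0)
        out.append(
            CandidateSelection(
                cdr3b_aa=p.cdr3b_aa,
                donor_id=p.donor_id,
                cells_in_target_cluster=in_target,
                fraction_in_target_cluster=frac,
                selected=in_target >= min_cells and frac > min_fraction,
            )
        )
    out.sort(key=lambda s: (-s.cells_in_target_cluster, s.cdr3b_aa))
    return out


def cohort_cluster_stats(
    profiles: Sequence[ClonotypeClusterProfile], target_cluster: int
) -> dict[Group, GroupClusterStats]:
    """Per-group accounting of the target cluster.

    A clonotype belongs to the cluster when at least one of its cells does;
    cell counts are cells inside the cluster.  Per-donor means and
    percentages are reported to one decimal.
    """
    stats: dict[Group, GroupClusterStats] = {}
    by_group: dict[Group, list[ClonotypeClusterProfile]] = {}
    for p in profiles:
        if p.cells_per_cluster.get(target_cluster, 0) >= 1:
            by_group.setdefault(p.group, []).append(p)
    for group, members in by_group.items():
        n_clono = len(members)
        n_cells = sum(p.cells_per_cluster[target_cluster] for p in members)
        donors = {p.donor_id for p in members}
        expanded = [p for p in members if p.exvivo_expanded]
        cells_expanded = sum(
            p.cells_per_cluster[target_cluster] for p in expanded
        )
        stats[group] = GroupClusterStats(
            group=group,
            n_clonotypes=n_clono,
            n_cells=n_cells,
            n_donors=len(donors),
            mean_clonotypes_per_donor=round(n_clono / len(donors), 1),
            pct_expanded_clonotypes=round(100.0 * len(expanded) / n_clono, 1),
            pct_cells_from_expanded=round(
                100.0 * cells_expanded / n_cells, 1
            ),
        )
    return stats


def vdj_mapping_rates(rates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cohort mapping-rate accounting.

    ``rates`` has one row per sample with columns ``sample_id``,
    ``trb_pct`` and optionally ``tra_pct`` (percent of cells with a mapped
    productive chain).  Returns the per-sample table and unweighted
    arithmetic cohort means, rounded to two decimals.
    """
    if rates is None or len(rates) == 0:
        raise ValidationError("vdj_mapping_rates: empty input")
    required = {"sample_id", "trb_pct"}
    missing = required - set(rates.columns)
    if missing:
        raise ValidationError(
            f"vdj_mapping_rates: missing column(s) {sorted(missing)}"
        )
    means = {"trb_mean": round(float(rates["trb_pct"].mean()), 2)}
    if "tra_pct" in rates.columns:
        means["tra_mean"] = round(float(rates["tra_pct"].mean()), 2)
    return rates.reset_index(drop=True), means


# ---------------------------------------------------------------------------
# Table exports
# ---------------------------------------------------------------------------


def profiles_frame(profiles: Iterable[ClonotypeClusterProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_id": p.donor_id,
                "group": p.group.value,
                "cdr3b_aa": p.cdr3b_aa,
                "total_cells": p.total_cells,
                "exvivo_expanded": p.exvivo_expanded,
                "cells_per_cluster": ";".join(
                    f"{k}:{v}" for k, v in p.cells_per_cluster.items()
                ),
            }
            for p in profiles
        ]
    )


def selection_frame(selections: Iterable[CandidateSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_id": s.donor_id,
                "cdr3b_aa": s.cdr3b_aa,
                "cells_in_target_cluster": s.cells_in_target_cluster,
                "fraction_in_target_cluster": s.fraction_in_target_cluster,
                "selected": s.selected,
            }
            for s in selections
        ]
    )
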