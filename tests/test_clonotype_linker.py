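import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonoreact import (
    CellRecord,
    CountsMatrix,
    Group,
    ValidationError,
    build_cluster_profiles,
    cohort_cluster_stats,
    filter_cells,
    filter_genes,
    pct_mito_from_counts,
    select_candidates,
    vdj_mapping_rates,
)
from clonoreact.clonotype_linker import (
    REASON_GENES,
    REASON_MITO,
    REASON_MULTI_TRB,
)
from clonoreact.synth import simulate_cell_dataset


def make_cell(
    barcode="B1",
    n_trb=1,
    pct_mito=5.0,
    n_genes=500,
    cdr3="CASSLF",
    cluster=1,
    donor="D1",
    group="AgD",
):
    return CellRecord(
        barcode=barcode,
        donor_id=donor,
        group=Group(group),
        sample_tag=f"{donor}_exvivo",
        n_genes_detected=n_genes,
        pct_mito=pct_mito,
        n_productive_trb=n_trb,
        n_productive_tra=1,
        cdr3b_aa=cdr3 if n_trb == 1 else None,
        cluster_id=cluster,
    )


class TestFilterCells:
    def test_passing_cell_kept(self):
        kept, removed = filter_cells([make_cell(pct_mito=9.9, n_genes=150)])
        assert len(kept) == 1 and not removed

    def test_multiple_trb_removed_first(self):
        # reason order is TRB -> mito -> genes even when several fail
        kept, removed = filter_cells(
            [make_cell(n_trb=2, pct_mito=50.0, n_genes=5)]
        )
        assert not kept
        assert removed[0].reason == REASON_MULTI_TRB

    def test_mito_boundary_inclusive_but_genes_fail(self):
        kept, removed = filter_cells([make_cell(pct_mito=10.0, n_genes=99)])
        assert removed[0].reason == REASON_GENES

    def test_mito_above_boundary_fails(self):
        _, removed = filter_cells([make_cell(pct_mito=10.01)])
        assert removed[0].reason == REASON_MITO

    def test_partition_property(self):
        cells, _ = simulate_cell_dataset(11, clonotypes_per_donor=10)
        kept, removed = filter_cells(cells)
        assert len(kept) + len(removed) == len(cells)
        assert {c.barcode for c in kept}.isdisjoint(r.barcode for r in removed)


class TestFilterGenes:
    def make_matrix(self, presence_counts, n_cells=12):
        rows = []
        for k in presence_counts:
            row = [1] * k + [0] * (n_cells - k)
            rows.append(row)
        return CountsMatrix(
            gene_ids=[f"G{i}" for i in range(len(rows))],
            barcodes=[f"B{i}" for i in range(n_cells)],
            values=sp.csr_matrix(np.array(rows)),
        )

    def test_boundary_at_min_cells(self):
        m = filter_genes(self.make_matrix([10, 9, 0]), min_cells=10)
        assert m.gene_ids == ["G0"]

    def test_cells_unchanged(self):
        m = filter_genes(self.make_matrix([10, 9]), min_cells=10)
        assert len(m.barcodes) == 12


def test_pct_mito_from_counts_prefix_rule():
    m = CountsMatrix(
        gene_ids=["MT-CO1", "CD8A"],
        barcodes=["B1", "B2"],
        values=sp.csr_matrix(np.array([[1, 0], [9, 5]])),
    )
    assert pct_mito_from_counts(m).tolist() == [10.0, 0.0]


class TestClusterProfiles:
    def test_repartition_fraction(self):
        cells = []
        i = 0
        for cluster, n in [(1, 43), (2, 2), (3, 1)]:
            for _ in range(n):
                cells.append(make_cell(barcode=f"B{i}", cluster=cluster))
                i += 1
        (profile,) = build_cluster_profiles(cells)
        assert profile.total_cells == 46
        assert profile.fraction_per_cluster[1] == pytest.approx(0.9348, abs=1e-4)
        assert profile.exvivo_expanded

    def test_singleton_not_expanded(self):
        (p,) = build_cluster_profiles([make_cell()])
        assert not p.exvivo_expanded

    def test_two_cells_same_cluster(self):
        ps = build_cluster_profiles(
            [make_cell(barcode="B1"), make_cell(barcode="B2")]
        )
        assert ps[0].fraction_per_cluster == {1: 1.0}
        assert ps[0].exvivo_expanded

    def test_cells_without_cluster_excluded(self):
        ps = build_cluster_profiles(
            [make_cell(barcode="B1"), make_cell(barcode="B2", cluster=None)]
        )
        assert ps[0].total_cells == 1

    def test_cell_conservation(self):
        cells, _ = simulate_cell_dataset(3, clonotypes_per_donor=8)
        kept, _ = filter_cells(cells)
        profiles = build_cluster_profiles(kept)
        labelled = [
            c for c in kept if c.cdr3b_aa is not None and c.cluster_id is not None
        ]
        assert sum(p.total_cells for p in profiles) == len(labelled)


def profile_with(target_cells, total, cdr3="CASSLF", donor="D1", group="AgD"):
    from clonoreact import ClonotypeClusterProfile

    other = total - target_cells
    cpc = {1: target_cells}
    if other:
        cpc[2] = other
    return ClonotypeClusterProfile(
        cdr3b_aa=cdr3,
        donor_id=donor,
        group=Group(group),
        total_cells=total,
        cells_per_cluster=cpc,
        fraction_per_cluster={k: v / total for k, v in cpc.items()},
        exvivo_expanded=total >= 2,
    )


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "target, total, expected",
        [
            (15, 20, True),  # 75% of 20, >=10 cells
            (9, 9, False),  # 100% but fewer than 10 cells
            (50, 100, False),  # 50% fails the >60% rule
            (10, 16, True),  # 62.5% boundary-adjacent pass
        ],
    )
    def test_rules(self, target, total, expected):
        (sel,) = select_candidates([profile_with(target, total)], 1)
        assert sel.selected is expected

    def test_monotone_in_thresholds(self):
        profiles = [
            profile_with(t, n, cdr3=f"CASS{c}F")
            for (t, n), c in zip(
                [(15, 20), (12, 15), (9, 9), (50, 100), (30, 40)], "ACDEG"
            )
        ]
        base = {
            s.cdr3b_aa for s in select_candidates(profiles, 1) if s.selected
        }
        stricter_cells = {
            s.cdr3b_aa
            for s in select_candidates(profiles, 1, min_cells=14)
            if s.selected
        }
        stricter_frac = {
            s.cdr3b_aa
            for s in select_candidates(profiles, 1, min_fraction=0.8)
            if s.selected
        }
        assert stricter_cells <= base and stricter_frac <= base

    def test_unknown_cluster_warns_and_selects_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="clonoreact"):
            sels = select_candidates([profile_with(15, 20)], 99)
        assert not any(s.selected for s in sels)
        assert caplog.records


class TestCohortStats:
    def build_cohort(self):
        """488 AgD clonotypes (5014 cells) over 3 donors and 696 Ri-AIE
        clonotypes (6584 cells) over 7 donors, all inside cluster 1."""
        profiles = []

        def add(group, n_donors, n_clono, n_cells, tag):
            base, rem = divmod(n_cells, n_clono)
            for i in range(n_clono):
                size = base + (1 if i < rem else 0)
                profiles.append(
                    profile_with(
                        size,
                        size,
                        cdr3=f"CASS{tag}{i}F".replace(str(i), "A" * (i % 3 + 1)),
                        donor=f"{group}{i % n_donors}",
                        group=group,
                    )
                )

        add("AgD", 3, 488, 5014, "G")
        add("Ri_AIE", 7, 696, 6584, "H")
        # distinct keys per profile
        for i, p in enumerate(profiles):
            p.cdr3b_aa = f"{p.cdr3b_aa}{'Q' * (i % 5)}"
        return profiles

    def test_group_means_and_totals(self):
        stats = cohort_cluster_stats(self.build_cohort(), 1)
        agd, ri = stats[Group.AgD], stats[Group.Ri_AIE]
        assert agd.n_clonotypes == 488 and agd.n_cells == 5014
        assert agd.mean_clonotypes_per_donor == 162.7
        assert ri.n_clonotypes == 696 and ri.n_cells == 6584
        assert ri.mean_clonotypes_per_donor == 99.4
        assert agd.n_cells + ri.n_cells == 11_598
        assert agd.n_clonotypes + ri.n_clonotypes == 1184

    def test_expanded_percentages(self):
        profiles = [
            profile_with(1, 1, cdr3="CASSAF"),
            profile_with(3, 3, cdr3="CASSDF"),
            profile_with(6, 6, cdr3="CASSEF"),
        ]
        stats = cohort_cluster_stats(profiles, 1)[Group.AgD]
        assert stats.pct_expanded_clonotypes == pytest.approx(66.7)
        assert stats.pct_cells_from_expanded == pytest.approx(90.0)


class TestVdjMappingRates:
    # per-sample mapped-chain percentages of the 11 sequencing libraries
    TRB = [97.9, 97.7, 94.7, 98.0, 97.9, 97.3, 98.6, 98.3, 97.8, 99.6, 96.8]
    TRA = [83.9, 73.4, 67.5, 69.2, 60.7, 56.2, 85.8, 88.3, 49.3, 42.3, 19.4]

    def test_cohort_means(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(11)],
                "trb_pct": self.TRB,
                "tra_pct": self.TRA,
            }
        )
        _, means = vdj_mapping_rates(df)
        assert means["trb_mean"] == 97.69
        assert means["tra_mean"] == 63.27

    def test_single_sample(self):
        df = pd.DataFrame({"sample_id": ["s"], "trb_pct": [50.0]})
        _, means = vdj_mapping_rates(df)
        assert means["trb_mean"] == 50.00

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            vdj_mapping_rates(pd.DataFrame(columns=["sample_id", "trb_pct"]))
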