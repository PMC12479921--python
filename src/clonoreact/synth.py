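"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* bulk repertoires with a rank power-law clone-size distribution (a few
  large clones, a long rare tail) sampled multinomially at sequencing depth;
* a coculture timecourse in which a small planted set of rare, reactive
  clones grows multiplicatively each week, with multinomial resampling at
  every timepoint (so a per-week growth factor g yields ~g^2 day-14 fold);
* clonotype-labelled single cells whose cluster memberships are
  Dirichlet-multinomial, with planted clonotypes concentrated in a target
  cluster and configurable fractions of cells failing each QC filter;
* negative-binomial count matrices with planted group log2 fold-changes;
* lognormal reporter readouts separating reactive from non-reactive TCRs,
  with HLA-block, mock and TransAct conditions.

Determinism: every generator draws from a named substream derived from the
single top-level seed, so identical (parameters, seed) give byte-identical
outputs and adding a generator does not perturb existing fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .io_formats import (
    AA_ALPHABET,
    CellRecord,
    ClonotypeRecord,
    Condition,
    CountsMatrix,
    Group,
    LuminescenceAssay,
    RepertoireSample,
    Timepoint,
)
from .repertoire_metrics import TimecourseRepertoire

AA_LETTERS = sorted(AA_ALPHABET)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    seed: int
    reactive_clonotypes: set[str] = field(default_factory=set)
    growth_factor_per_week: float = 1.0
    target_cluster_clonotypes: set[str] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)
    reactive_tcrs: set[str] = field(default_factory=set)
    pbmc_cross_tcrs: set[str] = field(default_factory=set)
    hla_dependent_tcrs: set[str] = field(default_factory=set)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    """Unique synthetic CDR3b amino-acid string, length 10-20, with the
    canonical C...F frame."""
    while True:
        length = int(rng.integers(10, 21))
        middle = "".join(
            rng.choice(AA_LETTERS, size=length - 2)
        )
        s = "C" + middle + "F"
        if s not in existing:
            existing.add(s)
            return s


# ---------------------------------------------------------------------------
# Bulk repertoires and the coculture timecourse
# ---------------------------------------------------------------------------


def simulate_repertoire(
    n_clonotypes: int,
    depth: int,
    seed: int,
    *,
    alpha: float = 2.0,
    sample_id: str = "synth_exvivo",
    donor_id: str = "synthD1",
    timepoint: Timepoint | str = Timepoint.ex_vivo,
    input_cell_count: Optional[int] = None,
) -> RepertoireSample:
    """Multinomial sample of a rank power-law repertoire.

    Clone probabilities are proportional to ``rank**(-alpha)``; counts are
    drawn multinomially at ``depth``.  Clonotypes drawn with zero count are
    omitted (they were not sequenced).
    """
    if n_clonotypes < 2:
        raise ParameterError("n_clonotypes must be >= 2")
    if depth < n_clonotypes:
        raise ParameterError("depth must be >= n_clonotypes")
    if alpha <= 0:
        raise ParameterError("power-law exponent alpha must be positive")
    rng = substream(seed, "repertoire")
    probs = np.arange(1, n_clonotypes + 1, dtype=float) ** (-alpha)
    probs /= probs.sum()
    counts = rng.multinomial(depth, probs)
    existing: set[str] = set()
    names = [_random_cdr3(rng, existing) for _ in range(n_clonotypes)]
    total = int(counts.sum())
    clonotypes = [
        ClonotypeRecord(
            cdr3b_aa=names[i],
            count=int(counts[i]),
            frequency=counts[i] / total,
            v_call=f"TRBV{(i % 30) + 1}",
            j_call=f"TRBJ{(i % 13) + 1}",
        )
        for i in np.flatnonzero(counts)
    ]
    clonotypes.sort(key=lambda c: (-c.count, c.cdr3b_aa))
    sample = RepertoireSample(
        sample_id=sample_id,
        donor_id=donor_id,
        timepoint=Timepoint(timepoint),
        clonotypes=clonotypes,
        total_count=total,
        input_cell_count=input_cell_count,
    )
    sample.validate()
    return sample


def simulate_coculture(
    base: RepertoireSample,
    n_reactive: int,
    seed: int,
    *,
    growth_factor: float = 20.0,
    depth: Optional[int] = None,
    rare_max_freq: float = 1e-4,
) -> tuple[TimecourseRepertoire, SyntheticTruth]:
    """Evolve an ex vivo repertoire through a 14-day neuron coculture.

    ``n_reactive`` clones are planted uniformly among clones with ex vivo
    frequency below ``rare_max_freq`` (the rare-precursor regime).  Each
    week their probability mass is multiplied by ``growth_factor``, the
    vector renormalized, and a new repertoire sampled multinomially at
    ``depth`` (default: the base sample's total count); week two grows from
    the day-7 empirical frequencies.
    """
    if growth_factor < 1:
        raise ParameterError(
            "growth_factor must be >= 1 (1 = null case, no growth)"
        )
    if n_reactive >= len(base.clonotypes):
        raise ParameterError("n_reactive must be below the clonotype number")
    rng = substream(seed, "coculture")
    depth = depth if depth is not None else base.total_count

    names = [c.cdr3b_aa for c in base.clonotypes]
    freqs = base.frequencies
    eligible = np.flatnonzero((freqs < rare_max_freq) & (freqs > 0))
    if len(eligible) < n_reactive:
        raise ParameterError(
            f"only {len(eligible)} clones below frequency {rare_max_freq}; "
            "increase the repertoire size or depth to obtain rare precursors"
        )
    reactive_idx = rng.choice(eligible, size=n_reactive, replace=False)
    reactive = {names[i] for i in reactive_idx}

    def grow_and_sample(current_freqs: np.ndarray, tag: str) -> RepertoireSample:
        boosted = current_freqs.copy()
        for i in reactive_idx:
            boosted[i] *= growth_factor
        boosted /= boosted.sum()
        counts = rng.multinomial(depth, boosted)
        total = int(counts.sum())
        clonos = [
            ClonotypeRecord(
                cdr3b_aa=names[i],
                count=int(counts[i]),
                frequency=counts[i] / total,
                v_call=base.clonotypes[i].v_call,
                j_call=base.clonotypes[i].j_call,
            )
            for i in np.flatnonzero(counts)
        ]
        clonos.sort(key=lambda c: (-c.count, c.cdr3b_aa))
        s = RepertoireSample(
            sample_id=f"{base.sample_id}_{tag}",
            donor_id=base.donor_id,
            timepoint=Timepoint(tag),
            clonotypes=clonos,
            total_count=total,
            input_cell_count=base.input_cell_count,
        )
        s.validate()
        return s

    day7 = grow_and_sample(freqs, "day7")
    day7_map = {c.cdr3b_aa: c.frequency for c in day7.clonotypes}
    day7_freqs = np.array([day7_map.get(n, 0.0) for n in names])
    if day7_freqs.sum() > 0:
        day7_freqs = day7_freqs / day7_freqs.sum()
    day14 = grow_and_sample(day7_freqs, "day14")

    exvivo = RepertoireSample(
        sample_id=base.sample_id,
        donor_id=base.donor_id,
        timepoint=Timepoint.ex_vivo,
        clonotypes=list(base.clonotypes),
        total_count=base.total_count,
        input_cell_count=base.input_cell_count,
    )
    tc = TimecourseRepertoire(
        donor_id=base.donor_id,
        samples={
            Timepoint.ex_vivo: exvivo,
            Timepoint.day7: day7,
            Timepoint.day14: day14,
        },
    )
    truth = SyntheticTruth(
        seed=seed,
        reactive_clonotypes=reactive,
        growth_factor_per_week=growth_factor,
    )
    return tc, truth


# ---------------------------------------------------------------------------
# Clonotype-labelled cells with cluster memberships
# ---------------------------------------------------------------------------


def simulate_cell_dataset(
    seed: int,
    *,
    n_donors_per_group: Mapping[str, int] = None,
    clonotypes_per_donor: int = 30,
    planted_per_donor: int = 3,
    n_clusters: int = 16,
    target_cluster: int = 1,
    planted_target_mass: float = 0.92,
    planted_concentration: float = 150.0,
    background_concentration: float = 5.0,
    planted_cells_range: tuple[int, int] = (25, 60),
    background_geometric_p: float = 0.55,
    background_cells_cap: int = 100,
    qc_fail_trb: float = 0.02,
    qc_fail_mito: float = 0.02,
    qc_fail_genes: float = 0.02,
) -> tuple[list[CellRecord], SyntheticTruth]:
    """Cells carrying clonotype labels with Dirichlet-multinomial cluster
    membership.

    Per donor, ``planted_per_donor`` clonotypes draw their cluster profile
    from a Dirichlet concentrated on the target cluster
    (``planted_target_mass`` expected fraction) and receive
    ``planted_cells_range`` cells; background clonotypes use a symmetric
    Dirichlet and 1 + geometric cell counts (many singletons).  Each QC
    field independently fails its filter with the configured fraction.
    """
    if n_clusters < 2:
        raise ParameterError("n_clusters must be >= 2")
    if not 0 < planted_target_mass < 1:
        raise ParameterError("planted_target_mass must lie in (0, 1)")
    if n_donors_per_group is None:
        n_donors_per_group = {"AgD": 3, "Ri_AIE": 7}
    rng = substream(seed, "cells")

    conc_planted = np.full(
        n_clusters,
        planted_concentration * (1 - planted_target_mass) / (n_clusters - 1),
    )
    conc_planted[target_cluster] = planted_concentration * planted_target_mass
    conc_background = np.full(n_clusters, background_concentration)

    cells: list[CellRecord] = []
    existing: set[str] = set()
    planted_set: set[str] = set()
    cell_no = 0
    for group_name, n_donors in n_donors_per_group.items():
        group = Group(group_name)
        for d in range(n_donors):
            donor = f"{group_name}{d + 1}"
            for k in range(clonotypes_per_donor):
                planted = k < planted_per_donor
                cdr3 = _random_cdr3(rng, existing)
                if planted:
                    planted_set.add(cdr3)
                    n_cells = int(rng.integers(*planted_cells_range))
                    conc = conc_planted
                else:
                    n_cells = min(
                        int(rng.geometric(background_geometric_p)),
                        background_cells_cap,
                    )
                    conc = conc_background
                cluster_probs = rng.dirichlet(conc)
                memberships = rng.choice(n_clusters, size=n_cells, p=cluster_probs)
                for cl in memberships:
                    fail_trb = rng.random() < qc_fail_trb
                    fail_mito = rng.random() < qc_fail_mito
                    fail_genes = rng.random() < qc_fail_genes
                    n_trb = int(rng.choice([0, 2])) if fail_trb else 1
                    pct_mito = (
                        float(rng.uniform(10.0, 30.0)) + 1e-6
                        if fail_mito
                        else float(rng.uniform(0.0, 10.0))
                    )
                    n_genes = (
                        int(rng.integers(10, 100))
                        if fail_genes
                        else int(rng.integers(500, 3000))
                    )
                    cell_no += 1
                    cells.append(
                        CellRecord(
                            barcode=f"BC{cell_no:07d}",
                            donor_id=donor,
                            group=group,
                            sample_tag=f"{donor}_exvivo",
                            n_genes_detected=n_genes,
                            pct_mito=min(pct_mito, 100.0),
                            n_productive_trb=n_trb,
                            n_productive_tra=int(rng.integers(0, 3)),
                            cdr3b_aa=cdr3 if n_trb == 1 else None,
                            cluster_id=int(cl),
                        )
                    )
    for c in cells:
        c.validate()
    truth = SyntheticTruth(seed=seed, target_cluster_clonotypes=planted_set)
    return cells, truth


# ---------------------------------------------------------------------------
# Negative-binomial counts with planted effects
# ---------------------------------------------------------------------------


def simulate_counts(
    n_genes: int,
    cells_per_group: int,
    seed: int,
    *,
    planted: Optional[Mapping[int, float]] = None,
    n_planted: int = 0,
    planted_log2fc: float = 1.0,
    nb_mean_log_mu: float = 0.0,
    nb_mean_log_sigma: float = 1.0,
    nb_dispersion: float = 0.5,
    group_names: tuple[str, str] = ("AgD", "Ri_AIE"),
) -> tuple[CountsMatrix, list[str], SyntheticTruth]:
    """Genes x cells negative-binomial counts for two cell groups.

    Baseline gene means are lognormal; for planted genes the second
    group's mean is scaled by ``2**log2fc``.  ``planted`` maps gene index
    to its log2 fold-change (positive = higher in the second group); when
    omitted, ``n_planted`` genes are chosen at random, half up, half down.
    Returns the matrix, per-cell group labels and the truth.
    """
    if nb_dispersion <= 0:
        raise ParameterError("nb_dispersion must be positive")
    rng = substream(seed, "counts")
    means = rng.lognormal(nb_mean_log_mu, nb_mean_log_sigma, size=n_genes)
    if not np.all(np.isfinite(means)):
        raise ParameterError("non-finite baseline mean drawn")

    if planted is None:
        planted = {}
        if n_planted:
            chosen = rng.choice(n_genes, size=n_planted, replace=False)
            for j, g in enumerate(chosen):
                planted[int(g)] = planted_log2fc if j % 2 == 0 else -planted_log2fc
    planted = dict(planted)

    lfc = np.zeros(n_genes)
    for g, v in planted.items():
        lfc[g] = v
    means2 = means * (2.0 ** lfc)

    size = 1.0 / nb_dispersion  # NB "number of successes" parameter

    def draw(m: np.ndarray, n_cells: int) -> np.ndarray:
        p = size / (size + m)
        return rng.negative_binomial(
            size, p[:, None], size=(n_genes, n_cells)
        )

    counts1 = draw(means, cells_per_group)
    counts2 = draw(means2, cells_per_group)
    values = np.concatenate([counts1, counts2], axis=1)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    barcodes = [
        f"{group_names[0]}_{i:05d}" for i in range(cells_per_group)
    ] + [f"{group_names[1]}_{i:05d}" for i in range(cells_per_group)]
    labels = [group_names[0]] * cells_per_group + [
        group_names[1]
    ] * cells_per_group
    import scipy.sparse as sp

    matrix = CountsMatrix(
        gene_ids=gene_ids,
        barcodes=barcodes,
        values=sp.csr_matrix(values, dtype=np.int64),
    )
    matrix.validate()
    truth = SyntheticTruth(
        seed=seed,
        de_genes={gene_ids[g]: v for g, v in planted.items()},
    )
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Reporter luminescence
# ---------------------------------------------------------------------------


def simulate_luminescence(
    n_tcrs: int,
    reactive_fraction: float,
    seed: int,
    *,
    reactive_median: float = 20000.0,
    background_median: float = 500.0,
    pbmc_cross_fraction: float = 0.85,
    pbmc_median: float = 8000.0,
    transact_median: float = 80000.0,
    sigma: float = 0.25,
    n_replicates: int = 2,
    groups: Optional[Sequence[str]] = None,
) -> tuple[list[LuminescenceAssay], SyntheticTruth]:
    """Reporter readouts for ``n_tcrs`` TCRs, a planted fraction reactive.

    Reactive TCRs emit lognormal signal (median ``reactive_median`` above
    background) on stimulated neurons, collapsing to background under HLA
    blockade; a planted subfraction also responds (more weakly) to PBMCs.
    Non-reactive TCRs stay at background everywhere.  Mock and TransAct
    conditions are always included; conditions carry ``n_replicates``
    replicates.
    """
    if not 0.0 <= reactive_fraction <= 1.0:
        raise ParameterError("reactive_fraction must lie in [0, 1]")
    rng = substream(seed, "luminescence")
    n_reactive = int(round(n_tcrs * reactive_fraction))
    reactive_ids = set(rng.choice(n_tcrs, size=n_reactive, replace=False))
    if groups is None:
        groups = [
            "AgD" if i < (n_tcrs + 1) // 2 else "Ri_AIE" for i in range(n_tcrs)
        ]

    def noise(median: float) -> list[float]:
        return [
            float(rng.lognormal(np.log(median), sigma))
            for _ in range(n_replicates)
        ]

    def background() -> list[float]:
        return noise(background_median)

    assays: list[LuminescenceAssay] = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_tcrs):
        tcr = f"TCR{i + 1:03d}"
        group = groups[i]
        donor = f"{group}_donor{(i % 3) + 1}"
        is_reactive = i in reactive_ids
        if is_reactive:
            truth.reactive_tcrs.add(tcr)
            truth.hla_dependent_tcrs.add(tcr)
            stim = [
                b + s
                for b, s in zip(background(), noise(reactive_median))
            ]
            pbmc_cross = rng.random() < pbmc_cross_fraction
            if pbmc_cross:
                truth.pbmc_cross_tcrs.add(tcr)
                pbmc = [
                    b + s for b, s in zip(background(), noise(pbmc_median))
                ]
            else:
                pbmc = background()
        else:
            stim = background()
            pbmc = background()
        per_condition = {
            Condition.neurons_stim: stim,
            Condition.neurons_unstim: background(),
            Condition.neurons_stim_hla_block: background(),
            Condition.pbmc: pbmc,
            Condition.transact: [
                b + s for b, s in zip(background(), noise(transact_median))
            ],
            Condition.mock: background(),
        }
        for cond, reps in per_condition.items():
            assays.append(
                LuminescenceAssay(
                    tcr_id=tcr,
                    donor_id=donor,
                    group=Group(group),
                    condition=cond,
                    replicates=reps,
                )
            )
    return assays, truth


# ---------------------------------------------------------------------------
# Miniature end-to-end study
# ---------------------------------------------------------------------------


def simulate_study(seed: int, outdir: Optional[str | Path] = None) -> dict:
    """Generate a complete miniature study: a coculture timecourse, a
    clonotype-labelled cell cohort (3 AgD + 7 Ri-AIE donors), a two-group
    count matrix and a reporter plate.  When ``outdir`` is given, all
    artifacts are written in their external formats plus a manifest JSON.

    Returns a dict with the in-memory artifacts and planted truths.
    """
    base = simulate_repertoire(
        n_clonotypes=3000,
        depth=100_000,
        seed=seed,
        alpha=2.0,
        sample_id="studyD1_exvivo",
        donor_id="studyD1",
        input_cell_count=100_000,
    )
    tc, tc_truth = simulate_coculture(base, n_reactive=5, seed=seed)
    cells, cell_truth = simulate_cell_dataset(seed)
    counts, labels, de_truth = simulate_counts(
        n_genes=800, cells_per_group=250, seed=seed, n_planted=40
    )
    assays, lum_truth = simulate_luminescence(
        n_tcrs=48, reactive_fraction=0.42, seed=seed
    )

    study = {
        "timecourse": tc,
        "timecourse_truth": tc_truth,
        "cells": cells,
        "cells_truth": cell_truth,
        "counts": counts,
        "counts_labels": labels,
        "counts_truth": de_truth,
        "assays": assays,
        "assays_truth": lum_truth,
    }

    if outdir is not None:
        from .io_formats import (
            write_airr_repertoire,
            write_cell_metadata,
            write_counts_mtx,
            write_luminescence,
        )

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for tp, sample in tc.samples.items():
            p = outdir / f"repertoire_{tp.value}.tsv"
            write_airr_repertoire(sample, p)
            paths[f"repertoire_{tp.value}"] = str(p)
        write_cell_metadata(cells, outdir / "cells.tsv")
        paths["cells"] = str(outdir / "cells.tsv")
        write_counts_mtx(counts, outdir / "counts")
        paths["counts_dir"] = str(outdir / "counts")
        (outdir / "counts_labels.tsv").write_text(
            "barcode\tgroup\n"
            + "".join(
                f"{bc}\t{lab}\n" for bc, lab in zip(counts.barcodes, labels)
            )
        )
        paths["counts_labels"] = str(outdir / "counts_labels.tsv")
        write_luminescence(assays, outdir / "plate.csv")
        paths["plate"] = str(outdir / "plate.csv")
        manifest = {
            "seed": seed,
            "paths": paths,
            "truth": {
                "reactive_clonotypes": sorted(tc_truth.reactive_clonotypes),
                "growth_factor_per_week": tc_truth.growth_factor_per_week,
                "target_cluster_clonotypes": sorted(
                    cell_truth.target_cluster_clonotypes
                ),
                "de_genes": de_truth.de_genes,
                "reactive_tcrs": sorted(lum_truth.reactive_tcrs),
                "pbmc_cross_tcrs": sorted(lum_truth.pbmc_cross_tcrs),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        study["manifest"] = manifest
    return study
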