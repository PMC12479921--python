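"""Readers/writers for the external formats the pipeline touches.

Bulk TCR-beta repertoires arrive as AIRR Rearrangement TSV, single-cell VDJ
as 10x ``filtered_contig_annotations.csv``, gene expression as a Matrix
Market triplet with feature/barcode lists, per-cell metadata as TSV and
reporter readouts as a long CSV.  Every reader validates its input and
returns a checked in-memory type; every writer round-trips through the
matching reader.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    EmptyRepertoireError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger("clonoreact")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

FREQ_TOL = 1e-9


class Timepoint(str, enum.Enum):
    """Coculture timepoints of the bulk repertoire timecourse."""

    ex_vivo = "ex_vivo"
    day7 = "day7"
    day14 = "day14"


class Group(str, enum.Enum):
    """Donor cohorts: aged donors without autoimmune disease (AgD),
    anti-Ri autoimmune-encephalitis patients (Ri_AIE), healthy donors (HD)."""

    AgD = "AgD"
    Ri_AIE = "Ri_AIE"
    HD = "HD"


class Condition(str, enum.Enum):
    """NFAT-reporter assay conditions."""

    neurons_stim = "neurons_stim"  # IFNg/TNFa-treated (HLA-I high) neurons
    neurons_unstim = "neurons_unstim"  # untreated neurons, HLA-I low
    neurons_stim_hla_block = "neurons_stim_hla_block"  # + anti-HLA-ABC
    pbmc = "pbmc"  # autologous PBMC coculture
    transact = "transact"  # anti-CD3/CD28 positive control
    mock = "mock"  # mock transfection: background signal


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype of a bulk repertoire, keyed by its CDR3-beta amino-acid
    sequence."""

    cdr3b_aa: str
    count: int
    frequency: float
    v_call: str = ""
    j_call: str = ""
    cdr3b_nt: Optional[str] = None

    def validate(self, total_count: int) -> None:
        if not self.cdr3b_aa:
            raise ValidationError("empty CDR3b amino-acid sequence")
        bad = set(self.cdr3b_aa) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"clonotype {self.cdr3b_aa!r}: non-standard amino-acid "
                f"letters {sorted(bad)}"
            )
        if self.count < 0:
            raise ValidationError(f"clonotype {self.cdr3b_aa}: negative count")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(
                f"clonotype {self.cdr3b_aa}: frequency {self.frequency} "
                "outside [0, 1]"
            )
        if total_count > 0:
            expected = self.count / total_count
            if not math.isclose(self.frequency, expected, abs_tol=FREQ_TOL):
                raise ValidationError(
                    f"clonotype {self.cdr3b_aa}: frequency {self.frequency} "
                    f"!= count/total = {expected}"
                )


@dataclass
class RepertoireSample:
    """One sample's bulk TCR-beta clonotype table at a timepoint.

    ``input_cell_count`` is the number of CD8+ T cells used as sequencing
    input; it sets the maximal theoretical (pseudo-)frequency 1/n assigned
    to clonotypes undetected ex vivo.
    """

    sample_id: str
    donor_id: str
    timepoint: Timepoint
    clonotypes: list[ClonotypeRecord]
    total_count: int
    input_cell_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)

    def validate(self) -> None:
        if self.total_count < 0:
            raise ValidationError(f"{self.sample_id}: negative total_count")
        if self.input_cell_count is not None and self.input_cell_count <= 0:
            raise ValidationError(
                f"{self.sample_id}: input_cell_count must be positive"
            )
        if sum(c.count for c in self.clonotypes) != self.total_count:
            raise ValidationError(
                f"{self.sample_id}: clonotype counts do not sum to total_count"
            )
        keys = [c.cdr3b_aa for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ValidationError(f"{self.sample_id}: duplicate CDR3b keys")
        for c in self.clonotypes:
            c.validate(self.total_count)
        if self.total_count > 0:
            fsum = sum(c.frequency for c in self.clonotypes)
            if abs(fsum - 1.0) > FREQ_TOL:
                raise ValidationError(
                    f"{self.sample_id}: frequencies sum to {fsum}, not 1"
                )

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clonotypes])

    def frequency_of(self, cdr3b_aa: str) -> float:
        """Measured frequency of a clonotype, 0.0 if undetected."""
        for c in self.clonotypes:
            if c.cdr3b_aa == cdr3b_aa:
                return c.frequency
        return 0.0


@dataclass
class CellRecord:
    """A single cell with QC fields and its (optional) clonotype/cluster
    assignment."""

    barcode: str
    donor_id: str
    group: Group
    sample_tag: str
    n_genes_detected: int
    pct_mito: float
    n_productive_trb: int
    n_productive_tra: int
    cdr3b_aa: Optional[str] = None
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)

    def validate(self) -> None:
        if not 0.0 <= self.pct_mito <= 100.0:
            raise ValidationError(
                f"cell {self.barcode}: pct_mito {self.pct_mito} outside [0, 100]"
            )
        for fname in ("n_genes_detected", "n_productive_trb", "n_productive_tra"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"cell {self.barcode}: negative {fname}")
        if self.cdr3b_aa is not None and self.n_productive_trb < 1:
            raise ValidationError(
                f"cell {self.barcode}: CDR3b present without a productive TRB"
            )
        if self.cdr3b_aa is None and self.n_productive_trb == 1:
            raise ValidationError(
                f"cell {self.barcode}: single productive TRB but no CDR3b"
            )


@dataclass
class ChainSummary:
    """Per-barcode summary of productive VDJ contigs."""

    barcode: str
    n_productive_trb: int
    n_productive_tra: int
    cdr3b_aa: Optional[str] = None


@dataclass
class CountsMatrix:
    """Gene x cell raw counts (sparse), with ordered identifier lists."""

    gene_ids: list[str]
    barcodes: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.barcodes):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes in counts matrix")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative entry in counts matrix")

    @property
    def library_sizes(self) -> np.ndarray:
        """Total counts per cell (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_genes(self, keep: Sequence[bool] | np.ndarray) -> "CountsMatrix":
        keep = np.asarray(keep, dtype=bool)
        return CountsMatrix(
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            barcodes=list(self.barcodes),
            values=self.values[keep, :],
        )

    def subset_cells(self, keep_barcodes: Sequence[str]) -> "CountsMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        cols = [index[b] for b in keep_barcodes]
        return CountsMatrix(
            gene_ids=list(self.gene_ids),
            barcodes=list(keep_barcodes),
            values=self.values[:, cols],
        )


@dataclass
class LuminescenceAssay:
    """Replicate relative-light-unit readouts of one TCR under one
    reporter-assay condition."""

    tcr_id: str
    donor_id: str
    group: Group
    condition: Condition
    replicates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.condition = Condition(self.condition)

    def validate(self) -> None:
        if not self.replicates:
            raise ValidationError(
                f"TCR {self.tcr_id} / {self.condition.value}: no replicates"
            )
        for r in self.replicates:
            if not math.isfinite(r):
                raise ValidationError(
                    f"TCR {self.tcr_id} / {self.condition.value}: "
                    "non-finite replicate"
                )
            if r < 0:
                raise ValidationError(
                    f"TCR {self.tcr_id} / {self.condition.value}: negative RLU"
                )


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------------

AIRR_REQUIRED = (
    "sequence_id",
    "locus",
    "junction_aa",
    "v_call",
    "j_call",
    "productive",
    "duplicate_count",
)

_TRUE_STRINGS = {"t", "true", "1", "yes"}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in _TRUE_STRINGS


def read_airr_repertoire(
    path: str | Path,
    *,
    locus: str = "TRB",
    sample_id: str,
    donor_id: str,
    timepoint: Timepoint | str,
    input_cell_count: Optional[int] = None,
) -> RepertoireSample:
    """Read an AIRR Rearrangement TSV and aggregate productive rows of the
    requested locus into clonotypes keyed by ``junction_aa``.

    Frequencies are recomputed from summed ``duplicate_count``; any frequency
    column in the file is ignored.  The V/J calls of a clonotype's most
    abundant row are retained for display.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required AIRR column(s): {', '.join(missing)}"
        )
    counts = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad = counts.isna() | (counts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: invalid duplicate_count at data row {row + 1}"
        )
    df = df.assign(_count=counts.astype(int))
    mask = df["productive"].map(_as_bool) & (df["locus"] == locus)
    prod = df.loc[mask]
    if prod.empty:
        raise EmptyRepertoireError(
            f"{path}: no productive {locus} rearrangement found"
        )

    has_nt = "junction" in df.columns
    records: list[ClonotypeRecord] = []
    total = int(prod["_count"].sum())
    for aa, grp in prod.groupby("junction_aa", sort=False):
        count = int(grp["_count"].sum())
        top = grp.loc[grp["_count"].idxmax()]
        records.append(
            ClonotypeRecord(
                cdr3b_aa=str(aa),
                count=count,
                frequency=count / total if total else 0.0,
                v_call=str(top["v_call"]),
                j_call=str(top["j_call"]),
                cdr3b_nt=str(top["junction"]) if has_nt else None,
            )
        )
    records.sort(key=lambda c: (-c.count, c.cdr3b_aa))
    sample = RepertoireSample(
        sample_id=sample_id,
        donor_id=donor_id,
        timepoint=Timepoint(timepoint),
        clonotypes=records,
        total_count=total,
        input_cell_count=input_cell_count,
    )
    sample.validate()
    return sample


def write_airr_repertoire(sample: RepertoireSample, path: str | Path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (one row per clonotype)."""
    rows = []
    for i, c in enumerate(sample.clonotypes):
        rows.append(
            {
                "sequence_id": f"{sample.sample_id}_c{i}",
                "locus": "TRB",
                "junction": c.cdr3b_nt if c.cdr3b_nt is not None else "",
                "junction_aa": c.cdr3b_aa,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "productive": "T",
                "duplicate_count": c.count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 10x VDJ contig annotations
# ---------------------------------------------------------------------------

CONTIG_REQUIRED = ("barcode", "chain", "cdr3", "productive")


def read_contig_annotations(path: str | Path) -> list[ChainSummary]:
    """Summarize a 10x ``filtered_contig_annotations.csv`` per barcode.

    Counts productive TRA/TRB contigs; the TRB CDR3 amino-acid sequence is
    recorded only when a barcode has exactly one productive TRB chain.
    Chains other than TRA/TRB are ignored with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CONTIG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing contig-annotation column(s): {', '.join(missing)}"
        )
    unknown = set(df["chain"].unique()) - {"TRA", "TRB"}
    if unknown:
        logger.warning(
            "%s: ignoring %d contig(s) with chain label(s) %s",
            path,
            int(df["chain"].isin(unknown).sum()),
            sorted(unknown),
        )
        df = df[~df["chain"].isin(unknown)]
    # barcode order fixed before the productive filter, so barcodes with
    # only non-productive contigs still appear (with zero counts)
    order = pd.unique(df["barcode"]) if len(df) else []
    prod = df[df["productive"].map(_as_bool)]

    summaries: list[ChainSummary] = []
    grouped = prod.groupby("barcode", sort=False)
    for bc in order:
        grp = (
            grouped.get_group(bc)
            if bc in grouped.groups
            else prod.iloc[0:0]
        )
        trb = grp[grp["chain"] == "TRB"]
        tra = grp[grp["chain"] == "TRA"]
        cdr3b = str(trb["cdr3"].iloc[0]) if len(trb) == 1 else None
        summaries.append(
            ChainSummary(
                barcode=str(bc),
                n_productive_trb=len(trb),
                n_productive_tra=len(tra),
                cdr3b_aa=cdr3b,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Matrix Market counts
# ---------------------------------------------------------------------------


def read_counts_mtx(directory: str | Path) -> CountsMatrix:
    """Read ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` from a
    directory into a genes x cells :class:`CountsMatrix`."""
    directory = Path(directory)
    try:
        mat = scipy.io.mmread(directory / "matrix.mtx")
    except ValueError as exc:
        raise FormatError(f"{directory}/matrix.mtx: {exc}") from exc
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{directory}: matrix dimensions {mat.shape} inconsistent with "
            f"{len(genes)} features / {len(barcodes)} barcodes"
        )
    cm = CountsMatrix(
        gene_ids=genes.astype(str).tolist(),
        barcodes=barcodes.astype(str).tolist(),
        values=sp.csr_matrix(mat, dtype=np.int64),
    )
    cm.validate()
    return cm


def write_counts_mtx(matrix: CountsMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(matrix.values))
    pd.Series(matrix.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(matrix.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Cell metadata TSV
# ---------------------------------------------------------------------------

CELL_META_REQUIRED = (
    "barcode",
    "donor_id",
    "group",
    "sample_tag",
    "n_genes_detected",
    "pct_mito",
    "n_productive_trb",
    "n_productive_tra",
)


def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read per-cell metadata TSV (QC fields, optional clonotype and
    cluster assignment) into validated :class:`CellRecord` objects."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in CELL_META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing cell-metadata column(s): {', '.join(missing)}"
        )
    cells: list[CellRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cdr3 = d.get("cdr3b_aa")
        cluster = d.get("cluster_id")
        cell = CellRecord(
            barcode=str(d["barcode"]),
            donor_id=str(d["donor_id"]),
            group=Group(d["group"]),
            sample_tag=str(d["sample_tag"]),
            n_genes_detected=int(d["n_genes_detected"]),
            pct_mito=float(d["pct_mito"]),
            n_productive_trb=int(d["n_productive_trb"]),
            n_productive_tra=int(d["n_productive_tra"]),
            cdr3b_aa=None if pd.isna(cdr3) else str(cdr3),
            cluster_id=None if pd.isna(cluster) else int(cluster),
        )
        cell.validate()
        cells.append(cell)
    if len({c.barcode for c in cells}) != len(cells):
        raise ValidationError(f"{path}: duplicate barcodes")
    return cells


def write_cell_metadata(
    cells: Iterable[CellRecord], path: str | Path, header_comment: str = ""
) -> None:
    rows = []
    for c in cells:
        rows.append(
            {
                "barcode": c.barcode,
                "donor_id": c.donor_id,
                "group": c.group.value,
                "sample_tag": c.sample_tag,
                "n_genes_detected": c.n_genes_detected,
                "pct_mito": c.pct_mito,
                "n_productive_trb": c.n_productive_trb,
                "n_productive_tra": c.n_productive_tra,
                "cdr3b_aa": c.cdr3b_aa if c.cdr3b_aa is not None else "",
                "cluster_id": c.cluster_id if c.cluster_id is not None else "",
            }
        )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Luminescence CSV
# ---------------------------------------------------------------------------

LUM_REQUIRED = ("tcr_id", "donor_id", "group", "condition", "replicate", "rlu")


def read_luminescence(path: str | Path) -> list[LuminescenceAssay]:
    """Read a long-format reporter readout CSV, grouping replicate RLU
    values per (TCR, condition)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LUM_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing luminescence column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("%s: luminescence file contains no data rows", path)
        return []
    allowed = {c.value for c in Condition}
    unknown = set(df["condition"].astype(str)) - allowed
    if unknown:
        raise ValidationError(
            f"{path}: unknown condition label(s) {sorted(unknown)}; "
            f"allowed values: {sorted(allowed)}"
        )
    if (pd.to_numeric(df["rlu"]) < 0).any():
        raise ValidationError(f"{path}: negative RLU value")

    assays: list[LuminescenceAssay] = []
    df = df.sort_values("replicate", kind="stable")
    keys = df[["tcr_id", "donor_id", "group", "condition"]].drop_duplicates()
    grouped = df.groupby(["tcr_id", "donor_id", "group", "condition"], sort=False)
    for key in keys.itertuples(index=False):
        grp = grouped.get_group(tuple(key))
        assay = LuminescenceAssay(
            tcr_id=str(key.tcr_id),
            donor_id=str(key.donor_id),
            group=Group(key.group),
            condition=Condition(key.condition),
            replicates=[float(v) for v in grp["rlu"]],
        )
        assay.validate()
        assays.append(assay)
    return assays


def write_luminescence(
    assays: Iterable[LuminescenceAssay], path: str | Path
) -> None:
    rows = []
    for a in assays:
        for i, rlu in enumerate(a.replicates, start=1):
            rows.append(
                {
                    "tcr_id": a.tcr_id,
                    "donor_id": a.donor_id,
                    "group": a.group.value,
                    "condition": a.condition.value,
                    "replicate": i,
                    "rlu": rlu,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generic TSV output helper
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame, path: str | Path, header_comment: str = ""
) -> None:
    """Write an output table as TSV with an optional leading comment line
    (tool version + configuration hash)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
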