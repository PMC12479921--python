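"""Pipeline thresholds, collected in one place.

Every decision rule in the pipeline (expansion calling, single-cell QC,
candidate selection, reporter positivity, differential expression) reads its
cutoffs from a :class:`PipelineConfig`, whose defaults are the values the
underlying study used.  Output writers stamp a short hash of the active
configuration into a header comment so result tables are traceable to the
thresholds that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds with the study's defaults.

    Attributes
    ----------
    fold_threshold
        Minimum day-14 / ex-vivo frequency ratio for a clonotype to be
        called expanded (inclusive).
    day14_freq_floor
        Day-14 frequency a clonotype must exceed (strictly) for an expanded
        call to be *reportable* (0.005 = 0.5% of the repertoire).
    control_fold_ceiling
        Fold-change below which (strictly) a clonotype qualifies as a
        non-expanded control.
    day7_exponential_ratio
        Minimum day-14 / day-7 frequency ratio regarded as "exponential"
        growth in the second culture week.
    max_pct_mito
        Cell QC: maximum percentage of mitochondrial reads (inclusive).
    min_genes
        Cell QC: minimum number of genes detected (inclusive).
    require_single_trb
        Cell QC: keep only cells with exactly one productive TCR-beta chain.
    min_cells_per_gene
        Gene filter: a gene must be detected in at least this many kept cells.
    target_min_cells
        Candidate selection: minimum cells of a clonotype inside the target
        cluster (inclusive).
    target_min_fraction
        Candidate selection: fraction of a clonotype's cells that must lie
        in the target cluster (strict >).
    lum_threshold
        Reporter positivity threshold on background-adjusted luminescence
        (relative light units).
    transact_min
        Minimum adjusted TransAct (anti-CD3/CD28) signal for the
        transfection control to pass.
    require_hla_block
        Demand loss of signal under HLA class I blockade for a
        neuron-reactive verdict.
    fc_cutoff
        Absolute average log2 fold-change cutoff for DE significance.
    alpha
        Benjamini-Hochberg adjusted p-value cutoff.
    min_pct
        Minimum fraction of expressing cells, in at least one group, for a
        gene to be tested.
    normalize_scale
        Per-cell scaling constant of the log normalization.
    mito_prefix
        Gene-identifier prefix marking mitochondrial genes.
    """

    fold_threshold: float = 9.0
    day14_freq_floor: float = 0.005
    control_fold_ceiling: float = 2.0
    day7_exponential_ratio: float = 2.0

    max_pct_mito: float = 10.0
    min_genes: int = 100
    require_single_trb: bool = True
    min_cells_per_gene: int = 10

    target_min_cells: int = 10
    target_min_fraction: float = 0.60

    lum_threshold: float = 5000.0
    transact_min: float = 5000.0
    require_hla_block: bool = True

    fc_cutoff: float = 0.5
    alpha: float = 0.05
    min_pct: float = 0.1
    normalize_scale: float = 1e4

    mito_prefix: str = "MT-"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """First 8 hex digits of the SHA-1 of the sorted JSON form."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:8]

    def header_comment(self) -> str:
        """Comment line stamped at the top of every output table."""
        return f"# clonoreact v{__version__} config={self.config_hash()}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
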