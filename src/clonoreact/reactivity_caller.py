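"""NFAT-reporter reactivity calling.

Jurkat reporter cells transfected with a candidate TCR emit luminescence
upon TCR engagement.  Per TCR, replicate readouts of each condition are
averaged and the mock-transfection background is subtracted (floored at
zero).  A TCR is called neuron-reactive when its adjusted signal on
cytokine-stimulated (HLA-I high) neurons exceeds the positivity threshold
(default 5000 RLU) and, by default, the signal collapses below that
threshold under HLA class I blockade — demonstrating that activation is
TCR/HLA-mediated.  PBMC cross-reactivity reuses the same threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG
from .errors import ConfigurationError, ValidationError
from .io_formats import Condition, Group, LuminescenceAssay

logger = logging.getLogger("clonoreact")


@dataclass
class ReactivityCall:
    tcr_id: str
    adjusted_signal: dict[Condition, float]
    transfection_ok: Optional[bool]  # None = TransAct control absent
    neuron_reactive: bool
    hla_dependent: bool
    pbmc_positive: Optional[bool] = None  # None = PBMC condition absent
    pbmc_lower_than_neurons: Optional[bool] = None
    hla_independent_activation: bool = False  # unstimulated neurons > threshold
    donor_id: str = ""
    group: Optional[Group] = None


def adjust_background(
    assays: Sequence[LuminescenceAssay],
) -> dict[Condition, float]:
    """Mean replicate signal per condition, minus the mock-transfection
    mean, floored at zero.  The mock condition itself maps to 0."""
    if not assays:
        raise ValidationError("adjust_background: no assays supplied")
    tcr_ids = {a.tcr_id for a in assays}
    if len(tcr_ids) != 1:
        raise ValidationError(
            f"adjust_background expects assays of one TCR, got {sorted(tcr_ids)}"
        )
    by_condition: dict[Condition, LuminescenceAssay] = {}
    for a in assays:
        a.validate()
        if a.condition in by_condition:
            raise ValidationError(
                f"TCR {a.tcr_id}: duplicate condition {a.condition.value}"
            )
        by_condition[a.condition] = a
    if Condition.mock not in by_condition:
        raise ConfigurationError(
            f"TCR {next(iter(tcr_ids))}: mock condition required for "
            "background adjustment"
        )
    background = float(np.mean(by_condition[Condition.mock].replicates))
    adjusted: dict[Condition, float] = {}
    for cond, assay in by_condition.items():
        if cond is Condition.mock:
            adjusted[cond] = 0.0
        else:
            adjusted[cond] = max(
                0.0, float(np.mean(assay.replicates)) - background
            )
    return adjusted


def qc_transfection(
    adjusted: Mapping[Condition, float],
    transact_min: float = DEFAULT_CONFIG.transact_min,
) -> Optional[bool]:
    """Transfection QC from the anti-CD3/CD28 (TransAct) positive control.
    Returns None (unknown, treated as pass downstream) when absent."""
    if Condition.transact not in adjusted:
        logger.warning(
            "TransAct positive control absent; transfection QC unknown "
            "(treated as pass)"
        )
        return None
    return adjusted[Condition.transact] >= transact_min


def call_reactivity(
    tcr_id: str,
    adjusted: Mapping[Condition, float],
    *,
    threshold: float = DEFAULT_CONFIG.lum_threshold,
    require_hla_block: bool = DEFAULT_CONFIG.require_hla_block,
    transact_min: float = DEFAULT_CONFIG.transact_min,
) -> ReactivityCall:
    """Call neuron reactivity for one TCR from adjusted signals.

    ``neuron_reactive`` requires the stimulated-neuron signal strictly
    above ``threshold``; with ``require_hla_block`` (default) the
    HLA-blocked signal must additionally fall to or below ``threshold``.
    """
    if Condition.neurons_stim not in adjusted:
        raise ValidationError(
            f"TCR {tcr_id}: stimulated-neuron condition missing"
        )
    stim = adjusted[Condition.neurons_stim]
    above = stim > threshold
    block = adjusted.get(Condition.neurons_stim_hla_block)
    if require_hla_block and block is None:
        raise ValidationError(
            f"TCR {tcr_id}: HLA-block condition required but missing"
        )
    hla_dependent = bool(above and block is not None and block <= threshold)
    neuron_reactive = hla_dependent if require_hla_block else above

    unstim = adjusted.get(Condition.neurons_unstim)
    hla_independent = bool(unstim is not None and unstim > threshold)
    if hla_independent:
        logger.warning(
            "TCR %s: activation on unstimulated (HLA-I low) neurons above "
            "threshold — possible HLA-independent activation",
            tcr_id,
        )
    return ReactivityCall(
        tcr_id=tcr_id,
        adjusted_signal=dict(adjusted),
        transfection_ok=qc_transfection(adjusted, transact_min),
        neuron_reactive=neuron_reactive,
        hla_dependent=hla_dependent,
        hla_independent_activation=hla_independent,
    )


def call_pbmc_crossreactivity(
    call: ReactivityCall,
    *,
    threshold: float = DEFAULT_CONFIG.lum_threshold,
) -> ReactivityCall:
    """Add PBMC cross-reactivity flags to an existing call.

    When the PBMC condition is absent the flags stay ``None`` (untested),
    not ``False``.
    """
    pbmc = call.adjusted_signal.get(Condition.pbmc)
    if pbmc is None:
        return call
    call.pbmc_positive = pbmc > threshold
    call.pbmc_lower_than_neurons = bool(
        call.pbmc_positive
        and pbmc < call.adjusted_signal[Condition.neurons_stim]
    )
    return call


def process_plate(
    assays: Sequence[LuminescenceAssay],
    *,
    threshold: float = DEFAULT_CONFIG.lum_threshold,
    require_hla_block: bool = DEFAULT_CONFIG.require_hla_block,
    transact_min: float = DEFAULT_CONFIG.transact_min,
) -> list[ReactivityCall]:
    """Group a plate's assays per TCR and run the full calling chain."""
    by_tcr: dict[str, list[LuminescenceAssay]] = {}
    for a in assays:
        by_tcr.setdefault(a.tcr_id, []).append(a)
    calls: list[ReactivityCall] = []
    for tcr_id in by_tcr:
        members = by_tcr[tcr_id]
        adjusted = adjust_background(members)
        call = call_reactivity(
            tcr_id,
            adjusted,
            threshold=threshold,
            require_hla_block=require_hla_block,
            transact_min=transact_min,
        )
        call = call_pbmc_crossreactivity(call, threshold=threshold)
        call.donor_id = members[0].donor_id
        call.group = members[0].group
        calls.append(call)
    return calls


@dataclass
class GroupReactivitySummary:
    group: Group
    n_tested: int
    n_reactive: int
    pct_reactive: float  # one decimal
    n_pbmc_tested_reactive: int = 0
    n_pbmc_positive: int = 0
    pct_pbmc_cross_among_reactive: Optional[float] = None


def summarize_reactivity(
    calls: Sequence[ReactivityCall],
) -> dict[Group, GroupReactivitySummary]:
    """Per-cohort reactive fraction and, among reactive TCRs with a PBMC
    condition, the cross-reactive fraction.  TCRs failing transfection QC
    are excluded from the denominators."""
    by_group: dict[Group, list[ReactivityCall]] = {}
    for c in calls:
        if c.transfection_ok is False:
            continue
        if c.group is None:
            raise ValidationError(f"TCR {c.tcr_id}: missing cohort label")
        by_group.setdefault(c.group, []).append(c)
    out: dict[Group, GroupReactivitySummary] = {}
    for group, members in by_group.items():
        if not members:
            logger.warning("group %s: no evaluable TCRs; omitted", group.value)
            continue
        reactive = [c for c in members if c.neuron_reactive]
        pbmc_tested = [c for c in reactive if c.pbmc_positive is not None]
        n_pbmc_pos = sum(bool(c.pbmc_positive) for c in pbmc_tested)
        out[group] = GroupReactivitySummary(
            group=group,
            n_tested=len(members),
            n_reactive=len(reactive),
            pct_reactive=round(100.0 * len(reactive) / len(members), 1),
            n_pbmc_tested_reactive=len(pbmc_tested),
            n_pbmc_positive=n_pbmc_pos,
            pct_pbmc_cross_among_reactive=(
                round(100.0 * n_pbmc_pos / len(pbmc_tested), 1)
                if pbmc_tested
                else None
            ),
        )
    return out


def calls_frame(calls: Iterable[ReactivityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "tcr_id": c.tcr_id,
            "donor_id": c.donor_id,
            "group": c.group.value if c.group else "",
            "transfection_ok": c.transfection_ok,
            "neuron_reactive": c.neuron_reactive,
            "hla_dependent": c.hla_dependent,
            "hla_independent_activation": c.hla_independent_activation,
            "pbmc_positive": c.pbmc_positive,
            "pbmc_lower_than_neurons": c.pbmc_lower_than_neurons,
        }
        for cond in Condition:
            if cond in c.adjusted_signal:
                row[f"adj_{cond.value}"] = c.adjusted_signal[cond]
        rows.append(row)
    return pd.DataFrame(rows)
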