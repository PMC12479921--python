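"""Repertoire diversity metrics and the coculture expansion caller.

Diversity is summarized by two standard repertoire statistics computed on
clonotype frequencies :math:`F_i`:

* **Shannon entropy** (bits): :math:`H = -\\sum_i F_i \\log_2 F_i`.
  Higher values indicate a more diverse repertoire; a monoclonal sample
  scores 0 and a perfectly even repertoire of *n* clonotypes scores
  :math:`\\log_2 n`.
* **Clonality**, defined as one minus the Pielou evenness index:
  :math:`1 - \\left(-\\sum_i F_i \\log_{10} F_i\\right) / \\log_{10} n`.
  Clonality is 0 for an even repertoire and approaches 1 as a single
  clonotype dominates.  The normalizing ratio is base-invariant, so any
  logarithm base yields the same value.

Expansion across the neuron-PBMC coculture timecourse compares each day-14
clonotype frequency to its ex vivo frequency.  A clonotype undetected
ex vivo receives the *maximal theoretical frequency* ``1 / input_cell_count``
(one cell among the CD8+ T cells used as sequencing input) so a finite
fold-change can always be formed; with an input of 1e5 cells this gives a
detection floor of 0.001%.  A clonotype is called **expanded** when its
fold-change reaches the fold threshold (default 9), **reportable** when it
is expanded and its day-14 frequency additionally exceeds the reporting
floor (default 0.5% of the repertoire), and a **non-expanded control** when
its fold-change stays below the control ceiling (default 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import (
    ConfigurationError,
    UndefinedStatisticError,
    ValidationError,
)
from .io_formats import RepertoireSample, Timepoint

logger = logging.getLogger("clonoreact")

_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Diversity metrics
# ---------------------------------------------------------------------------


def _check_frequencies(frequencies: Sequence[float]) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValidationError("empty frequency vector")
    if np.any(f <= 0):
        raise ValidationError(
            "non-positive frequency present; drop zero-frequency clonotypes "
            "before computing diversity metrics"
        )
    total = f.sum()
    if abs(total - 1.0) > _SUM_TOL * max(1.0, f.size):
        raise ValidationError(f"frequencies sum to {total!r}, expected 1")
    return f


def shannon_entropy(frequencies: Sequence[float]) -> float:
    """Shannon entropy of a clonotype frequency vector, in bits.

    Frequencies must be strictly positive and sum to 1.  A single
    clonotype gives 0 bits.
    """
    f = _check_frequencies(frequencies)
    if f.size == 1:
        return 0.0
    return float(-(f * np.log2(f)).sum())


def clonality(frequencies: Sequence[float]) -> float:
    """Clonality (1 minus Pielou evenness) of a frequency vector.

    Undefined for a single clonotype (the evenness denominator
    ``log10(1)`` vanishes); raises :class:`UndefinedStatisticError` there.
    """
    f = _check_frequencies(frequencies)
    if f.size == 1:
        raise UndefinedStatisticError(
            "clonality is undefined for a single clonotype (log10(1) = 0)"
        )
    h10 = -(f * np.log10(f)).sum()
    value = 1.0 - h10 / math.log10(f.size)
    # clamp round-off just outside [0, 1]
    return float(min(1.0, max(0.0, value)))


def pseudo_frequency(input_cell_count: int) -> float:
    """Maximal theoretical frequency of an undetected clonotype:
    one cell among ``input_cell_count`` sequencing-input cells."""
    if input_cell_count is None:
        raise ConfigurationError(
            "input_cell_count is required to assign a pseudo-frequency to a "
            "clonotype undetected ex vivo; supply the number of CD8+ T cells "
            "used as sequencing input"
        )
    if input_cell_count < 1:
        raise ValidationError("input_cell_count must be a positive integer")
    return 1.0 / input_cell_count


def fold_change(freq_day14: float, freq_exvivo_effective: float) -> float:
    """Day-14 over ex-vivo frequency ratio.

    The ex vivo frequency must already be effective (measured, or the
    pseudo-frequency when undetected): a zero denominator is an error.
    """
    if freq_exvivo_effective <= 0:
        raise ValidationError(
            "effective ex vivo frequency must be positive; apply "
            "pseudo_frequency() to undetected clonotypes first"
        )
    return freq_day14 / freq_exvivo_effective


# ---------------------------------------------------------------------------
# Timecourse types
# ---------------------------------------------------------------------------


@dataclass
class TimecourseRepertoire:
    """One donor's bulk repertoires across the coculture timecourse."""

    donor_id: str
    samples: dict[Timepoint, RepertoireSample] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = {Timepoint(k): v for k, v in self.samples.items()}
        for tp, s in self.samples.items():
            if s.donor_id != self.donor_id:
                raise ValidationError(
                    f"sample {s.sample_id} at {tp.value} has donor "
                    f"{s.donor_id!r}, expected {self.donor_id!r}"
                )
            if s.timepoint != tp:
                raise ValidationError(
                    f"sample {s.sample_id} labelled {s.timepoint.value} "
                    f"stored under {tp.value}"
                )


@dataclass
class ExpansionCall:
    """Per-clonotype verdict of the expansion caller."""

    cdr3b_aa: str
    freq_exvivo_effective: float
    pseudo_flag: bool
    freq_day14: float
    fold_change: float
    expanded: bool
    reportable: bool
    nonexpanded_control: bool
    freq_day7: Optional[float] = None
    exponential_day7_to_day14: Optional[bool] = None


@dataclass
class RepertoireSummary:
    """Diversity summary of a single repertoire sample."""

    sample_id: str
    n_clonotypes: int
    shannon_entropy_bits: float
    clonality: Optional[float]
    top_clonotype_freq: float


# ---------------------------------------------------------------------------
# Expansion calling
# ---------------------------------------------------------------------------


def call_expansions(
    tc: TimecourseRepertoire,
    *,
    fold_threshold: float = DEFAULT_CONFIG.fold_threshold,
    day14_freq_floor: float = DEFAULT_CONFIG.day14_freq_floor,
    control_fold_ceiling: float = DEFAULT_CONFIG.control_fold_ceiling,
    day7_exponential_ratio: float = DEFAULT_CONFIG.day7_exponential_ratio,
) -> list[ExpansionCall]:
    """Call expansion for every day-14 clonotype of a timecourse.

    For each clonotype observed at day 14, the ex vivo comparator is its
    measured ex vivo frequency or, when undetected, the pseudo-frequency
    ``1 / input_cell_count`` of the ex vivo sample.  Calls are sorted by
    descending day-14 frequency, ties broken lexicographically by CDR3b.
    """
    if Timepoint.ex_vivo not in tc.samples:
        raise ConfigurationError(
            f"donor {tc.donor_id}: ex vivo sample required for expansion calling"
        )
    if Timepoint.day14 not in tc.samples:
        raise ConfigurationError(
            f"donor {tc.donor_id}: day-14 sample required for expansion calling"
        )
    exvivo = tc.samples[Timepoint.ex_vivo]
    day14 = tc.samples[Timepoint.day14]
    day7 = tc.samples.get(Timepoint.day7)

    if not day14.clonotypes:
        logger.warning("donor %s: empty day-14 repertoire", tc.donor_id)
        return []

    exvivo_freqs = {c.cdr3b_aa: c.frequency for c in exvivo.clonotypes}
    day7_freqs = (
        {c.cdr3b_aa: c.frequency for c in day7.clonotypes} if day7 else {}
    )

    calls: list[ExpansionCall] = []
    for c in day14.clonotypes:
        measured = exvivo_freqs.get(c.cdr3b_aa, 0.0)
        if measured > 0:
            effective, pseudo = measured, False
        else:
            effective, pseudo = pseudo_frequency(exvivo.input_cell_count), True
        fc = fold_change(c.frequency, effective)
        expanded = fc >= fold_threshold
        f7 = day7_freqs.get(c.cdr3b_aa) if day7 else None
        exponential = None
        if f7 is not None and f7 > 0:
            exponential = (c.frequency / f7) >= day7_exponential_ratio
        calls.append(
            ExpansionCall(
                cdr3b_aa=c.cdr3b_aa,
                freq_exvivo_effective=effective,
                pseudo_flag=pseudo,
                freq_day7=f7,
                freq_day14=c.frequency,
                fold_change=fc,
                expanded=expanded,
                reportable=expanded and c.frequency > day14_freq_floor,
                nonexpanded_control=fc < control_fold_ceiling,
                exponential_day7_to_day14=exponential,
            )
        )
    calls.sort(key=lambda e: (-e.freq_day14, e.cdr3b_aa))
    return calls


def repertoire_summary(sample: RepertoireSample) -> RepertoireSummary:
    """Diversity summary (clonotype number, entropy, clonality, top
    frequency) for one sample.  Clonality is ``None`` for a monoclonal
    sample, where it is undefined."""
    if not sample.clonotypes or sample.total_count == 0:
        raise ValidationError(f"{sample.sample_id}: empty repertoire")
    freqs = [c.frequency for c in sample.clonotypes if c.frequency > 0]
    h = shannon_entropy(freqs)
    cl = clonality(freqs) if len(freqs) >= 2 else None
    return RepertoireSummary(
        sample_id=sample.sample_id,
        n_clonotypes=len(freqs),
        shannon_entropy_bits=h,
        clonality=cl,
        top_clonotype_freq=max(freqs),
    )


def expansion_calls_frame(calls: Iterable[ExpansionCall]):
    """ExpansionCall list -> pandas DataFrame (for TSV output)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cdr3b_aa": e.cdr3b_aa,
                "freq_exvivo_effective": e.freq_exvivo_effective,
                "pseudo_flag": e.pseudo_flag,
                "freq_day7": e.freq_day7,
                "freq_day14": e.freq_day14,
                "fold_change": e.fold_change,
                "expanded": e.expanded,
                "reportable": e.reportable,
                "nonexpanded_control": e.nonexpanded_control,
                "exponential_day7_to_day14": e.exponential_day7_to_day14,
            }
            for e in calls
        ]
    )
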