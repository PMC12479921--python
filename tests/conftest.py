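import numpy as np
import pytest

from clonoreact import (
    ClonotypeRecord,
    RepertoireSample,
    Timepoint,
    TimecourseRepertoire,
)


def make_repertoire(
    counts,
    *,
    sample_id="s",
    donor_id="d",
    timepoint=Timepoint.ex_vivo,
    input_cell_count=None,
    names=None,
):
    """Repertoire from integer counts, names auto-generated if omitted."""
    total = int(sum(counts))
    if names is None:
        aa = "ACDEFGHIKLMNPQRSTVWY"
        names = [
            f"CASS{aa[i % 20]}{'Q' * (i // 20)}F" for i in range(len(counts))
        ]
    clonotypes = [
        ClonotypeRecord(
            cdr3b_aa=n, count=int(c), frequency=c / total, v_call="TRBV1", j_call="TRBJ1"
        )
        for n, c in zip(names, counts)
        if c > 0
    ]
    sample = RepertoireSample(
        sample_id=sample_id,
        donor_id=donor_id,
        timepoint=timepoint,
        clonotypes=clonotypes,
        total_count=total,
        input_cell_count=input_cell_count,
    )
    sample.validate()
    return sample


@pytest.fixture
def make_timecourse():
    def _make(exvivo_counts, day14_counts, *, names, input_cell_count=None, day7_counts=None):
        samples = {
            Timepoint.ex_vivo: make_repertoire(
                exvivo_counts,
                names=names,
                timepoint=Timepoint.ex_vivo,
                input_cell_count=input_cell_count,
            ),
            Timepoint.day14: make_repertoire(
                day14_counts, names=names, timepoint=Timepoint.day14
            ),
        }
        if day7_counts is not None:
            samples[Timepoint.day7] = make_repertoire(
                day7_counts, names=names, timepoint=Timepoint.day7
            )
        return TimecourseRepertoire(donor_id="d", samples=samples)

    return _make
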