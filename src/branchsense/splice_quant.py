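"""PSI/PIR quantification and event classification from junction counts.

PSI (percent spliced in) for cassette exons and PIR (percent intron
retention) for retained introns are computed from junction read counts as
simple junction ratios:

* CE:  PSI = 100 * (inc1 + inc2) / (inc1 + inc2 + 2 * exc)
* IR:  PIR = 100 * mean(ei1, ei2) / (mean(ei1, ei2) + ee)

where inc1/inc2 are the two inclusion junctions, exc the exclusion
junction, ei1/ei2 the exon-intron boundary reads and ee the exon-exon
(spliced) junction.  These junction-ratio definitions are stand-ins for a
full read-rescaling quantifier (e.g. VAST-TOOLS); they agree with it in
expectation under uniform junction coverage.

Replicates are averaged per condition *before* taking the treated-minus-
control difference.  Events are classified with the conventional
thresholds |delta| >= 25 (regulated) and |delta| <= 5 (non-regulated),
with a minimum-coverage filter of 10 informative reads per condition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CE_COUNTS, IR_COUNTS, EventTable

__all__ = [
    "EventClass",
    "PsiRecord",
    "psi_ce",
    "pir",
    "delta",
    "classify",
    "quantify",
    "regulated_sets",
    "REGULATED_THRESHOLD",
    "NONDIFF_THRESHOLD",
]

REGULATED_THRESHOLD = 25.0
NONDIFF_THRESHOLD = 5.0
MIN_READS = 10


class EventClass(str, enum.Enum):
    """Regulation class of a splicing event (exhaustive, mutually exclusive)."""

    REGULATED_UP = "regulated_up"
    REGULATED_DOWN = "regulated_down"
    NONDIFF = "nondiff"
    INTERMEDIATE = "intermediate"
    LOW_COVERAGE = "low_coverage"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass(frozen=True)
class PsiRecord:
    """PSI/PIR of one event in control and treated conditions (percent)."""

    psi_control: float
    psi_treated: float
    covered: bool = True

    @property
    def delta(self) -> float:
        return delta(self.psi_treated, self.psi_control)


def psi_ce(inc1: int, inc2: int, exc: int) -> float:
    """Percent spliced in of a cassette exon from its three junction counts.

    Each inclusion read supports one of two inclusion junctions while an
    exclusion read supports the single skipping junction, hence the factor
    2 on ``exc``.  Returns NaN when all counts are zero.
    """
    if min(inc1, inc2, exc) < 0:
        raise ValueError("junction counts must be non-negative")
    total = inc1 + inc2 + 2 * exc
    if inc1 + inc2 + exc == 0:
        return math.nan
    return 100.0 * (inc1 + inc2) / total


def pir(ei1: int, ei2: int, ee: int) -> float:
    """Percent intron retention from the two exon-intron boundary counts and
    the spliced exon-exon junction count.  NaN when all counts are zero."""
    if min(ei1, ei2, ee) < 0:
        raise ValueError("junction counts must be non-negative")
    if ei1 + ei2 + ee == 0:
        return math.nan
    retained = 0.5 * (ei1 + ei2)
    return 100.0 * retained / (retained + ee)


def delta(treated: float, control: float) -> float:
    """Treated-minus-control difference of PSI or PIR, in percent points.

    Missing inputs propagate as NaN; by construction of PSI/PIR the result
    lies in [-100, 100] without clamping.
    """
    return treated - control


def classify(delta_value: float, min_reads: int = MIN_READS,
             total_reads: int | None = None,
             regulated_threshold: float = REGULATED_THRESHOLD,
             nondiff_threshold: float = NONDIFF_THRESHOLD) -> EventClass:
    """Classify one event from its delta PSI/PIR.

    ``total_reads`` is the smallest per-condition informative read count;
    below ``min_reads`` the event is LOW_COVERAGE regardless of delta.
    Boundaries are closed as conventionally printed: delta = 25 is
    regulated, delta = 5 is nondiff.
    """
    if total_reads is not None and total_reads < min_reads:
        return EventClass.LOW_COVERAGE
    if delta_value is None or math.isnan(delta_value):
        return EventClass.LOW_COVERAGE
    if abs(delta_value) >= regulated_threshold:
        return EventClass.REGULATED_UP if delta_value > 0 else EventClass.REGULATED_DOWN
    if abs(delta_value) <= nondiff_threshold:
        return EventClass.NONDIFF
    return EventClass.INTERMEDIATE


def _condition_psi(row: pd.Series, etype: str, samples: Sequence[str]) -> tuple[float, int]:
    """Replicate-averaged PSI/PIR and total informative reads for one condition."""
    family = CE_COUNTS if etype == "CE" else IR_COUNTS
    func = psi_ce if etype == "CE" else pir
    values, total = [], 0
    for s in samples:
        counts = [int(row[f"{b}_{s}"]) for b in family]
        total += sum(counts)
        v = func(*counts)
        if not math.isnan(v):
            values.append(v)
    return (float(np.mean(values)) if values else math.nan), total


def quantify(table: EventTable, control: Sequence[str], treated: Sequence[str],
             min_reads: int = MIN_READS,
             regulated_threshold: float = REGULATED_THRESHOLD,
             nondiff_threshold: float = NONDIFF_THRESHOLD) -> pd.DataFrame:
    """Quantify and classify every event of an :class:`EventTable`.

    ``control`` and ``treated`` name the replicate samples of each
    condition.  Returns a DataFrame indexed like the table with columns
    EVENT_ID, TYPE, psi_control, psi_treated, delta, total_reads, covered,
    event_class.
    """
    for s in list(control) + list(treated):
        if s not in table.samples:
            raise ValueError(f"unknown sample {s!r}; table has {table.samples}")
    rows = []
    for _, row in table.df.iterrows():
        etype = row["TYPE"]
        psi_c, reads_c = _condition_psi(row, etype, control)
        psi_t, reads_t = _condition_psi(row, etype, treated)
        d = delta(psi_t, psi_c)
        total = min(reads_c, reads_t)
        cls = classify(d, min_reads=min_reads, total_reads=total,
                       regulated_threshold=regulated_threshold,
                       nondiff_threshold=nondiff_threshold)
        rows.append({
            "EVENT_ID": row["EVENT_ID"], "TYPE": etype,
            "psi_control": psi_c, "psi_treated": psi_t, "delta": d,
            "total_reads": total, "covered": total >= min_reads,
            "event_class": str(cls),
        })
    return pd.DataFrame(rows)


def regulated_sets(quantified: Mapping[str, pd.DataFrame]) -> dict[str, dict[str, set[str]]]:
    """Per-drug sets of regulated event ids, split by direction.

    ``quantified`` maps drug name to the output of :func:`quantify`.  All
    drugs must cover the same event universe; a mismatch raises with the
    symmetric difference listed.  Returns
    ``{drug: {"up": ids, "down": ids, "regulated": ids}}``.
    """
    universes = {drug: frozenset(df["EVENT_ID"]) for drug, df in quantified.items()}
    ref_drug = next(iter(universes))
    for drug, universe in universes.items():
        if universe != universes[ref_drug]:
            diff = sorted(universe ^ universes[ref_drug])
            raise ValueError(
                f"event universes differ between {ref_drug!r} and {drug!r}: "
                f"symmetric difference {diff[:20]}{'...' if len(diff) > 20 else ''}"
            )
    out: dict[str, dict[str, set[str]]] = {}
    for drug in sorted(quantified):
        df = quantified[drug]
        up = set(df.loc[df["event_class"] == "regulated_up", "EVENT_ID"])
        down = set(df.loc[df["event_class"] == "regulated_down", "EVENT_ID"])
        out[drug] = {"up": up, "down": down, "regulated": up | down}
    return out
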