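"""Single-copy-ortholog completeness summaries and the haplotig-purge rule.

A BUSCO run classifies each marker of an ortholog set as complete
(single-copy or duplicated), fragmented, or missing. The duplication
rate (D as a percentage of all markers searched) drives the decision of
whether an assembly needs haplotig identification and removal: purging
is triggered when the duplication rate strictly exceeds the threshold
(default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import MarkerTable


@dataclass
class BuscoSummary:
    n_searched: int
    n_complete: int
    n_single: int
    n_duplicated: int
    n_fragmented: int
    n_missing: int
    pct_complete: float
    pct_single: float
    pct_duplicated: float
    pct_fragmented: float
    pct_missing: float
    duplication_rate_pct: float


def busco_summary(table: MarkerTable) -> BuscoSummary:
    """Summarize a marker table; a marker with >=2 placements counts once
    as duplicated, and n_searched is the number of distinct marker ids."""
    if not table.records:
        raise ValueError("empty marker table")
    by_id = {}
    for r in table.records:
        by_id.setdefault(r.marker_id, []).append(r)
    n_single = n_dup = n_frag = n_miss = 0
    for recs in by_id.values():
        statuses = {r.status for r in recs}
        if "duplicated" in statuses or len(recs) >= 2:
            n_dup += 1
        elif "complete_single" in statuses:
            n_single += 1
        elif "fragmented" in statuses:
            n_frag += 1
        else:
            n_miss += 1
    n = len(by_id)
    n_complete = n_single + n_dup
    pct = lambda k: 100.0 * k / n
    return BuscoSummary(
        n_searched=n,
        n_complete=n_complete,
        n_single=n_single,
        n_duplicated=n_dup,
        n_fragmented=n_frag,
        n_missing=n_miss,
        pct_complete=pct(n_complete),
        pct_single=pct(n_single),
        pct_duplicated=pct(n_dup),
        pct_fragmented=pct(n_frag),
        pct_missing=pct(n_miss),
        duplication_rate_pct=pct(n_dup),
    )


def purge_decision(summary: BuscoSummary, threshold_pct: float = 1.0) -> bool:
    """True iff the duplication rate strictly exceeds ``threshold_pct``."""
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be non-negative")
    return summary.duplication_rate_pct > threshold_pct
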