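"""Bundled multi-year nest census of 13 polydomous wood ant colonies.

Per-colony nest counts at the five mapping timepoints (summer of the first
study year, then spring and summer of the two following years).  The
bookkeeping helpers recompute net nest-count change over the study window
from the raw counts; published summary tables occasionally carry rounding
or transcription inconsistencies, so percentages here are always recomputed
from the counts rather than taken on faith.
"""

from __future__ import annotations

import pandas as pd

CENSUS_TIMEPOINTS = (
    "2012-summer", "2013-spring", "2013-summer", "2014-spring", "2014-summer",
)

#: nests present per colony at each timepoint
COLONY_CENSUS: dict[str, tuple[int, ...]] = {
    "I": (21, 16, 15, 11, 14),
    "IIa": (4, 3, 4, 4, 4),
    "IIb": (6, 6, 6, 9, 9),
    "III": (12, 12, 8, 9, 16),
    "IV": (12, 9, 6, 7, 7),
    "V": (14, 11, 10, 8, 2),
    "VI": (14, 12, 12, 13, 11),
    "VII": (7, 7, 4, 5, 8),
    "VIII": (6, 3, 4, 6, 4),
    "IX": (9, 11, 17, 11, 15),
    "X": (13, 8, 10, 9, 8),
    "XI": (20, 15, 10, 10, 17),
    "XII": (6, 6, 3, 8, 3),
}


def net_change(counts: tuple[int, ...] | list[int]) -> int:
    """Net change in nest number between the first and last timepoint."""
    return int(counts[-1]) - int(counts[0])


def net_change_percent(counts: tuple[int, ...] | list[int]) -> float:
    """Net change as a percentage of the initial nest count."""
    return 100.0 * net_change(counts) / counts[0]


def census_frame() -> pd.DataFrame:
    """The census as a tidy table with recomputed net-change columns."""
    rows = []
    for colony, counts in COLONY_CENSUS.items():
        row = {"colony_id": colony}
        row.update(dict(zip(CENSUS_TIMEPOINTS, counts)))
        row["net_change"] = net_change(counts)
        row["net_change_percent"] = round(net_change_percent(counts), 1)
        rows.append(row)
    return pd.DataFrame(rows)
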