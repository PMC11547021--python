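"""Temporal epoch labels for peri-operative activity trajectories.

A patient's normalized daily-activity trajectory over the four-year
peri-operative window is partitioned into up to six states: a pre-operative
baseline year, an acute pre-operative decline, transient pre-operative
spontaneous recoveries, the acute post-operative recovery, a fully recovered
plateau at (or above) baseline, and a secondary decline occurring only after
full recovery.
"""

from __future__ import annotations

import enum


class Epoch(enum.IntEnum):
    """Labels for the six temporal epochs, ordered as they may occur."""

    BASELINE = 1
    PRE_OP_DECLINE = 2
    SPONTANEOUS_RECOVERY = 3
    POST_OP_RECOVERY = 4
    FULLY_RECOVERED = 5
    SECONDARY_DECLINE = 6


#: Day window analyzed around surgery: two years before through two years
#: after.  Day 0 is the surgery day and belongs to the post-operative side,
#: so the grid is [-730, 729] (1460 days).
WINDOW_PRE_DAYS = 730
WINDOW_POST_DAYS = 730

#: The baseline year: the first year of the pre-operative window, whose mean
#: daily step count defines each patient's normalization constant.
BASELINE_YEAR = (-730, -366)
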