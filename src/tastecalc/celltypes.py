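"""KCl-based functional cell typing and the umami gating rule.

Taste cells responding to 50 mM KCl are presumed to express voltage-gated
calcium channels and are designated presumptive Type III; KCl-tested
non-responders are presumptive Type II.  Because monopotassium glutamate
(MPG) can depolarise Type III cells through its potassium ion alone, MPG
responses count as umami responses only in cells that did NOT respond to
KCl; KCl-positive (and KCl-untested) cells are dropped from umami
summaries, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .quantify import ResponseCall

logger = logging.getLogger(__name__)

PRESUMPTIVE_TYPE_III = "presumptive_TypeIII"
PRESUMPTIVE_TYPE_II = "presumptive_TypeII"
UNDETERMINED = "undetermined"


@dataclass
class CellProfile:
    """A cell's response calls across stimuli plus its KCl status."""

    cell_id: str
    group: str
    calls: dict[str, ResponseCall] = field(default_factory=dict)
    kcl_responsive: bool | None = None  # None = KCl epoch not tested

    @property
    def inferred_type(self) -> str:
        return classify_cell(self)


def classify_cell(profile: CellProfile) -> str:
    """KCl-positive → presumptive Type III; tested negative → presumptive
    Type II; untested → undetermined."""
    if profile.kcl_responsive is None:
        return UNDETERMINED
    return PRESUMPTIVE_TYPE_III if profile.kcl_responsive else PRESUMPTIVE_TYPE_II


def profiles_from_calls(
    calls: Iterable[ResponseCall], group: str
) -> list[CellProfile]:
    """Group per-epoch calls into per-cell profiles; the KCl call (stimulus
    ``KCL``) sets ``kcl_responsive`` and is kept out of the tastant map."""
    by_cell: dict[str, CellProfile] = {}
    for call in calls:
        prof = by_cell.setdefault(call.cell_id, CellProfile(call.cell_id, group))
        if call.stimulus.upper() == "KCL":
            prof.kcl_responsive = call.responsive
        else:
            prof.calls[call.stimulus] = call
    return list(by_cell.values())


def select_umami_responses(profiles: Iterable[CellProfile]) -> list[ResponseCall]:
    """MPG calls from KCl-non-responsive cells only.

    KCl-positive cells are excluded because their MPG response may reflect
    potassium-driven depolarisation rather than umami transduction; cells
    without a KCl test are excluded conservatively.
    """
    kept: list[ResponseCall] = []
    dropped_positive = dropped_untested = 0
    for prof in profiles:
        call = prof.calls.get("MPG")
        if call is None:
            continue
        if prof.kcl_responsive is None:
            dropped_untested += 1
        elif prof.kcl_responsive:
            dropped_positive += 1
        else:
            kept.append(call)
    if dropped_positive or dropped_untested:
        logger.info(
            "umami gating: dropped %d KCl-positive and %d KCl-untested cells "
            "from MPG analysis", dropped_positive, dropped_untested,
        )
    if dropped_untested:
        logger.warning(
            "%d cells lacked a KCl epoch and were excluded from umami analysis",
            dropped_untested,
        )
    return kept


def type_counts(profiles: Iterable[CellProfile]) -> dict[str, int]:
    """Counts over the three inferred types (partition of the cohort)."""
    counts = {PRESUMPTIVE_TYPE_III: 0, PRESUMPTIVE_TYPE_II: 0, UNDETERMINED: 0}
    for prof in profiles:
        counts[classify_cell(prof)] += 1
    return counts
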