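"""Quantify pairwise growth effects and assign one of six interaction types.

Each species' percent change in growth rate (community vs. isolation) is
reduced to a sign with a strict 10 % threshold — an interaction is only
considered to occur when the change exceeds 10 % in magnitude.  The sign pair
then maps onto the classical ecological interaction types:

====================  =========
(sign_a, sign_b)      type
====================  =========
(+, +)                mutualism
(+, 0) / (0, +)       commensalism
(+, −) / (−, +)       parasitism
(−, −)                competition
(−, 0) / (0, −)       amensalism
(0, 0)                neutralism
====================  =========

Positive interactions (mutualism, commensalism) are those where at least one
species benefits and none suffers; negative interactions (parasitism,
amensalism, competition) are those where at least one species suffers;
neutralism carries no polarity.

A species with zero growth in isolation but positive growth in community (an
obligate association) has an undefined percent change; it is reported with
the ``OBLIGATE_GAIN`` sentinel (``math.inf``) and counts as a positive effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from .diet_fba import GrowthResult
from .errors import FormatError

__all__ = [
    "OBLIGATE_GAIN",
    "InteractionRecord",
    "InteractionSummary",
    "percent_change",
    "effect_sign",
    "classify",
    "summarize",
    "write_interactions",
    "read_interactions",
    "INTERACTION_THRESHOLD",
    "TYPE_OF_SIGNS",
    "POLARITY_OF_TYPE",
]

#: Sentinel for an obligate gain: zero growth alone, positive growth together.
OBLIGATE_GAIN = math.inf

#: Strict percent-change threshold: an interaction occurs only over 10 %.
INTERACTION_THRESHOLD = 10.0

#: Growth below this counts as "no growth" when detecting obligate gains.
_GROWS = 1e-6
_ZERO = 1e-9

TYPE_OF_SIGNS: dict[tuple[str, str], str] = {
    ("+", "+"): "mutualism",
    ("+", "0"): "commensalism",
    ("0", "+"): "commensalism",
    ("+", "-"): "parasitism",
    ("-", "+"): "parasitism",
    ("-", "-"): "competition",
    ("-", "0"): "amensalism",
    ("0", "-"): "amensalism",
    ("0", "0"): "neutralism",
}

POLARITY_OF_TYPE: dict[str, str] = {
    "mutualism": "positive",
    "commensalism": "positive",
    "parasitism": "negative",
    "amensalism": "negative",
    "competition": "negative",
    "neutralism": "none",
}


@dataclass
class InteractionRecord:
    """Typed, signed interaction for one genome pair."""

    pair: tuple[str, str]
    change_a: float  # percent, or OBLIGATE_GAIN (inf)
    change_b: float
    sign_a: str
    sign_b: str
    type_label: str
    polarity: str


@dataclass
class InteractionSummary:
    """Counts by interaction type and polarity, with printed-style percents."""

    counts: dict[str, int]
    polarity_counts: dict[str, int]
    polarity_percent: dict[str, float]
    total: int


def percent_change(g_alone: float, g_together: float) -> float:
    """Percent change of the community growth rate relative to isolation.

    ``100 × (g_together − g_alone) / g_alone`` when the species grows alone;
    :data:`OBLIGATE_GAIN` when it only grows in company; 0 when it grows in
    neither case.
    """
    if g_alone < 0 or g_together < 0:
        raise ValueError(
            f"growth rates must be ≥ 0, got ({g_alone}, {g_together})"
        )
    if g_alone > _ZERO:
        return 100.0 * (g_together - g_alone) / g_alone
    if g_together > _GROWS:
        return OBLIGATE_GAIN
    return 0.0


def effect_sign(change: float) -> str:
    """Reduce a percent change to ``+``, ``0`` or ``-`` (strict 10 % rule)."""
    if change > INTERACTION_THRESHOLD:  # OBLIGATE_GAIN (inf) lands here
        return "+"
    if change < -INTERACTION_THRESHOLD:
        return "-"
    return "0"


def classify(growth: GrowthResult) -> InteractionRecord:
    """Assign the interaction type and polarity for one growth quadruple."""
    change_a = percent_change(growth.g_a_alone, growth.g_a_together)
    change_b = percent_change(growth.g_b_alone, growth.g_b_together)
    sign_a, sign_b = effect_sign(change_a), effect_sign(change_b)
    type_label = TYPE_OF_SIGNS[(sign_a, sign_b)]
    return InteractionRecord(
        pair=growth.pair,
        change_a=change_a,
        change_b=change_b,
        sign_a=sign_a,
        sign_b=sign_b,
        type_label=type_label,
        polarity=POLARITY_OF_TYPE[type_label],
    )


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(records: Sequence[InteractionRecord]) -> InteractionSummary:
    """Counts by type and polarity; polarity percents rounded half-up to 0.1."""
    if not records:
        raise ValueError("cannot summarize an empty set of interaction records")
    counts = {t: 0 for t in POLARITY_OF_TYPE}
    polarity_counts = {"positive": 0, "negative": 0, "none": 0}
    for rec in records:
        counts[rec.type_label] += 1
        polarity_counts[rec.polarity] += 1
    total = len(records)
    polarity_percent = {
        pol: _round_half_up(100.0 * n / total) for pol, n in polarity_counts.items()
    }
    return InteractionSummary(
        counts=counts,
        polarity_counts=polarity_counts,
        polarity_percent=polarity_percent,
        total=total,
    )


def _format_change(change: float) -> str:
    return "OBLIGATE_GAIN" if math.isinf(change) else f"{change:.9g}"


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("genome_a\tgenome_b\tchange_a\tchange_b\ttype\tpolarity\n")
        for r in records:
            handle.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{_format_change(r.change_a)}"
                f"\t{_format_change(r.change_b)}\t{r.type_label}\t{r.polarity}\n"
            )
    return path


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    path = Path(path)
    out: list[InteractionRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("genome_a"):
            raise FormatError(f"{path}: expected interaction-table header")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            change_a = OBLIGATE_GAIN if fields[2] == "OBLIGATE_GAIN" else float(fields[2])
            change_b = OBLIGATE_GAIN if fields[3] == "OBLIGATE_GAIN" else float(fields[3])
            out.append(
                InteractionRecord(
                    pair=(fields[0], fields[1]),
                    change_a=change_a,
                    change_b=change_b,
                    sign_a=effect_sign(change_a),
                    sign_b=effect_sign(change_b),
                    type_label=fields[4],
                    polarity=fields[5],
                )
            )
    return out
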