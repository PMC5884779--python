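"""Per-herb target attribution by component-connectivity medians.

For a multi-herb formula the question is which herb drives which target.
For each herb we count, per target, how many of that herb's compounds have
a retained compound->protein edge to it; a target is *major* for the herb
when its count is not less than (>=, inclusive) the herb's median count
over the targets it touches. Medians use the midpoint-of-two-central-values
convention, so fractional medians (e.g. 11.5) are possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

from .network import CTDNetwork

__all__ = ["HerbAttributionRow", "component_counts", "major_targets", "attribute_herbs"]


@dataclass(frozen=True)
class HerbAttributionRow:
    herb: str
    target: str
    component_count: int
    herb_median: float
    is_major: bool


def component_counts(
    net: CTDNetwork, herb: str, targets: Iterable[str]
) -> dict[str, int]:
    """Distinct compounds of ``herb`` with a retained edge to each target."""
    if herb not in net.graph or net.graph.nodes[herb]["kind"] != "herb":
        raise ValueError(f"unknown herb {herb!r}")
    herb_compounds = {
        c for c in net.graph.neighbors(herb) if net.graph.nodes[c]["kind"] == "compound"
    }
    counts: dict[str, int] = {}
    for t in targets:
        if t in net.graph:
            hits = sum(1 for c in net.graph.neighbors(t) if c in herb_compounds)
        else:
            hits = 0
        counts[t] = hits
    return counts


def major_targets(
    counts: Mapping[str, int],
    median_override: float | None = None,
    herb: str = "",
    include_zero_in_median: bool = False,
) -> list[HerbAttributionRow]:
    """Flag targets whose count is >= the herb's median component count.

    By default the median is taken over targets the herb actually touches
    (count > 0), since untouched targets say nothing about the herb's
    connectivity; set ``include_zero_in_median`` to widen it. The inclusive
    comparison means a count exactly equal to the median is major.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if median_override is not None:
        herb_median = float(median_override)
    else:
        pool = (
            list(counts.values())
            if include_zero_in_median
            else [c for c in counts.values() if c > 0]
        )
        herb_median = float(median(pool)) if pool else 0.0
    rows = [
        HerbAttributionRow(
            herb=herb,
            target=t,
            component_count=c,
            herb_median=herb_median,
            is_major=c >= herb_median,
        )
        for t, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r.component_count, r.target))
    return rows


def attribute_herbs(
    net: CTDNetwork, targets: Iterable[str]
) -> list[HerbAttributionRow]:
    """Run the count + median rule for every herb in the network."""
    targets = list(targets)
    rows: list[HerbAttributionRow] = []
    for herb in net.herbs:
        counts = component_counts(net, herb, targets)
        if not counts:
            continue
        rows.extend(major_targets(counts, herb=herb))
    return rows
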