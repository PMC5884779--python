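"""Gene-set over-representation analysis (ORA) of a target list.

Tests a query set of protein targets against a collection of named gene
sets (pathways, read from GMT) over a declared background universe, using
the exact hypergeometric upper tail. Two scores are offered:

* ``tail`` — P(X >= count), the standard Fisher-exact/ORA p-value;
* ``ease`` — P(X >= count - 1), the conservative one-fewer variant
  popularized by the DAVID/EASE tools.

Published ORA p-values are only reproducible when the background universe
and set collection are declared; this module therefore guarantees
oracle-exact results on *stated* backgrounds rather than chasing any
particular web service's hidden defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .enrichment import hypergeom_upper_tail
from .io import DiseaseTargetDB

__all__ = ["PathwayEnrichmentRow", "enrich_pathways"]


@dataclass(frozen=True)
class PathwayEnrichmentRow:
    """One pathway with its query overlap and enrichment p-value."""

    pathway: str
    count: int
    pathway_size: int
    background_size: int
    p_value: float


def enrich_pathways(
    query: Iterable[str],
    pathways: DiseaseTargetDB,
    background: Iterable[str] | None = None,
    variant: Literal["tail", "ease"] = "tail",
    min_count: int = 2,
) -> list[PathwayEnrichmentRow]:
    """Score each pathway's overlap with ``query`` over ``background``.

    ``background`` defaults to the union of all pathway sets; the query
    must be contained in it. Each pathway set is intersected with the
    background before testing. Rows with overlap below ``min_count`` are
    suppressed (pass 0 to report everything); survivors are sorted by
    ascending p-value, ties by descending count then name.
    """
    if variant not in ("tail", "ease"):
        raise ValueError(f"unknown variant {variant!r}")
    query_set = frozenset(query)
    bg = frozenset(background) if background is not None else pathways.universe
    offenders = query_set - bg
    if offenders:
        raise ValueError(
            f"{len(offenders)} query target(s) outside the background: "
            f"{sorted(offenders)[:10]}"
        )
    N = len(bg)
    n = len(query_set)
    rows = []
    for name, members in pathways.entries.items():
        in_bg = members & bg
        K = len(in_bg)
        count = len(in_bg & query_set)
        if count < min_count:
            continue
        k_tested = count if variant == "tail" else count - 1
        p = hypergeom_upper_tail(max(k_tested, 0), N, K, n)
        rows.append(
            PathwayEnrichmentRow(
                pathway=name,
                count=count,
                pathway_size=K,
                background_size=N,
                p_value=p,
            )
        )
    rows.sort(key=lambda r: (r.p_value, -r.count, r.pathway))
    return rows
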