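"""Hypergeometric disease-enrichment over the connected disease targets.

The repositioning statistic asks: of the n disease-database targets that end
up connected to the drug-target network, how surprising is it that k of them
belong to a particular disease with K targets in the N-target universe?
Sampling is without replacement, so X ~ Hypergeometric(N, K, n).

Two variants are exposed:

* ``point`` — the point probability P(X = k). This is the statistic that
  published compound-disease enrichment tables of this kind actually print
  under the name "p-value" (the K=1, k=1 rows equal exactly n/N, which only
  the point mass does), so it is the default.
* ``upper_tail`` — P(X >= k), the conventional over-representation p-value.

Both are computed with exact integer arithmetic (binomial coefficients via
``math.comb`` and :class:`fractions.Fraction`), so results are correct to
full double precision rather than to log-gamma rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Literal, Sequence

from .io import DiseaseTargetDB

__all__ = [
    "EnrichmentConfig",
    "DiseaseEnrichmentRow",
    "hypergeom_pmf",
    "hypergeom_upper_tail",
    "enrich_from_counts",
    "enrich_diseases",
    "select_major_diseases",
    "benjamini_hochberg",
]

Variant = Literal["point", "upper_tail"]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the disease-enrichment test.

    N is the disease-target universe size, n the number of connected
    (retained) disease targets. The selection filter keeps diseases with
    ``p_value < alpha`` and ``match > min_match``.
    """

    N: int
    n: int
    variant: Variant = "point"
    alpha: float = 0.05
    min_match: int = 2
    correction: Literal["none", "benjamini_hochberg"] = "none"

    def __post_init__(self) -> None:
        if not (0 < self.n <= self.N):
            raise ValueError(f"need 0 < n <= N, got n={self.n}, N={self.N}")
        if not (0.0 < self.alpha < 1.0) and self.alpha not in (0.0, 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.variant not in ("point", "upper_tail"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class DiseaseEnrichmentRow:
    """One disease: match count k, disease total K, and its p-value."""

    disease: str
    match: int
    total: int
    p_value: float
    q_value: float | None = None


def _check_args(k: int, N: int, K: int, n: int) -> None:
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N) or k < 0:
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, N={N}, K={K}, n={n}"
        )


def _pmf_fraction(k: int, N: int, K: int, n: int) -> Fraction:
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """Exact point probability P(X = k), X ~ Hypergeometric(N, K, n).

    Returns 0.0 outside the support max(0, n+K-N) <= k <= min(K, n).
    """
    _check_args(k, N, K, n)
    return float(_pmf_fraction(k, N, K, n))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k); equals 1 for k <= max(0, n+K-N)."""
    _check_args(k, N, K, n)
    lo = max(0, n + K - N)
    if k <= lo:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    total = Fraction(0)
    for j in range(k, hi + 1):
        total += _pmf_fraction(j, N, K, n)
    return float(total)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def enrich_from_counts(
    triples: Iterable[tuple[str, int, int]], config: EnrichmentConfig
) -> list[DiseaseEnrichmentRow]:
    """Score (disease, k, K) triples directly, bypassing set intersection.

    Rows are sorted by ascending p-value, ties broken by descending match
    count then disease name, giving a total deterministic ranking.
    """
    rows = []
    for disease, k, K in triples:
        if not (0 <= k <= min(K, config.n)) or K > config.N:
            raise ValueError(
                f"inconsistent counts for {disease!r}: k={k}, K={K}, "
                f"N={config.N}, n={config.n}"
            )
        if config.variant == "point":
            p = hypergeom_pmf(k, config.N, K, config.n)
        else:
            p = hypergeom_upper_tail(k, config.N, K, config.n)
        rows.append(DiseaseEnrichmentRow(disease=disease, match=k, total=K, p_value=p))
    rows.sort(key=lambda r: (r.p_value, -r.match, r.disease))
    if config.correction == "benjamini_hochberg":
        qs = benjamini_hochberg([r.p_value for r in rows])
        rows = [replace(r, q_value=q) for r, q in zip(rows, qs)]
    return rows


def enrich_diseases(
    db: DiseaseTargetDB, connected: Iterable[str], config: EnrichmentConfig
) -> list[DiseaseEnrichmentRow]:
    """Score every disease in ``db`` against the connected target set.

    ``connected`` must be a subset of the database universe with exactly
    ``config.n`` members, and the universe must have ``config.N`` members.
    Diseases with no overlap are reported (not dropped) so the output is a
    total ranking of the database.
    """
    connected_set = frozenset(connected)
    stray = connected_set - db.universe
    if stray:
        raise ValueError(
            f"{len(stray)} connected target(s) outside the disease universe, "
            f"e.g. {sorted(stray)[:5]}"
        )
    if len(connected_set) != config.n:
        raise ValueError(
            f"config.n={config.n} but |connected|={len(connected_set)}"
        )
    if db.n_universe != config.N:
        raise ValueError(
            f"config.N={config.N} but |universe|={db.n_universe}"
        )
    triples = [
        (name, len(members & connected_set), len(members))
        for name, members in db.entries.items()
    ]
    return enrich_from_counts(triples, config)


def select_major_diseases(
    rows: Sequence[DiseaseEnrichmentRow], config: EnrichmentConfig
) -> list[DiseaseEnrichmentRow]:
    """Keep diseases with p_value < alpha and match > min_match, in rank order."""
    return [r for r in rows if r.p_value < config.alpha and r.match > config.min_match]
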