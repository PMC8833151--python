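"""Rarity indices and multi-region richness partitioning.

Rarity follows the "rare = singletons + doubletons" convention, with the
singleton/unique count optionally replaced by its adjusted (true-
singleton) estimate.  Partitioning pools the per-region incidence
structures over every nonempty subset of the R regions (2^R − 1
combinations), applies a richness estimator to each pooled subset, and
decomposes the full-set estimate into exclusive (Venn) components by
Möbius inversion over the subset lattice.  Because the estimator is
nonlinear, exclusive components can come out slightly negative; they are
clamped to zero and the pre-clamp residual is reported, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import pandas as pd

from ._util import round_half_up
from .estimators import adjusted_chao2, chao2, chao2_ci, estimate_true_uniques
from .grid import FrequencyCounts, GridIncidence, tally_frequencies

__all__ = [
    "RarityResult",
    "PartitionTable",
    "rarity_metrics",
    "to_be_discovered",
    "pool_subset",
    "partition_richness",
]


# ---------------------------------------------------------------------------
# rarity


@dataclass(frozen=True)
class RarityResult:
    """Rare-species indices for one tally.

    ``rare_count`` = adjusted singletons (or uniques) + doubletons (or
    duplicates); ``rarity_fraction`` = rare_count / S_obs; ``ratio`` =
    adjusted singletons / doubletons (None when doubletons = 0).
    """

    mode: str
    rare_count: float
    rarity_fraction: float
    ratio: float | None


def rarity_metrics(
    counts: FrequencyCounts, adjusted_singletons: float | None = None
) -> RarityResult:
    """Rarity indices; pass the adjusted singleton estimate to discount
    false singletons, or omit it to use the observed count."""
    if counts.s_obs == 0:
        raise ValueError("rarity undefined for an empty assemblage")
    s1 = float(counts.q1 if adjusted_singletons is None else adjusted_singletons)
    if s1 < 0:
        raise ValueError("adjusted singletons must be >= 0")
    rare = s1 + counts.q2
    return RarityResult(
        mode=counts.mode,
        rare_count=rare,
        rarity_fraction=min(rare / counts.s_obs, 1.0),
        ratio=(s1 / counts.q2) if counts.q2 > 0 else None,
    )


def to_be_discovered(adjusted_point: float, s_obs: int) -> tuple[int, bool]:
    """Species still to be discovered: round(adjusted_point − S_obs).

    Returns ``(count, clamped)``; a negative difference reports 0 with
    the clamped flag set.
    """
    if adjusted_point < 0:
        raise ValueError("adjusted_point must be >= 0")
    diff = round_half_up(adjusted_point - s_obs)
    if diff < 0:
        return 0, True
    return int(diff), False


# ---------------------------------------------------------------------------
# subset pooling


def pool_subset(
    incidences: dict[str, GridIncidence], subset: list[str] | tuple[str, ...]
) -> GridIncidence:
    """Pool per-region incidences over a subset of region labels.

    Regions must be disjoint in sampling units, so pooled T is the sum
    of member T and a species' pooled Y is the sum of its per-region Y.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    unknown = [r for r in subset if r not in incidences]
    if unknown:
        raise KeyError(f"unknown region labels {unknown}")
    if len(subset) == 1:
        return incidences[subset[0]]

    T = 0
    incidence: dict[str, int] = {}
    cell_species: dict[object, frozenset] = {}
    for r in subset:
        inc = incidences[r]
        T += inc.T
        for sp, y in inc.incidence.items():
            incidence[sp] = incidence.get(sp, 0) + y
        for cell, members in inc.cell_species.items():
            if cell in cell_species:
                raise ValueError(
                    f"sampling unit {cell!r} appears in more than one region"
                )
            cell_species[cell] = members
    return GridIncidence(region="+".join(subset), T=T,
                         incidence=incidence, cell_species=cell_species)


# ---------------------------------------------------------------------------
# partitioning


def _chao2_point(inc: GridIncidence) -> tuple[float, float, float]:
    est = chao2_ci(chao2(tally_frequencies(inc)))
    return est.point, est.ci_lower, est.ci_upper


def _chao2_adj_point(inc: GridIncidence) -> tuple[float, float, float]:
    counts = tally_frequencies(inc)
    q1_hat, fb = estimate_true_uniques(counts)
    est = adjusted_chao2(counts, q1_hat, fallback_used=fb)
    return est.point, est.ci_lower, est.ci_upper

_ESTIMATORS: dict[str, Callable] = {
    "chao2": _chao2_point,
    "chao2_adj": _chao2_adj_point,
    "s_obs": lambda inc: (float(inc.s_obs), float(inc.s_obs), float(inc.s_obs)),
}


@dataclass
class PartitionTable:
    """The 2^R − 1 subset estimates and their Venn decomposition.

    ``estimates`` maps each nonempty label subset (frozenset) to its
    pooled S_obs / estimate / CI; ``exclusive`` holds the clamped Venn
    component for species confined to exactly that subset;
    ``residual`` is the total negative mass clamped away.  ``endemic``
    maps each region to its exclusive estimate and the percentage
    relative to that region's own estimated richness.
    """

    labels: list[str]
    estimator: str
    estimates: dict[frozenset, dict]
    exclusive: dict[frozenset, float]
    residual: float
    endemic: dict[str, dict]
    shared_all: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(1, len(self.labels) + 1):
            for combo in combinations(self.labels, k):
                key = frozenset(combo)
                e = self.estimates[key]
                mask = sum(1 << self.labels.index(r) for r in combo)
                rows.append({
                    "bitmask": mask,
                    "members": "+".join(combo),
                    "n_regions": k,
                    "T": e["T"],
                    "s_obs": e["s_obs"],
                    "estimate": e["point"],
                    "ci_lower": e["ci_lower"],
                    "ci_upper": e["ci_upper"],
                    "exclusive": self.exclusive[key],
                })
        return pd.DataFrame(rows)


def partition_richness(
    incidences: dict[str, GridIncidence],
    estimator: str | Callable[[GridIncidence], tuple[float, float, float]] = "chao2",
) -> PartitionTable:
    """Estimate richness for every nonempty region subset and decompose.

    ``estimator`` is ``"chao2"``, ``"chao2_adj"``, ``"s_obs"`` (exact
    union counts — useful as an additivity oracle), or a callable
    returning (point, ci_lower, ci_upper) for a pooled incidence.

    The exclusive component for a subset A (species occurring in exactly
    the regions of A) is obtained by Möbius inversion of
    M(A) = U(R) − U(R \\ A), where U is the subset estimate; endemic
    percentages are reported relative to each region's own estimate.
    """
    labels = list(incidences)
    R = len(labels)
    if not 2 <= R <= 8:
        raise ValueError("partitioning needs between 2 and 8 regions")
    fn = _ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    name = estimator if isinstance(estimator, str) else getattr(
        estimator, "__name__", "custom")

    estimates: dict[frozenset, dict] = {}
    for k in range(1, R + 1):
        for combo in combinations(labels, k):
            pooled = pool_subset(incidences, list(combo))
            try:
                point, lo, hi = fn(pooled)
            except Exception as exc:
                raise RuntimeError(
                    f"estimator failed on subset {'+'.join(combo)}"
                ) from exc
            estimates[frozenset(combo)] = {
                "T": pooled.T, "s_obs": pooled.s_obs,
                "point": point, "ci_lower": lo, "ci_upper": hi,
            }

    full = frozenset(labels)
    u_full = estimates[full]["point"]

    def contained(subset: frozenset) -> float:
        """M(A): estimated species confined to the regions of A."""
        if subset == full:
            return u_full
        rest = full - subset
        return u_full - estimates[rest]["point"]

    exclusive: dict[frozenset, float] = {}
    residual = 0.0
    for k in range(1, R + 1):
        for combo in combinations(labels, k):
            key = frozenset(combo)
            val = 0.0
            for kk in range(1, k + 1):
                for sub in combinations(sorted(key), kk):
                    val += (-1) ** (k - kk) * contained(frozenset(sub))
            if val < 0:
                residual += -val
                val = 0.0
            exclusive[key] = val

    endemic = {
        r: {
            "estimate": exclusive[frozenset([r])],
            "percent": 100.0 * exclusive[frozenset([r])]
            / estimates[frozenset([r])]["point"],
        }
        for r in labels
    }
    return PartitionTable(
        labels=labels, estimator=name, estimates=estimates,
        exclusive=exclusive, residual=residual, endemic=endemic,
        shared_all=exclusive[full],
    )
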