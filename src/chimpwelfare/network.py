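"""Nearest-night-neighbor social networks.

Once per night (between 19:00 and 00:00) each chimp's location
(indoor/outdoor) and nearest neighbor are recorded with a proximity
class: contact, within arm's reach, within 3 m, outside 3 m, or no
neighbor in shared space.  Pair matrices count, per unordered pair, the
number of nights the two were recorded as nearest neighbors; a night
counts once even if both members named each other.  Stratified matrices
keep one proximity class each (the "all" stratum accepts any named
neighbor, including outside 3 m); a cumulative option accumulates
closer-or-equal classes.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core import NightObservation, SchemaError

__all__ = [
    "PairFrequencyMatrix",
    "STRATA",
    "pair_matrix",
    "no_neighbor_counts",
    "location_tally",
    "sociogram_layout",
    "top_partners",
]

#: proximity classes ordered from closest to farthest
PROXIMITY_ORDER = ("contact", "arms_reach", "within_3m", "outside_3m")
STRATA = ("all", "contact", "arms_reach", "within_3m")


@dataclass(frozen=True)
class PairFrequencyMatrix:
    subjects: tuple[str, ...]
    counts: np.ndarray  # symmetric, zero diagonal
    stratum: str
    cumulative: bool = False

    def count(self, a: str, b: str) -> int:
        i, j = self.subjects.index(a), self.subjects.index(b)
        return int(self.counts[i, j])

    def edges(self) -> list[tuple[str, str, int]]:
        out = []
        n = len(self.subjects)
        for i in range(n):
            for j in range(i + 1, n):
                if self.counts[i, j] > 0:
                    out.append((self.subjects[i], self.subjects[j], int(self.counts[i, j])))
        return out


def _accepted_classes(stratum: str, cumulative: bool) -> tuple[str, ...]:
    if stratum == "all":
        return PROXIMITY_ORDER
    if stratum not in PROXIMITY_ORDER[:3]:
        raise ValueError(f"unknown stratum {stratum!r}; valid: {STRATA}")
    if cumulative:
        idx = PROXIMITY_ORDER.index(stratum)
        return PROXIMITY_ORDER[: idx + 1]
    return (stratum,)


def pair_matrix(
    observations: Iterable[NightObservation],
    group: Sequence[str],
    stratum: str = "all",
    cumulative: bool = False,
) -> PairFrequencyMatrix:
    """Nights-as-nearest-neighbors count matrix over a group.

    Per night, pair {a, b} increments by one if at least one of them
    named the other as nearest neighbor in an accepted proximity class.
    """
    subjects = tuple(group)
    index = {s: i for i, s in enumerate(subjects)}
    accepted = set(_accepted_classes(stratum, cumulative))
    pairs_by_night: dict[dt.date, set[frozenset[str]]] = {}
    for obs in observations:
        if obs.proximity == "no_neighbor" or obs.proximity not in accepted:
            continue
        if obs.chimp_id not in index:
            continue
        if obs.neighbor_id not in index:
            raise SchemaError(
                f"{obs.date}: neighbor {obs.neighbor_id!r} not in group roster"
            )
        pairs_by_night.setdefault(obs.date, set()).add(
            frozenset((obs.chimp_id, obs.neighbor_id))
        )
    counts = np.zeros((len(subjects), len(subjects)), dtype=int)
    for pairs in pairs_by_night.values():
        for pair in pairs:
            a, b = tuple(pair)
            i, j = index[a], index[b]
            counts[i, j] += 1
            counts[j, i] += 1
    return PairFrequencyMatrix(subjects=subjects, counts=counts,
                               stratum=stratum, cumulative=cumulative)


def no_neighbor_counts(
    observations: Iterable[NightObservation], group: Sequence[str]
) -> dict[str, int]:
    """Nights each group member had no neighbor in their space."""
    counts = Counter(
        obs.chimp_id
        for obs in observations
        if obs.proximity == "no_neighbor" and obs.chimp_id in set(group)
    )
    return {c: counts.get(c, 0) for c in group}


def location_tally(
    observations: Iterable[NightObservation],
    group: Sequence[str],
    period: tuple[dt.date, dt.date] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-chimp indoor/outdoor night counts; they partition observed nights."""
    members = set(group)
    tally = {c: {"indoor": 0, "outdoor": 0} for c in group}
    for obs in observations:
        if obs.chimp_id not in members:
            continue
        if period is not None and not (period[0] <= obs.date <= period[1]):
            continue
        tally[obs.chimp_id][obs.location] += 1
    return tally


def sociogram_layout(
    matrix: PairFrequencyMatrix, seed: int, iterations: int = 200
) -> dict:
    """Force-directed sociogram layout (seeded, deterministic).

    Edge weights are pair counts; heavier pairs are pulled closer, so
    marker distance reflects bond strength.  Returns node coordinates
    and weighted edges ready for JSON export or plotting.
    """
    if len(matrix.subjects) < 2:
        raise ValueError("need at least two subjects for a layout")
    g = nx.Graph()
    g.add_nodes_from(matrix.subjects)
    for a, b, w in matrix.edges():
        g.add_edge(a, b, weight=w)
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    return {
        "nodes": {n: [float(x), float(y)] for n, (x, y) in pos.items()},
        "edges": [{"a": a, "b": b, "weight": w} for a, b, w in matrix.edges()],
        "stratum": matrix.stratum,
    }


def top_partners(matrix: PairFrequencyMatrix, chimp_id: str, k: int = 3) -> list[tuple[str, int]]:
    """A chimp's k most frequent nearest-neighbor partners."""
    i = matrix.subjects.index(chimp_id)
    ranked = sorted(
        ((matrix.subjects[j], int(matrix.counts[i, j]))
         for j in range(len(matrix.subjects)) if j != i),
        key=lambda t: (-t[1], t[0]),
    )
    return [t for t in ranked[:k] if t[1] > 0]
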