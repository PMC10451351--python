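"""Nearest-night-neighbor matrices, tallies, and sociogram layout."""

import datetime as dt
import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimpwelfare.core import NightObservation, SchemaError
from chimpwelfare.network import (
    location_tally,
    no_neighbor_counts,
    pair_matrix,
    sociogram_layout,
    top_partners,
)

D0 = dt.date(2021, 3, 4)
GROUP = ["Blue", "Mitch", "Cecil", "Candi", "Alexis", "Isabelle"]


def night(chimp, neighbor, proximity="contact", day=0, location="indoor"):
    return NightObservation(chimp, D0 + dt.timedelta(days=day), location,
                            proximity, neighbor)


def alone(chimp, day=0, location="indoor"):
    return NightObservation(chimp, D0 + dt.timedelta(days=day), location,
                            "no_neighbor", None)


def test_repeated_contact_counts_each_night():
    obs = [night("Alexis", "Isabelle", day=d) for d in range(3)]
    for stratum in ("all", "contact"):
        m = pair_matrix(obs, GROUP, stratum=stratum)
        assert m.count("Alexis", "Isabelle") == 3


def test_mutual_naming_counts_once_per_night():
    obs = [night("Alexis", "Isabelle"), night("Isabelle", "Alexis")]
    m = pair_matrix(obs, GROUP)
    assert m.count("Alexis", "Isabelle") == 1


def test_matrix_symmetric_zero_diagonal_bounded_by_nights():
    obs = [night("Alexis", "Isabelle", day=d) for d in range(5)]
    obs += [night("Mitch", "Cecil", "within_3m", day=d) for d in range(2)]
    m = pair_matrix(obs, GROUP)
    assert np.array_equal(m.counts, m.counts.T)
    assert np.all(np.diag(m.counts) == 0)
    assert m.counts.max() <= 5


def test_outside_3m_only_in_all_stratum():
    obs = [night("Blue", "Mitch", "outside_3m")]
    assert pair_matrix(obs, GROUP, "all").count("Blue", "Mitch") == 1
    for stratum in ("contact", "arms_reach", "within_3m"):
        assert pair_matrix(obs, GROUP, stratum).count("Blue", "Mitch") == 0


def test_cumulative_strata_nest_elementwise():
    rng = np.random.default_rng(5)
    prox = ["contact", "arms_reach", "within_3m", "outside_3m"]
    obs = []
    for day in range(30):
        for chimp in GROUP:
            other = GROUP[(GROUP.index(chimp) + 1 + int(rng.integers(0, 5))) % 6]
            if other == chimp:
                continue
            obs.append(night(chimp, other, prox[int(rng.integers(0, 4))], day=day))
    contact = pair_matrix(obs, GROUP, "contact", cumulative=True)
    arms = pair_matrix(obs, GROUP, "arms_reach", cumulative=True)
    w3 = pair_matrix(obs, GROUP, "within_3m", cumulative=True)
    all_m = pair_matrix(obs, GROUP, "all")
    assert np.all(contact.counts <= arms.counts)
    assert np.all(arms.counts <= w3.counts)
    assert np.all(w3.counts <= all_m.counts)


def test_neighbor_outside_roster_rejected():
    obs = [night("Blue", "Stranger")]
    with pytest.raises(SchemaError, match="Stranger"):
        pair_matrix(obs, GROUP)


def _brute_force_counts(obs, group, accepted):
    """Oracle: enumerate named pairs night by night, dedup per night."""
    members = set(group)
    counts = Counter()
    for date in sorted({o.date for o in obs}):
        named = set()
        for o in obs:
            if (o.date == date and o.proximity in accepted
                    and o.chimp_id in members and o.neighbor_id in members):
                named.add(tuple(sorted((o.chimp_id, o.neighbor_id))))
        counts.update(named)
    return counts


@given(data=st.data())
@settings(max_examples=60, deadline=None)
def test_matrix_matches_per_night_brute_force(data):
    n = data.draw(st.integers(2, 10))
    nights_n = data.draw(st.integers(1, 30))
    group = [f"c{i}" for i in range(n)]
    prox = ["contact", "arms_reach", "within_3m", "outside_3m", "no_neighbor"]
    obs = []
    for day in range(nights_n):
        for i, chimp in enumerate(group):
            p = data.draw(st.sampled_from(prox))
            if p == "no_neighbor":
                obs.append(alone(chimp, day=day))
            else:
                j = data.draw(st.integers(0, n - 2))
                neighbor = group[j if j < i else j + 1]
                obs.append(night(chimp, neighbor, p, day=day))
    for stratum, accepted in [
        ("all", {"contact", "arms_reach", "within_3m", "outside_3m"}),
        ("contact", {"contact"}),
        ("within_3m", {"within_3m"}),
    ]:
        m = pair_matrix(obs, group, stratum)
        oracle = _brute_force_counts(obs, group, accepted)
        for a, b in itertools.combinations(group, 2):
            assert m.count(a, b) == oracle.get(tuple(sorted((a, b))), 0)


def test_no_neighbor_counts_tally_solo_nights():
    obs = [alone("Blue", day=d) for d in range(5)]
    obs += [night("Blue", "Mitch", day=5 + d) for d in range(5)]
    obs += [alone("Isabelle", day=0)]
    counts = no_neighbor_counts(obs, GROUP)
    assert counts["Blue"] == 5
    assert counts["Isabelle"] == 1
    assert counts["Candi"] == 0
    assert no_neighbor_counts(obs[::-1], GROUP) == counts


def test_location_tally_partitions_nights():
    obs = [night("Blue", "Mitch", day=d, location="indoor") for d in range(19)]
    obs.append(night("Blue", "Mitch", day=19, location="outdoor"))
    tally = location_tally(obs, GROUP)
    assert tally["Blue"] == {"indoor": 19, "outdoor": 1}
    assert tally["Blue"]["indoor"] + tally["Blue"]["outdoor"] == 20


def test_layout_deterministic_and_weight_ordered():
    # 3-node line graph: heavy pair (10) must sit closer than light pair (1)
    group = ["a", "b", "c"]
    obs = [night("a", "b", day=d) for d in range(10)]
    obs.append(night("b", "c", day=0))
    m = pair_matrix(obs, group)
    layout = sociogram_layout(m, seed=3)
    again = sociogram_layout(m, seed=3)
    assert layout == again
    nodes = layout["nodes"]
    dist = lambda u, v: np.hypot(nodes[u][0] - nodes[v][0], nodes[u][1] - nodes[v][1])
    assert dist("a", "b") < dist("b", "c")
    weights = {frozenset((e["a"], e["b"])): e["weight"] for e in layout["edges"]}
    assert weights == {frozenset(("a", "b")): 10, frozenset(("b", "c")): 1}


def test_layout_handles_isolated_nodes_and_rejects_singletons():
    m = pair_matrix([alone("Blue")], GROUP)
    layout = sociogram_layout(m, seed=0)
    assert set(layout["nodes"]) == set(GROUP)
    assert layout["edges"] == []
    with pytest.raises(ValueError):
        sociogram_layout(pair_matrix([], ["solo"]), seed=0)


def test_top_partners_ranked_by_count():
    obs = [night("Mitch", "Cecil", day=d) for d in range(4)]
    obs += [night("Mitch", "Candi", day=d) for d in range(2)]
    m = pair_matrix(obs, GROUP)
    assert top_partners(m, "Mitch", k=2) == [("Cecil", 4), ("Candi", 2)]
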