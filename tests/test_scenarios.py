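"""Improvement scenarios and population-weighted statistics."""
import numpy as np
import pytest

from emocaccess import (
    CostSurface,
    FacilityRecord,
    GridSpec,
    ScenarioSpec,
    apply_scenario,
    delineate,
    select_upgrades,
    total_journey,
    weighted_stats,
)
from emocaccess.catchments import facility_travel_times
from emocaccess.referral import build_referral_table
from emocaccess.scenarios import weighted_quantile


def uniform_cost(rows, cols, minutes, cell=1000.0):
    return CostSurface(cost=np.full((rows, cols), minutes),
                       grid=GridSpec(cell, 0.0, 0.0, rows, cols))


def fac(fid, x, y, level, score=10, transport=False, comm=False,
        caesarean=False):
    return FacilityRecord(id=fid, x=x, y=y, level=level,
                          readiness_score=score, has_transport=transport,
                          has_communication=comm,
                          caesarean_last_3_months=caesarean)


def test_model0_is_identity(facilities):
    out = apply_scenario(facilities, ScenarioSpec(0))
    assert out == facilities
    assert out is not facilities  # a copy, not the same objects


def test_model2_gives_everyone_vehicle_and_phone(facilities):
    out = apply_scenario(facilities, ScenarioSpec(2))
    assert all(f.has_transport and f.has_communication for f in out)


def test_model2_promotes_low_levels_with_frozen_score(facilities):
    """New transport promotes score-0-9 facilities to level 3; the
    readiness score itself is not re-counted."""
    out = apply_scenario(facilities, ScenarioSpec(2))
    by_id = {f.id: f for f in facilities}
    for f in out:
        before = by_id[f.id]
        assert f.readiness_score == before.readiness_score
        if before.level in (1, 2):
            assert f.level == 3
        else:
            assert f.level == before.level


def test_model3_increases_level5_count_by_k(facilities, cost, landscape):
    k = 2
    out = apply_scenario(facilities, ScenarioSpec(3, upgrades=k), cost,
                         landscape.population)
    n_before = sum(1 for f in facilities if f.level == 5)
    assert sum(1 for f in out if f.level == 5) == n_before + k


def test_upgrades_exceeding_candidates_rejected(facilities, cost, landscape):
    n4 = sum(1 for f in facilities if f.level == 4)
    with pytest.raises(ValueError, match="candidates"):
        apply_scenario(facilities, ScenarioSpec(1, upgrades=n4 + 1), cost,
                       landscape.population)


def test_single_candidate_is_selected():
    cs = uniform_cost(10, 10, 5.0)
    cand = fac("only", *cs.grid.cell_center(5, 5), 4)
    assert select_upgrades([cand], 1, cs, np.ones((10, 10)), []) == ["only"]


def test_greedy_picks_dominant_coverage():
    """The candidate covering 10x more uncovered population wins."""
    cs = uniform_cost(3, 101, minutes=30.0, cell=100.0)  # 4 cells = 2 h
    pop = np.zeros((3, 101))
    pop[1, 10] = 100.0
    pop[1, 90] = 10.0
    a = fac("A", *cs.grid.cell_center(1, 10), 4)
    b = fac("B", *cs.grid.cell_center(1, 90), 4)
    assert select_upgrades([a, b], 1, cs, pop, [])[0] == "A"


@pytest.mark.parametrize("seed", range(3))
def test_greedy_first_pick_equals_exhaustive_maximiser(seed):
    rng = np.random.default_rng(seed)
    cs = uniform_cost(20, 20, minutes=rng.uniform(10, 40), cell=500.0)
    pop = rng.uniform(0, 50, size=(20, 20))
    cands = []
    for i in range(5):
        r, c = rng.integers(0, 20, size=2)
        cands.append(fac(f"c{i}", *cs.grid.cell_center(int(r), int(c)), 4,
                         score=int(rng.integers(10, 15))))
    maps = facility_travel_times(cands, cs)
    first = select_upgrades(cands, 1, cs, pop, [], candidate_maps=maps)[0]
    gains = {c.id: pop[maps[i] < 120.0].sum() for i, c in enumerate(cands)}
    assert gains[first] == pytest.approx(max(gains.values()))


def test_upgraded_facilities_keep_position_and_gain_caesarean(facilities,
                                                              cost, landscape):
    out = apply_scenario(facilities, ScenarioSpec(1, upgrades=1), cost,
                         landscape.population)
    upgraded = [f for f in out if f.level == 5
                and {g.id: g for g in facilities}[f.id].level == 4]
    assert len(upgraded) == 1
    assert upgraded[0].caesarean_last_3_months


# ---------------------------------------------------------------------------
# Total journey
# ---------------------------------------------------------------------------

def line_world():
    """1x40 uniform world: a level 2 at cell 5, a level 5 at cell 20."""
    cs = uniform_cost(1, 40, minutes=10.0)
    lvl2 = fac("L2", *cs.grid.cell_center(0, 5), 2, score=8, transport=False,
               comm=True)
    lvl5 = fac("L5", *cs.grid.cell_center(0, 20), 5, score=12, transport=True,
               comm=True, caesarean=True)
    return cs, [lvl2, lvl5]


def test_total_journey_cells(road_graph_line=None):
    import networkx  # noqa: F401  (graph built inline below)
    from emocaccess import build_road_graph
    from emocaccess.synthetic import RoadSegment

    cs, roster = line_world()
    a = delineate(roster, cs)
    graph = build_road_graph(
        [RoadSegment(start=(roster[0].x, roster[0].y),
                     end=(roster[1].x, roster[1].y), road_class="tertiary")])
    referrals = build_referral_table(roster, graph)
    total = total_journey(a, referrals)

    # Cell 20 is the level 5 itself: total = segment 1 only (0 min).
    assert total[0, 20] == 0.0
    # Cell 4 is 1 cell (10 min) from the level 2 and in the level 5's
    # secondary only, so it stays local; its transfer is the 15 km road
    # at 30 km/h = 30 min, doubled (no vehicle) = 60 min.
    assert a.facility_ids[a.facility_index[0, 4]] == "L2"
    assert total[0, 4] == pytest.approx(10.0 + 60.0)


def test_total_journey_missing_facility_rejected(facilities, cost, road_graph):
    a = delineate(facilities, cost)
    referrals = build_referral_table(facilities, road_graph).drop(
        index=facilities[0].id)
    with pytest.raises(KeyError):
        total_journey(a, referrals)


@pytest.mark.parametrize("seed", range(2))
def test_total_journey_matches_per_cell_recomputation(seed, facilities, cost,
                                                      road_graph):
    a = delineate(facilities, cost)
    referrals = build_referral_table(facilities, road_graph)
    total = total_journey(a, referrals)
    rows, cols = cost.grid.shape
    rng = np.random.default_rng(seed)
    for _ in range(200):
        r, c = rng.integers(0, rows), rng.integers(0, cols)
        i = a.facility_index[r, c]
        if i < 0:
            assert np.isnan(total[r, c])
            continue
        fid = a.facility_ids[i]
        seg2 = 0.0 if a.facility_levels[i] == 5 \
            else referrals.loc[fid, "adjusted_min"]
        assert total[r, c] == pytest.approx(a.minutes[r, c] + seg2)


# ---------------------------------------------------------------------------
# Weighted statistics
# ---------------------------------------------------------------------------

def test_equal_weights_reduce_to_ordinary_stats():
    rng = np.random.default_rng(0)
    v = rng.uniform(0, 100, size=50)
    s = weighted_stats(v, np.ones(50))
    assert s.mean == pytest.approx(v.mean())
    assert s.sd == pytest.approx(v.std())
    assert s.p95 == pytest.approx(np.percentile(v, 95))
    assert s.max == v.max()


def test_single_positive_weight_collapses_all_stats():
    v = np.array([10.0, 99.0, 3.0])
    w = np.array([0.0, 5.0, 0.0])
    s = weighted_stats(v, w)
    assert s.mean == s.p95 == s.max == 99.0
    assert s.sd == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_weighted_stats_equal_weight_expanded_sample(seed):
    """Integer weights: every statistic matches the replicated sample."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 300, size=12)
    w = rng.integers(1, 9, size=12)
    expanded = np.repeat(v, w)
    s = weighted_stats(v, w.astype(float))
    assert s.mean == pytest.approx(expanded.mean())
    assert s.sd == pytest.approx(expanded.std())
    assert s.p95 == pytest.approx(np.percentile(expanded, 95))
    assert s.max == pytest.approx(expanded.max())


def test_weighted_quantile_endpoints():
    v = np.array([1.0, 2.0, 3.0])
    w = np.array([1.0, 1.0, 1.0])
    assert weighted_quantile(v, w, 0.0) == 1.0
    assert weighted_quantile(v, w, 1.0) == 3.0
    assert weighted_quantile(v, w, 0.5) == 2.0


def test_all_zero_weights_rejected():
    with pytest.raises(ValueError, match="positive"):
        weighted_stats(np.array([1.0]), np.array([0.0]))


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        weighted_stats(np.array([1.0, 2.0]), np.array([1.0, -1.0]))
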