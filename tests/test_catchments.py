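"""Prioritised catchment overlay (bypassing) and band populations."""
import numpy as np
import pandas as pd
import pytest

from emocaccess import (
    CatchmentClass,
    CatchmentRule,
    CostSurface,
    DEFAULT_RULES,
    FacilityRecord,
    GridSpec,
    band_population,
    delineate,
)
from conftest import random_cost_surface


def uniform_cost(rows, cols, minutes, cell=1000.0):
    return CostSurface(cost=np.full((rows, cols), minutes),
                       grid=GridSpec(cell, 0.0, 0.0, rows, cols))


def facility(fid, x, y, level, score=10):
    return FacilityRecord(id=fid, x=x, y=y, readiness_score=score, level=level)


def place(cs, row, col, fid, level):
    x, y = cs.grid.cell_center(row, col)
    return facility(fid, x, y, level)


def test_default_rules_match_level_definition_table():
    by_key = {(c.level, c.zone): c for c in DEFAULT_RULES.classes}
    assert (by_key[(5, "primary")].upper_h, by_key[(5, "primary")].rank) == (2.0, 1)
    assert (by_key[(4, "primary")].upper_h, by_key[(4, "primary")].rank) == (2.0, 2)
    assert (by_key[(3, "primary")].upper_h, by_key[(3, "primary")].rank) == (1.0, 3)
    assert (by_key[(2, "primary")].upper_h, by_key[(2, "primary")].rank) == (1.0, 4)
    assert (by_key[(5, "secondary")].upper_h, by_key[(5, "secondary")].rank) == (5.0, 5)
    assert (by_key[(4, "secondary")].upper_h, by_key[(4, "secondary")].rank) == (5.0, 6)
    assert (by_key[(3, "secondary")].upper_h, by_key[(3, "secondary")].rank) == (3.0, 7)
    assert (by_key[(2, "secondary")].upper_h, by_key[(2, "secondary")].rank) == (3.0, 8)
    assert (1, "primary") not in by_key  # level 1 has no primary zone
    assert (by_key[(1, "secondary")].upper_h, by_key[(1, "secondary")].rank) == (1.0, 9)
    assert DEFAULT_RULES.max_bound_h == 5.0


def test_rules_reject_non_permutation_ranks():
    bad = tuple(
        CatchmentClass(c.level, c.zone, c.lower_h, c.upper_h,
                       1 if c.rank == 2 else c.rank)
        for c in DEFAULT_RULES.classes
    )
    with pytest.raises(ValueError, match="permutation"):
        CatchmentRule(bad)


def test_bypass_between_level3_and_level5():
    """A woman inside both primaries goes to the level 5; inside the
    level-3 primary but only the level-5 secondary she stays local."""
    cs = uniform_cost(1, 40, minutes=6.0)  # 10 cells = 1 h
    lvl3 = place(cs, 0, 5, "L3", 3)
    lvl5 = place(cs, 0, 20, "L5", 5)
    a = delineate([lvl3, lvl5], cs)

    # cell 8: 3 cells from the level 3 (18 min), 12 from the level 5
    # (72 min) -> inside both primaries -> bypass to the level 5.
    assert a.facility_ids[a.facility_index[0, 8]] == "L5"
    assert a.rank[0, 8] == 1
    # cell 0: 5 cells from the level 3 (30 min), 20 cells from the
    # level 5 (120 min = its secondary) -> stays with the level 3.
    assert a.facility_ids[a.facility_index[0, 0]] == "L3"
    assert a.rank[0, 0] == 3
    # segment-1 time stored is the time to the assigned facility
    assert a.minutes[0, 0] == pytest.approx(30.0)


def test_single_reachable_facility_takes_cell():
    cs = uniform_cost(5, 5, minutes=10.0)
    fac = place(cs, 2, 2, "only", 2)
    a = delineate([fac], cs)
    assert a.facility_index[2, 2] == 0
    # corner cell: 2 diagonal steps > 28 min -> within the 0-1 h primary
    assert a.facility_ids[a.facility_index[0, 0]] == "only"


def test_cells_beyond_all_bounds_are_outside():
    cs = uniform_cost(1, 100, minutes=30.0)  # 2 cells = 1 h
    fac = place(cs, 0, 0, "far", 2)  # bounds end at 3 h = 6 cells
    a = delineate([fac], cs)
    assert not a.covered[0, 50]
    assert a.rank[0, 50] == 0 and np.isinf(a.minutes[0, 50])


def test_boundary_is_half_open():
    """A cell at exactly the primary bound falls in the secondary zone."""
    cs = uniform_cost(1, 30, minutes=12.0)  # 5 cells = 1 h
    fac = place(cs, 0, 0, "F", 5)  # primary bound 2 h = cell 10
    a = delineate([fac], cs)
    assert a.minutes[0, 10] == pytest.approx(120.0)
    assert a.rank[0, 10] == 5  # secondary, not primary
    assert a.rank[0, 9] == 1


def test_facility_outside_grid_rejected():
    cs = uniform_cost(5, 5, minutes=1.0)
    with pytest.raises(ValueError, match="ghost"):
        delineate([facility("ghost", 1e6, 1e6, 5)], cs)


def brute_force_assignment(facilities, cs, rules, travel_maps):
    """Per-cell exhaustive search over (facility, class) pairs."""
    rows, cols = cs.grid.shape
    idx = np.full((rows, cols), -1)
    rank = np.zeros((rows, cols), dtype=int)
    minutes = np.full((rows, cols), np.inf)
    for r in range(rows):
        for c in range(cols):
            options = []
            for i, f in enumerate(facilities):
                t = travel_maps[i][r, c]
                for cl in rules.classes:
                    if cl.level == f.level and cl.lower_h * 60 <= t < cl.upper_h * 60:
                        options.append((cl.rank, t, i))
            if options:
                best = min(options)
                rank[r, c], minutes[r, c], idx[r, c] = best
    return idx, rank, minutes


@pytest.mark.parametrize("seed", range(3))
def test_overlay_matches_per_cell_brute_force(seed):
    rng = np.random.default_rng(seed)
    cs = random_cost_surface(rng, 20, 20, impassable_frac=0.03)
    passable = np.argwhere(np.isfinite(cs.cost))
    facs = []
    for i, lvl in enumerate([5, 4, 3, 2, 1, 2]):
        r, c = passable[rng.integers(len(passable))]
        x, y = cs.grid.cell_center(int(r), int(c))
        facs.append(facility(f"f{i}", x, y, lvl))
    from emocaccess.catchments import facility_travel_times

    maps = facility_travel_times(facs, cs)
    a = delineate(facs, cs, travel_maps=maps)
    idx, rank, minutes = brute_force_assignment(facs, cs, DEFAULT_RULES, maps)
    assert np.array_equal(a.facility_index, idx)
    assert np.array_equal(a.rank, rank)
    assert np.allclose(a.minutes, minutes)


def test_priority_dominance_invariant(facilities, cost):
    """No assigned cell could do strictly better on rank elsewhere."""
    from emocaccess.catchments import facility_travel_times

    maps = facility_travel_times(facilities, cost)
    a = delineate(facilities, cost, travel_maps=maps)
    covered = a.covered
    for i, f in enumerate(facilities):
        for cl in DEFAULT_RULES.for_level(f.level):
            inside = (maps[i] >= cl.lower_h * 60) & (maps[i] < cl.upper_h * 60)
            assert not np.any(inside & covered & (cl.rank < a.rank)), \
                f"cells covered by {f.id} rank {cl.rank} assigned worse rank"


def test_level1_never_preferred_when_better_class_overlaps(facilities, cost):
    """Level-1 facilities (rank 9) hold only cells no other class reaches."""
    a = delineate(facilities, cost)
    lvl1 = a.assigned_level() == 1
    assert np.all(a.rank[lvl1] == 9)


# ---------------------------------------------------------------------------
# Band populations
# ---------------------------------------------------------------------------

def test_all_population_at_level5_cell():
    cs = uniform_cost(5, 5, minutes=10.0)
    fac = place(cs, 2, 2, "H", 5)
    a = delineate([fac], cs)
    pop = np.zeros((5, 5))
    pop[2, 2] = 1234.0
    table = band_population(a, pop)
    assert table.loc[5].iloc[0] == pytest.approx(1234.0)
    assert table.values.sum() == pytest.approx(1234.0)


def test_empty_population_gives_zero_table():
    cs = uniform_cost(4, 4, minutes=5.0)
    a = delineate([place(cs, 0, 0, "H", 4)], cs)
    table = band_population(a, np.zeros((4, 4)))
    assert (table.values == 0).all()


def test_band_population_conserves_total(facilities, cost, landscape):
    a = delineate(facilities, cost)
    table = band_population(a, landscape.population)
    assert table.values.sum() == pytest.approx(landscape.population.sum(),
                                               rel=1e-9)
    # OUTSIDE row carries exactly the uncovered population
    assert table.loc["OUTSIDE"].sum() == pytest.approx(
        landscape.population[~a.covered].sum())


def test_band_population_grid_mismatch_rejected(facilities, cost):
    a = delineate(facilities, cost)
    with pytest.raises(ValueError, match="match"):
        band_population(a, np.zeros((3, 3)))
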