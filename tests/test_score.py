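"""The m/k/t quantification rule: ranking, exclusion, selection, scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdl1score.score import (
    ScoringParams,
    exclude_top_m,
    rank_by_area,
    select_top_k,
    stratify,
    sweep_parameters,
    tps_star,
    tps_traditional,
)
from pdl1score.segment import CellRecord


def _cells(areas, positives=None, ratios=None):
    positives = positives or [False] * len(areas)
    records = []
    for i, a in enumerate(areas):
        records.append(
            CellRecord(
                id=i,
                center=(float(i % 17), float(i % 13)),
                nucleus_area=int(a),
                dilated_area=int(a) + 5,
                dab_ratio=None if ratios is None else ratios[i],
                is_positive=positives[i],
            )
        )
    return records


def _random_cells(rng, n):
    areas = rng.integers(5, 400, n)
    ratios = rng.uniform(0, 1, n)
    cells = []
    for i in range(n):
        cells.append(
            CellRecord(
                id=i,
                center=(float(rng.uniform(0, 512)), float(rng.uniform(0, 512))),
                nucleus_area=int(areas[i]),
                dilated_area=int(areas[i]) + 10,
                dab_ratio=float(ratios[i]),
            )
        )
    return cells


def _brute_force_tps_star(cells, m, k, t):
    """Independent enumeration oracle: selection-sort the cells by the
    declared ordering, slice, and count positives."""
    pool = list(cells)
    ordered = []
    while pool:
        best = pool[0]
        for c in pool[1:]:
            key_c = (-c.nucleus_area, c.center[1], c.center[0], c.id)
            key_b = (-best.nucleus_area, best.center[1], best.center[0], best.id)
            if key_c < key_b:
                best = c
        ordered.append(best)
        pool.remove(best)
    ordered = ordered[math.floor(m * len(ordered)) :]
    chosen = ordered[:k]
    pos = sum((c.dab_ratio >= t if t > 0 else c.dab_ratio > 0) for c in chosen)
    return 100.0 * pos / len(chosen), len(chosen)


def test_rank_by_area_with_ties():
    cells = _cells([5, 9, 9, 2])
    ranked = rank_by_area(cells)
    assert [c.nucleus_area for c in ranked] == [9, 9, 5, 2]
    tied = [c for c in ranked if c.nucleus_area == 9]
    assert (tied[0].center[1], tied[0].center[0], tied[0].id) < (
        tied[1].center[1],
        tied[1].center[0],
        tied[1].id,
    )
    assert rank_by_area(cells[:1]) == cells[:1]


def test_rank_matches_full_sort_oracle():
    rng = np.random.default_rng(0)
    cells = _random_cells(rng, 1000)
    ranked = rank_by_area(cells)
    keys = [(-c.nucleus_area, c.center[1], c.center[0], c.id) for c in cells]
    expected_ids = [cells[i].id for i in np.lexsort(tuple(zip(*keys))[::-1])]
    assert [c.id for c in ranked] == expected_ids


@pytest.mark.parametrize("n, m, removed", [(100, 0.06, 6), (50, 0.06, 3), (10, 0.0, 0)])
def test_exclude_top_m_counts(n, m, removed):
    ranked = rank_by_area(_cells(range(1, n + 1)))
    remaining = exclude_top_m(ranked, m)
    assert len(remaining) == n - removed
    assert remaining == ranked[removed:]


def test_select_top_k_and_saturation():
    ranked = rank_by_area(_cells(range(1, 11)))
    top, under = select_top_k(ranked, 4)
    assert [c.nucleus_area for c in top] == [10, 9, 8, 7]
    assert not under
    everything, under = select_top_k(ranked, 3000)
    assert len(everything) == 10 and under


def test_tps_star_hand_enumerated():
    """10 cells, m=0, k=4: positives among the 4 largest decide the score."""
    positives = [False] * 10
    positives[9] = positives[8] = True  # the two largest
    cells = _cells(range(1, 11), positives=positives)
    score = tps_star(cells, ScoringParams(m=0.0, k=4, min_cells=1))
    assert score.tps_star == 50.0
    assert score.n_selected == 4 and score.n_positive_selected == 2
    assert score.n_after_exclusion == 10


def test_tps_star_extremes():
    cells = _cells([10] * 8, positives=[True] * 8)
    assert tps_star(cells, ScoringParams(m=0.0, k=8, min_cells=1)).tps_star == 100.0
    cells = _cells([10] * 8)
    assert tps_star(cells, ScoringParams(m=0.0, k=8, min_cells=1)).tps_star == 0.0


def test_insufficient_cells_are_unscorable():
    cells = _cells([10, 20, 30])
    score = tps_star(cells, ScoringParams(k=3000))  # min_cells defaults to k
    assert not score.scorable
    assert score.tps_star is None
    assert score.reason == "insufficient cells"
    assert score.n_total == 3


def test_rule_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(1, 120))
        cells = _random_cells(rng, n)
        m = float(rng.uniform(0, 0.2))
        k = int(rng.integers(1, n + 1))
        t = float(rng.choice([0.0, 0.05, 0.1, 0.3, 0.5]))
        got = tps_star(cells, ScoringParams(m=m, k=k, t=t, min_cells=1))
        expected, n_sel = _brute_force_tps_star(cells, m, k, t)
        assert got.tps_star == pytest.approx(expected, abs=1e-12)
        assert got.n_selected == n_sel


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_score_invariant_to_input_order(seed):
    rng = np.random.default_rng(seed)
    cells = _random_cells(rng, 60)
    params = ScoringParams(m=0.1, k=30, t=0.1, min_cells=1)
    base = tps_star(cells, params)
    shuffled = list(cells)
    rng.shuffle(shuffled)
    assert tps_star(shuffled, params).tps_star == base.tps_star


def test_tps_star_non_increasing_in_t():
    rng = np.random.default_rng(7)
    cells = _random_cells(rng, 300)
    values = [
        tps_star(cells, ScoringParams(m=0.06, k=200, t=t, min_cells=1)).tps_star
        for t in (0.01, 0.05, 0.1, 0.3, 0.5)
    ]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_pipeline_identity_at_t_zero():
    """m=0, k>=N, t=0 scores exactly the fraction of cells with any brown."""
    rng = np.random.default_rng(3)
    cells = _random_cells(rng, 100)
    for i, c in enumerate(cells):
        if i % 3 == 0:
            c.dab_ratio = 0.0
    score = tps_star(cells, ScoringParams(m=0.0, k=100, t=0.0, min_cells=1))
    expected = 100.0 * sum(c.dab_ratio > 0 for c in cells) / len(cells)
    assert score.tps_star == expected


def test_tps_traditional():
    assert tps_traditional(30, 100) == 30.0
    assert tps_traditional(0, 17) == 0.0
    with pytest.raises(ValueError):
        tps_traditional(1, 0)
    with pytest.raises(ValueError):
        tps_traditional(5, 3)


def test_tps_traditional_matches_generator_truth(default_patch):
    from pdl1score.synthetic import TUMOR

    _, truth = default_patch
    tumor = [c for c in truth.cells if c.class_label == TUMOR]
    assert tps_traditional(sum(c.is_positive for c in tumor), len(tumor)) == truth.true_tps


@pytest.mark.parametrize("tps, expected", [(4.9, "low"), (5.0, "intermediate"), (49.9, "intermediate"), (50.0, "high"), (0.0, "low"), (100.0, "high")])
def test_stratify_default_boundaries(tps, expected):
    assert stratify(tps) == expected


def test_stratify_generalizes_and_matches_interval_oracle():
    assert stratify(0.5, [1.0]) == "stratum_0"
    assert stratify(1.0, [1.0]) == "stratum_1"
    rng = np.random.default_rng(1)
    for v in rng.uniform(0, 100, 100):
        expected = "low" if v < 5 else ("intermediate" if v < 50 else "high")
        assert stratify(float(v)) == expected


def test_scoring_params_validation():
    with pytest.raises(ValueError):
        ScoringParams(m=1.0)
    with pytest.raises(ValueError):
        ScoringParams(k=0)
    with pytest.raises(ValueError):
        ScoringParams(cutoffs=(50, 5))
    with pytest.raises(ValueError):
        ScoringParams(cutoffs=(0.0, 50.0))


def test_sweep_single_point_matches_direct_call():
    rng = np.random.default_rng(5)
    cells = _random_cells(rng, 150)
    params = ScoringParams(min_cells=1)
    table = sweep_parameters([cells], [0.06], [100], [0.1], base_params=params)
    direct = tps_star(cells, ScoringParams(m=0.06, k=100, t=0.1, min_cells=1))
    assert len(table) == 1
    assert table.loc[0, "tps_star"] == direct.tps_star


def test_sweep_monotone_in_t_and_epsilon_floor():
    rng = np.random.default_rng(9)
    slides = [_random_cells(rng, 200) for _ in range(4)]
    params = ScoringParams(min_cells=1)
    table = sweep_parameters(slides, [0.06], [150], [0.01, 0.1, 0.5], base_params=params)
    means = table.sort_values("t")["tps_star_mean"].to_numpy()
    assert (np.diff(means) <= 0).all()
    ref = [tps_star(s, ScoringParams(m=0.06, k=150, t=0.1, min_cells=1)).tps_star for s in slides]
    perfect = sweep_parameters(slides, [0.06], [150], [0.1], reference=ref, base_params=params)
    assert perfect.loc[0, "log_mse"] == pytest.approx(-12.0)
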