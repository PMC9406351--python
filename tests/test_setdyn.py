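import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

import radskin as rs
from radskin import reference_tables as ref
from radskin.errors import DataError
from radskin.setdyn import SDTGSet, common_unique_ratios, round_half_up


def make_sets(dose, members_by_tp, up_by_tp=None):
    out = []
    for tp, genes in members_by_tp.items():
        genes = set(genes)
        up = set(up_by_tp.get(tp, genes)) if up_by_tp else set(genes)
        out.append(SDTGSet(dose=dose, timepoint=tp, up=genes & up, down=genes - up))
    return out


def brute_force_blocks(sets_by_label):
    """Oracle: enumerate every gene's membership bitmask exhaustively."""
    labels = list(sets_by_label)
    universe = set().union(*sets_by_label.values())
    blocks = {}
    for gene in universe:
        mask = frozenset(lab for lab in labels if gene in sets_by_label[lab])
        blocks.setdefault(mask, set()).add(gene)
    return blocks


# ---- partition_sets ----------------------------------------------------------


def test_identical_sets_all_common():
    sets = make_sets(1.0, {"2h": range(10), "d4": range(10), "d7": range(10)})
    part = rs.partition_sets(sets)
    assert part.common_to_all_count == 10 == part.union_count
    assert all(v == 0 for v in part.unique_counts.values())


def test_disjoint_sets_all_unique():
    sets = make_sets(1.0, {"2h": range(5), "d4": range(5, 12), "d7": range(12, 15)})
    part = rs.partition_sets(sets)
    assert part.common_to_all_count == 0
    assert part.unique_counts == {"2h": 5, "d4": 7, "d7": 3}
    assert sum(part.unique_counts.values()) == part.union_count


def test_duplicate_labels_rejected():
    sets = make_sets(1.0, {"2h": range(5)}) * 2
    with pytest.raises(DataError, match="duplicated"):
        rs.partition_sets(sets)


def test_direction_consistency_annotation():
    a = SDTGSet(1.0, "2h", up={1, 2}, down={3})
    b = SDTGSet(1.0, "d4", up={1}, down={2, 3})
    part = rs.partition_sets([a, b])
    assert part.direction_consistent == {1: True, 2: False, 3: True}


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.integers(2, 5),
    st.lists(st.sets(st.integers(0, 49)), min_size=5, max_size=5),
)
def test_partition_matches_bitmask_oracle(n_sets, gene_sets):
    labels = ["2h", "d4", "d7", "d21", "d28"][:n_sets]
    by_label = dict(zip(labels, gene_sets))
    sets = make_sets(3.0, by_label)
    part = rs.partition_sets(sets)
    oracle = brute_force_blocks(by_label)
    assert part.blocks == oracle
    # conservation: Venn blocks partition the union exactly
    union = set().union(*by_label.values())
    assert part.union_count == len(union)
    assert sum(len(b) for b in part.blocks.values()) == len(union)
    flat = list(itertools.chain.from_iterable(part.blocks.values()))
    assert len(flat) == len(set(flat))


# ---- printed-table fixtures --------------------------------------------------


def _assert_matches_printed(computed: float, printed: float):
    """Agreement to one unit in the last printed digit (the published tables
    round some cells half-up and truncate others)."""
    decimals = len(str(printed).split(".")[1]) if "." in str(printed) else 0
    assert computed == pytest.approx(printed, abs=10.0**-decimals + 1e-12)


def test_per_dose_partition_fixture_1gy():
    union, common, unique = ref.PER_DOSE_PARTITION[1.0]
    labels = list(unique)
    sets_by_tp = ref.reconstruct_partition_sets(
        union, common, {tp: unique[tp][0] for tp in labels}, labels
    )
    part = rs.partition_sets(make_sets(1.0, sets_by_tp))
    assert part.union_count == 619
    assert part.common_to_all_count == 1
    assert part.unique_counts["2h"] == 125
    _assert_matches_printed(part.unique_percent["2h"], 20.2)


def test_stationarity_20gy_fixture():
    union, common, unique = ref.PER_DOSE_PARTITION[20.0]
    labels = list(unique)
    sets_by_tp = ref.reconstruct_partition_sets(
        union, common, {tp: unique[tp][0] for tp in labels}, labels
    )
    part = rs.partition_sets(make_sets(20.0, sets_by_tp))
    index, ratio = rs.stationarity_stats(part)
    assert index == pytest.approx(609 / 1038)
    assert round(index, 3) in (0.586, 0.587)  # printed as 58.6%
    assert ratio == pytest.approx(57 / 609)


def test_stationarity_common_zero_flags_infinite():
    union, common, unique = ref.PER_DOSE_PARTITION[3.0]
    labels = list(unique)
    sets_by_tp = ref.reconstruct_partition_sets(
        union, common, {tp: unique[tp][0] for tp in labels}, labels
    )
    part = rs.partition_sets(make_sets(3.0, sets_by_tp))
    index, ratio = rs.stationarity_stats(part)
    assert index == 0.0
    assert math.isinf(ratio)


def test_stationarity_singleton_experiment():
    sets = make_sets(1.0, {"2h": {7}, "d4": {7}})
    part = rs.partition_sets(sets)
    index, ratio = rs.stationarity_stats(part)
    assert index == 1.0
    assert ratio == 0.0


def test_stationarity_empty_union_undefined():
    part = rs.partition_sets(make_sets(1.0, {"2h": set(), "d4": set()}))
    assert rs.stationarity_stats(part) == (None, None)


def test_both_ratio_orientations_labelled():
    sets = make_sets(1.0, {"2h": {1, 2, 3, 9}, "d4": {3, 4, 9}, "d7": {3, 5, 9}})
    part = rs.partition_sets(sets)
    ratios = common_unique_ratios(part)
    # common = {3, 9}; uniques: 2h {1,2}, d4 {4}, d7 {5}
    assert ratios["unique_over_common"] == pytest.approx(2 / 2)
    assert ratios["common_over_unique_total"] == pytest.approx(2 / 4)


# ---- trajectories ------------------------------------------------------------


def test_all_up_trajectory():
    sets = make_sets(1.0, {"2h": range(4), "d4": range(6), "d7": range(2)})
    summary = rs.direction_trajectory(sets)
    assert all(v == 100.0 for v in summary.percent_up.values())
    assert summary.peak_tp_up == "d4"


def test_empty_tp_percent_is_missing_not_zero():
    sets = [
        SDTGSet(1.0, "2h", up={1}, down={2}),
        SDTGSet(1.0, "d4", up=set(), down=set()),
    ]
    summary = rs.direction_trajectory(sets)
    assert summary.percent_up["d4"] is None
    assert summary.percent_up["2h"] == 50.0


def test_peak_tie_broken_to_earliest():
    sets = [
        SDTGSet(1.0, "2h", up={1, 2}, down=set()),
        SDTGSet(1.0, "d4", up={3, 4}, down=set()),
    ]
    assert rs.direction_trajectory(sets).peak_tp_up == "2h"


def test_trajectory_orders_timepoints():
    sets = make_sets(1.0, {"d28": {1}, "2h": {2}, "d7": {3}})
    summary = rs.direction_trajectory(sets)
    assert summary.timepoints == ("2h", "d7", "d28")


# ---- crosstab and rounding ---------------------------------------------------


def test_round_half_up_matches_table_convention():
    assert round_half_up(2.2222, 2) == 2.22
    assert round_half_up(0.125, 2) == 0.13  # half rounds up, not to even
    assert round_half_up(58.6705, 1) == 58.7
    assert round_half_up(20.1938, 1) == 20.2


def test_crosstab_report_layout():
    sets = make_sets(1.0, {"2h": range(8), "d4": range(4, 12)})
    table = rs.crosstab_report([rs.partition_sets(sets)])
    row = table.iloc[0]
    assert row["union"] == 12
    assert row["common_to_all"] == 4
    assert row["unique[2h]"] == 4
    assert row["unique_percent[2h]"] == pytest.approx(33.33)


def test_crosstab_empty_grid_flags_undefined():
    sets = make_sets(1.0, {"2h": set(), "d4": set()})
    table = rs.crosstab_report([rs.partition_sets(sets)])
    row = table.iloc[0]
    assert row["union"] == 0
    assert row.isna()["common_percent"]
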