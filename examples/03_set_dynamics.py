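"""Longitudinal set dynamics: Venn partitions and up/down trajectories.

The published per-dose partition counts are used directly as a worked
example: the 20 Gy arm keeps ~59% of its union common to all time points
(stationary response) while sublethal arms stay below 1%.
"""

import radskin as rs
from radskin import reference_tables as ref
from radskin.setdyn import SDTGSet

for dose, (union, common, unique) in ref.PER_DOSE_PARTITION.items():
    members = ref.reconstruct_partition_sets(
        union, common, {tp: unique[tp][0] for tp in unique}, list(unique)
    )
    sets = [SDTGSet(dose, tp, up=set(members[tp])) for tp in unique]
    part = rs.partition_sets(sets)
    index, ratio = rs.stationarity_stats(part)
    ratio_str = "inf" if ratio == float("inf") else f"{ratio:.3f}"
    print(
        f"{dose:>4g} Gy: union {part.union_count:4d}, "
        f"common {part.common_to_all_count:3d} "
        f"({100 * index:5.2f}% stationarity), "
        f"unique/common at first TP = {ratio_str}"
    )
# Output mirrors the printed per-dose table: stationarity 0.16%, 0%, 0.52%
# for 1/3/6 Gy versus 58.67% for 20 Gy - the common-to-unique contrast that
# separates lethal from sublethal exposure.

matrix, _ = rs.simulate_experiment(rs.study_preset(n_genes=8000, seed=7))
for dose in (1.0, 6.0):
    sets = [
        rs.call_sdtgs(rs.moderated_t_contrast(matrix, d, tp))
        for d, tp in matrix.groups()
        if d == dose
    ]
    summary = rs.direction_trajectory(sets)
    ups = {tp: f"{p:.0f}%" for tp, p in summary.percent_up.items() if p is not None}
    print(f"{dose:g} Gy percent-up trajectory {ups} -> peak at {summary.peak_tp_up}")
# Upregulation peaks at d4 for 1 Gy but d7 for 6 Gy: the peak shift that
# orders doses within the sublethal range.
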