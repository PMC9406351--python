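"""SDTG set dynamics: Venn partitions, up/down trajectories, stationarity.

Significant-gene sets are compared along one of two axes — across time
points within a dose, or across doses within a time point.  "Unique" means
present in exactly one label's set (the Venn singleton block); "common"
means present in all labels' sets.  Intermediate overlap blocks are retained
in the full Venn decomposition but the headline statistics report only
unique and common counts, matching how longitudinal radiation responses are
summarized: a lethal exposure yields a high common-to-all (stationarity)
fraction, sublethal exposures yield mostly time-point-unique genes.

Partitions are identity-based: a gene counted as common may still flip
regulation direction between time points, so a separate direction-
consistency annotation is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .errors import DataError
from .io import timepoint_index


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed summary tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SDTGSet:
    """Significant genes of one (dose, timepoint) contrast, by direction."""

    dose: float
    timepoint: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise DataError(
                f"genes in both directions at ({self.dose} Gy, {self.timepoint}): "
                f"{sorted(map(str, overlap))[:5]}"
            )

    @property
    def genes(self) -> set:
        return self.up | self.down

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def total(self) -> int:
        return self.n_up + self.n_down

    @property
    def percent_up(self) -> float | None:
        """100 * n_up / total; None (undefined, not 0) for an empty set."""
        if self.total == 0:
            return None
        return 100.0 * self.n_up / self.total

    def direction_of(self, gene) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)


@dataclass
class SetPartition:
    """Venn decomposition of labelled gene sets along one axis.

    ``blocks`` maps a frozenset of labels to the genes found in exactly that
    combination of sets; blocks are disjoint and their union is the union of
    all input sets.  Percentages are exact (unrounded) fractions of the
    union; ``None`` when the union is empty.
    """

    axis: str
    labels: tuple
    blocks: dict
    direction_consistent: dict = field(default_factory=dict)

    @property
    def union_count(self) -> int:
        return sum(len(g) for g in self.blocks.values())

    @property
    def common_to_all(self) -> set:
        return set(self.blocks.get(frozenset(self.labels), set()))

    @property
    def common_to_all_count(self) -> int:
        return len(self.common_to_all)

    def unique_set(self, label) -> set:
        return set(self.blocks.get(frozenset([label]), set()))

    @property
    def unique_counts(self) -> dict:
        return {lab: len(self.unique_set(lab)) for lab in self.labels}

    def _percent(self, count: int) -> float | None:
        u = self.union_count
        return None if u == 0 else 100.0 * count / u

    @property
    def unique_percent(self) -> dict:
        return {lab: self._percent(n) for lab, n in self.unique_counts.items()}

    @property
    def common_percent(self) -> float | None:
        return self._percent(self.common_to_all_count)


def partition_sets(sets: list[SDTGSet], axis: str = "across-TPs-within-dose") -> SetPartition:
    """Exact Venn decomposition of >= 2 SDTG sets sharing a gene universe.

    Labels are time points (within-dose axis) or doses (within-timepoint
    axis); duplicated labels are an error.  Every gene's membership mask is
    enumerated, so block sizes conserve the union exactly.
    """
    if len(sets) < 2:
        raise DataError("need at least 2 sets to partition")
    if axis == "across-TPs-within-dose":
        labels = tuple(s.timepoint for s in sets)
    elif axis == "across-doses-within-TP":
        labels = tuple(s.dose for s in sets)
    else:
        raise DataError(f"unknown axis {axis!r}")
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicated axis labels: {labels}")

    membership: dict = {}
    for lab, s in zip(labels, sets):
        for gene in s.genes:
            membership.setdefault(gene, set()).add(lab)
    blocks: dict = {}
    for gene, labs in membership.items():
        blocks.setdefault(frozenset(labs), set()).add(gene)

    # direction consistency of each multi-set gene across the sets it is in
    by_label = dict(zip(labels, sets))
    consistent: dict = {}
    for gene, labs in membership.items():
        if len(labs) > 1:
            dirs = {by_label[lab].direction_of(gene) for lab in labs}
            consistent[gene] = len(dirs) == 1
    return SetPartition(axis=axis, labels=labels, blocks=blocks,
                        direction_consistent=consistent)


@dataclass
class DynamicsSummary:
    """Per-dose longitudinal regulation statistics.

    ``percent_up`` per time point (None where the set is empty);
    ``peak_tp_up`` = time point of the largest upregulated count (ties to
    the earliest); ``stationarity_index`` = common-to-all / union;
    ``unique_common_ratio`` = first-TP-unique / common-to-all (inf flag when
    nothing is common).
    """

    dose: float
    timepoints: tuple
    n_up: dict
    n_down: dict
    percent_up: dict
    peak_tp_up: str | None
    stationarity_index: float | None
    unique_common_ratio: float | None


def stationarity_stats(partition: SetPartition) -> tuple[float | None, float | None]:
    """(stationarity index, unique/common ratio) with exact arithmetic.

    The index is common-to-all / union (None when the union is empty); the
    ratio is first-label-unique / common-to-all, flagged +inf when the
    common block is empty but uniques exist, 0/0 -> None.
    """
    union = partition.union_count
    if union == 0:
        return None, None
    common = partition.common_to_all_count
    index = float(Fraction(common, union))
    first_unique = partition.unique_counts[partition.labels[0]]
    if common == 0:
        ratio = float("inf") if first_unique > 0 else None
    else:
        ratio = float(Fraction(first_unique, common))
    return index, ratio


def common_unique_ratios(partition: SetPartition) -> dict:
    """Both orientations of the unique-vs-common ratio, labelled explicitly.

    ``unique_over_common`` uses the first label's unique count;
    ``common_over_unique_total`` divides the common count by the total of
    all labels' unique counts.  Infinite values flag empty denominators.
    """
    common = partition.common_to_all_count
    first_unique = partition.unique_counts[partition.labels[0]]
    total_unique = sum(partition.unique_counts.values())

    def _ratio(num: int, den: int) -> float | None:
        if den == 0:
            return float("inf") if num > 0 else None
        return num / den

    return {
        "unique_over_common": _ratio(first_unique, common),
        "common_over_unique_total": _ratio(common, total_unique),
    }


def direction_trajectory(sets: list[SDTGSet]) -> DynamicsSummary:
    """Longitudinal up/down statistics for one dose's time-ordered sets."""
    if not sets:
        raise DataError("no sets given")
    doses = {s.dose for s in sets}
    if len(doses) != 1:
        raise DataError(f"sets span multiple doses: {sorted(doses)}")
    ordered = sorted(sets, key=lambda s: timepoint_index(s.timepoint))
    tps = tuple(s.timepoint for s in ordered)
    n_up = {s.timepoint: s.n_up for s in ordered}
    n_down = {s.timepoint: s.n_down for s in ordered}
    percent_up = {s.timepoint: s.percent_up for s in ordered}

    peak_tp = None
    if any(v > 0 for v in n_up.values()):
        best = max(n_up.values())
        peak_tp = next(tp for tp in tps if n_up[tp] == best)  # earliest on ties

    stationarity = ratio = None
    if len(ordered) >= 2:
        part = partition_sets(ordered, axis="across-TPs-within-dose")
        stationarity, ratio = stationarity_stats(part)
    return DynamicsSummary(
        dose=doses.pop(),
        timepoints=tps,
        n_up=n_up,
        n_down=n_down,
        percent_up=percent_up,
        peak_tp_up=peak_tp,
        stationarity_index=stationarity,
        unique_common_ratio=ratio,
    )


def crosstab_report(partitions: list[SetPartition]) -> pd.DataFrame:
    """Union / common / per-label unique counts and percentages, one row per
    partition block, percentages rounded half-up to 2 decimals (None kept as
    NA when the union is empty)."""
    rows = []
    for part in partitions:
        row: dict = {
            "axis": part.axis,
            "union": part.union_count,
            "common_to_all": part.common_to_all_count,
            "common_percent": (
                None
                if part.common_percent is None
                else round_half_up(part.common_percent, 2)
            ),
        }
        for lab in part.labels:
            row[f"unique[{lab}]"] = part.unique_counts[lab]
            pct = part.unique_percent[lab]
            row[f"unique_percent[{lab}]"] = None if pct is None else round_half_up(pct, 2)
        rows.append(row)
    return pd.DataFrame(rows)
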