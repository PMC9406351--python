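"""Decision rules: lethal vs sublethal call, dose-class estimate, marker panel.

The classifier operationalizes the qualitative exposure signatures of the
skin time course: a lethal dose shows predominantly *downregulated* SDTGs at
the early time points (2h-d7) together with a high stationarity index (large
common-to-all-TP fraction), while sublethal doses show up-dominated, dynamic
(low-stationarity) responses whose upregulation peak shifts later as the
dose grows.  The directional rules come from the study; the numeric cutoffs
are package defaults chosen midway between the reported lethal (~90% down,
~59% common) and sublethal (~70% up, <=11% common) signatures, and are all
configurable.  "Indeterminate" is a first-class outcome - conflicting rules
never yield a silent default call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import timepoint_index
from .setdyn import DynamicsSummary, SetPartition

#: time points of the first post-exposure week, the decision window
N_EARLY_TPS = 3


def _default_peak_order() -> dict:
    # upregulation peaking at 2h/d4 marks the low end of the sublethal range
    # (1-3 Gy), a d7 peak the upper end (6 Gy), later peaks higher still
    return {"2h": "low", "d4": "low", "d7": "mid", "d21": "high", "d28": "high"}


@dataclass(frozen=True)
class DosimetryRules:
    """Cutoffs for the rule cascade; every threshold is overridable."""

    lethal_down_fraction_min: float = 0.60
    lethal_stationarity_min: float = 0.40
    sublethal_up_fraction_min: float = 0.55
    peak_order: dict = field(default_factory=_default_peak_order)
    panel_fc_min: float = 2.0
    panel_mean_fc_min: float = 3.0
    lethal_dose: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "lethal_down_fraction_min",
            "lethal_stationarity_min",
            "sublethal_up_fraction_min",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} outside (0, 1)")
        if self.panel_fc_min <= 0 or self.panel_mean_fc_min <= 0:
            raise ConfigError("panel fold-change thresholds must be positive")


@dataclass
class DoseCallReport:
    """Outcome of the rule cascade with its full evidence trail."""

    call: str  # "lethal" | "sublethal" | "indeterminate"
    dose_class_estimate: str | None
    evidence: dict
    reasons: list = field(default_factory=list)
    panel: dict | None = None

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "dose_class_estimate": self.dose_class_estimate,
            "evidence": self.evidence,
            "reasons": list(self.reasons),
            "panel": self.panel,
        }


def classify_exposure(
    summary: DynamicsSummary,
    partition: SetPartition | None = None,
    rules: DosimetryRules | None = None,
) -> DoseCallReport:
    """Deterministic rule cascade over one dose arm's dynamics statistics.

    lethal    <=> every early TP is down-dominated (down fraction >=
                  ``lethal_down_fraction_min``) AND the stationarity index is
                  >= ``lethal_stationarity_min`` (both rules must fire);
    sublethal <=> every early TP is up-dominated (up fraction >=
                  ``sublethal_up_fraction_min``) AND stationarity is below
                  the lethal cutoff; the dose class then follows the
                  upregulation peak via ``peak_order``;
    otherwise -> indeterminate, with the reasons recorded.
    """
    if rules is None:
        rules = DosimetryRules()
    stationarity = summary.stationarity_index
    if partition is not None:
        from .setdyn import stationarity_stats

        stationarity = stationarity_stats(partition)[0]

    early = [tp for tp in summary.timepoints if timepoint_index(tp) < N_EARLY_TPS]
    early_pct = {tp: summary.percent_up.get(tp) for tp in early}
    evidence = {
        "early_percent_up": early_pct,
        "stationarity_index": stationarity,
        "peak_tp_up": summary.peak_tp_up,
        "unique_common_ratio": summary.unique_common_ratio,
    }

    defined = {tp: p for tp, p in early_pct.items() if p is not None}
    if len(defined) < 2:
        return DoseCallReport(
            "indeterminate",
            None,
            evidence,
            reasons=["fewer than 2 early time points with any SDTGs"],
        )

    down_dominant = all(
        (100.0 - p) / 100.0 >= rules.lethal_down_fraction_min
        for p in defined.values()
    )
    up_dominant = all(
        p / 100.0 >= rules.sublethal_up_fraction_min for p in defined.values()
    )
    stationary = stationarity is not None and stationarity >= rules.lethal_stationarity_min

    if down_dominant and stationary:
        return DoseCallReport(
            "lethal",
            None,
            evidence,
            reasons=[
                "early time points down-dominated",
                f"stationarity index {stationarity:.3f} >= {rules.lethal_stationarity_min}",
            ],
        )
    if up_dominant and not stationary:
        dose_class = rules.peak_order.get(summary.peak_tp_up)
        return DoseCallReport(
            "sublethal",
            dose_class,
            evidence,
            reasons=[
                "early time points up-dominated",
                "low stationarity (dynamic, TP-specific response)",
                f"upregulation peak at {summary.peak_tp_up}",
            ],
        )
    reasons = ["rules conflict or neither signature reached:"]
    reasons.append(f"down-dominant early TPs: {down_dominant}")
    reasons.append(f"up-dominant early TPs: {up_dominant}")
    reasons.append(f"stationary: {stationary} (index={stationarity})")
    return DoseCallReport("indeterminate", None, evidence, reasons=reasons)


def panel_score(
    fc_grid: pd.DataFrame,
    panel_genes: list,
    rules: DosimetryRules | None = None,
) -> tuple[int, dict]:
    """Sign-consistency score of a marker panel over a (gene x group) FC grid.

    ``fc_grid`` holds signed linear fold changes, indexed by gene, with one
    column per (dose, timepoint) cell (tuple or MultiIndex columns).  A gene
    is consistent iff FC >= ``panel_fc_min`` at every sublethal cell and
    FC <= -``panel_fc_min`` at every lethal cell; genes with missing cells
    are unevaluable and excluded from the count.  Invariant to gene and
    column order.
    """
    if rules is None:
        rules = DosimetryRules()
    lethal_cols = [c for c in fc_grid.columns if float(c[0]) == rules.lethal_dose]
    sub_cols = [c for c in fc_grid.columns if float(c[0]) != rules.lethal_dose]
    verdicts: dict = {}
    n_consistent = 0
    for gene in panel_genes:
        if gene not in fc_grid.index:
            verdicts[gene] = {"verdict": "unevaluable", "reason": "gene missing"}
            continue
        row = fc_grid.loc[gene]
        if row[list(fc_grid.columns)].isna().any():
            verdicts[gene] = {"verdict": "unevaluable", "reason": "missing cells"}
            continue
        sub_ok = bool((row[sub_cols] >= rules.panel_fc_min).all()) if sub_cols else True
        lethal_ok = (
            bool((row[lethal_cols] <= -rules.panel_fc_min).all()) if lethal_cols else True
        )
        ok = sub_ok and lethal_ok
        verdicts[gene] = {
            "verdict": "consistent" if ok else "inconsistent",
            "mean_abs_fc": float(np.abs(row.to_numpy(dtype=float)).mean()),
            "sublethal_ok": sub_ok,
            "lethal_ok": lethal_ok,
        }
        n_consistent += int(ok)
    return n_consistent, verdicts


def sublethal_unique_screen(
    sdtg_grid: dict,
    rules: DosimetryRules | None = None,
) -> set:
    """Genes upregulated in *every* sublethal (dose, TP <= d7) cell and absent
    from every lethal SDTG set (any direction, any time point).

    ``sdtg_grid`` maps (dose, timepoint) -> :class:`SDTGSet`.
    """
    if rules is None:
        rules = DosimetryRules()
    sub_cells = [
        s
        for (d, tp), s in sdtg_grid.items()
        if d != rules.lethal_dose and timepoint_index(tp) < N_EARLY_TPS
    ]
    lethal_cells = [s for (d, _), s in sdtg_grid.items() if d == rules.lethal_dose]
    if not sub_cells:
        return set()
    up_everywhere = set.intersection(*[s.up for s in sub_cells])
    lethal_any: set = set().union(*[s.genes for s in lethal_cells]) if lethal_cells else set()
    return up_everywhere - lethal_any
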