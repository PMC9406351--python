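"""Significantly differentially transcribed gene (SDTG) calling.

Each (dose, timepoint) group is contrasted against the 0 Gy control at the
same timepoint with an empirical-Bayes moderated two-sample t-statistic:
gene-wise sample variances s_g^2 (d_g residual df) are shrunk toward a prior
(d0, s0^2) fitted to the whole gene list by method of moments on the log
variances, giving the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_g = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2)) on d0 + d_g degrees of
freedom.  P-values are Benjamini-Hochberg adjusted within the contrast's
full gene list.  The fold change is defined on the log2 scale as the mean
log2 expression of the exposed group minus the mean log2 expression of the
control group; the signed linear FC is 2**log2FC for upregulation and
-2**(-log2FC) for downregulation, so |FC| >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, GroupAbsentError
from .io import ExpressionMatrix

_VAR_FLOOR = 1e-8
_D0_CAP = 1e8  # effectively full shrinkage


@dataclass(frozen=True)
class DEThresholds:
    """Significance and fold-change cutoffs for SDTG calling."""

    p_adj_max: float = 0.05
    fc_min: float = 2.0
    fc_top: float = 3.5  # stricter reporting threshold for top-gene tables
    fc_panel_mean: float = 3.0  # panel-average threshold for marker tables
    use_raw_p: bool = False  # threshold raw p instead of BH-adjusted

    def __post_init__(self) -> None:
        if not 0 < self.p_adj_max <= 1:
            raise ConfigError(f"p_adj_max={self.p_adj_max} outside (0, 1]")
        if self.fc_min < 1:
            raise ConfigError(f"fc_min={self.fc_min} must be >= 1")
        if self.fc_top <= 0 or self.fc_panel_mean <= 0:
            raise ConfigError("fold-change thresholds must be positive")


@dataclass(frozen=True)
class ModerationParams:
    """Variance-prior hyperparameters of the moderated t."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ConfigError("d0 must be >= 0 and s0_sq > 0")

    def posterior_variance(self, s_sq: np.ndarray, dg: float) -> np.ndarray:
        if self.d0 == 0:
            return np.asarray(s_sq, dtype=float)
        if not np.isfinite(self.d0) or self.d0 >= _D0_CAP:
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + dg * s_sq) / (self.d0 + dg)


@dataclass
class ContrastResult:
    """Per-gene statistics for one (dose, timepoint) vs control contrast."""

    dose: float
    timepoint: str
    table: pd.DataFrame | None
    params: ModerationParams | None
    group_absent: bool = False
    n_exposed: int = 0
    n_control: int = 0


def fold_change(mean_log2_exposed: float, mean_log2_control: float) -> tuple[float, float]:
    """(log2FC, signed linear FC) from two group means of log2 expression."""
    log2fc = float(mean_log2_exposed) - float(mean_log2_control)
    if not np.isfinite(log2fc):
        raise DataError("non-finite group means")
    return log2fc, signed_fc(log2fc)


def signed_fc(log2fc):
    """Signed linear fold change: 2**lfc if lfc >= 0 else -2**(-lfc)."""
    arr = np.asarray(log2fc, dtype=float)
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    return float(out) if np.isscalar(log2fc) else out


def _trigamma(x: np.ndarray) -> np.ndarray:
    return polygamma(1, x)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(sample_vars: np.ndarray, dg: float) -> ModerationParams:
    """Fit the (d0, s0^2) variance prior by moments on log sample variances.

    With s_g^2 * dg / sigma_g^2 ~ chi^2(dg) and sigma_g^2 scaled inverse
    chi-square(d0, s0^2), z_g = log s_g^2 has var(z) = trigamma(dg/2) +
    trigamma(d0/2) and a mean linking s0^2 through digamma terms; excess
    variance below trigamma(dg/2) means no dispersion of true variances and
    the prior degenerates to d0 = +inf (full shrinkage).
    """
    from scipy.special import digamma

    s2 = np.maximum(np.asarray(sample_vars, dtype=float), _VAR_FLOOR)
    if s2.size < 2:
        raise DataError("need at least 2 genes to estimate the variance prior")
    z = np.log(s2)
    e = z - digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(dg / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: variances are exchangeable, shrink fully to
        # their arithmetic mean
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t_contrast(
    matrix: ExpressionMatrix,
    dose: float,
    timepoint: str,
    control_dose: float = 0.0,
    params: ModerationParams | None = None,
) -> ContrastResult:
    """Moderated-t contrast of (dose, timepoint) against control at the same
    timepoint.  ``params=None`` estimates the variance prior from this
    contrast's gene-wise pooled variances; pass explicit params to share a
    prior or to force the ordinary-t (d0=0) / full-shrinkage (d0=inf) limits.

    A missing exposed group yields an explicit ``group_absent`` result.
    """
    try:
        exposed = matrix.group_values(dose, timepoint).to_numpy(dtype=float)
    except GroupAbsentError:
        return ContrastResult(dose, timepoint, None, None, group_absent=True)
    control = matrix.group_values(control_dose, timepoint).to_numpy(dtype=float)
    n1, n2 = exposed.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"contrast ({dose} Gy, {timepoint}) needs >= 2 replicates per group"
        )
    dg = n1 + n2 - 2

    log2fc = exposed.mean(axis=1) - control.mean(axis=1)
    ss = exposed.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    s_sq = np.maximum(ss / dg, _VAR_FLOOR)

    if params is None:
        params = estimate_moderation(s_sq, dg)
    s_tilde_sq = params.posterior_variance(s_sq, dg)
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    t_mod = log2fc / se
    # total df capped at the family's summed residual df (a d0=inf prior
    # cannot be more informative than pooling every gene's variance)
    df = min(params.d0 + dg, len(log2fc) * dg)
    p_raw = 2.0 * t_dist.sf(np.abs(t_mod), df)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    fc = signed_fc(log2fc)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": fc,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=matrix.probe_ids.rename("gene"),
    )
    return ContrastResult(
        dose, timepoint, table, params, n_exposed=n1, n_control=n2
    )


def flag_sdtgs(table: pd.DataFrame, thresholds: DEThresholds) -> pd.Series:
    p = table["p_raw"] if thresholds.use_raw_p else table["p_adj"]
    return (p < thresholds.p_adj_max) & (table["fc"].abs() >= thresholds.fc_min)


def call_sdtgs(result: ContrastResult, thresholds: DEThresholds | None = None):
    """Reduce a contrast to its SDTG set (see :mod:`radskin.setdyn`).

    Returns an :class:`~radskin.setdyn.SDTGSet`; raises on a group-absent
    contrast (callers decide how to treat a truncated arm).
    """
    from .setdyn import SDTGSet

    if thresholds is None:
        thresholds = DEThresholds()
    if result.group_absent or result.table is None:
        raise GroupAbsentError(
            f"no data for dose={result.dose} Gy at {result.timepoint!r}"
        )
    tab = result.table
    is_sdtg = flag_sdtgs(tab, thresholds)
    hits = tab[is_sdtg]
    return SDTGSet(
        dose=result.dose,
        timepoint=result.timepoint,
        up=set(hits.index[hits["direction"] == "up"]),
        down=set(hits.index[hits["direction"] == "down"]),
    )


def contrast_table_with_flags(
    result: ContrastResult, thresholds: DEThresholds | None = None
) -> pd.DataFrame:
    """Full per-gene contrast table with the ``is_sdtg`` flag column."""
    if thresholds is None:
        thresholds = DEThresholds()
    if result.table is None:
        raise GroupAbsentError(
            f"no data for dose={result.dose} Gy at {result.timepoint!r}"
        )
    out = result.table.copy()
    out["is_sdtg"] = flag_sdtgs(out, thresholds)
    return out
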