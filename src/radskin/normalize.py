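"""Preprocessing: within-sample lowess detrending, between-sample quantile
normalization, and PCA-based outlier exclusion.

Stage order is fixed as lowess -> quantile -> PCA filter.  Outliers are
judged within (dose, timepoint) groups rather than globally, because dose
itself separates samples in this design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DataError
from .io import ExpressionMatrix

#: conventional two-color defaults; the source protocol names no values
DEFAULT_SPAN = 0.3
DEFAULT_K_SD = 4.0
_MIN_PROBES = 10


@dataclass
class NormalizationReport:
    """What preprocessing did: spans, reference summary, exclusions."""

    lowess_span: float | None = None
    quantile_reference_summary: dict = field(default_factory=dict)
    excluded_samples: list = field(default_factory=list)
    filter_refused: bool = False

    def to_dict(self) -> dict:
        return {
            "lowess_span": self.lowess_span,
            "quantile_reference_summary": self.quantile_reference_summary,
            "excluded_samples": self.excluded_samples,
            "filter_refused": self.filter_refused,
        }


def lowess_detrend(
    sample_values: np.ndarray,
    covariate: np.ndarray,
    span: float = DEFAULT_SPAN,
) -> np.ndarray:
    """Subtract a lowess fit of ``sample_values`` on ``covariate``.

    Returns values minus the fit, i.e. the intensity-detrended residuals.
    Refuses fewer than 10 probes (the local fit is unstable there).
    """
    y = np.asarray(sample_values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DataError("values and covariate must be equal-length vectors")
    if y.size < _MIN_PROBES:
        raise DataError(f"need at least {_MIN_PROBES} probes for lowess detrending")
    if not 0.0 < span <= 1.0:
        raise DataError(f"span must be in (0, 1], got {span}")
    # delta skips refits within 1% of the covariate range: standard lowess
    # speedup, negligible effect on the smooth at array scale
    delta = 0.01 * float(np.ptp(x))
    fit = _sm_lowess(y, x, frac=span, delta=delta, return_sorted=False)
    return y - fit


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-order-statistics reference.

    After normalization each sample's sorted values equal the cross-sample
    mean of order statistics; tied values receive the mean of their tied
    ranks' reference values.  Idempotent: a second application is a no-op.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = values.shape
    if n_samples == 1:
        import warnings

        warnings.warn("single-sample matrix: quantile normalization is identity")
        return ExpressionMatrix(matrix.values.copy(), matrix.meta.copy())
    sorted_vals = np.sort(values, axis=0)
    reference = sorted_vals.mean(axis=1)
    # rows of identical order statistics must map to themselves exactly
    # (np.mean of n equal values can be off by an ulp), so idempotence is exact
    const = sorted_vals[:, 0] == sorted_vals[:, -1]
    reference[const] = sorted_vals[const, 0]
    # each tie run spans ranks [rmin, rmax]; its members all receive the mean
    # of the reference values over that span (cumsum makes the mean O(1))
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values)
    for j in range(n_samples):
        rmin = rankdata(values[:, j], method="min")  # 1-based
        rmax = rankdata(values[:, j], method="max")
        col = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
        untied = rmin == rmax  # take the reference directly: exact, so a
        col[untied] = reference[rmin[untied] - 1]  # second pass is a no-op
        out[:, j] = col
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, matrix.meta.copy())


def pca_outlier_filter(
    matrix: ExpressionMatrix,
    k_sd: float = DEFAULT_K_SD,
    report: NormalizationReport | None = None,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Drop samples whose PC1/PC2 score is a within-group robust outlier.

    Scores are projected by a PCA over all samples; a sample is flagged when
    its PC1 or PC2 score deviates from its (dose, timepoint) group median by
    more than ``k_sd`` robust SDs (1.4826 * MAD).  Refuses (keeps everything,
    sets ``filter_refused``) rather than removing more than 20% of samples;
    raises if every sample would be removed.
    """
    if report is None:
        report = NormalizationReport()
    if matrix.n_samples < 4:
        raise DataError("PCA outlier filtering needs at least 4 samples")
    X = matrix.values.to_numpy(dtype=float).T  # samples x probes
    n_comp = min(2, matrix.n_samples - 1)
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    flagged: list[dict] = []
    if np.isfinite(k_sd):
        groups = matrix.meta.groupby(["dose_gy", "timepoint"], sort=False).groups
        pos = {s: i for i, s in enumerate(matrix.sample_ids)}
        for (dose, tp), samples in groups.items():
            idx = [pos[s] for s in samples]
            g = scores[idx]
            med = np.median(g, axis=0)
            mad = np.median(np.abs(g - med), axis=0)
            robust_sd = np.where(mad > 0, 1.4826 * mad, np.inf)
            for s, row in zip(samples, g):
                dev = np.abs(row - med) / robust_sd
                if np.any(dev > k_sd):
                    pc = int(np.argmax(dev)) + 1
                    flagged.append(
                        {
                            "sample_id": str(s),
                            "dose_gy": float(dose),
                            "timepoint": str(tp),
                            "pc_scores": [float(v) for v in row],
                            "rule": f"|PC{pc} deviation| > {k_sd} robust SD within group",
                        }
                    )

    if len(flagged) == matrix.n_samples:
        raise DataError("PCA outlier filter would remove every sample")
    if len(flagged) > 0.2 * matrix.n_samples:
        report.filter_refused = True
        report.excluded_samples = []
        return matrix, report

    report.excluded_samples = flagged
    if not flagged:
        return matrix, report
    drop = {f["sample_id"] for f in flagged}
    keep = [s for s in matrix.sample_ids if s not in drop]
    return matrix.subset_samples(keep), report


def normalize_matrix(
    matrix: ExpressionMatrix,
    span: float = DEFAULT_SPAN,
    k_sd: float = DEFAULT_K_SD,
    lowess: bool = True,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Full preprocessing pass: lowess -> quantile -> PCA outlier filter."""
    report = NormalizationReport(lowess_span=span if lowess else None)
    work = matrix
    if lowess:
        covariate = work.values.mean(axis=1).to_numpy()
        detrended = {
            s: lowess_detrend(work.values[s].to_numpy(), covariate, span)
            for s in work.sample_ids
        }
        frame = pd.DataFrame(detrended, index=work.values.index)[work.sample_ids]
        work = ExpressionMatrix(frame, work.meta.copy())
    work = quantile_normalize(work)
    ref = np.sort(work.values.to_numpy(), axis=0).mean(axis=1)
    report.quantile_reference_summary = {
        "min": float(ref.min()),
        "median": float(np.median(ref)),
        "max": float(ref.max()),
    }
    work, report = pca_outlier_filter(work, k_sd=k_sd, report=report)
    return work, report
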