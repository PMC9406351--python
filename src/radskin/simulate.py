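"""Synthetic dose x time skin-expression experiments with planted ground truth.

The generator emulates the response architecture of a mouse whole-body
irradiation time course: five replicates per (dose, time point) group,
~20,000 probes on the log2 scale, and a dose-dependent differential-
transcription architecture in which a lethal dose (20 Gy, animals lost after
the first post-exposure week) produces a large, stationary, down-dominated
gene set shared across time points, while sublethal doses (1, 3, 6 Gy)
produce smaller, dynamic, up-dominated, time-point-specific sets whose
response peak shifts later as the dose increases.

Each dose's planted set is a common-to-all-time-points block plus
time-point-unique blocks; the common block size is solved in closed form
from the configured common fraction and per-group counts.  Gene-wise noise
variances follow a scaled inverse chi-square prior, matching the moderated-t
model used by the differential-expression stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, TIMEPOINT_ORDER

#: number of gene ids reserved for the designated marker/screen panels
_RESERVED_IDS = 8
_MARKER_IDS = (0, 1, 2, 3, 4)
_SUBLETHAL_UNIQUE_IDS = (5, 6, 7)


def probe_id(gene: int) -> str:
    """Probe label used in generated matrices for integer gene id ``gene``."""
    return f"g{gene:05d}"


@dataclass
class SimConfig:
    """Configuration of one synthetic irradiation experiment.

    ``de_counts`` gives the planted significantly-modulated gene count per
    (dose, timepoint) group; ``common_fraction`` the fraction of each dose's
    distinct planted genes shared by all of its time points; ``up_fraction``
    the upregulated fraction per group.  ``lfc_range`` bounds planted
    |log2 fold change| (the default cap of log2(20) mirrors fold changes up
    to ~20-fold).  ``variance_prior`` = (d0, s0_sq) parameterizes the scaled
    inverse chi-square gene-variance prior.
    """

    n_genes: int = 20_000
    n_replicates: int = 5
    doses: tuple[float, ...] = (1.0, 3.0, 6.0, 20.0)
    timepoints: tuple[str, ...] = TIMEPOINT_ORDER
    lethal_dose: float = 20.0
    n_lethal_timepoints: int = 3
    de_counts: dict = field(default_factory=dict)
    common_fraction: dict = field(default_factory=dict)
    up_fraction: dict = field(default_factory=dict)
    peak_tp: dict = field(default_factory=dict)
    lfc_range: tuple[float, float] = (1.5, np.log2(20.0))
    variance_prior: tuple[float, float] = (4.0, 0.25**2)
    baseline_range: tuple[float, float] = (6.0, 12.0)
    special_panels: bool = True
    seed: int = 0

    # ---- derived views ---------------------------------------------------

    def timepoints_for(self, dose: float) -> tuple[str, ...]:
        """Time points at which a dose's groups exist (lethal arm truncated)."""
        if dose == self.lethal_dose:
            return self.timepoints[: self.n_lethal_timepoints]
        return self.timepoints

    def any_planted(self) -> bool:
        return any(v > 0 for v in self.de_counts.values())

    def validate(self) -> None:
        if self.n_genes < _RESERVED_IDS + 1:
            raise ConfigError("n_genes too small")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates per group")
        if not (0 < self.lfc_range[0] <= self.lfc_range[1]):
            raise ConfigError(f"invalid lfc_range {self.lfc_range}")
        d0, s0_sq = self.variance_prior
        if d0 <= 0 or s0_sq <= 0:
            raise ConfigError("variance_prior components must be positive")
        for dose in self.doses:
            f = self.common_fraction.get(dose, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"common_fraction[{dose}]={f} outside [0,1]")
            for tp in self.timepoints:
                key = (dose, tp)
                if tp not in self.timepoints_for(dose):
                    if self.de_counts.get(key, 0) > 0:
                        raise ConfigError(
                            f"dose {dose} Gy has no group at {tp} "
                            "(lethal arm ends after the first post-exposure week)"
                        )
                    continue
                n = self.de_counts.get(key, 0)
                if not 0 <= n <= self.n_genes:
                    raise ConfigError(f"de_counts[{key}]={n} exceeds n_genes")
                u = self.up_fraction.get(key, 0.5)
                if not 0.0 <= u <= 1.0:
                    raise ConfigError(f"up_fraction[{key}]={u} outside [0,1]")


@dataclass
class SimTruth:
    """Planted ground truth: per-group effects and the designated panels.

    ``planted_de`` maps (dose, timepoint) to {gene id: signed true log2FC};
    ``marker_panel`` holds the five gene ids planted up in every sublethal
    group and down in every lethal group (first three time points);
    ``sublethal_unique`` the three ids planted up only in sublethal groups.
    """

    planted_de: dict
    marker_panel: tuple[int, ...]
    sublethal_unique: tuple[int, ...]

    def planted_genes(self, dose: float, timepoint: str) -> set[int]:
        return set(self.planted_de.get((dose, timepoint), {}))

    def planted_probe_ids(self, dose: float, timepoint: str) -> set[str]:
        return {probe_id(g) for g in self.planted_genes(dose, timepoint)}

    def all_planted_probe_ids(self) -> set[str]:
        out: set[str] = set()
        for effects in self.planted_de.values():
            out |= {probe_id(g) for g in effects}
        return out


# ---- presets ---------------------------------------------------------------

#: per-(dose, timepoint) planted SDTG totals.  Each dose's distinct-gene union
#: reproduces the study's per-dose union counts (619 / 411 / 765 / 1038 genes
#: for 1 / 3 / 6 / 20 Gy) and its common-to-all-time-points fraction
#: (0.16% / 0% / 0.52% / 58.7%); upregulated counts peak at d4 for 1 and 3 Gy
#: and at d7 for 6 Gy, while the lethal arm is down-dominated throughout.
_PRESET_COUNTS = {
    1.0: {"2h": 131, "d4": 181, "d7": 116, "d21": 99, "d28": 96},
    3.0: {"2h": 90, "d4": 120, "d7": 75, "d21": 66, "d28": 60},
    6.0: {"2h": 114, "d4": 174, "d7": 244, "d21": 134, "d28": 115},
    20.0: {"2h": 739, "d4": 759, "d7": 758},
}
_PRESET_COMMON = {1.0: 1 / 619, 3.0: 0.0, 6.0: 4 / 765, 20.0: 609 / 1038}
_PRESET_UP = {
    1.0: {"2h": 0.70, "d4": 0.75, "d7": 0.60, "d21": 0.45, "d28": 0.40},
    3.0: {"2h": 0.70, "d4": 0.75, "d7": 0.60, "d21": 0.45, "d28": 0.40},
    6.0: {"2h": 0.60, "d4": 0.65, "d7": 0.75, "d21": 0.45, "d28": 0.40},
    20.0: {"2h": 0.10, "d4": 0.10, "d7": 0.10},
}
_PRESET_PEAK = {1.0: "d4", 3.0: "d4", 6.0: "d7", 20.0: "d4"}


def study_preset(
    doses: tuple[float, ...] = (1.0, 3.0, 6.0, 20.0),
    n_genes: int = 20_000,
    seed: int = 0,
) -> SimConfig:
    """The default study-conditions preset (optionally restricted to a subset
    of dose arms, e.g. one arm per simulated cohort)."""
    unknown = set(doses) - set(_PRESET_COUNTS)
    if unknown:
        raise ConfigError(f"no preset architecture for dose(s) {sorted(unknown)}")
    de_counts = {
        (d, tp): n for d in doses for tp, n in _PRESET_COUNTS[d].items()
    }
    up_fraction = {
        (d, tp): u for d in doses for tp, u in _PRESET_UP[d].items()
    }
    return SimConfig(
        n_genes=n_genes,
        doses=tuple(float(d) for d in doses),
        de_counts=de_counts,
        common_fraction={d: _PRESET_COMMON[d] for d in doses},
        up_fraction=up_fraction,
        peak_tp={d: _PRESET_PEAK[d] for d in doses},
        seed=seed,
    )


def null_preset(n_genes: int = 20_000, doses=(1.0,), seed: int = 0) -> SimConfig:
    """A no-signal experiment: identical group means for every gene."""
    return SimConfig(
        n_genes=n_genes,
        doses=tuple(float(d) for d in doses),
        de_counts={},
        special_panels=False,
        seed=seed,
    )


# ---- planted-set allocation -------------------------------------------------


def _common_block_size(counts: list[int], fraction: float) -> int:
    """Closed-form common-to-all block size C with C = fraction * union.

    With per-time-point totals n_t, a common block C and unique blocks
    n_t - C, the union is C + sum(n_t - C); requiring C = f * union gives
    C = f * sum(n_t) / (1 + f * (k - 1)).
    """
    k = len(counts)
    if k == 0 or fraction <= 0.0:
        return 0
    c = round(fraction * sum(counts) / (1.0 + fraction * (k - 1)))
    return min(c, min(counts))


def _allocate_sets(config: SimConfig) -> dict:
    """Assign gene ids to each dose's common and unique blocks.

    Returns {(dose, tp): sorted list of member gene ids}.  Pools for
    different doses are disjoint and start after the reserved panel ids, so
    the layout is independent of n_genes.
    """
    members: dict = {}
    next_id = _RESERVED_IDS
    for dose in config.doses:
        tps = [
            tp
            for tp in config.timepoints_for(dose)
            if config.de_counts.get((dose, tp), 0) > 0
        ]
        counts = [config.de_counts[(dose, tp)] for tp in tps]
        c = _common_block_size(counts, config.common_fraction.get(dose, 0.0))
        common = list(range(next_id, next_id + c))
        next_id += c
        for tp, n in zip(tps, counts):
            unique = list(range(next_id, next_id + (n - c)))
            next_id += n - c
            members[(dose, tp)] = common + unique
    if next_id > config.n_genes:
        raise ConfigError(
            f"planted architecture needs {next_id} genes but n_genes={config.n_genes}"
        )
    return members


def _plant_effects(config: SimConfig) -> SimTruth:
    """Draw signed true log2 fold changes for every planted (gene, group)."""
    members = _allocate_sets(config)
    rng_eff = np.random.default_rng([config.seed, 11])
    rng_special = np.random.default_rng([config.seed, 13])
    lo, hi = config.lfc_range
    planted: dict = {}

    for dose in config.doses:
        for tp in config.timepoints_for(dose):
            ids = members.get((dose, tp), [])
            if not ids:
                continue
            n = len(ids)
            k_up = int(round(config.up_fraction.get((dose, tp), 0.5) * n))
            mags = rng_eff.uniform(lo, hi, size=n)
            # highest ids (the TP-unique block) take the up slots, so the
            # common block stays direction-consistent across time points
            signs = np.where(np.arange(n) >= n - k_up, 1.0, -1.0)
            planted[(dose, tp)] = dict(
                zip(ids, (signs * mags).tolist())
            )

    marker_panel: tuple[int, ...] = ()
    sublethal_unique: tuple[int, ...] = ()
    if config.special_panels and config.any_planted():
        marker_panel = _MARKER_IDS
        sublethal_unique = _SUBLETHAL_UNIQUE_IDS
        early = config.timepoints[: config.n_lethal_timepoints]
        for dose in config.doses:
            lethal = dose == config.lethal_dose
            for tp in early:
                if tp not in config.timepoints_for(dose):
                    continue
                eff = planted.setdefault((dose, tp), {})
                for g in marker_panel:
                    mag = rng_special.uniform(lo, hi)
                    eff[g] = -mag if lethal else mag
                if not lethal:
                    for g in sublethal_unique:
                        eff[g] = rng_special.uniform(lo, hi)
                else:
                    # keep the special-magnitude stream aligned across arms
                    rng_special.uniform(lo, hi, size=len(sublethal_unique))
    return SimTruth(planted, marker_panel, sublethal_unique)


# ---- matrix generation ------------------------------------------------------


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    all_doses = (0.0,) + tuple(d for d in config.doses if d != 0.0)
    for dose in all_doses:
        tps = config.timepoints if dose == 0.0 else config.timepoints_for(dose)
        dlabel = f"{dose:g}"
        for tp in tps:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"gy{dlabel}_{tp}_r{r}", dose, tp, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "dose_gy", "timepoint", "replicate"]
    ).set_index("sample_id")


def simulate_experiment(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate one experiment: log2 matrix plus complete planted truth.

    Deterministic given ``config.seed``.  Non-planted genes have equal group
    means; planted genes have the group mean shifted by their true log2FC in
    the designated (dose, timepoint) groups only.  Gene variances are drawn
    from the scaled inverse chi-square prior; noise is Gaussian on the log2
    scale.  Noise rows are laid out gene-major from a single stream, so
    enlarging n_genes appends genes without reshuffling earlier ones.
    """
    config.validate()
    truth = _plant_effects(config)
    meta = _sample_table(config)
    n_samples = len(meta)

    d0, s0_sq = config.variance_prior
    sigma2 = d0 * s0_sq / np.random.default_rng([config.seed, 1]).chisquare(
        d0, size=config.n_genes
    )
    baseline = np.random.default_rng([config.seed, 2]).uniform(
        *config.baseline_range, size=config.n_genes
    )
    noise = np.random.default_rng([config.seed, 3]).standard_normal(
        (config.n_genes, n_samples)
    )
    values = baseline[:, None] + np.sqrt(sigma2)[:, None] * noise

    col_index = {s: j for j, s in enumerate(meta.index)}
    group_cols = {
        (d, t): [
            col_index[s]
            for s in meta[(meta["dose_gy"] == d) & (meta["timepoint"] == t)].index
        ]
        for d, t in {(d, t) for d, t in zip(meta["dose_gy"], meta["timepoint"])}
    }
    for (dose, tp), effects in truth.planted_de.items():
        cols = group_cols[(dose, tp)]
        genes = np.fromiter(effects.keys(), dtype=int)
        lfcs = np.fromiter(effects.values(), dtype=float)
        values[np.ix_(genes, cols)] += lfcs[:, None]

    frame = pd.DataFrame(
        values,
        index=pd.Index([probe_id(i) for i in range(config.n_genes)], name="probe_id"),
        columns=meta.index,
    )
    return ExpressionMatrix(frame, meta), truth


# ---- truth round-trip -------------------------------------------------------


def write_truth(truth: SimTruth, path) -> None:
    """Serialize planted truth to JSON (lossless round-trip)."""
    payload = {
        "planted_de": {
            f"{dose:g}|{tp}": {str(g): lfc for g, lfc in effects.items()}
            for (dose, tp), effects in truth.planted_de.items()
        },
        "marker_panel": list(truth.marker_panel),
        "sublethal_unique": list(truth.sublethal_unique),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    planted = {}
    for key, effects in payload["planted_de"].items():
        dose_s, _, tp = key.partition("|")
        planted[(float(dose_s), tp)] = {int(g): float(v) for g, v in effects.items()}
    return SimTruth(
        planted,
        tuple(payload["marker_panel"]),
        tuple(payload["sublethal_unique"]),
    )
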