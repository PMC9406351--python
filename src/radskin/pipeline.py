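"""End-to-end pipeline driver: normalize -> DE -> set dynamics -> dose call.

Every artifact is plain text (TSV/CSV/JSON) and carries provenance (config
hash, seed, package version); re-running with the same config reproduces
byte-identical outputs.  Stage failures abort with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .detest import DEThresholds, call_sdtgs, contrast_table_with_flags, moderated_t_contrast
from .dosimeter import DosimetryRules, classify_exposure, panel_score, sublethal_unique_screen
from .embedding import (
    expression_distances,
    hier_cluster,
    linkage_to_newick,
    sammon_map,
)
from .errors import RadskinError
from .io import (
    ExpressionMatrix,
    read_expression_tsv,
    timepoint_index,
    write_expression_tsv,
)
from .normalize import normalize_matrix
from .setdyn import (
    crosstab_report,
    direction_trajectory,
    partition_sets,
    stationarity_stats,
)
from .simulate import SimConfig, probe_id, simulate_experiment, study_preset, write_truth

log = logging.getLogger("radskin")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run (schema version 1)."""

    out_dir: str = "radskin_run"
    seed: int = 0
    # input: either simulate with the study preset / an explicit SimConfig,
    # or read matrix_tsv + meta_tsv
    simulate: bool = True
    matrix_tsv: str | None = None
    meta_tsv: str | None = None
    # stage parameter blocks
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    normalize: dict = field(
        default_factory=lambda: {"lowess": False, "span": 0.3, "k_sd": 4.0}
    )
    thresholds: dict = field(default_factory=dict)  # DEThresholds fields
    rules: dict = field(default_factory=dict)  # DosimetryRules fields
    embed: dict = field(
        default_factory=lambda: {"enabled": True, "top_n_variable": 500}
    )
    log_level: str = "INFO"
    schema_version: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log level excluded, so moving a run does not change its identity)."""
        payload = {
            k: v
            for k, v in self.to_dict().items()
            if k not in ("out_dir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(map(str, o))
    if isinstance(o, float) and o != o:
        return None
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def _sdtg_grid(matrix: ExpressionMatrix, thresholds: DEThresholds, de_dir: Path):
    """Run every (dose>0, TP) contrast; write CSVs; return sets and FC grid."""
    grid = {}
    fc_rows: dict = {}
    for dose, tp in matrix.groups():
        if dose == 0.0:
            continue
        result = moderated_t_contrast(matrix, dose, tp)
        if result.group_absent:
            continue
        table = contrast_table_with_flags(result, thresholds)
        table.to_csv(de_dir / f"de_gy{dose:g}_{tp}.csv", float_format="%.8g")
        grid[(dose, tp)] = call_sdtgs(result, thresholds)
        fc_rows[(dose, tp)] = table["fc"]
    fc_grid = pd.DataFrame(fc_rows)
    return grid, fc_grid


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage = "setup"
    try:
        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "radskin_version": __version__,
            "schema_version": config.schema_version,
        }
        _write_json(out / "run_config.json", {**config.to_dict(), "provenance": provenance})

        stage = "input"
        truth = None
        if config.simulate:
            sim_over = dict(config.sim)
            if set(sim_over) <= {"doses", "n_genes"}:
                cfg = study_preset(seed=config.seed, **sim_over)
            else:
                cfg = SimConfig(seed=config.seed, **sim_over)
            matrix, truth = simulate_experiment(cfg)
            write_truth(truth, out / "truth.json")
        else:
            if not (config.matrix_tsv and config.meta_tsv):
                from .errors import ConfigError

                raise ConfigError("matrix_tsv and meta_tsv required when simulate=False")
            matrix = read_expression_tsv(config.matrix_tsv, config.meta_tsv)
        log.info("input: %d probes x %d samples", matrix.n_probes, matrix.n_samples)

        stage = "normalize"
        normed, norm_report = normalize_matrix(
            matrix,
            span=config.normalize.get("span", 0.3),
            k_sd=config.normalize.get("k_sd", 4.0),
            lowess=config.normalize.get("lowess", False),
        )
        write_expression_tsv(normed, out / "normalized.tsv", out / "meta.tsv")
        _write_json(out / "norm_report.json", norm_report.to_dict())

        stage = "detest"
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        thresholds = DEThresholds(**config.thresholds)
        grid, fc_grid = _sdtg_grid(normed, thresholds, de_dir)

        stage = "setdyn"
        dyn_dir = out / "dynamics"
        dyn_dir.mkdir(exist_ok=True)
        doses = sorted({d for d, _ in grid})
        summaries = {}
        partitions = []
        dynamics_json: dict = {}
        for dose in doses:
            sets = [grid[(d, t)] for d, t in grid if d == dose]
            summary = direction_trajectory(sets)
            summaries[dose] = summary
            if len(sets) >= 2:
                part = partition_sets(
                    sorted(sets, key=lambda s: timepoint_index(s.timepoint)),
                    axis="across-TPs-within-dose",
                )
                partitions.append(part)
            dynamics_json[f"{dose:g}"] = {
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "percent_up": summary.percent_up,
                "peak_tp_up": summary.peak_tp_up,
                "stationarity_index": summary.stationarity_index,
                "unique_common_ratio": summary.unique_common_ratio,
            }
        if partitions:
            crosstab_report(partitions).to_csv(
                dyn_dir / "partitions_within_dose.csv", index=False
            )
        tp_partitions = []
        for tp in sorted({t for _, t in grid}, key=timepoint_index):
            sets = [grid[(d, t)] for d, t in grid if t == tp]
            if len(sets) >= 2:
                tp_partitions.append(partition_sets(sets, axis="across-doses-within-TP"))
        if tp_partitions:
            crosstab_report(tp_partitions).to_csv(
                dyn_dir / "partitions_within_timepoint.csv", index=False
            )
        _write_json(dyn_dir / "dynamics.json", dynamics_json)

        stage = "dosimeter"
        rules = DosimetryRules(**config.rules)
        calls = {}
        for dose in doses:
            report = classify_exposure(summaries[dose], rules=rules)
            calls[f"{dose:g}"] = report.to_dict()
        panel_block = None
        if truth is not None and truth.marker_panel:
            panel_ids = [probe_id(g) for g in truth.marker_panel]
            early_cols = [
                c for c in fc_grid.columns if timepoint_index(c[1]) < 3
            ]
            n_cons, verdicts = panel_score(fc_grid[early_cols], panel_ids, rules)
            screen = sublethal_unique_screen(grid, rules)
            panel_block = {
                "n_consistent": n_cons,
                "verdicts": verdicts,
                "sublethal_unique_screen": sorted(screen),
            }
        _write_json(out / "report.json", {"calls": calls, "panel": panel_block,
                                          "provenance": provenance})

        if config.embed.get("enabled", True):
            stage = "embed"
            dist = expression_distances(
                normed, top_n_variable=config.embed.get("top_n_variable", 500)
            )
            emb = sammon_map(dist, seed=config.seed)
            coords = pd.DataFrame(
                emb.coords, index=normed.sample_ids, columns=["sammon1", "sammon2"]
            )
            coords.insert(0, "timepoint", normed.meta["timepoint"].values)
            coords.insert(0, "dose_gy", normed.meta["dose_gy"].values)
            coords.to_csv(out / "embedding.tsv", sep="\t", float_format="%.8g")
            pd.DataFrame(
                {"stress": [emb.stress], "n_iter": [emb.n_iter], "converged": [emb.converged]}
            ).to_csv(out / "stress.csv", index=False, float_format="%.8g")
            pear = expression_distances(
                normed,
                metric="uncentered_pearson",
                top_n_variable=config.embed.get("top_n_variable", 500),
            )
            link = hier_cluster(pear)
            (out / "dendrogram.newick").write_text(
                linkage_to_newick(link, list(normed.sample_ids)) + "\n"
            )
        return out
    except RadskinError:
        log.error("pipeline failed in stage %r", stage)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise
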