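"""Run the end-to-end pipeline (simulate -> normalize -> DE -> dynamics ->
classification -> ordination) and read its report."""

import json
import tempfile
from pathlib import Path

from radskin import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        out_dir=str(Path(tmp) / "run"),
        seed=7,
        sim={"n_genes": 12_000},
        embed={"enabled": False},
    )
    out = run_pipeline(config)
    report = json.loads((out / "report.json").read_text())
    for dose, block in sorted(report["calls"].items(), key=lambda kv: float(kv[0])):
        ev = block["evidence"]
        print(
            f"{dose:>2s} Gy -> {block['call']:12s} "
            f"stationarity={ev['stationarity_index']:.3f} "
            f"peak={ev['peak_tp_up']}"
        )
    print(f"marker panel consistent: {report['panel']['n_consistent']}/5")
    print("artifacts:", sorted(p.name for p in out.iterdir()))
# Re-running with the same config and seed reproduces byte-identical outputs;
# the report carries the config hash and package version as provenance.
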