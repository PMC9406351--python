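import numpy as np
import pandas as pd
import pytest

from radskin.io import ExpressionMatrix


def two_group_matrix(
    n_genes: int = 200,
    n: int = 5,
    dose: float = 1.0,
    timepoint: str = "2h",
    shift=None,
    sigma: float = 0.25,
    seed: int = 0,
) -> ExpressionMatrix:
    """Exposed-vs-control matrix with an optional per-gene mean shift."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(6, 12, n_genes)
    vals = base[:, None] + sigma * rng.standard_normal((n_genes, 2 * n))
    if shift is not None:
        vals[: len(shift), :n] += np.asarray(shift)[:, None]
    cols = [f"e{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "dose_gy": [dose] * n + [0.0] * n,
            "timepoint": [timepoint] * 2 * n,
            "replicate": list(range(1, n + 1)) * 2,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    frame = pd.DataFrame(
        vals, index=pd.Index([f"g{i:04d}" for i in range(n_genes)], name="probe_id"),
        columns=cols,
    )
    return ExpressionMatrix(frame, meta)


@pytest.fixture(scope="session")
def small_experiment():
    """One full study-preset experiment at reduced gene count (shared)."""
    import radskin as rs

    cfg = rs.study_preset(n_genes=6000, seed=11)
    return rs.simulate_experiment(cfg)
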