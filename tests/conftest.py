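import numpy as np
import pandas as pd
import pytest

from mirax.containers import ExpressionMatrix


def make_expr(values, groups=None, patients=None, assay="mrna", scale="counts",
              features=None, samples=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"g{i}" for i in range(n_feat)]
    samples = samples or [f"s{i}" for i in range(n_samp)]
    groups = groups or ["tumor"] * n_samp
    patients = patients or [f"p{i}" for i in range(n_samp)]
    meta = pd.DataFrame(
        {"group": groups, "patient_id": patients, "cohort": "toy"},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples),
        meta, assay=assay, scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    from mirax.simulate import SimulationConfig, generate_cohort

    cfg = SimulationConfig(n_genes=600, n_mirnas=80, n_tumor=60, n_normal=30,
                           targets_per_mirna=8, decoys_per_mirna=8,
                           n_validation=80, seed=42)
    mrna, mirna, targets, surv, truth = generate_cohort(cfg)
    return dict(cfg=cfg, mrna=mrna, mirna=mirna, targets=targets, surv=surv, truth=truth)


def toy_survival(times, events, index=None, **clin):
    idx = index or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time_months": times, "event": events},
                      index=pd.Index(idx, name="sample_id"))
    for k, v in clin.items():
        df[k] = v
    return df
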