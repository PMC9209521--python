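"""Shared builders for synthetic feature tables used across test modules."""

import numpy as np
import pandas as pd

import exporf


def signal_domain_cohort(seed: int, n: int = 500):
    """Feature table where all outcome signal lives in the biological domain."""
    rng = np.random.default_rng(seed)
    domains = ["demographic", "lifestyle", "environmental", "biological"]
    cols, doms = [], []
    for d in domains:
        for j in range(5):
            cols.append(f"{d[:3]}{j}.AUE")
            doms.append(d)
    X = pd.DataFrame(
        rng.normal(size=(n, len(cols))),
        columns=cols,
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    logit = 1.6 * X["bio0.AUE"] + 1.6 * X["bio1.AUE"] - 1.2
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    meta = pd.DataFrame(
        {"feature_id": cols, "exposure_id": [c.split(".")[0] for c in cols],
         "kind": "AUE", "domain": doms}
    ).set_index("feature_id")
    table = exporf.SummaryFeatureTable(
        values=X, missing_mask=X.isna(), feature_meta=meta
    )
    return table, y
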