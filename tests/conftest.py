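import numpy as np
import pandas as pd
import pytest

import colonysig as cs


@pytest.fixture(scope="session")
def small_truth():
    return cs.make_truth(n_genes=400, n_role=30, n_effort=20, n_modules=2,
                         module_size=25, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    """28-nest colony simulation with counts for the sequenced subset."""
    designs = cs.generate_colonies(28, (3, 5), seed=11)
    meta = cs.generate_phenotypes(designs, small_truth, seed=12)
    meta = cs.sequenced_subset(meta, seed=13)
    seq = meta[meta["sequenced"]]
    counts = cs.generate_counts(seq, small_truth, seed=14)
    return counts, seq, small_truth


def split_metadata(n_repro=19, n_nonrep=64, seed=0):
    """Minimal metadata for the 19-vs-64 role contrast, efforts drawn from
    the queue effort model."""
    rng = np.random.default_rng(seed)
    ranks = np.concatenate([np.ones(n_repro, dtype=int),
                            rng.integers(2, 6, n_nonrep)])
    ids = [f"w{i:03d}" for i in range(n_repro + n_nonrep)]
    model = cs.EffortModel()
    t = model.intercept + model.slope * ranks + rng.normal(0, model.noise_sd, ranks.size)
    t[ranks == 1] = np.abs(rng.normal(0, model.rank1_sd, (ranks == 1).sum()))
    effort = np.sin(np.clip(t, 0, np.pi / 2)) ** 2
    return pd.DataFrame({
        "nest_id": "N01",
        "rank_pre": ranks,
        "rank_post": ranks,
        "role": np.where(ranks == 1, "reproductive", "non_reproductive"),
        "age_days": 30.0 - 3 * ranks,
        "foraging_effort": effort,
        "promoted": False,
        "eggs": np.where(ranks == 1, 12, 0),
        "inseminated": ranks == 1,
    }, index=pd.Index(ids, name="individual_id"))
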