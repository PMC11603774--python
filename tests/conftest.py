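import numpy as np
import pandas as pd
import pytest

from ntaflow import synth
from ntaflow.types import FeatureTable


def build_table(
    abundance: np.ndarray,
    mz=None,
    rt=None,
    ion_mode="positive",
    matrix="serum",
    batch=None,
    outcome=None,
    creatinine=None,
    adduct_link=None,
    feature_ids=None,
    sample_ids=None,
) -> FeatureTable:
    """Hand-rolled FeatureTable builder for small test matrices."""
    ab = np.asarray(abundance, dtype=float)
    n_feat, n_samp = ab.shape
    fids = feature_ids or [f"F{i + 1:03d}" for i in range(n_feat)]
    sids = sample_ids or [f"S{j + 1:03d}" for j in range(n_samp)]

    def broadcast(value, default, n):
        if value is None:
            value = default
        if value is None or np.isscalar(value) or isinstance(value, str):
            return [value] * n
        return list(value)

    feats = pd.DataFrame(
        {
            "mz": broadcast(mz, None, n_feat) if mz is not None else np.linspace(100, 500, n_feat),
            "rt": broadcast(rt, None, n_feat) if rt is not None else np.linspace(1, 20, n_feat),
            "ion_mode": broadcast(ion_mode, "positive", n_feat),
            "adduct_link": broadcast(adduct_link, None, n_feat),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "matrix": broadcast(matrix, "serum", n_samp),
            "batch": broadcast(batch, 1, n_samp),
            "outcome": broadcast(outcome, "term", n_samp),
            "creatinine": broadcast(creatinine, np.nan, n_samp),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    abundance_df = pd.DataFrame(ab, index=feats.index, columns=samples.index)
    return FeatureTable(feats, abundance_df, samples).validate()


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation, shared across the session (read-only)."""
    config = synth.SimConfig()
    manifest, pos, neg, spectra, library, truth = synth.simulate(config)
    return {
        "config": config,
        "manifest": manifest,
        "pos": pos,
        "neg": neg,
        "spectra": spectra,
        "library": library,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
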