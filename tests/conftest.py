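import numpy as np
import pandas as pd
import pytest

from diauxflux import synthetic_data as sd
from diauxflux.metabolomics_preprocess import PeakTable


@pytest.fixture(scope="session")
def toy_pair():
    """One seeded toy model pair shared by read-only tests."""
    return sd.make_toy_model_pair(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """Small two-batch peak table with one planted phase effect."""
    design = sd.SimDesign(n_strains=2, replicates_per_condition=4,
                          n_batches=2, n_features=40, missing_rate=0.0, seed=7)
    effects = [{"feature": "F0001", "log2fc": 1.0, "phase": "post"}]
    return sd.simulate_peak_table(design, effects=effects)


def make_peak_table(intensities: np.ndarray, classes=None, batches=None,
                    phases=None, strains=None, mz=None, rt=None, sn=None):
    """Hand-built PeakTable for unit fixtures."""
    n_feat, n_samp = intensities.shape
    fids = [f"F{i:03d}" for i in range(n_feat)]
    sids = [f"S{i:03d}" for i in range(n_samp)]
    fmeta = pd.DataFrame({
        "mz": mz if mz is not None else np.linspace(100, 200, n_feat),
        "rt": rt if rt is not None else np.linspace(1, 5, n_feat),
        "adduct": ["[M+H]+"] * n_feat,
        "identification": [f"cmpd{i}" for i in range(n_feat)],
    }, index=pd.Index(fids, name="feature_id"))
    if sn is not None:
        fmeta["sn"] = sn
    smeta = pd.DataFrame({
        "batch": batches if batches is not None else ["B1"] * n_samp,
        "injection_order": np.arange(1, n_samp + 1),
        "class": classes if classes is not None else ["sample"] * n_samp,
        "strain": strains if strains is not None else ["WT"] * n_samp,
        "phase": phases if phases is not None else ["pre"] * n_samp,
    }, index=pd.Index(sids, name="sample_id"))
    # injection order must be unique per batch
    for b, grp in smeta.groupby("batch"):
        smeta.loc[grp.index, "injection_order"] = np.arange(1, len(grp) + 1)
    X = pd.DataFrame(intensities, index=fmeta.index, columns=smeta.index)
    return PeakTable(X, fmeta, smeta)
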