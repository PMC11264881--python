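import numpy as np
import pandas as pd
import pytest

from neometab.io_model import FeatureTable, SpectrumMS2


def make_table(values, plates=None, orders=None, flags=None, feature_ids=None):
    """Small FeatureTable from a 2-D list/array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    fids = feature_ids or [f"F{j}" for j in range(m)]
    return FeatureTable(
        intensities=pd.DataFrame(arr, index=idx, columns=fids),
        plate=pd.Series(plates or ["p1"] * n, index=idx),
        injection_order=pd.Series(orders or list(range(1, n + 1)), index=idx),
        qc_flag=pd.Series(flags or ["analytical"] * n, index=idx),
    )


def make_spectrum(mz, intensity, precursor=100.0, sid="s"):
    return SpectrumMS2(sid, precursor, np.column_stack([mz, intensity]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by several tests (fixed seed)."""
    from neometab import synthetic_data as sd

    cfg = sd.SimConfig(n_pairs=80, n_features=40, n_plates=3, seed=42)
    records, truth = sd.generate_neonatal_cohort(cfg)
    table = sd.generate_feature_matrix(records, truth, cfg)
    return cfg, records, truth, table
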