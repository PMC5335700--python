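import numpy as np
import pandas as pd
import pytest

import structconn as sc
from structconn import features as feat


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Strong-signal synthetic connectome with ~1500 tested pairs."""
    return sc.generate_dataset(sc.classifier_benchmark_config(seed=0))


@pytest.fixture(scope="session")
def benchmark_features(benchmark_dataset):
    features, laminar = feat.build_feature_table(
        benchmark_dataset.areas, benchmark_dataset.projections
    )
    return features, laminar


@pytest.fixture(scope="session")
def benchmark_Xy(benchmark_features):
    features, _ = benchmark_features
    X = features[["abs_log_ratio_density", "distance"]].to_numpy(float)
    y = features["present"].to_numpy(bool)
    return X, y


@pytest.fixture(scope="session")
def full_dataset():
    """The 91-area / 29-injection emulation of the full study design."""
    return sc.generate_dataset(sc.default_config(seed=3))


@pytest.fixture
def tiny_tables():
    """Hand-written 4-area cortex with a fully known 3x3 injected block."""
    areas = pd.DataFrame(
        {
            "area_id": ["V1", "V2", "FEF", "TEO"],
            "density": [170000.0, 120000.0, 60000.0, np.nan],
            "thickness": [1.6, 1.8, 2.6, 2.2],
            "x": [0.0, 3.0, 0.0, 1.0],
            "y": [0.0, 4.0, 0.0, 2.0],
            "z": [0.0, 0.0, 3.0, 2.0],
            "injected": [True, True, True, False],
            "core": [False, False, True, False],
            "module": ["M1", "M1", "M2", ""],
        }
    )
    projections = pd.DataFrame(
        {
            "source": ["V1", "V2", "V1", "FEF", "V2", "FEF", "TEO", "TEO", "V1"],
            "target": ["V2", "V1", "FEF", "V1", "FEF", "V2", "V1", "V2", "TEO"],
            "status": ["present", "present", "absent", "present", "present",
                       "absent", "present", "absent", "unknown"],
            "n_total": [90, 25, 0, 20, 10, 0, 21, 0, 0],
            "n_supra": [80, 10, 0, 5, 4, 0, 7, 0, 0],
            "n_infra": [10, 15, 0, 15, 6, 0, 14, 0, 0],
        }
    )
    return areas, projections
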