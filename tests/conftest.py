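import numpy as np
import pandas as pd
import pytest

from bivlogit.simulate import CovariateSpec, SimulationConfig, simulate_dataset
from bivlogit.spatial import SpatialWeights, ZoneRates


@pytest.fixture
def table2_counts():
    """The 2x2 joint table of the two outcomes: (n11, n10, n01, n00)."""
    return 1308, 388, 907, 336


@pytest.fixture
def table2_records(table2_counts):
    """The 2x2 table expanded to one row per woman (unit weights)."""
    n11, n10, n01, n00 = table2_counts
    y1 = [1] * n11 + [1] * n10 + [0] * n01 + [0] * n00
    y2 = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    return pd.DataFrame({"y1": y1, "y2": y2, "weight": 1.0,
                         "cluster_id": 0, "zone_id": 0})


@pytest.fixture
def small_recovery_data():
    """20k-woman single-level dataset with one binary covariate."""
    cfg = SimulationConfig(
        n_zones=4, lattice_dims=(2, 2), clusters_per_zone=5,
        women_per_cluster=1000,
        beta1=np.array([-0.5, 0.8]), beta2=np.array([0.2, -0.4]),
        log_psi=float(np.log(2)),
        covariate_spec=[CovariateSpec("xvar", ["a", "b"], [0.5, 0.5])],
        seed=3)
    rec, zones, truth = simulate_dataset(cfg)
    return rec, truth


def rates_and_weights(y, a):
    """Package containers from a raw rate vector and adjacency matrix."""
    n = len(y)
    zr = ZoneRates(rates={i: float(y[i]) for i in range(n)},
                   denominators={i: 1.0 for i in range(n)})
    wb = SpatialWeights(zone_order=list(range(n)), w=np.asarray(a, float),
                        style="binary")
    rs = np.asarray(a, float)
    rsum = rs.sum(axis=1, keepdims=True)
    rs = np.divide(rs, rsum, out=np.zeros_like(rs), where=rsum > 0)
    wr = SpatialWeights(zone_order=list(range(n)), w=rs, style="row_standardized")
    return zr, wb, wr
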