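import numpy as np
import pandas as pd
import pytest

from pengrowth import load_table1
from pengrowth.growthcurves import MassSeries


@pytest.fixture(scope="session")
def table1():
    return load_table1()


def make_series(ages, masses, chick_id="c1", brood_id="b1", season=2001, fledged=False):
    return MassSeries(
        chick_id=chick_id,
        brood_id=brood_id,
        season=season,
        ages=np.asarray(ages, dtype=float),
        masses=np.asarray(masses, dtype=float),
        fledged=fledged,
    )


@pytest.fixture
def linear_series():
    ages = np.arange(20, 50, 3, dtype=float)
    return make_series(ages, 100.0 + 25.0 * ages)


@pytest.fixture(scope="session")
def paper_growth_data():
    """Paper-scale synthetic growth dataset with ground-truth types (seeded)."""
    from pengrowth import growthcurves, synthdata

    cfg = synthdata.paper_preset()
    meas, broods, truth = synthdata.gen_growth_curves(cfg, 2298, seed=20240901)
    series, report = growthcurves.validate_series(meas)
    params = growthcurves.params_table(series, broods)
    return {"measurements": meas, "broods": broods, "truth": truth,
            "series": series, "report": report, "params": params}


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated Gaussian blobs (centroids >= 6 sd apart)."""
    rng = np.random.default_rng(1)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 8.0]])
    X = np.vstack([rng.normal(c, 1.0, size=(100, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], 100)
    idx = [f"r{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx, columns=["PC1", "PC2"]), pd.Series(labels, index=idx)
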