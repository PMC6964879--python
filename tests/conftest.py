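import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import smokecast as sc

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return sc.ModelSpec()


@pytest.fixture(scope="session")
def small_panel():
    """Measured synthetic panel small enough for fast estimation tests."""
    _, measured, _ = sc.generate_panel(sc.SynthConfig(seed=42, n_states=16))
    return measured


@pytest.fixture(scope="session")
def full_panels():
    """Default-size (51 x 1992-2014) latent and measured panels."""
    latent, measured, report = sc.generate_panel(sc.SynthConfig(seed=7))
    return latent, measured, report


@pytest.fixture(scope="session")
def noiseless_panels():
    cfg = sc.noiseless(sc.SynthConfig(seed=5))
    latent, measured, report = sc.generate_panel(cfg)
    return latent, measured, report


def tiny_frame(n_states=3, n_years=4, start=2000, seed=0):
    """Hand-sized well-formed panel frame."""
    rng = np.random.default_rng(seed)
    rows = []
    regions = ["NE", "SE", "FW", "GL", "PL", "SW", "RM", "ME"]
    for i in range(n_states):
        for t in range(n_years):
            rows.append({
                "state": f"X{i}", "year": start + t, "region": regions[i % 8],
                "hexp": 4000 + 100 * t + 50 * i + rng.uniform(0, 10),
                "prev": 20.0 - t + i, "cons": 400.0 - 10 * t + 5 * i,
                "income": 30000.0 + 500 * t + 100 * i, "elderly": 12 + 0.1 * t,
                "black": 8 + 0.2 * i, "hispanic": 6 + 0.1 * i + 0.05 * t,
                "tax": 0.5 + 0.05 * t + 0.01 * i, "population": 1e6 * (i + 1),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel():
    return sc.StatePanel(tiny_frame())


def make_design(y, X, states, years, Z=None, endog=(), spec=None):
    """Assemble a DesignMatrix from plain arrays for unit tests."""
    idx = pd.MultiIndex.from_arrays([states, years], names=["state", "year"])
    Xf = pd.DataFrame(np.asarray(X, float), index=idx)
    Xf.columns = [f"x{j}" for j in range(Xf.shape[1])] if not isinstance(X, pd.DataFrame) else X.columns
    Zf = (pd.DataFrame(np.asarray(Z, float), index=idx) if Z is not None
          else pd.DataFrame(index=idx))
    if Z is not None and not isinstance(Z, pd.DataFrame):
        Zf.columns = [f"z{j}" for j in range(Zf.shape[1])]
    st = pd.Series(list(states), index=idx)
    return sc.DesignMatrix(
        y=pd.Series(np.asarray(y, float), index=idx, name="y"),
        X=Xf, Z=Zf, endog=list(endog), clusters=st, fe_groups=st.copy(),
        regions=pd.Series(["NE"] * len(st), index=idx),
        spec=spec or sc.ModelSpec(),
    )
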