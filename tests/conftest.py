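import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from fluxresp import PipelineConfig, SiteSeries, SyntheticSiteConfig, generate_site

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_site():
    """One full-size synthetic site (true optimum 25, default noise)."""
    return generate_site(SyntheticSiteConfig(seed=42))


@pytest.fixture(scope="session")
def small_site():
    """A lighter site for forest-based tests."""
    return generate_site(SyntheticSiteConfig(n_records=5000, seed=7))


def make_series(
    n: int = 48,
    er=None,
    er_qc=0,
    sm=None,
    gpp=None,
    isr=None,
    tair=None,
    vpd=None,
    site_id: str = "TEST",
    start: str = "2015-06-01",
) -> SiteSeries:
    """Hand-rolled SiteSeries for targeted unit tests."""
    def col(v, default):
        if v is None:
            return np.full(n, default, dtype=float)
        return np.asarray(v, dtype=float)

    data = pd.DataFrame(
        {
            "timestamp": pd.date_range(start, periods=n, freq="30min"),
            "er": col(er, 2.0),
            "er_qc": np.full(n, er_qc, dtype=float) if np.isscalar(er_qc) else np.asarray(er_qc, float),
            "sm": col(sm, 20.0),
            "gpp": col(gpp, 5.0),
            "isr": col(isr, 300.0),
            "tair": col(tair, 15.0),
            "vpd": col(vpd, 8.0),
        }
    )
    return SiteSeries(site_id=site_id, data=data)
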