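import numpy as np
import pandas as pd
import pytest

from larix import microclimate as mc
from larix import synth


@pytest.fixture(scope="session")
def transect():
    return {s.site_id: s for s in synth.default_transect()}


@pytest.fixture(scope="session")
def met_s1200(transect):
    """One year of hourly weather at the lower instrumented site (with a
    scripted mid-summer drought)."""
    return synth.gen_microclimate(transect["S1200"], 2013, seed=11)


@pytest.fixture(scope="session")
def met_s2000(transect):
    """One year at the subalpine site (no drought scripting)."""
    return synth.gen_microclimate(transect["S2000"], 2013, seed=11)


def _daily(met, spec):
    d = mc.aggregate_daily(met)
    d["pet"] = mc.compute_pet_fao56(d, spec.latitude_deg, spec.elevation_m)
    return d


@pytest.fixture(scope="session")
def daily_s1200(met_s1200, transect):
    return _daily(met_s1200, transect["S1200"])


@pytest.fixture(scope="session")
def daily_s2000(met_s2000, transect):
    return _daily(met_s2000, transect["S2000"])


@pytest.fixture(scope="session")
def monthly_station():
    """81 years of monthly T/P at the valley climate station elevation."""
    return synth.gen_monthly_climate(synth.SiteSpec("station", 1310.0),
                                     1930, 81, seed=99)


@pytest.fixture(scope="session")
def ring_ensemble(monthly_station):
    """Ring-width ensemble with a June-precipitation signal (beta = 0.6)."""
    series, truth = synth.gen_ringwidths(
        monthly_station, n_trees=10, seed=7, beta=0.6, rbar_target=0.5)
    return series, truth
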