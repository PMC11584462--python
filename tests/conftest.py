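"""Shared fixtures: small synthetic bundles generated at test time."""

import numpy as np
import pandas as pd
import pytest

import dendrogap as dg


def make_dendro(values, tree_id="T", start="2020-01-01", flags=None):
    """DendroSeries from a plain list (NaN = missing)."""
    idx = pd.date_range(start, periods=len(values), freq="30min")
    return dg.DendroSeries.from_arrays(tree_id, idx, values, flags)


def make_growth(g_values, tree_id="T", start="2020-01-01", twd=None):
    idx = pd.date_range(start, periods=len(g_values), freq="30min")
    twd = twd if twd is not None else np.zeros(len(g_values))
    return dg.GrowthSeries.from_arrays(tree_id, idx, g_values, twd)


@pytest.fixture(scope="session")
def one_year_params():
    return dg.SimParams(years=(2020,), noise_sd=2.0, seed=7)


@pytest.fixture(scope="session")
def one_year_bundle(one_year_params):
    """One simulated tree over a single year (dendro, truth, climate, meta)."""
    return dg.simulate_tree(one_year_params)


@pytest.fixture(scope="session")
def clean_growth(one_year_bundle):
    dendro, truth, climate, meta = one_year_bundle
    return dg.winter_correction(dg.zero_growth(dendro))
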