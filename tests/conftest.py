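"""Shared fixtures: small synthetic stacks, tables, and labeled data.

All fixtures are generated programmatically with fixed seeds; no data files
ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import predchar as pc


@pytest.fixture(scope="session")
def default_truth_stack():
    """Clean latent truth (k = 4/3/3) and its 36x36 stack."""
    truth = pc.synthetic.default_truth(seed=11, true_k=(4, 3, 3), noise_sd=0.05)
    stack = pc.synthetic.make_stack(truth, 36, 36)
    return truth, stack


@pytest.fixture(scope="session")
def study_bundle():
    """Physically named stack + occurrences (monthly columns) + DSr table."""
    truth = pc.synthetic.study_truth(seed=21)
    stack = pc.synthetic.make_stack(truth, 36, 36)
    occ = pc.synthetic.sample_occurrences(truth, stack, n=400, monthly_columns=True)
    ev = pc.synthetic.simulate_dsr(truth, occ.iloc[:250])
    ev = pd.concat([ev, occ.iloc[:250][stack.names()].reset_index(drop=True)], axis=1)
    return truth, stack, occ, ev


@pytest.fixture()
def tiny_spec():
    return pc.GridSpec(n_rows=10, n_cols=10, xll=0.0, yll=0.0, cell_size=1.0)


def make_population_table(
    iar_dm=None,
    iar_dm_f=None,
    ec=None,
    texture=None,
    elc=None,
    prefix="ID_",
):
    """Hand-built characterized population table for filtering tests."""
    n = max(len(x) for x in (iar_dm, iar_dm_f, ec, texture, elc) if x is not None)

    def col(x, default):
        return list(x) if x is not None else [default] * n

    return pd.DataFrame(
        {
            "pop_id": [f"{prefix}{i:04d}" for i in range(n)],
            "taxon": ["L. nigricans"] * n,
            "lon": np.linspace(0, 5, n),
            "lat": np.linspace(40, 42, n),
            "country": ["X"] * n,
            "iar_dm": col(iar_dm, 30.0),
            "iar_dm_f": col(iar_dm_f, 30.0),
            "topsoil_ec": col(ec, 0.5),
            "texture_class": col(texture, "Other"),
            "elc_category": pd.array(col(elc, 1), dtype="Int64"),
        }
    )
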