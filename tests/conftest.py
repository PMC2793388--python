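"""Shared fixtures: parameter sets, physiological rate contexts, and a
cached short Kowaltowski simulation used by several structural tests."""

import numpy as np
import pytest

from mitodyn.params import load_parameters
from mitodyn.rates import RateContext, FLUX_NAMES


@pytest.fixture(scope="session")
def pset():
    return load_parameters()


def make_context(pset, **overrides):
    """A representative energized physiological state for rate-law tests.

    Concentrations are molar; the defaults describe a polarized,
    substrate-replete matrix against a respiration-buffer exterior.
    """
    cx = {"PYR": 2e-4, "CoASH": 1.5e-3, "AcCoA": 5e-4, "CIT": 4e-4,
          "ISOC": 6e-5, "aKG": 3e-4, "SCoA": 2e-4, "SUC": 8e-4,
          "FUM": 3e-4, "MAL": 8e-4, "OAA": 5e-6, "GLU": 6e-3, "ASP": 5e-3,
          "NAD": 2e-3, "NADH": 2.5e-3, "GDP": 5e-3, "GTP": 2.5e-3,
          "ADP": 8e-3, "ATP": 6e-3, "AMP": 7e-4, "Pi": 3e-3,
          "UQ": 9e-4, "UQH2": 1.1e-3}
    ci = {"PYR": 1e-4, "CIT": 1e-5, "ISOC": 2e-6, "aKG": 5e-5, "SUC": 1e-4,
          "FUM": 5e-5, "MAL": 2e-3, "GLU": 5e-3, "ASP": 1e-4, "Pi": 2e-3,
          "ATP": 2e-4, "ADP": 1e-4, "AMP": 1e-5, "GLC": 1e-3, "G6P": 1e-5,
          "cox": 1.2e-4, "cred": 1.5e-5, "MgATP": 1e-4, "MgADP": 3e-5}
    ce = dict(ci)
    fx = {"H": 10 ** -7.5, "K": 0.12, "Na": 5e-3, "Mg": 4e-4, "Ca": 5e-7}
    fi = {"H": 10 ** -7.2, "K": 0.135, "Na": 5e-3, "Mg": 8e-4, "Ca": 6e-7}
    fe = dict(fi)
    ligfree_x = {"ATP": 6e-4, "ADP": 2e-3}
    ligfree_i = {"ATP": 2e-5, "ADP": 3e-5}
    tf = {r: 1.0 for r in FLUX_NAMES + ("TCC", "DCC")}
    kw = dict(cx=cx, ci=ci, ce=ce, fx=fx, fi=fi, fe=fe,
              ligfree_x=ligfree_x, ligfree_i=ligfree_i, poly_x={},
              dpsi=-170.0, V_mtx=0.8, T=25.0, tf=tf, p=pset)
    kw.update(overrides)
    return RateContext(**kw)


@pytest.fixture()
def ctx(pset):
    return make_context(pset)


@pytest.fixture(scope="session")
def kow_short():
    """A short Kowaltowski swelling trajectory shared by structural tests
    (base condition with ATP and oligomycin, four simulated minutes)."""
    from mitodyn.protocols import run_kowaltowski
    return run_kowaltowski(condition="atp_oligo", t_end=4.0, n_save=9)
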