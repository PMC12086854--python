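"""Shared fixtures: solved SCF states and response channels are expensive,
so they are computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from vcdkit.chemio import load_builtin_basis
from vcdkit.fixtures import make_fixture
from vcdkit.perturbations import (build_mfpt_channels, build_ndpt_channels,
                                  build_nvpt_channels)
from vcdkit.ao_response import solve_response
from vcdkit.mo_response import solve_sternheimer
from vcdkit.scf import run_scf


@pytest.fixture(scope="session")
def mini():
    return load_builtin_basis("mini")


@pytest.fixture(scope="session")
def h2o_scf(mini):
    return run_scf(make_fixture("h2o"), mini)


@pytest.fixture(scope="session")
def h2o2_scf(mini):
    return run_scf(make_fixture("h2o2_P"), mini)


def solve_all_theories(st, solver="both", tol=5e-12):
    """Solve NDPT, NVPT and MFPT channels; returns per-channel records with
    AO and (optionally) MO results."""
    ints = st.ints
    recs = {}

    def run(problems):
        for p in problems:
            rec = {"problem": p, "S1": p.S1}
            if solver in ("ao", "both"):
                ao = solve_response(p, st, tol=tol)
                rec["ao"] = ao
                rec["D1"] = ao.D1
            if solver in ("mo", "both"):
                mo = solve_sternheimer(p.H1, p.S1, st, p.flavor, tol=tol,
                                       coupling=p.coupling, channel=p.channel)
                rec["mo"] = mo
                if solver == "mo":
                    rec["D1"] = mo.D1_mo
            recs[p.channel] = rec

    run(build_ndpt_channels(st, ints).problems)
    d1R = {k: v["D1"] for k, v in recs.items()}
    run(build_nvpt_channels(st, ints, d1R).problems)
    run(build_mfpt_channels(st, ints).problems)
    return recs


@pytest.fixture(scope="session")
def h2o_channels(h2o_scf):
    return solve_all_theories(h2o_scf)


@pytest.fixture(scope="session")
def h2o2_channels(h2o2_scf):
    return solve_all_theories(h2o2_scf)


def split(recs, prefix):
    return {k: v["D1"] for k, v in recs.items() if k.startswith(prefix)}


def split_s1(recs, prefix):
    return {k: v["S1"] for k, v in recs.items() if k.startswith(prefix)}
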