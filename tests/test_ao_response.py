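"""AO-basis density-matrix response solver: Loewdin transforms, projectors,
occ-occ resolution, and the solver contract (residual, hermiticity class,
differentiated idempotency, electron-number conservation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from vcdkit.ao_response import (ResponseProblem, lowdin_transform,
                                occ_occ_block, project_redundant,
                                solve_response)

TOL = 5e-12


def _random_spd(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


@given(seed=hst.integers(0, 1000))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_lowdin_round_trip(seed):
    n = 5
    S = _random_spd(n, seed)
    M = np.random.default_rng(seed + 1).normal(size=(n, n))
    back = lowdin_transform(lowdin_transform(M, S, "covariant"), S, "inverse")
    assert np.max(np.abs(back - M)) < 1e-10


def test_lowdin_identity_and_overlap():
    S = _random_spd(4, 7)
    M = np.random.default_rng(3).normal(size=(4, 4))
    assert np.allclose(lowdin_transform(M, np.eye(4), "covariant"), M)
    assert np.allclose(lowdin_transform(S, S, "covariant"), np.eye(4),
                       atol=1e-12)


def test_sqrt_property():
    S = _random_spd(6, 11)
    w, V = np.linalg.eigh(S)
    Sp = V @ np.diag(np.sqrt(w)) @ V.T
    assert np.max(np.abs(Sp @ Sp - S)) < 1e-10


def test_lowdin_rejects_non_pd():
    with pytest.raises(ValueError):
        lowdin_transform(np.eye(2), np.diag([1.0, -1.0]), "covariant")


def test_projector_annihilates_occ_occ(h2o_scf):
    st = h2o_scf
    out = project_redundant(st.D0, st.D0, st.S0)
    assert np.max(np.abs(out)) < 1e-10


@given(seed=hst.integers(0, 1000))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_projector_idempotent(seed):
    n = 6
    S = np.eye(n)
    rng = np.random.default_rng(seed)
    C = np.linalg.qr(rng.normal(size=(n, n)))[0][:, :2]
    D = C @ C.T
    A = rng.normal(size=(n, n))
    P1 = project_redundant(A, D, S)
    P2 = project_redundant(P1, D, S)
    assert np.max(np.abs(P1 - P2)) < 1e-12


def test_projector_hand_case():
    """S = I, D = diag(1, 0): diagonal entries zeroed, off-diagonal kept."""
    D = np.diag([1.0, 0.0])
    A = np.array([[1.0, 2.0], [3.0, 4.0]])
    out = project_redundant(A, D, np.eye(2))
    assert np.allclose(out, [[0.0, 2.0], [3.0, 0.0]])


def test_occ_occ_block(h2o_scf, h2o_channels):
    st = h2o_scf
    assert np.max(np.abs(occ_occ_block(st.D0, np.zeros_like(st.S0)))) == 0.0
    rec = h2o_channels["V[1,x]"]
    S1 = rec["S1"]
    assert np.allclose(occ_occ_block(st.D0, S1), -st.D0 @ S1 @ st.D0)


def test_zero_perturbation_gives_zero(h2o_scf):
    n = len(h2o_scf.S0)
    p = ResponseProblem("real_symmetric", np.zeros((n, n)), np.zeros((n, n)),
                        channel="null")
    resp = solve_response(p, h2o_scf)
    assert np.max(np.abs(resp.D1)) < 1e-12
    assert np.max(np.abs(resp.X1)) < 1e-12


def test_flavor_mismatch_rejected(h2o_scf):
    n = len(h2o_scf.S0)
    M = np.triu(np.ones((n, n)))
    with pytest.raises(ValueError):
        ResponseProblem("real_symmetric", M, np.zeros((n, n)))
    with pytest.raises(ValueError):
        ResponseProblem("imag_antihermitian", np.eye(n), np.zeros((n, n)))


def test_solver_contract_all_channels(h2o_scf, h2o_channels):
    """Residual <= 5e-12, hermiticity class by flavor, differentiated
    idempotency and d/dx tr(DS) = 0 within 10x tolerance on every channel."""
    st = h2o_scf
    D0, S0 = st.D0, st.S0
    for label, rec in h2o_channels.items():
        ao = rec["ao"]
        S1 = rec["S1"]
        assert ao.residual_norm <= TOL, label
        D1 = ao.D1
        if rec["problem"].flavor == "real_symmetric":
            assert np.max(np.abs(D1 - D1.T)) < 10 * TOL, label
        else:
            assert np.max(np.abs(D1 + D1.T)) < 10 * TOL, label
        idem = D1 @ S0 @ D0 + D0 @ S1 @ D0 + D0 @ S0 @ D1 - D1
        assert np.max(np.abs(idem)) < 10 * TOL, label
        assert abs(np.trace(D1 @ S0) + np.trace(D0 @ S1)) < 10 * TOL, label


def test_electric_field_like_channel_pure_ov(h2o_scf):
    """S1 = 0 channel: the occ-occ block vanishes and D1 is the projected
    occ-virt response (prior-art limit)."""
    st = h2o_scf
    p = ResponseProblem("real_symmetric", st.ints.Dip[2],
                        np.zeros_like(st.S0), coupling="full", channel="E_z")
    resp = solve_response(p, st)
    assert np.max(np.abs(resp.D1_oo)) < 1e-14
    oo = st.D0 @ st.S0 @ resp.D1 @ st.S0 @ st.D0
    vv = ((np.eye(len(st.S0)) - st.D0 @ st.S0) @ resp.D1
          @ (np.eye(len(st.S0)) - st.S0 @ st.D0))
    assert np.max(np.abs(oo)) < 1e-9
    assert np.max(np.abs(vv)) < 1e-9


def test_stagnation_raises_with_history(h2o_scf):
    n = len(h2o_scf.S0)
    p = ResponseProblem("real_symmetric", h2o_scf.ints.Dip[0],
                        np.zeros((n, n)), coupling="full", channel="tight")
    with pytest.raises(RuntimeError):
        solve_response(p, h2o_scf, tol=1e-30, max_iter=2000)
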