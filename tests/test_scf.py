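"""Restricted Hartree-Fock ground state against an independent minimal
implementation and the density validity conditions."""

import numpy as np
import pytest
from scipy.special import erf

from vcdkit.chemio import BasisSet, GaussianShell, load_builtin_basis, \
    make_molecule
from vcdkit.fixtures import make_fixture
from vcdkit.integrals import compute_core_integrals
from vcdkit.scf import SCFConfig, build_fock, nuclear_gradient, run_scf


def _independent_h2_rhf(R=1.4):
    """Textbook closed-form s-primitive RHF for H2/minimal basis, written
    only from the classic s-Gaussian integral formulas (no shared code with
    the production engine)."""
    exps = np.array([3.42525091, 0.62391373, 0.16885540])
    coefs = np.array([0.15432897, 0.53532814, 0.44463454])
    norms = (2 * exps / np.pi) ** 0.75
    c = coefs * norms
    centers = [np.array([0, 0, 0.0]), np.array([0, 0, R])]

    def F0(t):
        t = max(t, 1e-14)
        return 0.5 * np.sqrt(np.pi / t) * erf(np.sqrt(t))

    def s_ab(a, b, A, B):
        p = a + b
        return (np.pi / p) ** 1.5 * np.exp(-a * b / p * np.sum((A - B) ** 2))

    def t_ab(a, b, A, B):
        p = a + b
        mu = a * b / p
        ab2 = np.sum((A - B) ** 2)
        return mu * (3 - 2 * mu * ab2) * s_ab(a, b, A, B)

    def v_ab(a, b, A, B, C):
        p = a + b
        P = (a * A + b * B) / p
        return (-2 * np.pi / p * np.exp(-a * b / p * np.sum((A - B) ** 2))
                * F0(p * np.sum((P - C) ** 2)))

    def eri_p(a, b, c2, d, A, B, C, D):
        p, q = a + b, c2 + d
        P = (a * A + b * B) / p
        Q = (c2 * C + d * D) / q
        return (2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                * np.exp(-a * b / p * np.sum((A - B) ** 2))
                * np.exp(-c2 * d / q * np.sum((C - D) ** 2))
                * F0(p * q / (p + q) * np.sum((P - Q) ** 2)))

    n = 2
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for a, ca in zip(exps, c):
                for b, cb in zip(exps, c):
                    S[i, j] += ca * cb * s_ab(a, b, centers[i], centers[j])
                    T[i, j] += ca * cb * t_ab(a, b, centers[i], centers[j])
                    for C in centers:
                        V[i, j] += ca * cb * v_ab(a, b, centers[i],
                                                  centers[j], C)
    ERI = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    for a, ca in zip(exps, c):
                        for b, cb in zip(exps, c):
                            for c3, cc in zip(exps, c):
                                for d, cd in zip(exps, c):
                                    ERI[i, j, k, l] += (
                                        ca * cb * cc * cd
                                        * eri_p(a, b, c3, d, centers[i],
                                                centers[j], centers[k],
                                                centers[l]))
    h = T + V
    w, U = np.linalg.eigh(S)
    X = U @ np.diag(w ** -0.5) @ U.T
    D = np.zeros((n, n))
    E = 0.0
    for _ in range(100):
        J = np.einsum("mnks,ks->mn", ERI, D)
        K = np.einsum("mksn,ks->mn", ERI, D)
        F = h + 2 * J - K
        e, Cm = np.linalg.eigh(X @ F @ X)
        C = X @ Cm
        D = np.outer(C[:, 0], C[:, 0])
        E_new = np.einsum("mn,mn->", D, h + F) + 1.0 / R
        if abs(E_new - E) < 1e-12:
            break
        E = E_new
    return E_new


def test_h2_energy_vs_independent_oracle():
    mol = make_molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4]])
    st = run_scf(mol, load_builtin_basis("mini"))
    assert abs(st.E_total - _independent_h2_rhf(1.4)) < 1e-8


def test_density_validity_conditions(h2o_scf):
    """D^T = D, D S D = D, tr(DS) = n_occ, [F, DS] = 0 at convergence."""
    st = h2o_scf
    D, S, F = st.D0, st.S0, st.H0
    assert np.max(np.abs(D - D.T)) < 1e-12
    assert np.max(np.abs(D @ S @ D - D)) < 1e-10
    assert abs(np.trace(D @ S) - 5.0) < 1e-10   # 5 for H2O, spinless
    assert np.max(np.abs(F @ D @ S - S @ D @ F)) < 1e-8


def test_fock_from_zero_density_is_core(h2o_scf):
    ints = h2o_scf.ints
    F = build_fock(ints, np.zeros_like(h2o_scf.D0))
    assert np.max(np.abs(F - ints.hcore)) < 1e-14


def test_fock_symmetric(h2o_scf):
    F = build_fock(h2o_scf.ints, h2o_scf.D0)
    assert np.max(np.abs(F - F.T)) < 1e-12


def test_translation_invariance_of_energy(mini):
    mol = make_fixture("h2o")
    st1 = run_scf(mol, mini)
    st2 = run_scf(mol.with_positions(mol.positions + np.array([1.3, -0.7, 2.1])),
                  mini)
    assert abs(st1.E_total - st2.E_total) < 1e-10


def test_analytic_gradient_vs_fd(mini):
    mol = make_fixture("h2o")
    st = run_scf(mol, mini)
    g = nuclear_gradient(st)
    h = 1e-4
    for lam, beta in [(0, 2), (1, 0)]:
        pp, pm = mol.positions.copy(), mol.positions.copy()
        pp[lam, beta] += h
        pm[lam, beta] -= h
        fd = (run_scf(mol.with_positions(pp), mini).E_total
              - run_scf(mol.with_positions(pm), mini).E_total) / (2 * h)
        assert abs(g[lam, beta] - fd) < 1e-7
    assert np.max(np.abs(g.sum(axis=0))) < 1e-10  # translational invariance


def test_odd_electron_count_rejected(mini):
    oh = make_molecule(["O", "H"], [[0, 0, 0], [0, 0, 1.8]])
    with pytest.raises(ValueError):
        run_scf(oh, mini)


def test_nonconvergence_reports_trace(mini):
    mol = make_fixture("h2o")
    with pytest.raises(RuntimeError, match="it"):
        run_scf(mol, mini, SCFConfig(max_iter=2))
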