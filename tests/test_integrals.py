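"""Gaussian integral engine: zeroth-order matrices against independent
quadrature/closed-form oracles, and first-order (perturbed) integrals
against geometric and complex-phase finite differences."""

import numpy as np
import pytest
from scipy.special import erf

from vcdkit.chemio import (BasisSet, GaussianShell, load_builtin_basis,
                           make_molecule)
from vcdkit.fixtures import make_fixture
from vcdkit.integrals import (AOBasis, compute_core_integrals,
                              giao_first_order, nuclear_derivative_integrals,
                              vao_first_order)
from vcdkit import refint


@pytest.fixture(scope="module")
def h2o_ints():
    mol = make_fixture("h2o")
    return compute_core_integrals(mol, load_builtin_basis("mini"))


def test_ao_self_overlap_unit(h2o_ints):
    """Every contracted Cartesian AO is unit-normalized."""
    assert np.max(np.abs(np.diag(h2o_ints.S0) - 1.0)) < 1e-12


def test_ao_self_overlap_unit_polarized():
    ints = compute_core_integrals(make_fixture("h2o"), load_builtin_basis("pol"))
    assert np.max(np.abs(np.diag(ints.S0) - 1.0)) < 1e-12


def test_two_center_overlap_vs_quadrature():
    """<s(A)|s(B)> for two unit primitives vs dense 3-D quadrature."""
    basis = BasisSet({"H": [GaussianShell(-1, 0, [1.0], [1.0])]})
    mol = make_molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
    ints = compute_core_integrals(mol, basis)
    x, w = np.polynomial.legendre.leggauss(90)
    x = x * 7.0
    w = w * 7.0
    norm = (2.0 / np.pi) ** 0.75
    gz1 = norm ** (1 / 3) * np.exp(-x ** 2)        # 1D factors
    gz2 = norm ** (1 / 3) * np.exp(-(x - 1.0) ** 2)
    gperp = norm ** (1 / 3) * np.exp(-x ** 2)
    s_quad = (w @ (gperp * gperp)) ** 2 * (w @ (gz1 * gz2))
    assert abs(ints.S0[0, 1] - s_quad) < 1e-8


def test_core_matrix_symmetries(h2o_ints):
    ints = h2o_ints
    for M in (ints.S0, ints.T, ints.Vne, *ints.Dip):
        assert np.max(np.abs(M - M.T)) < 1e-12
    for M in (*ints.Nabla, *ints.AngMom):
        assert np.max(np.abs(M + M.T)) < 1e-12
        assert np.max(np.abs(np.diag(M))) < 1e-12
    assert np.linalg.eigvalsh(ints.S0)[0] > 1e-9


def test_eri_permutation_symmetry(h2o_ints):
    E = h2o_ints.ERI
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        assert np.max(np.abs(E - E.transpose(perm))) < 1e-12


def test_linear_dependence_detected():
    sh = GaussianShell(-1, 0, [0.5], [1.0])
    basis = BasisSet({"H": [sh, GaussianShell(-1, 0, [0.5 + 1e-13], [1.0])]})
    mol = make_molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4]])
    with pytest.raises(ValueError, match="linear"):
        compute_core_integrals(mol, basis)


def test_coulomb_energy_closed_form():
    """ERI contraction with an s-density vs the erf closed form for the
    Coulomb energy of spherical Gaussian charge distributions."""
    a1, a2 = 0.8, 1.3
    R = 1.7
    basis = BasisSet({"H": [GaussianShell(-1, 0, [a1], [1.0])],
                      "He": [GaussianShell(-1, 0, [a2], [1.0])]})
    mol = make_molecule(["H", "He"], [[0, 0, 0], [0, 0, R]], charge=1)
    ints = compute_core_integrals(mol, basis)
    # (11|22): Coulomb energy of two unit s-Gaussian densities (2a1), (2a2)
    p1, p2 = 2 * a1, 2 * a2
    mu = p1 * p2 / (p1 + p2)
    ref = erf(np.sqrt(mu) * R) / R
    assert abs(ints.ERI[0, 0, 1, 1] - ref) < 1e-10


def test_nuclear_derivative_vs_fd():
    """Analytic dS/dR, dT/dR, dVne/dR against central differences (1e-5)."""
    mol = make_fixture("h2o")
    basis = load_builtin_basis("mini")
    ints = compute_core_integrals(mol, basis)
    h = 1e-5
    for lam, beta in [(0, 2), (1, 0)]:
        per = nuclear_derivative_integrals(ints, lam, beta)
        pp, pm = mol.positions.copy(), mol.positions.copy()
        pp[lam, beta] += h
        pm[lam, beta] -= h
        ip = compute_core_integrals(mol.with_positions(pp), basis)
        im = compute_core_integrals(mol.with_positions(pm), basis)
        for anal, attr in [(per.S1, "S0"), (per.pieces["dT"], "T"),
                           (per.pieces["dVne"], "Vne")]:
            fd = (getattr(ip, attr) - getattr(im, attr)) / (2 * h)
            assert np.max(np.abs(anal - fd)) < 1e-7


def test_nuclear_derivative_translational_sum(h2o_ints):
    """Rigid translation: sum_lam dS/dR_lam = 0."""
    tot = sum(nuclear_derivative_integrals(h2o_ints, lam, 2).S1
              for lam in range(3))
    assert np.max(np.abs(tot)) < 1e-12


def test_nuclear_derivative_two_center_antisymmetry():
    """s-shell diatomic: dS/dz of atom 1 = -dS/dz of atom 2."""
    basis = BasisSet({"H": [GaussianShell(-1, 0, [0.7], [1.0])]})
    mol = make_molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4]])
    ints = compute_core_integrals(mol, basis)
    d1 = nuclear_derivative_integrals(ints, 0, 2).S1
    d2 = nuclear_derivative_integrals(ints, 1, 2).S1
    assert np.max(np.abs(d1 + d2)) < 1e-12


def test_vao_s1_single_center_parity():
    """All functions on one center with O_sp at that center: S1(V) = 0 for
    s functions (odd integrand)."""
    basis = load_builtin_basis("mini")
    he = make_molecule(["He"], [[0.0, 0.0, 0.0]])
    ints = compute_core_integrals(he, basis)
    per = vao_first_order(ints, 0, 2)
    assert np.max(np.abs(per.S1)) < 1e-12


def test_vao_s1_antisymmetry(h2o_ints):
    per = vao_first_order(h2o_ints, 1, 0)
    assert np.max(np.abs(per.S1 + per.S1.T)) < 1e-14


def test_vao_first_order_vs_complex_fd(h2o_ints):
    """Analytic VAO S1 and one-electron H1 against finite differences of
    complex-phased (velocity-gauge) integrals at Rdot = 1e-5."""
    ints = h2o_ints
    eng = ints.engine
    mol = eng.mol
    eps, lam, beta = 1e-5, 1, 0
    per = vao_first_order(ints, lam, beta)
    n = eng.n_ao
    aop = refint.vao_aos(eng, +eps, lam, beta, ints.gauge.O_sp)
    aom = refint.vao_aos(eng, -eps, lam, beta, ints.gauge.O_sp)
    S1 = np.zeros((n, n), complex)
    H1 = np.zeros((n, n), complex)
    for i in range(n):
        for j in range(n):
            S1[i, j] = (refint.overlap(aop[i], aop[j])
                        - refint.overlap(aom[i], aom[j]))
            H1[i, j] = (refint.kinetic(aop[i], aop[j])
                        + refint.nuclear(aop[i], aop[j], mol)
                        - refint.kinetic(aom[i], aom[j])
                        - refint.nuclear(aom[i], aom[j], mol))
    S1 /= 2j * eps
    H1 /= 2j * eps
    assert np.max(np.abs(per.S1 - S1.real)) < 1e-7
    assert np.max(np.abs(per.pieces["h1_vao_1el"] - H1.real)) < 1e-7


def test_giao_single_center_s1_zero():
    basis = load_builtin_basis("mini")
    he = make_molecule(["He"], [[0.3, -0.1, 0.8]])
    ints = compute_core_integrals(he, basis)
    for per in giao_first_order(ints):
        assert np.max(np.abs(per.S1)) < 1e-14


def test_giao_s1_omag_invariance(h2o_ints):
    """S1(B) depends only on center differences: shifting O_mag by
    (10,0,0) bohr leaves it unchanged."""
    from vcdkit.chemio import GaugeConfig

    mol = make_fixture("h2o")
    basis = load_builtin_basis("mini")
    ints2 = compute_core_integrals(mol, basis, GaugeConfig(O_mag=(10, 0, 0)))
    p1 = giao_first_order(h2o_ints)
    p2 = giao_first_order(ints2)
    for a in range(3):
        assert np.max(np.abs(p1[a].S1 - p2[a].S1)) == 0.0
        assert np.max(np.abs(p1[a].pieces["h1_1el"]
                             - p2[a].pieces["h1_1el"])) == 0.0


def test_giao_s1_vs_complex_fd(h2o_ints):
    """GIAO overlap derivative vs complex-phase FD at |B| = 1e-6."""
    eng = h2o_ints.engine
    n = eng.n_ao
    pers = giao_first_order(h2o_ints)
    Bmag = 1e-6
    for alpha in (0, 2):
        B = np.zeros(3)
        B[alpha] = Bmag
        gp = refint.giao_aos(eng, +B, (0, 0, 0))
        gm = refint.giao_aos(eng, -B, (0, 0, 0))
        fd = np.array([[refint.overlap(gp[i], gp[j])
                        - refint.overlap(gm[i], gm[j]) for j in range(n)]
                       for i in range(n)]) / (2j * Bmag)
        assert np.max(np.abs(pers[alpha].S1 - fd.real)) < 1e-7


def test_eri_raised_index_consistency():
    """Moment-weighted ERIs from the raised-AO tensor agree with the
    reference complex-center evaluator's plain real ERIs."""
    basis = load_builtin_basis("mini")
    mol = make_molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4]])
    eng = AOBasis(mol, basis)
    TR = eng.eri_raised(2)
    aos = refint.plain_aos(eng)
    # raised AO 0: (r_z - A0z) chi_0
    raised = []
    for p in aos[0]:
        l = list(p.l)
        l[2] += 1
        raised.append(refint.Prim(p.a, p.c, p.A, l))
    ref = refint.eri(raised, aos[1], aos[0], aos[1])
    assert abs(TR[0, 1, 0, 1] - ref.real) < 1e-10
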