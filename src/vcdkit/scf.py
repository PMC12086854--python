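"""Restricted Hartree-Fock ground state: the unperturbed reference.

Spinless density convention: D = sum_occ C C^T with occupations f_j = 1, so
the idempotency condition reads D S D = D literally. Factors of two appear in
the Coulomb build and in expectation values of one-electron operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import BasisSet, GaugeConfig, Molecule
from .integrals import IntegralSet, compute_core_integrals, nuclear_derivative_integrals


@dataclass
class SCFConfig:
    max_iter: int = 200
    conv_tol: float = 1e-10        # max-abs commutator FDS - SDF
    energy_tol: float = 1e-10
    diis_depth: int = 8


@dataclass
class SCFState:
    C0: np.ndarray           # all MO coefficients (n_ao x n_mo)
    eps: np.ndarray          # orbital energies
    n_occ: int
    D0: np.ndarray           # spinless density, tr(D0 S0) = n_occ
    H0: np.ndarray           # converged Fock matrix
    E_total: float
    S0: np.ndarray
    ints: IntegralSet = field(repr=False)
    mol: Molecule = field(repr=False)
    history: list = field(default_factory=list, repr=False)

    @property
    def f(self) -> np.ndarray:
        """Occupation numbers in the spinless convention."""
        occ = np.zeros(self.C0.shape[1])
        occ[: self.n_occ] = 1.0
        return occ

    @property
    def C_occ(self) -> np.ndarray:
        return self.C0[:, : self.n_occ]

    @property
    def eps_occ(self) -> np.ndarray:
        return self.eps[: self.n_occ]

    def electric_dipole(self, origin=None) -> np.ndarray:
        """Total SCF electric dipole (length form), a.u."""
        from .chemio import nuclear_dipole

        origin = self.ints.gauge.O_sp if origin is None else origin
        elec = -2.0 * np.einsum("mn,xmn->x", self.D0, self.ints.Dip)
        return elec + nuclear_dipole(self.mol, origin)


def coulomb(ERI: np.ndarray, D: np.ndarray) -> np.ndarray:
    """J(D)_mn = sum_ks (mn|ks) D_ks."""
    return np.einsum("mnks,ks->mn", ERI, D)


def exchange(ERI: np.ndarray, D: np.ndarray) -> np.ndarray:
    """K(D)_mn = sum_ks (mk|sn) D_ks (valid for Hermitian D stored by its
    real symmetric or real antisymmetric factor)."""
    return np.einsum("mksn,ks->mn", ERI, D)


def g_matrix(ERI: np.ndarray, D: np.ndarray, mode: str = "full") -> np.ndarray:
    """Two-electron response operator G(D) in the spinless convention.

    mode 'full': 2J - K (real symmetric densities); 'exchange': -K only
    (exact G for imaginary antihermitian densities, whose Coulomb response
    vanishes identically); 'none': zero.
    """
    if mode == "none":
        return np.zeros_like(D)
    if mode == "exchange":
        return -exchange(ERI, D)
    return 2.0 * coulomb(ERI, D) - exchange(ERI, D)


def build_fock(ints: IntegralSet, D: np.ndarray) -> np.ndarray:
    """F = h + 2 J(D) - K(D)."""
    return ints.hcore + g_matrix(ints.ERI, D)


def electronic_energy(ints: IntegralSet, D: np.ndarray, F: np.ndarray) -> float:
    """tr(D (h + F)) in the spinless convention."""
    return float(np.einsum("mn,mn->", D, ints.hcore + F))


def _density_from_fock(F, X):
    """Diagonalize F in the Loewdin-orthonormal basis X = S^{-1/2}."""
    Ft = X @ F @ X
    eps, Ct = np.linalg.eigh(Ft)
    C = X @ Ct
    return eps, C


def run_scf(mol: Molecule, basis: BasisSet, config: SCFConfig | None = None,
            gauge: GaugeConfig | None = None,
            ints: IntegralSet | None = None) -> SCFState:
    """Converge the Roothaan-Hall equations with commutator DIIS.

    At convergence the density satisfies D^T = D, D S D = D, tr(D S) = n_occ
    and F D S - S D F = 0 (to config.conv_tol)."""
    mol.require_closed_shell()
    config = config or SCFConfig()
    if ints is None:
        ints = compute_core_integrals(mol, basis, gauge)
    n_occ = mol.n_electrons // 2
    S = ints.S0
    w, V = np.linalg.eigh(S)
    X = V @ np.diag(w ** -0.5) @ V.T

    eps, C = _density_from_fock(ints.hcore, X)   # core guess
    D = C[:, :n_occ] @ C[:, :n_occ].T
    E_old = 0.0
    errs: list[np.ndarray] = []
    focks: list[np.ndarray] = []
    history = []
    Vnn = mol.nuclear_repulsion()
    for it in range(config.max_iter):
        F = build_fock(ints, D)
        err = F @ D @ S - S @ D @ F
        res = float(np.max(np.abs(err)))
        E = electronic_energy(ints, D, F) + Vnn
        history.append((it, E, res))
        if res < config.conv_tol and abs(E - E_old) < config.energy_tol and it > 0:
            eps, C = _density_from_fock(F, X)
            D = C[:, :n_occ] @ C[:, :n_occ].T
            F = build_fock(ints, D)
            E = electronic_energy(ints, D, F) + Vnn
            state = SCFState(C, eps, n_occ, D, F, E, S, ints, mol, history)
            _assert_valid_density(state, config.conv_tol)
            return state
        E_old = E
        # DIIS on the orthonormal-basis residual
        errs.append(X @ err @ X)
        focks.append(F)
        if len(errs) > config.diis_depth:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.vdot(errs[i], errs[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                F = sum(c * f for c, f in zip(coef, focks))
            except np.linalg.LinAlgError:
                pass
        eps, C = _density_from_fock(F, X)
        D = C[:, :n_occ] @ C[:, :n_occ].T
    raise RuntimeError(
        "SCF failed to converge in "
        f"{config.max_iter} iterations; trace: "
        + "; ".join(f"it {i}: E={e:.10f}, res={r:.2e}" for i, e, r in history[-5:]))


def _assert_valid_density(st: SCFState, tol: float):
    D, S = st.D0, st.S0
    checks = {
        "symmetry": np.max(np.abs(D - D.T)),
        "idempotency": np.max(np.abs(D @ S @ D - D)),
        "trace": abs(np.trace(D @ S) - st.n_occ),
        "stationarity": np.max(np.abs(st.H0 @ D @ S - S @ D @ st.H0)),
    }
    for name, val in checks.items():
        if val > 100 * max(tol, 1e-12):
            raise AssertionError(
                f"converged density violates {name}: {val:.3e}")


# ----------------------------------------------------------------------------
# analytic nuclear gradient
# ----------------------------------------------------------------------------


def g1_matrix(ints: IntegralSet, lam: int, beta: int, D: np.ndarray,
              mode: str = "full") -> np.ndarray:
    """Derivative two-electron matrix G^(1)(D) for displacing atom ``lam``
    along ``beta``: contraction of derivative ERIs (all four indices) with a
    fixed symmetric density D.

    G1_mn = sum_ks D_ks [2 d(mn|ks) - d(mk|ns)].
    """
    eng = ints.engine
    Td = eng.eri_dcenter(beta)           # (d a / dA_b, b | c, d)
    sel = eng.ao_on_atom(lam).astype(float)
    if mode == "none":
        return np.zeros_like(D)
    # Coulomb: four derivative positions
    if mode != "exchange":
        P1 = np.einsum("mnks,ks->mn", Td, D) * sel[:, None]
        P2 = np.einsum("nmks,ks->mn", Td, D) * sel[None, :]
        P3 = np.einsum("ksmn,ks,k->mn", Td, D, sel)
        P4 = np.einsum("skmn,ks,s->mn", Td, D, sel)
        Jpart = P1 + P2 + P3 + P4
    else:
        Jpart = 0.0
    # exchange: K_mn = sum (mk|sn) D_ks, derivative on each position
    K1 = np.einsum("mkns,ks->mn", Td, D) * sel[:, None]          # d(mu)
    K2 = np.einsum("kmns,ks,k->mn", Td, D, sel)                  # d(kappa)
    K3 = np.einsum("nsmk,ks->mn", Td, D) * sel[None, :]          # d(nu)
    K4 = np.einsum("snmk,ks,s->mn", Td, D, sel)                  # d(sigma)
    Kpart = K1 + K2 + K3 + K4
    if mode == "exchange":
        return -Kpart
    return 2.0 * Jpart - Kpart


def nuclear_gradient(st: SCFState) -> np.ndarray:
    """Analytic dE/dR (n_atoms x 3), Hartree/bohr.

    dE = 2 tr(D dh) + tr(D G1(D)) - 2 tr(W dS) + dVnn with the
    energy-weighted density W = C_occ eps_occ C_occ^T.
    """
    mol = st.mol
    ints = st.ints
    D = st.D0
    W = st.C_occ @ np.diag(st.eps_occ) @ st.C_occ.T
    grad = np.zeros((mol.n_atoms, 3))
    R = mol.positions
    Z = mol.charges
    for lam in range(mol.n_atoms):
        for beta in range(3):
            per = nuclear_derivative_integrals(ints, lam, beta)
            g = 2.0 * np.einsum("mn,mn->", D, per.pieces["dh"])
            g += np.einsum("mn,mn->", D, g1_matrix(ints, lam, beta, D))
            g -= 2.0 * np.einsum("mn,mn->", W, per.S1)
            grad[lam, beta] += g
        # nuclear repulsion gradient
        for c in range(mol.n_atoms):
            if c == lam:
                continue
            d = R[lam] - R[c]
            grad[lam] += -Z[lam] * Z[c] * d / np.linalg.norm(d) ** 3
    return grad
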