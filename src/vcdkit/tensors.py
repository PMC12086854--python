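"""Atomic polar tensors (length and velocity forms), atomic axial tensors
(NVPT and MFPT), and per-mode rotational and dipole strengths.

Conventions (a.u., CGS magnetic factors):
  electric dipole  mu = -sum_i r_i + sum_l Z_l (R_l - O_sp)
  magnetic dipole  m  = -(1/2c) sum_i (r_i - O_mag) x p_i   (electrons)
  APT   P^l_ab = d mu_a / d R_b^l  (length, NDPT)  or d<mu-dot_a>/d Rdot_b^l
        (velocity, NVPT); nuclear part Z_l delta_ab in both.
  AAT   M^l_ab = (1/2) d<m_a>/d Rdot_b^l (electronic, NVPT) or the
        equivalent mixed derivative via MFPT; nuclear part
        (Z_l/4c) eps_{agb} R^l_g. The 1/2 matches the nuclear-part
        convention so that R_i = sum_a (sum P S)_a (sum M S)_a.
  strengths (fundamental 0->1, harmonic):
        D_i = (1/2 w_i) sum_a (sum_lb P^l_ab S_i^lb)^2
        R_i =           sum_a (sum P S)_a (sum M S)_a
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemio import (DIPSTRENGTH_AU_TO_1E40ESU2CM2, HARTREE_TO_CM1,
                     ROTSTRENGTH_AU_TO_1E44ESU2CM2, SPEED_OF_LIGHT_AU as C_AU)
from .integrals import IntegralSet, levi_civita
from .scf import SCFState


@dataclass
class PropertyTensors:
    """Per-atom 3x3 tensors, first index alpha = moment direction, second
    beta = nuclear displacement/velocity direction."""

    el: np.ndarray            # (n_atoms, 3, 3) electronic part
    nuc: np.ndarray           # (n_atoms, 3, 3) nuclear part
    kind: str                 # 'apt' | 'aat'
    theory: str               # 'ndpt' | 'nvpt' | 'mfpt'
    solver: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.el + self.nuc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lam in range(self.el.shape[0]):
            for a in range(3):
                for b in range(3):
                    rows.append({
                        "atom": lam, "alpha": "xyz"[a], "beta": "xyz"[b],
                        "electronic": self.el[lam, a, b],
                        "nuclear": self.nuc[lam, a, b],
                        "total": self.total[lam, a, b]})
        df = pd.DataFrame(rows)
        df.attrs["kind"] = self.kind
        df.attrs["theory"] = self.theory
        return df


def _ao_centers(eng):
    return np.array([eng.prim_center[np.nonzero(eng.W[r])[0][0]]
                     for r in range(eng.n_ao)])


def nuclear_apt(mol) -> np.ndarray:
    out = np.zeros((mol.n_atoms, 3, 3))
    for lam, Z in enumerate(mol.charges):
        out[lam] = Z * np.eye(3)
    return out


def nuclear_aat(mol) -> np.ndarray:
    """(Z_l / 4c) eps_{a g b} R_g^l."""
    eps = levi_civita()
    out = np.zeros((mol.n_atoms, 3, 3))
    for lam, Z in enumerate(mol.charges):
        out[lam] = (Z / (4.0 * C_AU)) * np.einsum(
            "agb,g->ab", eps, mol.positions[lam])
    return out


# ----------------------------------------------------------------------------
# APT, length form (NDPT)
# ----------------------------------------------------------------------------


def apt_length(scf_state: SCFState, ndpt_d1: dict[str, np.ndarray],
               ints: IntegralSet, solver: str = "") -> PropertyTensors:
    """P^l_ab = Z_l d_ab - 2 [ tr(D1(R_b^l) Dip_a) + tr(D0 dDip_a/dR_b^l) ].

    The second trace is the basis-derivative (Pulay) term; the dipole
    operator itself does not move with the nuclei.
    """
    mol = scf_state.mol
    eng = ints.engine
    D0 = scf_state.D0
    el = np.zeros((mol.n_atoms, 3, 3))
    for lam in range(mol.n_atoms):
        selp = np.diag(eng.atom_prim_mask(lam))
        for b in range(3):
            D1 = ndpt_d1[f"R[{lam},{'xyz'[b]}]"]
            dc = selp @ eng.dcenter_map(b)
            for a in range(3):
                mom = eng.moment_map(a, ints.gauge.O_sp)
                dDip = (eng.matrix("S", bra_map=dc, ket_map=mom)
                        + eng.matrix("S", ket_map=dc @ mom))
                el[lam, a, b] = -2.0 * (np.einsum("mn,mn->", D1, ints.Dip[a])
                                        + np.einsum("mn,mn->", D0, dDip))
    return PropertyTensors(el, nuclear_apt(mol), "apt", "ndpt", solver)


# ----------------------------------------------------------------------------
# APT, velocity form (NVPT)
# ----------------------------------------------------------------------------


def apt_velocity(scf_state: SCFState, nvpt_d1: dict[str, np.ndarray],
                 ints: IntegralSet, solver: str = "") -> PropertyTensors:
    """P^l_ab = Z_l d_ab - 2 [ tr(d1(V_b^l) Nabla_a) + tr(D0 Pi) ] with Pi
    the VAO-phase derivative of the momentum-operator matrix:
    Pi = P*(sel_nu - sel_mu) + d_ab S0*sel_nu,  P_mn = <m_b chi_mu|d_a chi_nu>.
    """
    mol = scf_state.mol
    eng = ints.engine
    D0 = scf_state.D0
    S0 = scf_state.S0
    el = np.zeros((mol.n_atoms, 3, 3))
    for lam in range(mol.n_atoms):
        sel = eng.ao_on_atom(lam).astype(float)
        for b in range(3):
            d1 = nvpt_d1[f"V[{lam},{'xyz'[b]}]"]
            momb = eng.moment_map(b, ints.gauge.O_sp)
            for a in range(3):
                P = eng.matrix("S", bra_map=momb, ket_map=eng.nabla_map(a))
                Pi = P * sel[None, :] - P * sel[:, None]
                if a == b:
                    Pi = Pi + S0 * sel[None, :]
                # expectation trace is sum_mn M_mn D1_nm: note the index
                # order matters for the antisymmetric stored-real response
                el[lam, a, b] = -2.0 * (np.einsum("mn,nm->", ints.Nabla[a], d1)
                                        + np.einsum("mn,mn->", D0, Pi))
    return PropertyTensors(el, nuclear_apt(mol), "apt", "nvpt", solver)


# ----------------------------------------------------------------------------
# AAT, NVPT
# ----------------------------------------------------------------------------


def aat_nvpt(scf_state: SCFState, nvpt_d1: dict[str, np.ndarray],
             ints: IntegralSet, solver: str = "") -> PropertyTensors:
    """M^l_ab(el) = 1/2 d<m_a>/dRdot_b^l
                  = 1/2 [ -(1/c) tr(d1 AngMom_a) + 2 tr(D0 Theta) ]
    with Theta the VAO-phase derivative of the magnetic-moment matrix."""
    mol = scf_state.mol
    eng = ints.engine
    D0 = scf_state.D0
    gauge = ints.gauge
    eps = levi_civita()
    el = np.zeros((mol.n_atoms, 3, 3))
    # angular-momentum ket maps (about O_mag) per alpha
    amaps = []
    for a in range(3):
        m = np.zeros((eng.n_prim, eng.n_prim))
        for g in range(3):
            for d in range(3):
                if eps[a, g, d]:
                    m += eps[a, g, d] * eng.nabla_map(d) @ eng.moment_map(
                        g, gauge.O_mag)
        amaps.append(m)
    for lam in range(mol.n_atoms):
        sel = eng.ao_on_atom(lam).astype(float)
        for b in range(3):
            d1 = nvpt_d1[f"V[{lam},{'xyz'[b]}]"]
            momb = eng.moment_map(b, gauge.O_sp)
            for a in range(3):
                Wm = eng.matrix("S", bra_map=momb, ket_map=amaps[a])
                Theta = -(Wm * sel[None, :] - Wm * sel[:, None]) / (2 * C_AU)
                for g in range(3):
                    if eps[a, g, b]:
                        momg = eng.matrix(
                            "S", ket_map=eng.moment_map(g, gauge.O_mag))
                        Theta -= (eps[a, g, b] / (2 * C_AU)) * momg * sel[None, :]
                el[lam, a, b] = 0.5 * (
                    -(1.0 / C_AU) * np.einsum("mn,nm->", ints.AngMom[a], d1)
                    + 2.0 * np.einsum("mn,mn->", D0, Theta))
    return PropertyTensors(el, nuclear_aat(mol), "aat", "nvpt", solver)


# ----------------------------------------------------------------------------
# AAT, MFPT
# ----------------------------------------------------------------------------


def _mfpt_ingredients(scf_state, ints, lam, beta, alpha):
    """Integral matrices for one (lam, beta; alpha) MFPT AAT element.

    Bd  = <d chi_mu/dR | chi_nu>             (bra derivative, atom lam)
    Gk  = <chi_mu | g_nu chi_nu>, the stored-real GIAO ket phase derivative
          g_nu = -(1/2c) (R_nu x r)_alpha  (center-referenced; the GIAO
          construction leaves no magnetic-origin dependence)
    BdG = <d chi_mu/dR | g_nu chi_nu>
    """
    eng = ints.engine
    eps = levi_civita()
    A = _ao_centers(eng)
    selp = np.diag(eng.atom_prim_mask(lam))
    dc = selp @ eng.dcenter_map(beta)
    Bd = eng.matrix("S", bra_map=dc)
    n = eng.n_ao
    Gk = np.zeros((n, n))
    BdG = np.zeros((n, n))
    for g in range(3):
        for d in range(3):
            e = eps[alpha, g, d]
            if e == 0:
                continue
            mom0 = eng.matrix("S", ket_map=eng.moment_map(d, (0, 0, 0)))
            momd = eng.matrix("S", bra_map=dc,
                              ket_map=eng.moment_map(d, (0, 0, 0)))
            Gk += e * A[:, g][None, :] * mom0
            BdG += e * A[:, g][None, :] * momd
    Gk *= -1.0 / (2.0 * C_AU)
    BdG *= -1.0 / (2.0 * C_AU)
    return Bd, Gk, BdG


def aat_mfpt(scf_state: SCFState, mfpt_d1: list[np.ndarray],
             ndpt_d1: dict[str, np.ndarray], ints: IntegralSet,
             ndpt_s1: dict[str, np.ndarray], mfpt_s1: list[np.ndarray],
             solver: str = "",
             ndpt_c1: dict[str, np.ndarray] | None = None,
             mfpt_c1: list[np.ndarray] | None = None) -> PropertyTensors:
    """Electronic AAT as the overlap of first-order wavefunctions,

        M^l_ab(el) = Im < dPsi/dR_b^l | dPsi/dB_a >

    expanded over the occupied determinant (including the basis-function
    derivatives on both sides). With MO responses available (``ndpt_c1``,
    ``mfpt_c1``) the overlap is evaluated directly; otherwise it is assembled
    purely from density responses using the occupied/virtual projector
    identities (the density-matrix form of the same expression).
    """
    st = scf_state
    mol = st.mol
    D0, S0 = st.D0, st.S0
    Co = st.C_occ
    el = np.zeros((mol.n_atoms, 3, 3))
    Pv = np.eye(len(S0)) - D0 @ S0
    use_mo = ndpt_c1 is not None and mfpt_c1 is not None
    for lam in range(mol.n_atoms):
        for b in range(3):
            rlbl = f"R[{lam},{'xyz'[b]}]"
            S1R = ndpt_s1[rlbl]
            for a in range(3):
                Bd, Gk, BdG = _mfpt_ingredients(st, ints, lam, b, a)
                if use_mo:
                    C1R = ndpt_c1[rlbl]
                    c1B = mfpt_c1[a]
                    T1 = 2.0 * (np.trace(C1R.T @ S0 @ c1B)
                                + np.trace(C1R.T @ Gk @ Co)
                                + np.trace(Co.T @ Bd @ c1B)
                                + np.trace(Co.T @ BdG @ Co))
                    U = C1R.T @ S0 @ Co + Co.T @ Bd @ Co
                    V = Co.T @ (S0 @ c1B + Gk @ Co)
                    T2 = -2.0 * np.trace(U @ V)
                    T3 = 4.0 * np.trace(U) * np.trace(V)
                else:
                    D1R = ndpt_d1[rlbl]
                    d1B = mfpt_d1[a]
                    s1B = mfpt_s1[a]
                    T1a = (np.einsum("mn,mn->", Pv @ D1R,
                                     S0 @ (Pv @ d1B) @ S0.T)
                           + 0.25 * np.trace(S1R @ D0 @ s1B @ D0))
                    T1b = (np.trace(S0 @ D1R.T @ Pv.T @ Gk @ D0)
                           - 0.5 * np.trace(S1R @ D0 @ Gk @ D0))
                    T1c = (np.trace(Bd @ Pv @ d1B @ S0 @ D0)
                           - 0.5 * np.trace(Bd @ D0 @ s1B @ D0))
                    T1d = np.trace(BdG @ D0)
                    T1 = 2.0 * (T1a + T1b + T1c + T1d)
                    Umat = (-0.5 * S1R + Bd) @ D0
                    Vmat = (-0.5 * s1B + Gk) @ D0
                    T2 = -2.0 * np.trace(Umat @ Vmat)
                    T3 = 4.0 * np.trace(Umat) * np.trace(Vmat)
                el[lam, a, b] = T1 + T2 + T3
    return PropertyTensors(el, nuclear_aat(mol), "aat", "mfpt", solver)


# ----------------------------------------------------------------------------
# strengths
# ----------------------------------------------------------------------------


@dataclass
class StrengthTable:
    table: pd.DataFrame          # per vibrational mode
    theory_apt: str
    theory_aat: str | None

    def __len__(self):
        return len(self.table)


def strengths(apt: PropertyTensors, aat: PropertyTensors | None,
              vib_model) -> StrengthTable:
    """Contract APTs (and AATs, if given) over the normal modes.

    D_i = (1/2 w_i) |sum_lb P^l_ab S_i^lb|^2 summed over a (a.u.), reported
    also in 1e-40 esu^2 cm^2; R_i = sum_a (P.S)_a (M.S)_a (a.u.), reported
    also in 1e-44 esu^2 cm^2. Rigid (projected-out) modes are excluded.
    """
    P = apt.total
    n_atoms = P.shape[0]
    if aat is not None and aat.total.shape[0] != n_atoms:
        raise ValueError("APT/AAT atom-count mismatch")
    if vib_model.modes.shape[1:] != (n_atoms, 3):
        raise ValueError(
            f"mode vectors for {vib_model.modes.shape[1]} atoms do not match "
            f"tensors for {n_atoms} atoms")
    rows = []
    for i, w_cm in enumerate(vib_model.freqs_cm1):
        S = vib_model.modes[i]                      # (n_atoms, 3)
        mu1 = np.einsum("lab,lb->a", P, S)
        w_au = abs(w_cm) / HARTREE_TO_CM1
        D_au = float(mu1 @ mu1) / (2.0 * w_au) if w_au > 0 else np.nan
        row = {"mode": i, "wavenumber_cm1": w_cm,
               "D_au": D_au,
               "D_1e40esu2cm2": D_au * DIPSTRENGTH_AU_TO_1E40ESU2CM2}
        if aat is not None:
            m1 = np.einsum("lab,lb->a", aat.total, S)
            R_au = float(mu1 @ m1)
            row["R_au"] = R_au
            row["R_1e44esu2cm2"] = R_au * ROTSTRENGTH_AU_TO_1E44ESU2CM2
        rows.append(row)
    return StrengthTable(pd.DataFrame(rows), apt.theory,
                         aat.theory if aat is not None else None)
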