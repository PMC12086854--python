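"""Channel builders: turn integrals into ResponseProblem instances.

NDPT (nuclear displacement, real symmetric): for each atom lam and direction
beta, H1 = dh/dR + G1(D0) from derivative ERIs, S1 = dS/dR; fully coupled.

NVPT (nuclear velocity, imaginary antihermitian): velocity atomic orbitals
attach the phase exp(i Rdot.(r - O_sp)) to functions on the moving atom. The
fixed part of the perturbation matrix collects (i) the phase derivative of
the unperturbed Fock matrix, one- and two-electron (the two-electron part
carries the phases of all four ERI indices: bra/ket AND density phases,
which at Hartree-Fock contribute through the exchange term), (ii) the
nuclear-momentum coupling -i Rdot.grad_lam acting on the basis functions of
the moving atom, and (iii) the coupling to the nuclear-displacement response
D(1,R) (the coefficient part of grad_lam). The raw sum N of these pieces is
not termwise antihermitian; both solvers only ever consume its action on the
occupied space and the occ-virt blocks, so the channel matrix is the
antihermitian completion H1 = N D0 S0 - (N D0 S0)^T, which reproduces
N C0_j modulo components annihilated by the virtual projector.

MFPT (magnetic field, imaginary antihermitian): GIAO phases make every
matrix element depend only on center differences; H1 and S1 are independent
of O_mag by construction. Exactly three channels (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ao_response import ResponseProblem
from .chemio import SPEED_OF_LIGHT_AU as C_AU
from .integrals import IntegralSet, levi_civita, nuclear_derivative_integrals, \
    giao_first_order, vao_first_order
from .scf import SCFState, coulomb, exchange, g1_matrix


@dataclass
class ChannelSet:
    theory: str                       # 'ndpt' | 'nvpt' | 'mfpt'
    problems: list[ResponseProblem]
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.problems)


def channel_label(theory: str, lam_or_alpha, beta=None) -> str:
    if theory == "mfpt":
        return f"B[{'xyz'[lam_or_alpha]}]"
    k = "R" if theory == "ndpt" else "V"
    return f"{k}[{lam_or_alpha},{'xyz'[beta]}]"


# ----------------------------------------------------------------------------
# NDPT
# ----------------------------------------------------------------------------


def build_ndpt_channels(scf_state: SCFState, ints: IntegralSet) -> ChannelSet:
    """3N real-symmetric coupled channels (atom-major, x,y,z order)."""
    mol = scf_state.mol
    problems, labels = [], []
    for lam in range(mol.n_atoms):
        for beta in range(3):
            per = nuclear_derivative_integrals(ints, lam, beta)
            H1 = per.pieces["dh"] + g1_matrix(ints, lam, beta, scf_state.D0)
            lbl = channel_label("ndpt", lam, beta)
            problems.append(ResponseProblem(
                flavor="real_symmetric", H1=H1, S1=per.S1,
                coupling="full", channel=lbl))
            labels.append(lbl)
    return ChannelSet("ndpt", problems, labels)


# ----------------------------------------------------------------------------
# NVPT
# ----------------------------------------------------------------------------


def _vao_phase_2e(scf_state: SCFState, ints: IntegralSet, lam: int, beta: int
                  ) -> np.ndarray:
    """Two-electron part of the VAO phase derivative of the Fock matrix
    (stored-real factor of i), channel (lam, beta).

    ERIs acquire the phase weight i m(r) (m = (r - O_sp)_beta) on each index
    carrying a moving-atom function, with sign - for bra-side (conjugated)
    and + for ket-side indices. Electron-2 Coulomb weights cancel against the
    symmetric density; exchange keeps all four.
    """
    eng = ints.engine
    D0 = scf_state.D0
    ERI = ints.ERI
    TR = eng.eri_raised(beta)
    sel = eng.ao_on_atom(lam).astype(float)
    ao_cen = np.array([eng.prim_center[np.nonzero(eng.W[r])[0][0]]
                       for r in range(eng.n_ao)])
    w = ao_cen[:, beta] - ints.gauge.O_sp[beta]   # center shift of the moment
    J0 = coulomb(ERI, D0)
    K0 = exchange(ERI, D0)

    # Coulomb, electron-1 phases: + on ket(nu), - on bra(mu)
    J1 = np.einsum("nmks,ks->mn", TR, D0) + w[None, :] * J0
    J2 = np.einsum("mnks,ks->mn", TR, D0) + w[:, None] * J0
    j_phase = J1 * sel[None, :] - J2 * sel[:, None]

    # exchange K_mn = sum (m k|s n) D_ks; phases: +kappa, -mu, +nu, -sigma
    K1 = (np.einsum("kmsn,ks,k->mn", TR, D0, sel)
          + np.einsum("mksn,ks,k->mn", ERI, D0, sel * w))
    K2 = (np.einsum("mksn,ks->mn", TR, D0) + w[:, None] * K0) * sel[:, None]
    K3 = (np.einsum("nsmk,ks->mn", TR, D0) * sel[None, :]
          + K0 * (sel * w)[None, :])
    K4 = (np.einsum("snmk,ks,s->mn", TR, D0, sel)
          + np.einsum("mksn,ks,s->mn", ERI, D0, sel * w))
    k_phase = K1 - K2 + K3 - K4
    return 2.0 * j_phase - k_phase


def antihermitian_completion(N: np.ndarray, D0: np.ndarray, S0: np.ndarray
                             ) -> np.ndarray:
    """H1 = N D0 S0 - (N D0 S0)^T: antisymmetric, and H1 C0 = N C0 up to
    components in the occupied dual space (annihilated by the virtual
    projector in both solvers)."""
    M = N @ D0 @ S0
    return M - M.T


def build_nvpt_channels(scf_state: SCFState, ints: IntegralSet,
                        ndpt_results: dict[str, np.ndarray]) -> ChannelSet:
    """3N imaginary-antihermitian channels; requires the NDPT density
    responses D(1,R) for the coefficient cross term.

    ndpt_results maps NDPT channel labels to D1 matrices.
    """
    mol = scf_state.mol
    S0, D0 = scf_state.S0, scf_state.D0
    problems, labels = [], []
    for lam in range(mol.n_atoms):
        for beta in range(3):
            rlbl = channel_label("ndpt", lam, beta)
            if rlbl not in ndpt_results:
                raise ValueError(
                    f"NVPT needs the NDPT response for channel {rlbl}")
            per = vao_first_order(ints, lam, beta)
            N = per.pieces["h1_vao_1el"] + _vao_phase_2e(scf_state, ints,
                                                         lam, beta)
            N = N + per.pieces["h1_nab"]
            N = N - S0 @ ndpt_results[rlbl] @ S0       # coefficient cross term
            H1 = antihermitian_completion(N, D0, S0)
            lbl = channel_label("nvpt", lam, beta)
            problems.append(ResponseProblem(
                flavor="imag_antihermitian", H1=H1, S1=per.S1,
                coupling="exchange", channel=lbl))
            labels.append(lbl)
    return ChannelSet("nvpt", problems, labels)


# ----------------------------------------------------------------------------
# MFPT
# ----------------------------------------------------------------------------


def _giao_phase_2e(scf_state: SCFState, ints: IntegralSet, alpha: int
                   ) -> np.ndarray:
    """Two-electron GIAO first-order term (stored-real factor of i):
    derivative ERIs are moment-weighted ERIs with pairwise center-difference
    prefactors (O_mag cancels), contracted with D0 in Coulomb and exchange
    patterns."""
    eng = ints.engine
    D0 = scf_state.D0
    ERI = ints.ERI
    eps = levi_civita()
    A = np.array([eng.prim_center[np.nonzero(eng.W[r])[0][0]]
                  for r in range(eng.n_ao)])
    J0 = coulomb(ERI, D0)
    K0 = exchange(ERI, D0)
    n = eng.n_ao
    GJ = np.zeros((n, n))
    GK = np.zeros((n, n))
    for g in range(3):
        for d in range(3):
            e = eps[alpha, g, d]
            if e == 0:
                continue
            TR = eng.eri_raised(d)
            # Coulomb: weight (A_mu - A_nu)_g on the electron-1 moment
            Jm = np.einsum("mnks,ks->mn", TR, D0) + A[:, d][:, None] * J0
            GJ += e * (A[:, g][:, None] - A[:, g][None, :]) * Jm
            # exchange electron 1: weight (A_mu - A_kappa)_g
            t1 = np.einsum("mksn,ks->mn", TR, D0) * A[:, g][:, None]
            t2 = np.einsum("mksn,ks,k->mn", TR, D0, A[:, g])
            t3 = K0 * (A[:, g] * A[:, d])[:, None]
            t4 = np.einsum("mksn,ks,k->mn", ERI, D0, A[:, g]) * A[:, d][:, None]
            # exchange electron 2: weight (A_sigma - A_nu)_g
            u1 = np.einsum("snmk,ks,s->mn", TR, D0, A[:, g])
            u2 = np.einsum("snmk,ks->mn", TR, D0) * A[:, g][None, :]
            u3 = np.einsum("mksn,ks,s->mn", ERI, D0, A[:, g] * A[:, d])
            u4 = np.einsum("mksn,ks,s->mn", ERI, D0, A[:, d]) * A[:, g][None, :]
            GK += e * (t1 - t2 + t3 - t4 + u1 - u2 + u3 - u4)
    out = (2.0 * GJ - GK) / (2.0 * C_AU)
    asym = 0.5 * (out - out.T)
    resid = np.max(np.abs(out - asym))
    if resid > 1e-8 * max(1.0, np.max(np.abs(out))):
        raise AssertionError(
            f"GIAO 2e H1(B_{'xyz'[alpha]}) antisymmetry violated: {resid:.3e}")
    return asym


def build_mfpt_channels(scf_state: SCFState, ints: IntegralSet) -> ChannelSet:
    """Exactly three imaginary-antihermitian channels, one per Cartesian
    field direction; every ingredient is independent of O_mag."""
    pers = giao_first_order(ints)
    problems, labels = [], []
    for alpha, per in enumerate(pers):
        H1 = per.pieces["h1_1el"] + _giao_phase_2e(scf_state, ints, alpha)
        lbl = channel_label("mfpt", alpha)
        problems.append(ResponseProblem(
            flavor="imag_antihermitian", H1=H1, S1=per.S1,
            coupling="exchange", channel=lbl))
        labels.append(lbl)
    return ChannelSet("mfpt", problems, labels)
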