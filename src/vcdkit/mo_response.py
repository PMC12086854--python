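"""MO-based Sternheimer linear response: the independent validation path.

For each occupied orbital j the perturbed coefficients are obtained from the
first-order Roothaan equation projected onto the virtual space,

    (F0 - eps_j S0) C1_j = -Q^T (H1 - eps_j S1 + G(D1)) C0_j ,
    Q = 1 - D0 S0  (S-orthogonal projector onto the virtual space),

solved per orbital with preconditioned conjugate gradients. The
occupied-occupied response is not solved for; differentiating the
orthonormality condition C^T S C = 1 fixes it (up to the standard
antisymmetric freedom, resolved symmetrically) as

    C1_j^(oo) = -1/2 sum_k C0_k (C0_k^T S1 C0_j) ,

which reproduces the occupied-occupied density block -D0 S1 D0. Coupled
channels (nuclear displacement; exchange coupling of imaginary channels at
Hartree-Fock) iterate the G(D1) term to self-consistency with damping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scf import SCFState, g_matrix


@dataclass
class MOResponse:
    C1: np.ndarray            # perturbed occupied coefficients (stored real)
    D1_mo: np.ndarray         # assembled density response, AO representation
    n_outer: int
    channel: str = ""
    flavor: str = ""
    history: list = field(default_factory=list, repr=False)


def assemble_density_response(C_occ: np.ndarray, C1: np.ndarray,
                              flavor: str) -> np.ndarray:
    """D1 from perturbed occupied coefficients.

    Real channels: D1 = C1 C0^T + C0 C1^T (symmetric). Imaginary channels
    (C1 stores the real factor of i): D1/i = C1 C0^T - C0 C1^T
    (antisymmetric).
    """
    if flavor == "real_symmetric":
        return C1 @ C_occ.T + C_occ @ C1.T
    return C1 @ C_occ.T - C_occ @ C1.T


def _cg_orbital(Fs, rhs, Q, Cv, gap, tol, max_iter=400, channel=""):
    """CG solve of Q^T Fs Q y = rhs in the projected virtual space with the
    virtual-orbital energy-difference preconditioner."""
    y = np.zeros_like(rhs)
    r = rhs.copy()

    def prec(x):
        return Cv @ ((Cv.T @ x) / gap)

    z = prec(r)
    p = z
    rz = r @ z
    for it in range(max_iter):
        if np.linalg.norm(r) <= tol:
            return y
        Ap = Q.T @ (Fs @ (Q @ p))
        alpha = rz / (p @ Ap)
        y = y + alpha * p
        r = r - alpha * Ap
        z = prec(r)
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise RuntimeError(f"{channel}: per-orbital CG failed to converge "
                       f"(residual {np.linalg.norm(r):.3e})")


def solve_sternheimer(H1: np.ndarray, S1: np.ndarray, scf_state: SCFState,
                      flavor: str, tol: float = 5e-12,
                      coupling: str = "full", damping: float = 0.5,
                      max_outer: int = 200, channel: str = "") -> MOResponse:
    """Solve one channel through the Sternheimer equation.

    H1 and S1 are stored-real matrices ('times i' convention for imaginary
    channels). ``coupling`` as in the AO solver; for imaginary channels
    'full' degrades to 'exchange' automatically.
    """
    st = scf_state
    S0, F0, ERI = st.S0, st.H0, st.ints.ERI
    Co = st.C_occ
    eo = st.eps_occ
    n_occ = st.n_occ
    C_all = st.C0
    eps = st.eps
    Cv = C_all[:, n_occ:]
    ev = eps[n_occ:]
    # near-degeneracy guard
    gap_all = ev[None, :] - eo[:, None]
    if gap_all.size and np.min(gap_all) < 1e-6:
        j, a = np.unravel_index(np.argmin(gap_all), gap_all.shape)
        raise RuntimeError(
            f"{channel}: near-degenerate occupied-virtual pair "
            f"(occ {j}, virt {n_occ + a}, gap {gap_all[j, a]:.3e} a.u.)")
    Q = np.eye(len(S0)) - st.D0 @ S0

    if flavor == "imag_antihermitian" and coupling == "full":
        coupling = "exchange"

    # occupied-occupied part from the orthonormality derivative
    S1mo = Co.T @ S1 @ Co
    C1_oo = -0.5 * Co @ S1mo

    D1 = np.zeros_like(S0)
    C1 = np.zeros_like(Co)
    history = []
    n_outer = 0
    for outer in range(max_outer):
        Gm = (g_matrix(ERI, D1, coupling) if coupling != "none"
              else np.zeros_like(S0))
        C1_new = np.zeros_like(Co)
        for j in range(n_occ):
            rhs = -(Q.T @ ((H1 + Gm) @ Co[:, j] - eo[j] * (S1 @ Co[:, j])))
            Fs = F0 - eo[j] * S0
            y = _cg_orbital(Fs, rhs, Q, Cv, ev - eo[j], 0.1 * tol,
                            channel=channel)
            C1_new[:, j] = Q @ y + C1_oo[:, j]
        D1_new = assemble_density_response(Co, C1_new, flavor)
        delta = float(np.max(np.abs(D1_new - D1)))
        history.append(delta)
        n_outer = outer + 1
        if coupling == "none":
            C1, D1 = C1_new, D1_new
            break
        if outer == 0:
            C1, D1 = C1_new, D1_new
        else:
            C1 = damping * C1_new + (1 - damping) * C1
            D1 = assemble_density_response(Co, C1, flavor)
        if delta <= 10 * tol:
            break
    else:
        raise RuntimeError(
            f"{channel}: coupled outer loop not converged "
            f"(last |dD1| {history[-1]:.3e})")
    return MOResponse(C1, D1, n_outer, channel=channel, flavor=flavor,
                      history=history)
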