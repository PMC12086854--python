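"""AO-basis density-matrix linear response with nonzero perturbed overlap.

The first-order density is parametrized through an anti-Hermitian generator
acting on the reference density (exponential parametrization, truncated at
strict first order),

    D1 = D1_occ-occ + D0 S0 X - X S0 D0 ,    D1_oo = -D0 S1 D0 ,

which preserves the differentiated idempotency and trace conditions by
construction. Projecting the differentiated stationarity condition
d/dx (F D S - S D F) = 0 onto the occupied-virtual block in the Loewdin
(symmetrically orthogonalized) basis yields the working equation solved here
by preconditioned conjugate gradients:

    U Ft - Ft U + o G(U + s U^T) v = -( o [H1 + G(D1_oo)] v - o Ft Dt0 S1t v )

with o = Dt0, v = 1 - Dt0 the occupied/virtual projectors, s = +1 for real
symmetric channels (X antisymmetric) and s = -1 for imaginary antihermitian
channels (stored-real X symmetric), and U = o X v the unknown block. All
algebra is real; imaginary channels work with the real factor multiplying i,
for which the Coulomb response vanishes identically and G reduces to the
exchange term (exact at Hartree-Fock).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scf import SCFState, g_matrix


@dataclass
class ResponseProblem:
    """One perturbation channel for the density-matrix response solver."""

    flavor: str                  # 'real_symmetric' | 'imag_antihermitian'
    H1: np.ndarray               # fixed perturbation Fock matrix (stored real)
    S1: np.ndarray               # perturbed overlap (stored real)
    coupling: str = "full"       # 'full' | 'exchange' | 'none'
    channel: str = ""

    def __post_init__(self):
        scale = max(1.0, float(np.max(np.abs(self.H1))))
        if self.flavor == "real_symmetric":
            if np.max(np.abs(self.H1 - self.H1.T)) > 1e-8 * scale:
                raise ValueError(f"{self.channel}: H1 not symmetric")
        elif self.flavor == "imag_antihermitian":
            if np.max(np.abs(self.H1 + self.H1.T)) > 1e-8 * scale:
                raise ValueError(f"{self.channel}: stored H1 not antisymmetric")
        else:
            raise ValueError(f"unknown flavor {self.flavor!r}")

    @property
    def sigma(self) -> float:
        return 1.0 if self.flavor == "real_symmetric" else -1.0


@dataclass
class DensityResponse:
    X1: np.ndarray               # occ-virt generator block (Loewdin basis)
    D1_oo: np.ndarray            # occupied-occupied block, AO representation
    D1: np.ndarray               # assembled first-order density, AO rep
    residual_norm: float
    n_iter: int
    channel: str = ""
    flavor: str = ""
    history: list = field(default_factory=list, repr=False)


# ----------------------------------------------------------------------------
# Loewdin transforms and projectors
# ----------------------------------------------------------------------------


def _s_roots(S0):
    w, V = np.linalg.eigh(S0)
    if w[0] <= 0:
        raise ValueError("overlap matrix is not positive definite")
    return (V @ np.diag(w ** 0.5) @ V.T, V @ np.diag(w ** -0.5) @ V.T)


def lowdin_transform(M: np.ndarray, S0: np.ndarray, direction: str) -> np.ndarray:
    """Symmetric-orthogonalization transform.

    'covariant'    : S^{-1/2} M S^{-1/2}   (Fock/overlap-like quantities)
    'contravariant': S^{+1/2} M S^{+1/2}   (density-like quantities)
    'inverse'      : inverse of 'covariant' (identical to 'contravariant';
                     provided so round-trips read naturally)
    """
    Sp, Sm = _s_roots(S0)
    if direction == "covariant":
        return Sm @ M @ Sm
    if direction in ("contravariant", "inverse"):
        return Sp @ M @ Sp
    raise ValueError(f"unknown direction {direction!r}")


def project_redundant(A: np.ndarray, D0: np.ndarray, S0: np.ndarray) -> np.ndarray:
    """Annihilate the occupied-occupied and virtual-virtual components of a
    density-like matrix A; idempotent."""
    o = D0 @ S0
    v = np.eye(len(S0)) - o
    return o @ A @ v.T + v @ A @ o.T


def occ_occ_block(D0: np.ndarray, S1: np.ndarray) -> np.ndarray:
    """Occupied-occupied response resolved from the differentiated
    idempotency condition: D1_oo = -D0 S1 D0."""
    return -D0 @ S1 @ D0


# ----------------------------------------------------------------------------
# solver
# ----------------------------------------------------------------------------


class CGStagnation(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def solve_response(problem: ResponseProblem, scf_state: SCFState,
                   tol: float = 5e-12, max_iter: int = 400) -> DensityResponse:
    """Solve one response channel to residual norm <= tol (a.u.)."""
    S0 = scf_state.S0
    ERI = scf_state.ints.ERI
    Sp, Sm = _s_roots(S0)
    Ft = Sm @ scf_state.H0 @ Sm
    Dt0 = Sp @ scf_state.D0 @ Sp
    n = len(S0)
    Iden = np.eye(n)
    o = Dt0
    v = Iden - Dt0
    sig = problem.sigma
    gmode = problem.coupling
    if problem.flavor == "imag_antihermitian" and gmode == "full":
        gmode = "exchange"   # Coulomb response of an antisymmetric density is 0

    def G_t(At):
        """Loewdin-basis two-electron response of a Loewdin density block."""
        if gmode == "none":
            return np.zeros_like(At)
        A_ao = Sm @ At @ Sm
        return Sm @ g_matrix(ERI, A_ao, gmode) @ Sm

    H1t = Sm @ problem.H1 @ Sm
    S1t = Sm @ problem.S1 @ Sm
    D1oo_t = -Dt0 @ S1t @ Dt0

    b = o @ (H1t + G_t(D1oo_t)) @ v - o @ Ft @ Dt0 @ S1t @ v
    rhs = -b

    def L(U):
        U = o @ U @ v                      # keep the ov block pattern
        out = U @ Ft - Ft @ U + o @ G_t(U + sig * U.T) @ v
        return o @ out @ v

    # Jacobi preconditioner from occupied/virtual level differences in the
    # Loewdin basis (eigen-decomposition of Ft; exact for the uncoupled part)
    eps_t, Wt = np.linalg.eigh(Ft)
    occ_like = np.einsum("ik,ij,jk->k", Wt, Dt0, Wt)
    occ_mask = occ_like > 0.5
    gap = eps_t[None, ~occ_mask] - eps_t[occ_mask, None]
    if gap.size and np.min(gap) < 1e-6:
        raise RuntimeError(
            f"{problem.channel}: near-degenerate occ-virt level pair "
            f"(gap {np.min(gap):.3e} a.u.)")
    Wo = Wt[:, occ_mask]
    Wv = Wt[:, ~occ_mask]

    def precond(R):
        return Wo @ ((Wo.T @ R @ Wv) / gap) @ Wv.T

    U = np.zeros((n, n))                   # deterministic zero initial guess
    r = rhs - L(U)
    z = precond(r)
    p = z
    rz = np.vdot(r, z)
    history = []
    best = np.inf
    stagnant = 0
    n_it = 0
    res = float(np.linalg.norm(r))
    for it in range(max_iter):
        res = float(np.linalg.norm(r))
        history.append(res)
        if res <= tol:
            break
        if res < best - 1e-2 * best:
            best = res
            stagnant = 0
        else:
            stagnant += 1
            if stagnant > 25:
                raise CGStagnation(
                    f"{problem.channel}: CG stagnated at residual {res:.3e} "
                    f"(history tail {history[-5:]})", history)
        Lp = L(p)
        alpha = rz / np.vdot(p, Lp)
        U = U + alpha * p
        r = r - alpha * Lp
        z = precond(r)
        rz_new = np.vdot(r, z)
        p = z + (rz_new / rz) * p
        rz = rz_new
        n_it = it + 1
    else:
        raise RuntimeError(
            f"{problem.channel}: response CG did not reach tol {tol:.1e} in "
            f"{max_iter} iterations (last residual {history[-1]:.3e})")

    U = o @ U @ v
    D1t = D1oo_t + U + sig * U.T
    D1 = Sm @ D1t @ Sm
    D1_oo = Sm @ D1oo_t @ Sm
    resp = DensityResponse(U, D1_oo, D1, res, n_it,
                           channel=problem.channel, flavor=problem.flavor,
                           history=history)
    _assert_response_valid(resp, problem, scf_state, tol)
    return resp


def _assert_response_valid(resp: DensityResponse, problem: ResponseProblem,
                           st: SCFState, tol: float):
    """Flavor preservation, differentiated idempotency, electron count."""
    D1, D0, S0, S1 = resp.D1, st.D0, st.S0, problem.S1
    scale = max(1.0, float(np.max(np.abs(D1))))
    if problem.flavor == "real_symmetric":
        herm = np.max(np.abs(D1 - D1.T))
    else:
        herm = np.max(np.abs(D1 + D1.T))
    idem = np.max(np.abs(D1 @ S0 @ D0 + D0 @ S1 @ D0 + D0 @ S0 @ D1 - D1))
    trace = abs(np.trace(D1 @ S0) + np.trace(D0 @ S1))
    lim = max(1e4 * tol, 1e-9 * scale)
    for name, val in (("hermiticity class", herm),
                      ("differentiated idempotency", idem),
                      ("electron-number conservation", trace)):
        if val > lim:
            raise AssertionError(
                f"{resp.channel}: {name} violated by {val:.3e}")
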