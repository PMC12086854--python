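"""Harmonic vibrational analysis and spectrum synthesis.

The Hessian is seminumerical: central (three-point) differences of the
analytic Hartree-Fock nuclear gradient with a default increment of
1e-2 bohr. Rigid translations and rotations are projected out (Eckart frame)
before diagonalizing the mass-weighted Hessian. Broadened IR and VCD spectra
use unit-area Lorentzian lines of full width at half maximum w (default
12 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import BasisSet, GaugeConfig, HARTREE_TO_CM1, Molecule
from .scf import SCFConfig, SCFState, nuclear_gradient, run_scf

#: rigid-mode rejection threshold after projection (cm^-1)
RIGID_MODE_CM1 = 15.0


@dataclass
class VibrationalModel:
    hessian: np.ndarray           # 3N x 3N, a.u. (Eh / bohr^2), symmetric
    freqs_cm1: np.ndarray         # vibrational modes only; negative = imaginary
    modes: np.ndarray             # (n_modes, n_atoms, 3) Cartesian S_i^{lb}
    n_imaginary: int
    mol: Molecule = field(repr=False, default=None)
    symmetrization_residual: float = 0.0

    @property
    def n_rigid(self) -> int:
        return 3 * self.mol.n_atoms - len(self.freqs_cm1)


def optimize_geometry(mol: Molecule, basis: BasisSet,
                      scf_config: SCFConfig | None = None,
                      gauge: GaugeConfig | None = None,
                      max_force: float = 3e-5, rms_force: float = 1.5e-5,
                      max_steps: int = 200) -> Molecule:
    """Quasi-Newton (BFGS) minimization of the SCF energy with analytic
    gradients; converges to max |g| <= 3e-5 and rms(g) <= 1.5e-5 a.u."""
    from scipy.optimize import minimize

    x0 = mol.positions.ravel().copy()

    def fun(x):
        st = run_scf(mol.with_positions(x), basis, scf_config, gauge)
        return st.E_total, nuclear_gradient(st).ravel()

    res = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": 0.5 * max_force, "maxiter": max_steps,
                            "norm": np.inf})
    g = res.jac
    if np.max(np.abs(g)) > max_force or np.sqrt(np.mean(g ** 2)) > rms_force:
        raise RuntimeError(
            f"geometry optimization not converged: max|g|="
            f"{np.max(np.abs(g)):.2e}, rms={np.sqrt(np.mean(g**2)):.2e}")
    return mol.with_positions(res.x)


def _rigid_space(mol: Molecule) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N x k)."""
    n = mol.n_atoms
    m = np.sqrt(mol.masses)
    R = mol.positions
    com = (mol.masses[:, None] * R).sum(0) / mol.masses.sum()
    vecs = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = m
        vecs.append(t.ravel())
    for a in range(3):
        e = np.zeros(3)
        e[a] = 1.0
        r = np.cross(R - com, e) * m[:, None]
        vecs.append(r.ravel())
    V = np.array(vecs).T
    # orthonormalize, dropping null vectors (linear molecules)
    q, s, _ = np.linalg.svd(V, full_matrices=False)
    return q[:, s > 1e-8 * s[0]]


def numeric_hessian(mol: Molecule, basis: BasisSet, step: float = 1e-2,
                    scf_config: SCFConfig | None = None,
                    gauge: GaugeConfig | None = None) -> VibrationalModel:
    """Three-point central differences of the analytic gradient.

    step: displacement in bohr (default 1e-2 a.u.). SCF failures at
    displaced geometries propagate with the displacement named.
    """
    if step <= 0:
        raise ValueError("displacement step must be positive")
    n = mol.n_atoms
    x0 = mol.positions.ravel()
    H = np.zeros((3 * n, 3 * n))
    for k in range(3 * n):
        gpm = []
        for sgn in (+1.0, -1.0):
            x = x0.copy()
            x[k] += sgn * step
            try:
                st = run_scf(mol.with_positions(x), basis, scf_config, gauge)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"SCF failed at displacement {'+-'[sgn < 0]}{step} bohr "
                    f"of coordinate {k} (atom {k // 3}, {'xyz'[k % 3]})"
                ) from exc
            gpm.append(nuclear_gradient(st).ravel())
        H[:, k] = (gpm[0] - gpm[1]) / (2.0 * step)
    sym_res = float(np.max(np.abs(H - H.T)) / max(np.max(np.abs(H)), 1e-300))
    H = 0.5 * (H + H.T)
    return analyze_hessian(H, mol, symmetrization_residual=sym_res)


def analyze_hessian(H: np.ndarray, mol: Molecule,
                    symmetrization_residual: float = 0.0) -> VibrationalModel:
    """Mass-weight, Eckart-project, diagonalize; return vibrational modes."""
    minv = 1.0 / np.sqrt(np.repeat(mol.masses, 3))
    Hmw = H * minv[:, None] * minv[None, :]
    V = _rigid_space(mol)
    P = np.eye(len(Hmw)) - V @ V.T
    Hp = P @ Hmw @ P
    Hp = 0.5 * (Hp + Hp.T)
    w, L = np.linalg.eigh(Hp)
    thr = (RIGID_MODE_CM1 / HARTREE_TO_CM1) ** 2
    keep = np.abs(w) > thr
    w = w[keep]
    L = L[:, keep]
    freqs = np.sign(w) * np.sqrt(np.abs(w)) * HARTREE_TO_CM1
    order = np.argsort(freqs)
    freqs = freqs[order]
    L = L[:, order]
    modes = (L.T * minv[None, :]).reshape(-1, mol.n_atoms, 3)
    return VibrationalModel(H, freqs, modes, int(np.sum(freqs < 0)), mol,
                            symmetrization_residual)


# ----------------------------------------------------------------------------
# spectrum synthesis
# ----------------------------------------------------------------------------


@dataclass
class Spectrum:
    grid: np.ndarray             # wavenumbers, cm^-1
    intensity: np.ndarray
    width: float                 # Lorentzian FWHM, cm^-1
    shift: float = 0.0
    kind: str = ""


def broaden(frequencies_cm1, strengths, w: float = 12.0, grid=None,
            shift: float = 0.0, kind: str = "") -> Spectrum:
    """Sum of unit-area Lorentzians: L(x) = sum_i s_i (w/2pi) /
    ((x - x_i - shift)^2 + (w/2)^2); single-mode peak height 2 s_i / (pi w).
    """
    if w <= 0:
        raise ValueError("Lorentzian width must be positive")
    frequencies_cm1 = np.asarray(frequencies_cm1, float)
    strengths = np.asarray(strengths, float)
    if grid is None:
        lo = max(0.0, frequencies_cm1.min() - 40 * w) if len(frequencies_cm1) else 0.0
        hi = (frequencies_cm1.max() + 40 * w) if len(frequencies_cm1) else 4000.0
        grid = np.arange(lo, hi + shift + 1.0, 1.0)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    # accumulate mode by mode: memory-safe for very wide/dense grids
    intensity = np.zeros_like(grid)
    for f, s in zip(frequencies_cm1, strengths):
        x = grid - f - shift
        intensity += s * (w / (2.0 * np.pi)) / (x ** 2 + (w / 2.0) ** 2)
    return Spectrum(grid, intensity, w, shift, kind)
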