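"""Molecule and basis-set data model, file I/O, physical constants, gauge configuration.

All quantities are stored internally in Hartree atomic units; magnetic
operators follow the CGS convention (explicit factors of 1/c, with c the
speed of light in atomic units). Positions are stored in bohr.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

# ----------------------------------------------------------------------------
# physical constants (CODATA 2018)
# ----------------------------------------------------------------------------

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
SPEED_OF_LIGHT_AU = 137.035999084
HARTREE_TO_CM1 = 219474.6313632
AMU_TO_ME = 1822.888486209
#: (e a0)^2 in 10^-40 esu^2 cm^2 — dipole-strength report unit
DIPSTRENGTH_AU_TO_1E40ESU2CM2 = 6.460434e4
#: (e a0)^2 in 10^-44 esu^2 cm^2 — rotational-strength report unit (the
#: magnetic moment matrix carries its 1/c factor explicitly, so R_i in a.u.
#: has the same dimension as D_i)
ROTSTRENGTH_AU_TO_1E44ESU2CM2 = 6.460434e8

_ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

#: isotope-averaged atomic masses (amu)
_MASSES_AMU = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
}


def element_number(symbol: str) -> int:
    sym = symbol.strip().capitalize()
    if sym not in _ELEMENTS:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return _ELEMENTS.index(sym)


def element_mass_amu(symbol: str) -> float:
    sym = symbol.strip().capitalize()
    if sym not in _MASSES_AMU:
        raise ValueError(f"no tabulated mass for element {symbol!r}")
    return _MASSES_AMU[sym]


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------


@dataclass
class Atom:
    """One nucleus: element symbol, nuclear charge Z, mass (a.u. of mass,
    i.e. electron masses) and position R (bohr)."""

    symbol: str
    Z: int
    mass: float
    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.Z <= 0:
            raise ValueError("nuclear charge must be positive")
        if self.mass <= 0:
            raise ValueError("atomic mass must be positive")
        if self.R.shape != (3,):
            raise ValueError("position must be a 3-vector")


@dataclass
class Molecule:
    atoms: list[Atom]
    charge: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_electrons(self) -> int:
        return int(sum(a.Z for a in self.atoms) - self.charge)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.R for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([float(a.Z) for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        """Nuclear masses in electron-mass units."""
        return np.array([a.mass for a in self.atoms])

    def require_closed_shell(self):
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count ({self.n_electrons}); only closed-shell "
                "molecules are supported"
            )

    def with_positions(self, positions: np.ndarray) -> "Molecule":
        positions = np.asarray(positions, float).reshape(self.n_atoms, 3)
        atoms = [
            Atom(a.symbol, a.Z, a.mass, positions[i])
            for i, a in enumerate(self.atoms)
        ]
        return Molecule(atoms, self.charge)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        R = self.positions
        Z = self.charges
        for i in range(self.n_atoms):
            for j in range(i):
                e += Z[i] * Z[j] / np.linalg.norm(R[i] - R[j])
        return e


def make_molecule(symbols, positions, charge: int = 0,
                  masses_amu=None) -> Molecule:
    """Build a Molecule from symbols and positions in bohr.

    Masses default to the built-in isotope-averaged table and may be
    overridden per atom with ``masses_amu``.
    """
    atoms = []
    positions = np.asarray(positions, float).reshape(len(symbols), 3)
    for i, s in enumerate(symbols):
        m = masses_amu[i] if masses_amu is not None else element_mass_amu(s)
        atoms.append(Atom(s, element_number(s), m * AMU_TO_ME, positions[i]))
    return Molecule(atoms, charge)


@dataclass
class GaussianShell:
    """A contracted Cartesian Gaussian shell on one atom.

    ``coefs`` multiply *unit-normalized primitives*; on construction the
    contraction is rescaled so every Cartesian component AO has self-overlap
    one (asserted by the integrals module to 1e-12).
    """

    atom_index: int
    l: int
    exponents: np.ndarray
    coefs: np.ndarray

    def __post_init__(self):
        self.exponents = np.asarray(self.exponents, float)
        self.coefs = np.asarray(self.coefs, float)
        if self.l < 0:
            raise ValueError("angular momentum must be non-negative")
        if np.any(self.exponents <= 0):
            raise ValueError("primitive exponents must be positive")
        if self.exponents.shape != self.coefs.shape:
            raise ValueError("exponent/coefficient length mismatch")

    @property
    def n_cartesian(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


@dataclass
class BasisSet:
    """Per-element lists of shells (atom_index unset, -1, until attached)."""

    shells_by_element: dict[str, list[GaussianShell]]
    name: str = ""

    def shells_for(self, mol: Molecule) -> list[GaussianShell]:
        out = []
        for i, atom in enumerate(mol.atoms):
            sym = atom.symbol.capitalize()
            if sym not in self.shells_by_element:
                raise ValueError(f"basis {self.name!r} has no element {sym}")
            for sh in self.shells_by_element[sym]:
                out.append(GaussianShell(i, sh.l, sh.exponents.copy(),
                                         sh.coefs.copy()))
        return out


@dataclass
class GaugeConfig:
    """Spatial (velocity) and magnetic gauge origins, bohr.

    The default common-origin choice places both at (0,0,0).
    """

    O_sp: np.ndarray = field(default_factory=lambda: np.zeros(3))
    O_mag: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.O_sp = np.asarray(self.O_sp, float).reshape(3)
        self.O_mag = np.asarray(self.O_mag, float).reshape(3)
        if not (np.all(np.isfinite(self.O_sp)) and np.all(np.isfinite(self.O_mag))):
            raise ValueError("gauge origins must be finite")


# ----------------------------------------------------------------------------
# XYZ I/O
# ----------------------------------------------------------------------------


def read_xyz(path, unit: str = "angstrom", charge: int = 0) -> Molecule:
    """Read a standard 2-header-line XYZ file.

    ``unit`` declares the file's length unit ('angstrom' or 'bohr');
    positions are converted to bohr internally and atom order is preserved.
    """
    if unit not in ("angstrom", "bohr"):
        raise ValueError("unit must be 'angstrom' or 'bohr'")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty or malformed XYZ file (line 1)")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError(f"{path}: line 1 is not an atom count") from exc
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom lines, file truncated")
    symbols, positions = [], []
    for k in range(n):
        ln = lines[2 + k].split()
        if len(ln) < 4:
            raise ValueError(f"{path}: malformed atom line {2 + k + 1}")
        try:
            xyz = [float(v) for v in ln[1:4]]
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-numeric coordinate on line {2 + k + 1}") from exc
        element_number(ln[0])  # raises for unknown elements
        symbols.append(ln[0])
        positions.append(xyz)
    positions = np.array(positions)
    if unit == "angstrom":
        positions *= BOHR_PER_ANGSTROM
    return make_molecule(symbols, positions, charge=charge)


def write_xyz(path, mol: Molecule, unit: str = "angstrom", comment: str = ""):
    if unit not in ("angstrom", "bohr"):
        raise ValueError("unit must be 'angstrom' or 'bohr'")
    scale = ANGSTROM_PER_BOHR if unit == "angstrom" else 1.0
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{comment}\n")
        for a in mol.atoms:
            x, y, z = a.R * scale
            fh.write(f"{a.symbol:<3s} {x:22.14f} {y:22.14f} {z:22.14f}\n")


# ----------------------------------------------------------------------------
# NWChem-style basis I/O
# ----------------------------------------------------------------------------

_SHELL_L = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}


def read_basis(path_or_text, name: str = "") -> BasisSet:
    """Parse an NWChem-style basis text.

    Element header lines ("O  SP"), followed by rows of one exponent and one
    coefficient per shell (two for SP). SP blocks are split into an S and a P
    shell. Contractions are renormalized downstream so that each Cartesian AO
    is unit-normalized.
    """
    text = path_or_text
    if "\n" not in str(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
        name = name or str(path_or_text)

    shells: dict[str, list[GaussianShell]] = {}
    current = None  # (element, label, rows)

    def flush():
        nonlocal current
        if current is None:
            return
        elem, label, rows = current
        if not rows:
            raise ValueError(f"basis block {elem} {label} has no primitives")
        arr = np.array(rows)
        exps = arr[:, 0]
        if np.any(exps <= 0):
            raise ValueError(f"non-positive exponent in {elem} {label} block")
        if label == "SP":
            if arr.shape[1] != 3:
                raise ValueError("SP block needs exponent + 2 coefficients")
            shells.setdefault(elem, []).append(
                GaussianShell(-1, 0, exps, arr[:, 1]))
            shells.setdefault(elem, []).append(
                GaussianShell(-1, 1, exps, arr[:, 2]))
        else:
            if label not in _SHELL_L:
                raise ValueError(f"unknown shell label {label!r}")
            shells.setdefault(elem, []).append(
                GaussianShell(-1, _SHELL_L[label], exps, arr[:, 1]))
        current = None

    for raw in text.splitlines():
        line = raw.split("#")[0].strip()
        if not line or line.lower() in ("basis", "end") or line.startswith("*"):
            if line.lower() == "end":
                flush()
            continue
        parts = line.split()
        try:
            row = [float(p.replace("D", "E").replace("d", "e")) for p in parts]
            if current is None:
                raise ValueError("primitive row before any shell header")
            current[2].append(row)
            continue
        except ValueError:
            pass
        # header line
        flush()
        if len(parts) != 2:
            raise ValueError(f"malformed basis header line: {raw!r}")
        elem = parts[0].capitalize()
        element_number(elem)
        label = parts[1].upper()
        if label != "SP" and label not in _SHELL_L:
            raise ValueError(f"unknown shell label {label!r}")
        current = (elem, label, [])
    flush()
    if not shells:
        raise ValueError("no shells found in basis input")
    return BasisSet(shells, name=name)


#: built-in basis ladder: minimal -> split-valence -> polarized
BUILTIN_BASES = ("mini", "sv", "pol")


def load_builtin_basis(name: str) -> BasisSet:
    if name not in BUILTIN_BASES:
        raise ValueError(f"unknown built-in basis {name!r}; choose from {BUILTIN_BASES}")
    text = (importlib.resources.files("vcdkit") / "data" / f"{name}.nwbas").read_text()
    return read_basis(text, name=name)


# ----------------------------------------------------------------------------
# simple molecular properties
# ----------------------------------------------------------------------------


def nuclear_dipole(mol: Molecule, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Nuclear part of the electric dipole, sum_l Z_l (R^l - origin)."""
    origin = np.asarray(origin, float)
    return np.einsum("a,ax->x", mol.charges, mol.positions - origin)
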