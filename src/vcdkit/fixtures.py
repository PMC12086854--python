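"""Built-in test molecules.

All geometries were optimized with this package's restricted Hartree-Fock
gradients in the built-in minimal basis (max force 3e-5, rms 1.5e-5 a.u.),
so that the seminumerical Hessians have no spurious imaginary modes:

  h2          equilibrium diatomic (one vibrational mode)
  h2o         planar C2v minimum (achiral: all rotational strengths vanish)
  hof         planar Cs minimum (achiral)
  h2o2_P/M    the chiral C2 skew minimum of hydrogen peroxide and its exact
              mirror image (M = P with x -> -x); HOOH dihedral +/-125 deg at
              this level of theory
  h2o2_planar the achiral trans-planar saddle point (one imaginary mode)

Coordinates in bohr. ``refine_geometry`` re-optimizes a fixture at any basis.
"""

from __future__ import annotations

import numpy as np

from .chemio import Molecule, make_molecule

_GEOMETRIES: dict[str, tuple[list[str], list[list[float]]]] = {
    "h2": (["H", "H"], [
        [0.0, 0.0, -0.67296025],
        [0.0, 0.0, 0.67296025]]),
    "h2o": (["O", "H", "H"], [
        [0.0, 0.0, -0.09699733],
        [1.43256671, 0.0, 1.10449866],
        [-1.43256671, 0.0, 1.10449866]]),
    "hof": (["O", "H", "F"], [
        [-0.02609055, 0.0, 0.10484388],
        [1.83792474, 0.0, -0.26750337],
        [-0.02997582, 0.0, 2.66508042]]),
    "h2o2_P": (["O", "O", "H", "H"], [
        [0.01549241, 0.08953272, 0.07591706],
        [-0.08881685, 0.01917523, 2.71142898],
        [-1.81293040, -0.10941177, -0.36705000],
        [0.78058051, 1.63993343, 3.15439603]]),
    "h2o2_planar": (["O", "O", "H", "H"], [
        [-0.04347234, 0.0, 0.06975610],
        [0.04347234, 0.0, 2.71758993],
        [1.80537773, 0.0, -0.31309218],
        [-1.80537773, 0.0, 3.10043821]]),
}

FIXTURE_NAMES = ("h2", "h2o", "hof", "h2o2_P", "h2o2_M", "h2o2_planar")


def make_fixture(name: str) -> Molecule:
    if name == "h2o2_M":
        sym, pos = _GEOMETRIES["h2o2_P"]
        pos = np.array(pos) * np.array([-1.0, 1.0, 1.0])
        return make_molecule(sym, pos)
    if name == "h2o2":
        name = "h2o2_P"
    if name not in _GEOMETRIES:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    sym, pos = _GEOMETRIES[name]
    return make_molecule(sym, np.array(pos))


def refine_geometry(name: str, basis, **kwargs) -> Molecule:
    """Re-optimize a fixture geometry in the given basis."""
    from .vibspec import optimize_geometry

    return optimize_geometry(make_fixture(name), basis, **kwargs)
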