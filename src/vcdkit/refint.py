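"""Reference integrals over complex-center Cartesian Gaussians.

A slow, pure-python McMurchie-Davidson evaluator used exclusively as a test
oracle: a basis function carrying a linear phase exp(i k.r) is exactly a
Cartesian Gaussian with a complex-shifted center (times a scalar), so the
finite-difference derivative of phased zeroth-order integrals provides an
independent check of every analytic first-order integral (velocity and
magnetic channels). Never used in the production path.
"""

from __future__ import annotations

import math

import numpy as np

from .chemio import SPEED_OF_LIGHT_AU


def boys(n: int, T: complex) -> complex:
    """Boys function for complex argument (series / asymptotic)."""
    if abs(T) < 1e-13:
        return 1.0 / (2 * n + 1) - T / (2 * n + 3)
    if T.real > 38.0:
        # asymptotic with downward-safe direct formula
        val = 0.5 * np.sqrt(np.pi / T)
        for m in range(1, n + 1):
            val = ((2 * m - 1) * val) / (2 * T)
        return val
    term = 1.0 / (2 * n + 1)
    s = term
    k = 1
    while True:
        term = term * 2 * T / (2 * n + 2 * k + 1)
        s += term
        if abs(term) < 1e-17 * abs(s):
            break
        k += 1
    return np.exp(-T) * s


def _E(i, j, t, p, PA, PB, K):
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return K
    if i > 0:
        return (_E(i - 1, j, t - 1, p, PA, PB, K) / (2 * p)
                + PA * _E(i - 1, j, t, p, PA, PB, K)
                + (t + 1) * _E(i - 1, j, t + 1, p, PA, PB, K))
    return (_E(i, j - 1, t - 1, p, PA, PB, K) / (2 * p)
            + PB * _E(i, j - 1, t, p, PA, PB, K)
            + (t + 1) * _E(i, j - 1, t + 1, p, PA, PB, K))


def _R(t, u, v, n, p, PC):
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == u == v == 0:
        return (-2 * p) ** n * boys(n, p * (PC[0] ** 2 + PC[1] ** 2 + PC[2] ** 2))
    if t > 0:
        return ((t - 1) * _R(t - 2, u, v, n + 1, p, PC)
                + PC[0] * _R(t - 1, u, v, n + 1, p, PC))
    if u > 0:
        return ((u - 1) * _R(t, u - 2, v, n + 1, p, PC)
                + PC[1] * _R(t, u - 1, v, n + 1, p, PC))
    return ((v - 1) * _R(t, u, v - 2, n + 1, p, PC)
            + PC[2] * _R(t, u, v - 1, n + 1, p, PC))


class Prim:
    """One Cartesian primitive c * (x-Ax)^lx (y-Ay)^ly (z-Az)^lz exp(-a(r-A)^2)
    with a possibly complex center and coefficient."""

    __slots__ = ("a", "c", "A", "l")

    def __init__(self, a, c, A, l):
        self.a = a
        self.c = c
        self.A = np.asarray(A, complex)
        self.l = tuple(int(x) for x in l)

    def conj(self):
        return Prim(self.a, np.conj(self.c), np.conj(self.A), self.l)


def phase_shift(prim: Prim, k: np.ndarray) -> list[Prim]:
    """exp(i k.r) * prim as a sum of complex-center primitives.

    The Gaussian center shifts by i k/(2a); the polynomial, still referenced
    to the old center, is re-expanded binomially about the new one.
    """
    k = np.asarray(k, float)
    a = prim.a
    Anew = prim.A + 1j * k / (2 * a)
    pref = prim.c * np.exp(1j * np.dot(k, prim.A) - np.dot(k, k) / (4 * a))
    terms = [(pref, (0, 0, 0))]
    # (r_d - A_d)^l_d = sum_m C(l,m) (r_d - Anew_d)^m (Anew_d - A_d)^(l-m)
    out = []
    shift = Anew - prim.A
    for lx in range(prim.l[0] + 1):
        cx = math.comb(prim.l[0], lx) * shift[0] ** (prim.l[0] - lx)
        for ly in range(prim.l[1] + 1):
            cy = math.comb(prim.l[1], ly) * shift[1] ** (prim.l[1] - ly)
            for lz in range(prim.l[2] + 1):
                cz = math.comb(prim.l[2], lz) * shift[2] ** (prim.l[2] - lz)
                out.append(Prim(a, pref * cx * cy * cz, Anew, (lx, ly, lz)))
    return out


def _pair(p1: Prim, p2: Prim):
    p = p1.a + p2.a
    mu = p1.a * p2.a / p
    AB = p1.A - p2.A
    P = (p1.a * p1.A + p2.a * p2.A) / p
    K = [np.exp(-mu * AB[d] ** 2) for d in range(3)]
    return p, P, K


def overlap(f: list[Prim], g: list[Prim]) -> complex:
    """<f|g> (bra conjugated)."""
    out = 0.0j
    for p1 in (x.conj() for x in f):
        for p2 in g:
            p, P, K = _pair(p1, p2)
            val = p1.c * p2.c
            for d in range(3):
                val *= _E(p1.l[d], p2.l[d], 0, p, P[d] - p1.A[d],
                          P[d] - p2.A[d], K[d]) * np.sqrt(np.pi / p)
            out += val
    return out


def kinetic(f: list[Prim], g: list[Prim]) -> complex:
    out = 0.0j
    for p1 in (x.conj() for x in f):
        for p2 in g:
            p, P, K = _pair(p1, p2)
            b = p2.a
            s = [None] * 3
            t = [None] * 3
            for d in range(3):
                i, j = p1.l[d], p2.l[d]
                PA = P[d] - p1.A[d]
                PB = P[d] - p2.A[d]
                sp = np.sqrt(np.pi / p)
                s[d] = _E(i, j, 0, p, PA, PB, K[d]) * sp
                tv = -2.0 * b * b * _E(i, j + 2, 0, p, PA, PB, K[d]) * sp
                tv += b * (2 * j + 1) * _E(i, j, 0, p, PA, PB, K[d]) * sp
                if j >= 2:
                    tv -= 0.5 * j * (j - 1) * _E(i, j - 2, 0, p, PA, PB, K[d]) * sp
                t[d] = tv
            out += p1.c * p2.c * (t[0] * s[1] * s[2] + s[0] * t[1] * s[2]
                                  + s[0] * s[1] * t[2])
    return out


def nuclear(f: list[Prim], g: list[Prim], mol) -> complex:
    out = 0.0j
    for p1 in (x.conj() for x in f):
        for p2 in g:
            p, P, K = _pair(p1, p2)
            pref = p1.c * p2.c * 2 * np.pi / p
            for c in range(mol.n_atoms):
                acc = 0.0j
                for t in range(p1.l[0] + p2.l[0] + 1):
                    ex = _E(p1.l[0], p2.l[0], t, p, P[0] - p1.A[0],
                            P[0] - p2.A[0], K[0])
                    for u in range(p1.l[1] + p2.l[1] + 1):
                        ey = _E(p1.l[1], p2.l[1], u, p, P[1] - p1.A[1],
                                P[1] - p2.A[1], K[1])
                        for v in range(p1.l[2] + p2.l[2] + 1):
                            ez = _E(p1.l[2], p2.l[2], v, p, P[2] - p1.A[2],
                                    P[2] - p2.A[2], K[2])
                            acc += ex * ey * ez * _R(t, u, v, 0, p,
                                                     P - mol.atoms[c].R)
                out += -mol.atoms[c].Z * pref * acc
    return out


def eri(f, g, h, k) -> complex:
    """(f g | h k), bra functions (f and h) conjugated."""
    out = 0.0j
    for p1 in (x.conj() for x in f):
        for p2 in g:
            p, P, Kb = _pair(p1, p2)
            for p3 in (x.conj() for x in h):
                for p4 in k:
                    q, Q, Kk = _pair(p3, p4)
                    al = p * q / (p + q)
                    pref = (p1.c * p2.c * p3.c * p4.c
                            * 2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q)))
                    acc = 0.0j
                    lb = [p1.l[d] + p2.l[d] for d in range(3)]
                    lk = [p3.l[d] + p4.l[d] for d in range(3)]
                    for t in range(lb[0] + 1):
                        ex = _E(p1.l[0], p2.l[0], t, p, P[0] - p1.A[0],
                                P[0] - p2.A[0], Kb[0])
                        for u in range(lb[1] + 1):
                            ey = _E(p1.l[1], p2.l[1], u, p, P[1] - p1.A[1],
                                    P[1] - p2.A[1], Kb[1])
                            for v in range(lb[2] + 1):
                                ez = _E(p1.l[2], p2.l[2], v, p, P[2] - p1.A[2],
                                        P[2] - p2.A[2], Kb[2])
                                for tt in range(lk[0] + 1):
                                    fx = _E(p3.l[0], p4.l[0], tt, q,
                                            Q[0] - p3.A[0], Q[0] - p4.A[0], Kk[0])
                                    for uu in range(lk[1] + 1):
                                        fy = _E(p3.l[1], p4.l[1], uu, q,
                                                Q[1] - p3.A[1], Q[1] - p4.A[1], Kk[1])
                                        for vv in range(lk[2] + 1):
                                            fz = _E(p3.l[2], p4.l[2], vv, q,
                                                    Q[2] - p3.A[2], Q[2] - p4.A[2], Kk[2])
                                            sgn = (-1.0) ** (tt + uu + vv)
                                            acc += (ex * ey * ez * fx * fy * fz
                                                    * sgn
                                                    * _R(t + tt, u + uu, v + vv,
                                                         0, al, P - Q))
                    out += pref * acc
    return out


# ----------------------------------------------------------------------------
# phased AO sets
# ----------------------------------------------------------------------------


def plain_aos(engine) -> list[list[Prim]]:
    """The engine's contracted AOs as reference primitive lists."""
    out = []
    for r in range(engine.n_ao):
        idx = np.nonzero(engine.W[r])[0]
        out.append([Prim(engine.prim_alpha[i], engine.W[r, i],
                         engine.prim_center[i], engine.prim_l[i])
                    for i in idx])
    return out


def vao_aos(engine, eps: float, lam: int, beta: int, O_sp) -> list[list[Prim]]:
    """Velocity atomic orbitals at finite nuclear velocity eps:
    functions on atom lam carry exp(i eps (r - O_sp)_beta)."""
    k = np.zeros(3)
    k[beta] = eps
    phase0 = np.exp(-1j * eps * O_sp[beta])
    out = []
    for r, ao in enumerate(plain_aos(engine)):
        if engine.ao_atom[r] == lam:
            phased = []
            for prim in ao:
                for q in phase_shift(prim, k):
                    q.c = q.c * phase0
                    phased.append(q)
            out.append(phased)
        else:
            out.append(ao)
    return out


def giao_aos(engine, B: np.ndarray, O_mag) -> list[list[Prim]]:
    """Gauge-including AOs at finite field B:
    chi~_nu = exp[-(i/2c)(B x (R_nu - O_mag)).r] chi_nu."""
    out = []
    for r, ao in enumerate(plain_aos(engine)):
        Rn = np.real(ao[0].A)
        k = -np.cross(B, Rn - np.asarray(O_mag)) / (2 * SPEED_OF_LIGHT_AU)
        phased = []
        for prim in ao:
            phased.extend(phase_shift(prim, k))
        out.append(phased)
    return out
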