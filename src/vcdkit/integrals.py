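"""Analytic Gaussian integrals: core one-/two-electron matrices, moment /
momentum / angular-momentum integrals, and every first-order (perturbed)
integral required by the nuclear-displacement (NDPT), nuclear-velocity
(NVPT) and magnetic-field (MFPT) perturbation channels.

Design
------
McMurchie-Davidson recursions over Cartesian Gaussians, jitted with numba.
All operator-modified one-electron matrices (moments about arbitrary points,
nabla, angular momentum, center derivatives, and their products) are obtained
*exactly* through linear maps acting on an extended primitive table that is
closed under raising the angular momentum by two: multiplying a primitive by
(r_g - A_g) raises l_g, and d/dA_g mixes l_g +- 1. No numerical
differentiation occurs in the production path; finite-difference versions of
every first-order integral exist only as test oracles.

Imaginary matrices (velocity and magnetic channels) are stored as the real
matrix multiplying i ("times i" convention), so all solver algebra stays in
real arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .chemio import BasisSet, GaugeConfig, Molecule

# ============================================================================
# numba kernels
# ============================================================================


@njit(cache=True)
def _boys_fill(T, nmax, out):
    """Boys function F_n(T) for n = 0..nmax (scalar T >= 0)."""
    if T < 1e-13:
        for n in range(nmax + 1):
            out[n] = 1.0 / (2.0 * n + 1.0) - T / (2.0 * n + 3.0)
        return
    if T < 35.0:
        # Kummer series at nmax, then downward recursion (stable)
        expT = np.exp(-T)
        term = 1.0 / (2.0 * nmax + 1.0)
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (2.0 * nmax + 2.0 * k + 1.0)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        out[nmax] = expT * s
        for n in range(nmax - 1, -1, -1):
            out[n] = (2.0 * T * out[n + 1] + expT) / (2.0 * n + 1.0)
    else:
        # asymptotic F_0 + upward recursion (stable for large T)
        expT = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for n in range(nmax):
            out[n + 1] = ((2.0 * n + 1.0) * out[n] - expT) / (2.0 * T)


@njit(cache=True)
def _E_table(imax, jmax, p, PA, PB, Kab, E):
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction.

    E has shape at least (imax+1, jmax+1, imax+jmax+1); E[i,j,t] is filled
    for t <= i+j, with E[0,0,0] = Kab = exp(-mu*AB^2).
    """
    q = 1.0 / (2.0 * p)
    for i in range(imax + 1):
        for j in range(jmax + 1):
            for t in range(imax + jmax + 1):
                E[i, j, t] = 0.0
    E[0, 0, 0] = Kab
    for i in range(1, imax + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t]
            if t > 0:
                v += q * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                v += (t + 1.0) * E[i - 1, 0, t + 1]
            E[i, 0, t] = v
    for j in range(1, jmax + 1):
        for i in range(imax + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t]
                if t > 0:
                    v += q * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    v += (t + 1.0) * E[i, j - 1, t + 1]
                E[i, j, t] = v


@njit(cache=True)
def _R_table(ntot, p, X, Y, Z, boys, R):
    """Hermite Coulomb integrals R^0_{tuv} for t+u+v <= ntot.

    R has shape at least (ntot+1,)*4 indexed [n,t,u,v]; boys holds
    F_n(p*(X^2+Y^2+Z^2)) for n = 0..ntot.
    """
    for n in range(ntot + 1):
        for t in range(ntot + 1):
            for u in range(ntot + 1):
                for v in range(ntot + 1):
                    R[n, t, u, v] = 0.0
    m2p = 1.0
    for n in range(ntot + 1):
        R[n, 0, 0, 0] = m2p * boys[n]
        m2p *= -2.0 * p
    for n in range(ntot - 1, -1, -1):
        for t in range(ntot - n + 1):
            for u in range(ntot - n - t + 1):
                for v in range(ntot - n - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val


@njit(cache=True)
def _oneel_kernel(cen, lv, al, atpos, S, T, V):
    """Overlap, kinetic and per-nucleus 1/|r-C| matrices over primitives.

    cen (np,3) centers, lv (np,3) angular momenta, al (np,) exponents;
    atpos (nat,3). Fills S (np,np), T (np,np), V (nat,np,np); all symmetric.
    """
    npr = cen.shape[0]
    nat = atpos.shape[0]
    LM = 0
    for P in range(npr):
        s = lv[P, 0] + lv[P, 1] + lv[P, 2]
        if s > LM:
            LM = s
    # E needs jmax+2 for the kinetic formula
    Esz = 2 * LM + 3
    E = np.zeros((3, LM + 1, LM + 3, Esz))
    ntot_max = 2 * LM
    Rt = np.zeros((ntot_max + 1, ntot_max + 1, ntot_max + 1, ntot_max + 1))
    boys = np.zeros(ntot_max + 1)
    sq = np.zeros(3)
    tk = np.zeros(3)
    for P in range(npr):
        a = al[P]
        for Q in range(P + 1):
            b = al[Q]
            p = a + b
            mu = a * b / p
            Px = (a * cen[P, 0] + b * cen[Q, 0]) / p
            Py = (a * cen[P, 1] + b * cen[Q, 1]) / p
            Pz = (a * cen[P, 2] + b * cen[Q, 2]) / p
            AB2 = ((cen[P, 0] - cen[Q, 0]) ** 2 + (cen[P, 1] - cen[Q, 1]) ** 2
                   + (cen[P, 2] - cen[Q, 2]) ** 2)
            if mu * AB2 > 46.0:   # exp(-46) ~ 1e-20: negligible pair
                S[P, Q] = 0.0
                S[Q, P] = 0.0
                T[P, Q] = 0.0
                T[Q, P] = 0.0
                for c in range(nat):
                    V[c, P, Q] = 0.0
                    V[c, Q, P] = 0.0
                continue
            spp = np.sqrt(np.pi / p)
            for d in range(3):
                i = lv[P, d]
                j = lv[Q, d]
                PA = (Px, Py, Pz)[d] - cen[P, d]
                PB = (Px, Py, Pz)[d] - cen[Q, d]
                Kab = np.exp(-mu * (cen[P, d] - cen[Q, d]) ** 2)
                _E_table(i, j + 2, p, PA, PB, Kab, E[d])
                sq[d] = E[d][i, j, 0] * spp
                # 1D kinetic: -2b^2 S(j+2) + b(2j+1) S(j) - j(j-1)/2 S(j-2)
                tval = -2.0 * b * b * E[d][i, j + 2, 0] * spp
                tval += b * (2.0 * j + 1.0) * E[d][i, j, 0] * spp
                if j >= 2:
                    tval -= 0.5 * j * (j - 1.0) * E[d][i, j - 2, 0] * spp
                tk[d] = tval
            Sv = sq[0] * sq[1] * sq[2]
            Tv = tk[0] * sq[1] * sq[2] + sq[0] * tk[1] * sq[2] + sq[0] * sq[1] * tk[2]
            S[P, Q] = Sv
            S[Q, P] = Sv
            T[P, Q] = Tv
            T[Q, P] = Tv
            ltot = (lv[P, 0] + lv[P, 1] + lv[P, 2]
                    + lv[Q, 0] + lv[Q, 1] + lv[Q, 2])
            for c in range(nat):
                X = Px - atpos[c, 0]
                Y = Py - atpos[c, 1]
                Z = Pz - atpos[c, 2]
                _boys_fill(p * (X * X + Y * Y + Z * Z), ltot, boys)
                _R_table(ltot, p, X, Y, Z, boys, Rt)
                acc = 0.0
                for t in range(lv[P, 0] + lv[Q, 0] + 1):
                    et = E[0][lv[P, 0], lv[Q, 0], t]
                    for u in range(lv[P, 1] + lv[Q, 1] + 1):
                        eu = E[1][lv[P, 1], lv[Q, 1], u]
                        for v in range(lv[P, 2] + lv[Q, 2] + 1):
                            acc += et * eu * E[2][lv[P, 2], lv[Q, 2], v] * Rt[0, t, u, v]
                acc *= 2.0 * np.pi / p
                V[c, P, Q] = acc
                V[c, Q, P] = acc


@njit(cache=True)
def _eri_kernel(cenA, nprA, alA, cfA, lvA,
                cenB, nprB, alB, cfB, lvB,
                cenC, nprC, alC, cfC, lvC,
                cenD, nprD, alD, cfD, lvD,
                same_all, out):
    """Two-electron repulsion tensor (ab|cd) over four contracted AO sets.

    Each set: centers (n,3), primitive counts (n,), exponents/coefficients
    (n,mx), per-primitive angular momenta (n,mx,3). ``same_all`` enables the
    8-fold permutational fast path (requires identical sets).
    """
    na, nb, nc, nd = cenA.shape[0], cenB.shape[0], cenC.shape[0], cenD.shape[0]
    LF = 4  # max single-function angular momentum supported
    Eb = np.zeros((3, LF + 1, LF + 1, 2 * LF + 1))
    Ek = np.zeros((3, LF + 1, LF + 1, 2 * LF + 1))
    NT = 4 * LF
    Rt = np.zeros((NT + 1, NT + 1, NT + 1, NT + 1))
    boys = np.zeros(NT + 1)
    mxb = alA.shape[1] * alB.shape[1]
    # per bra-primitive-pair data
    bp_p = np.zeros(mxb)
    bp_P = np.zeros((mxb, 3))
    bp_c = np.zeros(mxb)
    bp_E = np.zeros((mxb, 3, LF + 1, LF + 1, 2 * LF + 1))
    bp_l = np.zeros((mxb, 2, 3), np.int64)
    for a in range(na):
        for b in range(nb):
            if same_all and b > a:
                continue
            # ---- bra pair primitive data
            nbp = 0
            for i in range(nprA[a]):
                for j in range(nprB[b]):
                    aa = alA[a, i]
                    ab = alB[b, j]
                    p = aa + ab
                    mu = aa * ab / p
                    AB2 = 0.0
                    for d in range(3):
                        AB2 += (cenA[a, d] - cenB[b, d]) ** 2
                    if mu * AB2 > 46.0:
                        continue
                    bp_p[nbp] = p
                    bp_c[nbp] = cfA[a, i] * cfB[b, j]
                    for d in range(3):
                        Pd = (aa * cenA[a, d] + ab * cenB[b, d]) / p
                        bp_P[nbp, d] = Pd
                        il = lvA[a, i, d]
                        jl = lvB[b, j, d]
                        bp_l[nbp, 0, d] = il
                        bp_l[nbp, 1, d] = jl
                        Kab = np.exp(-mu * (cenA[a, d] - cenB[b, d]) ** 2)
                        _E_table(il, jl, p, Pd - cenA[a, d], Pd - cenB[b, d],
                                 Kab, bp_E[nbp, d])
                    nbp += 1
            if nbp == 0:
                continue
            for c in range(nc):
                for dd in range(nd):
                    if same_all:
                        if dd > c:
                            continue
                        if c * (c + 1) // 2 + dd > a * (a + 1) // 2 + b:
                            continue
                    val = 0.0
                    for i in range(nprC[c]):
                        for j in range(nprD[dd]):
                            ac = alC[c, i]
                            ad = alD[dd, j]
                            q = ac + ad
                            muk = ac * ad / q
                            CD2 = 0.0
                            for d in range(3):
                                CD2 += (cenC[c, d] - cenD[dd, d]) ** 2
                            if muk * CD2 > 46.0:
                                continue
                            Qx = (ac * cenC[c, 0] + ad * cenD[dd, 0]) / q
                            Qy = (ac * cenC[c, 1] + ad * cenD[dd, 1]) / q
                            Qz = (ac * cenC[c, 2] + ad * cenD[dd, 2]) / q
                            lk = np.zeros((2, 3), np.int64)
                            for d in range(3):
                                il = lvC[c, i, d]
                                jl = lvD[dd, j, d]
                                lk[0, d] = il
                                lk[1, d] = jl
                                Qd = (Qx, Qy, Qz)[d]
                                Kcd = np.exp(-muk * (cenC[c, d] - cenD[dd, d]) ** 2)
                                _E_table(il, jl, q, Qd - cenC[c, d],
                                         Qd - cenD[dd, d], Kcd, Ek[d])
                            ck = cfC[c, i] * cfD[dd, j]
                            lkx = lk[0, 0] + lk[1, 0]
                            lky = lk[0, 1] + lk[1, 1]
                            lkz = lk[0, 2] + lk[1, 2]
                            for bp in range(nbp):
                                p = bp_p[bp]
                                alpha = p * q / (p + q)
                                X = bp_P[bp, 0] - Qx
                                Y = bp_P[bp, 1] - Qy
                                Z = bp_P[bp, 2] - Qz
                                lbx = bp_l[bp, 0, 0] + bp_l[bp, 1, 0]
                                lby = bp_l[bp, 0, 1] + bp_l[bp, 1, 1]
                                lbz = bp_l[bp, 0, 2] + bp_l[bp, 1, 2]
                                ntot = lbx + lby + lbz + lkx + lky + lkz
                                _boys_fill(alpha * (X * X + Y * Y + Z * Z),
                                           ntot, boys)
                                _R_table(ntot, alpha, X, Y, Z, boys, Rt)
                                pref = (2.0 * np.pi ** 2.5
                                        / (p * q * np.sqrt(p + q)))
                                acc = 0.0
                                for t in range(lbx + 1):
                                    et = bp_E[bp, 0, bp_l[bp, 0, 0],
                                              bp_l[bp, 1, 0], t]
                                    if et == 0.0:
                                        continue
                                    for u in range(lby + 1):
                                        eu = bp_E[bp, 1, bp_l[bp, 0, 1],
                                                  bp_l[bp, 1, 1], u]
                                        if eu == 0.0:
                                            continue
                                        for v in range(lbz + 1):
                                            ev = bp_E[bp, 2, bp_l[bp, 0, 2],
                                                      bp_l[bp, 1, 2], v]
                                            if ev == 0.0:
                                                continue
                                            etuv = et * eu * ev
                                            for tt in range(lkx + 1):
                                                ft = Ek[0][lk[0, 0], lk[1, 0], tt]
                                                if ft == 0.0:
                                                    continue
                                                for uu in range(lky + 1):
                                                    fu = Ek[1][lk[0, 1], lk[1, 1], uu]
                                                    if fu == 0.0:
                                                        continue
                                                    for vv in range(lkz + 1):
                                                        fv = Ek[2][lk[0, 2],
                                                                   lk[1, 2], vv]
                                                        if fv == 0.0:
                                                            continue
                                                        sgn = 1.0
                                                        if (tt + uu + vv) % 2 == 1:
                                                            sgn = -1.0
                                                        acc += (etuv * ft * fu
                                                                * fv * sgn
                                                                * Rt[0, t + tt,
                                                                     u + uu,
                                                                     v + vv])
                                val += pref * acc * bp_c[bp] * ck
                    out[a, b, c, dd] = val
                    if same_all:
                        out[b, a, c, dd] = val
                        out[a, b, dd, c] = val
                        out[b, a, dd, c] = val
                        out[c, dd, a, b] = val
                        out[dd, c, a, b] = val
                        out[c, dd, b, a] = val
                        out[dd, c, b, a] = val


# ============================================================================
# primitive table, maps, AO sets
# ============================================================================

_CART_ORDER: dict[int, list[tuple[int, int, int]]] = {}


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian component ordering for shell l (lexicographic, x-major:
    l=1 -> x,y,z; l=2 -> xx,xy,xz,yy,yz,zz)."""
    if l not in _CART_ORDER:
        comps = [(l - a, a - b, b) for a in range(l + 1) for b in range(a + 1)]
        _CART_ORDER[l] = comps
    return _CART_ORDER[l]


def _double_fact(n: int) -> float:
    out = 1.0
    k = n
    while k > 1:
        out *= k
        k -= 2
    return out


def _prim_pair_overlap(a1, a2, l) -> float:
    """Self-center overlap of two unnormalized primitives with equal l."""
    p = a1 + a2
    val = (np.pi / p) ** 1.5
    for ld in l:
        val *= _double_fact(2 * ld - 1) / (2.0 * p) ** ld
    return val


@dataclass
class AOSetArrays:
    """Flat contracted-function arrays consumed by the ERI kernel."""

    cen: np.ndarray
    nprim: np.ndarray
    alpha: np.ndarray
    coef: np.ndarray
    lvec: np.ndarray

    @property
    def n(self):
        return self.cen.shape[0]


class AOBasis:
    """Contracted Cartesian AO basis over an extended primitive table.

    The table contains, for every unique (center, exponent), all Cartesian
    angular momenta up to the shell maximum plus a margin of two, so that
    moment multiplication and center differentiation act as exact linear
    maps on primitive coefficient vectors.
    """

    _MARGIN = 2

    def __init__(self, mol: Molecule, basis: BasisSet):
        self.mol = mol
        self.basis = basis
        self.shells = basis.shells_for(mol)

        # -- unique (atom, alpha) -> lmax
        key_lmax: dict[tuple[int, float], int] = {}
        for sh in self.shells:
            for a in sh.exponents:
                k = (sh.atom_index, float(a))
                key_lmax[k] = max(key_lmax.get(k, -1), sh.l)

        # -- extended primitive table
        pcen, plv, pal, patom = [], [], [], []
        self._pindex: dict[tuple[int, float, tuple[int, int, int]], int] = {}
        for (ai, alpha), lmax in sorted(key_lmax.items()):
            for L in range(lmax + self._MARGIN + 1):
                for comp in cartesian_components(L):
                    self._pindex[(ai, alpha, comp)] = len(pcen)
                    pcen.append(mol.atoms[ai].R)
                    plv.append(comp)
                    pal.append(alpha)
                    patom.append(ai)
        self.prim_center = np.array(pcen)
        self.prim_l = np.array(plv, dtype=np.int64)
        self.prim_alpha = np.array(pal)
        self.prim_atom = np.array(patom, dtype=np.int64)
        self.n_prim = len(pal)

        # -- AO list and contraction matrix W (nao x nprim)
        ao_rows, ao_atom, ao_l, ao_shell = [], [], [], []
        for si, sh in enumerate(self.shells):
            for comp in cartesian_components(sh.l):
                row = np.zeros(self.n_prim)
                for a, c in zip(sh.exponents, sh.coefs):
                    pn = self._prim_norm(a, comp)
                    row[self._pindex[(sh.atom_index, float(a), comp)]] += c * pn
                ao_rows.append(row)
                ao_atom.append(sh.atom_index)
                ao_l.append(comp)
                ao_shell.append(si)
        self.W = np.array(ao_rows)
        self.ao_atom = np.array(ao_atom, dtype=np.int64)
        self.ao_l = np.array(ao_l, dtype=np.int64)
        self.ao_shell = np.array(ao_shell, dtype=np.int64)
        self.n_ao = self.W.shape[0]

        # -- renormalize every contracted Cartesian AO to unit self-overlap
        for r in range(self.n_ao):
            idx = np.nonzero(self.W[r])[0]
            s = 0.0
            for i in idx:
                for j in idx:
                    s += (self.W[r, i] * self.W[r, j]
                          * _prim_pair_overlap(self.prim_alpha[i],
                                               self.prim_alpha[j],
                                               self.prim_l[i]))
            self.W[r] /= np.sqrt(s)

        self._prim_mats = None   # (S, T, V[nat]) over primitives
        self._maps: dict = {}
        self._eri_cache: dict = {}

    # -- primitive-level helpers -------------------------------------------

    @staticmethod
    def _prim_norm(alpha: float, l) -> float:
        L = sum(l)
        val = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
        for ld in l:
            val /= np.sqrt(_double_fact(2 * ld - 1))
        return val

    def _ensure_prim_mats(self):
        if self._prim_mats is None:
            S = np.zeros((self.n_prim, self.n_prim))
            T = np.zeros_like(S)
            V = np.zeros((self.mol.n_atoms, self.n_prim, self.n_prim))
            _oneel_kernel(self.prim_center, self.prim_l, self.prim_alpha,
                          self.mol.positions, S, T, V)
            self._prim_mats = (S, T, V)
        return self._prim_mats

    # -- linear maps on the primitive space --------------------------------

    def _lookup(self, atom, alpha, comp):
        return self._pindex.get((atom, float(alpha), tuple(int(c) for c in comp)))

    def raise_map(self, g: int) -> np.ndarray:
        """Map of multiplying by (r_g - A_g) (center-referenced moment)."""
        key = ("raise", g)
        if key not in self._maps:
            M = np.zeros((self.n_prim, self.n_prim))
            for p in range(self.n_prim):
                comp = self.prim_l[p].copy()
                comp[g] += 1
                q = self._lookup(self.prim_atom[p], self.prim_alpha[p], comp)
                if q is not None:
                    M[p, q] = 1.0
            self._maps[key] = M
        return self._maps[key]

    def moment_map(self, g: int, origin) -> np.ndarray:
        """Map of multiplying by (r_g - origin_g)."""
        shift = self.prim_center[:, g] - float(origin[g])
        return self.raise_map(g) + np.diag(shift)

    def dcenter_map(self, g: int) -> np.ndarray:
        """Map of d/dA_g (derivative with respect to the function's own
        center): 2*alpha * raise - l_g * lower."""
        key = ("dcenter", g)
        if key not in self._maps:
            M = 2.0 * self.prim_alpha[:, None] * self.raise_map(g)
            for p in range(self.n_prim):
                lg = self.prim_l[p, g]
                if lg > 0:
                    comp = self.prim_l[p].copy()
                    comp[g] -= 1
                    q = self._lookup(self.prim_atom[p], self.prim_alpha[p], comp)
                    M[p, q] -= lg
            self._maps[key] = M
        return self._maps[key]

    def nabla_map(self, g: int) -> np.ndarray:
        """Map of d/dr_g acting on the function (= -d/dA_g)."""
        return -self.dcenter_map(g)

    def atom_prim_mask(self, lam: int) -> np.ndarray:
        return (self.prim_atom == lam).astype(float)

    def ao_on_atom(self, lam: int) -> np.ndarray:
        return self.ao_atom == lam

    # -- one-electron AO matrices ------------------------------------------

    def matrix(self, core: str = "S", bra_map=None, ket_map=None,
               atom: int | None = None) -> np.ndarray:
        """AO matrix <map_b chi_mu | Core | map_k chi_nu>.

        core: 'S' (identity/overlap), 'T' (kinetic), 'V' (1/|r-C| for
        ``atom`` C, positive sign), 'Vne' (full nuclear attraction,
        -sum_C Z_C/|r-C|).
        """
        S, T, V = self._ensure_prim_mats()
        if core == "S":
            M = S
        elif core == "T":
            M = T
        elif core == "V":
            M = V[atom]
        elif core == "Vne":
            M = -np.einsum("a,aij->ij", self.mol.charges, V)
        else:
            raise ValueError(f"unknown core {core!r}")
        Wb = self.W if bra_map is None else self.W @ bra_map
        Wk = self.W if ket_map is None else self.W @ ket_map
        return Wb @ M @ Wk.T

    # -- AO sets for ERI kernels -------------------------------------------

    def _ao_set(self, mapmat=None) -> AOSetArrays:
        """Flatten (optionally mapped) AOs for the ERI kernel."""
        W = self.W if mapmat is None else self.W @ mapmat
        rows = []
        maxp = 0
        for r in range(self.n_ao):
            idx = np.nonzero(np.abs(W[r]) > 1e-300)[0]
            rows.append(idx)
            maxp = max(maxp, len(idx))
        maxp = max(maxp, 1)
        n = self.n_ao
        cen = np.zeros((n, 3))
        nprim = np.zeros(n, dtype=np.int64)
        alpha = np.ones((n, maxp))
        coef = np.zeros((n, maxp))
        lvec = np.zeros((n, maxp, 3), dtype=np.int64)
        for r, idx in enumerate(rows):
            nprim[r] = len(idx)
            if len(idx):
                cen[r] = self.prim_center[idx[0]]
            for k, pi in enumerate(idx):
                alpha[r, k] = self.prim_alpha[pi]
                coef[r, k] = W[r, pi]
                lvec[r, k] = self.prim_l[pi]
        return AOSetArrays(cen, nprim, alpha, coef, lvec)

    def eri(self) -> np.ndarray:
        """Base two-electron tensor (mu nu | ka si), chemists' notation."""
        if "base" not in self._eri_cache:
            s = self._ao_set()
            out = np.zeros((s.n,) * 4)
            _eri_kernel(s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        True, out)
            self._eri_cache["base"] = out
        return self._eri_cache["base"]

    def _eri_aug(self, mapmat, key) -> np.ndarray:
        """Rectangular ERI tensor with the first index replaced by the mapped
        AO set: (map(mu) nu | ka si)."""
        if key not in self._eri_cache:
            sa = self._ao_set(mapmat)
            s = self._ao_set()
            out = np.zeros((sa.n, s.n, s.n, s.n))
            _eri_kernel(sa.cen, sa.nprim, sa.alpha, sa.coef, sa.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        s.cen, s.nprim, s.alpha, s.coef, s.lvec,
                        False, out)
            self._eri_cache[key] = out
        return self._eri_cache[key]

    def eri_raised(self, g: int) -> np.ndarray:
        """((r_g - A_mu) chi_mu, nu | ka, si): center-referenced moment on
        the first index."""
        return self._eri_aug(self.raise_map(g), ("raised", g))

    def eri_dcenter(self, g: int) -> np.ndarray:
        """(d chi_mu / dA_g, nu | ka, si): own-center derivative on the
        first index."""
        return self._eri_aug(self.dcenter_map(g), ("dcenter", g))

    def clear_eri_cache(self):
        self._eri_cache.clear()


# ============================================================================
# integral containers and spec-level operations
# ============================================================================


@dataclass
class IntegralSet:
    """Zeroth-order integrals over the AO list.

    Nabla[g] is the matrix of d/dr_g (antisymmetric); the matrix of the
    momentum operator -i*nabla is -i*Nabla. AngMom[g] is
    <mu|((r-O_mag) x nabla)_g|nu> (antisymmetric).
    """

    S0: np.ndarray
    T: np.ndarray
    Vne: np.ndarray
    ERI: np.ndarray
    Dip: np.ndarray
    Nabla: np.ndarray
    AngMom: np.ndarray
    gauge: GaugeConfig
    engine: AOBasis = field(repr=False, default=None)

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.Vne


@dataclass
class PerturbedIntegrals:
    """First-order integrals for one channel.

    ``flavor`` is 'real_symmetric' (nuclear displacement) or
    'imag_antihermitian' (nuclear velocity / magnetic field). For imaginary
    channels S1 and the H1 pieces hold the *real factor multiplying i*; the
    stored matrices are then real antisymmetric.
    """

    channel: str
    flavor: str
    S1: np.ndarray
    pieces: dict = field(default_factory=dict)

    def __post_init__(self):
        tol = 1e-10 * max(1.0, float(np.max(np.abs(self.S1))))
        if self.flavor == "real_symmetric":
            if np.max(np.abs(self.S1 - self.S1.T)) > tol:
                raise ValueError(f"{self.channel}: S1 not symmetric")
        elif self.flavor == "imag_antihermitian":
            if np.max(np.abs(self.S1 + self.S1.T)) > tol:
                raise ValueError(f"{self.channel}: stored S1 not antisymmetric")
        else:
            raise ValueError(f"unknown flavor {self.flavor!r}")


def compute_core_integrals(mol: Molecule, basis: BasisSet,
                           gauge: GaugeConfig | None = None,
                           engine: AOBasis | None = None) -> IntegralSet:
    """All zeroth-order matrices: S0, T, Vne, ERI, dipole moments about
    O_sp, nabla, and angular momentum about O_mag."""
    gauge = gauge or GaugeConfig()
    eng = engine or AOBasis(mol, basis)
    S0 = eng.matrix("S")
    ev = np.linalg.eigvalsh(S0)
    if ev[0] < 1e-9:
        raise ValueError(
            f"basis is (near-)linearly dependent: min overlap eigenvalue "
            f"{ev[0]:.3e} < 1e-9; choose a less redundant basis")
    T = eng.matrix("T")
    Vne = eng.matrix("Vne")
    Dip = np.array([eng.matrix("S", ket_map=eng.moment_map(g, gauge.O_sp))
                    for g in range(3)])
    Nabla = np.array([eng.matrix("S", ket_map=eng.nabla_map(g))
                      for g in range(3)])
    eps = _LEVI
    AngMom = np.zeros((3, eng.n_ao, eng.n_ao))
    for a in range(3):
        for g in range(3):
            for d in range(3):
                if eps[a, g, d] == 0:
                    continue
                km = eng.nabla_map(d) @ eng.moment_map(g, gauge.O_mag)
                AngMom[a] += eps[a, g, d] * eng.matrix("S", ket_map=km)
    return IntegralSet(S0, T, Vne, eng.eri(), Dip, Nabla, AngMom, gauge, eng)


_LEVI = np.zeros((3, 3, 3))
for _i, _j, _k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _LEVI[_i, _j, _k] = 1.0
    _LEVI[_i, _k, _j] = -1.0


def levi_civita() -> np.ndarray:
    return _LEVI


# ----------------------------------------------------------------------------
# R channels: nuclear displacement derivatives
# ----------------------------------------------------------------------------


def nuclear_derivative_integrals(ints: IntegralSet, lam: int, beta: int
                                 ) -> PerturbedIntegrals:
    """dS/dR, dT/dR, dVne/dR for displacing atom ``lam`` along ``beta``.

    The basis-center derivative follows from the l+-1 identity; the operator
    (Hellmann-Feynman) derivative of the attraction to the moving nucleus is
    recovered from translational invariance of the pair integral:
    dV_C/dC = -(d/dA + d/dB) V_C at fixed operator.
    """
    eng: AOBasis = ints.engine
    mol = eng.mol
    sel = np.diag(eng.atom_prim_mask(lam))
    dmap = eng.dcenter_map(beta) @ sel  # nonzero only for prims on lam
    bra = sel @ eng.dcenter_map(beta)   # bra-side: apply to bra functions

    dS = eng.matrix("S", bra_map=bra) + eng.matrix("S", ket_map=dmap)
    dT = eng.matrix("T", bra_map=bra) + eng.matrix("T", ket_map=dmap)

    dV = np.zeros_like(dS)
    Z = mol.charges
    for c in range(mol.n_atoms):
        bc = eng.matrix("V", atom=c, bra_map=bra)
        kc = eng.matrix("V", atom=c, ket_map=dmap)
        dV -= Z[c] * (bc + kc)
        if c == lam:
            # operator derivative: d/dC = -(d/dA + d/dB) over ALL pairs
            bAll = eng.matrix("V", atom=c, bra_map=eng.dcenter_map(beta))
            kAll = eng.matrix("V", atom=c, ket_map=eng.dcenter_map(beta))
            dV -= Z[c] * (-(bAll + kAll))
    return PerturbedIntegrals(
        channel=f"R[{lam},{'xyz'[beta]}]", flavor="real_symmetric",
        S1=dS, pieces={"dT": dT, "dVne": dV, "dh": dT + dV,
                       "lam": lam, "beta": beta})


# ----------------------------------------------------------------------------
# V channels: nuclear velocity (VAO) first-order integrals
# ----------------------------------------------------------------------------


def vao_first_order(ints: IntegralSet, lam: int, beta: int) -> PerturbedIntegrals:
    """First-order velocity-gauge integrals for channel (lam, beta).

    The velocity atomic orbital attaches the phase exp(i Rdot.(r - O_sp)) to
    every function on the moving atom; at first order a function on atom lam
    acquires the factor i (r_beta - O_sp,beta). Stored matrices are the real
    factors multiplying i.

    S1 = Dip_beta * (sel_ket - sel_bra)                    (antisymmetric)
    one-electron Fock phase piece:
        h1_vao = <mu| h m_b |nu> sel_nu - <m_b mu| h |nu> sel_mu,  h = T+Vne
    nabla piece (nuclear-momentum coupling on basis functions of lam):
        h1_nab = Nabla_beta * sel_ket  -- combined antihermitian-ly below
    """
    eng: AOBasis = ints.engine
    gauge = ints.gauge
    selv = eng.ao_on_atom(lam).astype(float)
    mm = eng.moment_map(beta, gauge.O_sp)
    sel_p = np.diag(eng.atom_prim_mask(lam))

    # S1 (times i): Dip_b selected on ket minus bra
    S1 = ints.Dip[beta] * selv[None, :] - ints.Dip[beta] * selv[:, None]

    # <mu|h (m_b nu)> and <(m_b mu)|h|nu> with the moment on atom-lam functions;
    # select the lam-atom functions first, then multiply by the moment
    km = sel_p @ mm
    h_ket = (eng.matrix("T", ket_map=km) + eng.matrix("Vne", ket_map=km))
    h_bra = (eng.matrix("T", bra_map=km) + eng.matrix("Vne", bra_map=km))
    h1_vao_1el = h_ket - h_bra

    # nuclear-momentum coupling: +i <mu|d_beta nu> for nu on lam, i.e. stored
    # real part Nabla_b * sel_ket; its transpose partner enters through the
    # full assembly in the perturbations module.
    h1_nab = ints.Nabla[beta] * selv[None, :]

    return PerturbedIntegrals(
        channel=f"V[{lam},{'xyz'[beta]}]", flavor="imag_antihermitian",
        S1=S1, pieces={"h1_vao_1el": h1_vao_1el, "h1_nab": h1_nab,
                       "lam": lam, "beta": beta})


# ----------------------------------------------------------------------------
# B channels: GIAO first-order integrals
# ----------------------------------------------------------------------------


def giao_first_order(ints: IntegralSet) -> list[PerturbedIntegrals]:
    """First-order gauge-including (GIAO) integrals for B_x, B_y, B_z.

    GIAO phase: chi~_nu = exp[-(i/2c)(B x (R_nu - O_mag)).r] chi_nu, the sign
    matching the minimal coupling H = (p + A/c)^2/2 + V for an electron
    (charge -1, CGS) with A = B x (r - O_mag)/2, so that the local gauge at
    the ket center is restored. The first-order overlap depends only on the
    center difference R_mu - R_nu and is therefore independent of O_mag:

        S1(B_a) = +(1/2c) eps_{agd} (R_mu - R_nu)_g <mu| r_d |nu>   (times i)

    One-electron Hamiltonian derivative (h = T + Vne): phase-derivative term
    +(1/2c) eps_{agd} (R_mu-R_nu)_g <mu| r_d h |nu> plus the paramagnetic
    term -(1/2c) <mu| ((r - R_nu) x nabla)_a |nu> with the local gauge at
    the ket center. The derivative of a Hermitian matrix even in B is
    i * (real antisymmetric); exact antisymmetry is asserted.
    """
    from .chemio import SPEED_OF_LIGHT_AU as c

    eng: AOBasis = ints.engine
    n = eng.n_ao
    ao_cen = np.array([eng.prim_center[np.nonzero(eng.W[r])[0][0]]
                       for r in range(n)])
    # plain moment integrals about the absolute origin
    mom0 = np.array([eng.matrix("S", ket_map=eng.moment_map(g, (0, 0, 0)))
                     for g in range(3)])
    # moment-weighted core h = T + Vne. In the local-gauge form the phase
    # derivative multiplies the integrand chi_mu * (h chi_nu) as a plain
    # function, so the moment attaches to the BRA (it must not be acted on
    # by the kinetic operator).
    hmom = np.array([
        eng.matrix("T", bra_map=eng.moment_map(g, (0, 0, 0)))
        + eng.matrix("Vne", bra_map=eng.moment_map(g, (0, 0, 0)))
        for g in range(3)])
    # angular momentum about each AO's own KET center: build from maps
    # <mu | ((r - R_nu) x nabla)_a | nu> = eps_agd [ <mu|(r_g) d_d|nu>
    #                                      - R_nu,g <mu|d_d|nu> ]
    momnab = np.zeros((3, 3, n, n))  # [g, d] of <mu| r_g d_d |nu>
    for g in range(3):
        for d in range(3):
            km = eng.nabla_map(d) @ eng.moment_map(g, (0, 0, 0))
            momnab[g, d] = eng.matrix("S", ket_map=km)

    out = []
    Rmn = ao_cen[:, None, :] - ao_cen[None, :, :]  # R_mu - R_nu
    for a in range(3):
        S1 = np.zeros((n, n))
        H1 = np.zeros((n, n))
        for g in range(3):
            for d in range(3):
                e = _LEVI[a, g, d]
                if e == 0:
                    continue
                S1 += e * Rmn[:, :, g] * mom0[d]
                # phase-derivative of h-matrix elements
                H1 += e * Rmn[:, :, g] * hmom[d]
                # paramagnetic term, local gauge at the ket center R_nu
                H1 -= e * (momnab[g, d] - ao_cen[None, :, g] * ints.Nabla[d])
        S1 *= 1.0 / (2.0 * c)
        H1 *= 1.0 / (2.0 * c)
        # exact antisymmetry holds analytically; enforce and verify
        asym = 0.5 * (H1 - H1.T)
        resid = np.max(np.abs(H1 - asym))
        if resid > 1e-8 * max(1.0, np.max(np.abs(H1))):
            raise AssertionError(
                f"GIAO H1(B_{'xyz'[a]}) antisymmetry violated: {resid:.3e}")
        out.append(PerturbedIntegrals(
            channel=f"B[{'xyz'[a]}]", flavor="imag_antihermitian",
            S1=S1, pieces={"h1_1el": asym, "alpha": a}))
    return out


# ----------------------------------------------------------------------------
# optional HDF5 dump
# ----------------------------------------------------------------------------


def dump_integrals(ints: IntegralSet, path):
    """Debug dump of the zeroth-order integrals (fixed dataset names)."""
    import h5py

    with h5py.File(path, "w") as f:
        f["S0"] = ints.S0
        f["T"] = ints.T
        f["Vne"] = ints.Vne
        f["ERI"] = ints.ERI
        for g, name in enumerate("xyz"):
            f[f"Dip_{name}"] = ints.Dip[g]
            f[f"Nabla_{name}"] = ints.Nabla[g]
            f[f"AngMom_{name}"] = ints.AngMom[g]
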