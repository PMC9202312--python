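"""Dense determinant-basis reference implementation for small systems.

Everything here works in the full N-electron determinant space spanned by a
handful of spin orbitals, where the Schroedinger equation and all
coupled-cluster constructions can be evaluated exactly with dense linear
algebra.  It is deliberately independent of the term-table machinery: the
operators are applied bit-by-bit to determinant occupation masks.  The
module serves as the arbiter for the production equations (CCSD is exact
for two electrons, so its dynamics must reproduce full CI) and is usable as
a tool in its own right on systems with up to ~12 spin orbitals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eigh, expm

from .system import IntegralSet


def determinants(n_orb: int, n_el: int) -> list[int]:
    """All N-electron occupation bitmasks, lexicographic in orbital indices."""
    return [
        sum(1 << p for p in occ) for occ in combinations(range(n_orb), n_el)
    ]


def _parity_below(det: int, p: int) -> int:
    return 1 - 2 * (bin(det & ((1 << p) - 1)).count("1") & 1)


def _annihilate(det: int, p: int):
    if not det & (1 << p):
        return None
    return det & ~(1 << p), _parity_below(det, p)


def _create(det: int, p: int):
    if det & (1 << p):
        return None
    return det | (1 << p), _parity_below(det, p)


def one_body_matrix(m: np.ndarray, dets: list[int]) -> np.ndarray:
    """Matrix of ``sum_pq m[p,q] a_p^+ a_q`` in the determinant basis."""
    L = m.shape[0]
    index = {d: k for k, d in enumerate(dets)}
    out = np.zeros((len(dets), len(dets)), complex)
    for col, det in enumerate(dets):
        for q in range(L):
            aq = _annihilate(det, q)
            if aq is None:
                continue
            d1, s1 = aq
            for p in range(L):
                cp = _create(d1, p)
                if cp is None:
                    continue
                d2, s2 = cp
                out[index[d2], col] += m[p, q] * s1 * s2
    return out


def two_body_matrix(w: np.ndarray, dets: list[int]) -> np.ndarray:
    """Matrix of ``1/4 sum w[p,q,r,s] a_p^+ a_q^+ a_s a_r`` (w antisymmetric)."""
    L = w.shape[0]
    index = {d: k for k, d in enumerate(dets)}
    out = np.zeros((len(dets), len(dets)), complex)
    for col, det in enumerate(dets):
        occ = [p for p in range(L) if det & (1 << p)]
        for r in occ:
            d1, s1 = _annihilate(det, r)
            for s in range(L):
                a2 = _annihilate(d1, s)
                if a2 is None:
                    continue
                d2, s2 = a2
                for q in range(L):
                    c1 = _create(d2, q)
                    if c1 is None:
                        continue
                    d3, s3 = c1
                    for p in range(L):
                        c2 = _create(d3, p)
                        if c2 is None:
                            continue
                        d4, s4 = c2
                        out[index[d4], col] += (
                            0.25 * w[p, q, r, s] * s1 * s2 * s3 * s4
                        )
    return out


class DenseSystem:
    """Cache of dense determinant-space operators for one IntegralSet."""

    def __init__(self, ints: IntegralSet):
        self.ints = ints
        self.dets = determinants(ints.n_orbitals, ints.n_electrons)
        self.index = {d: k for k, d in enumerate(self.dets)}
        self.h_mat = one_body_matrix(ints.h, self.dets)
        self.v_mat = two_body_matrix(ints.v, self.dets)
        self.hamiltonian = (
            self.h_mat + self.v_mat + ints.e_nuc * np.eye(len(self.dets))
        )
        self.dipole_mats = np.stack(
            [one_body_matrix(m, self.dets) for m in ints.dipole]
        )
        self.ref = sum(1 << p for p in range(ints.n_electrons))

    def ground_state(self) -> tuple[float, np.ndarray]:
        w, V = eigh(self.hamiltonian)
        return float(w[0]), V[:, 0]

    def excitation_index(self, holes, particles) -> tuple[int, float]:
        """(row, phase) of ``a_a^+ a_b^+ ... a_j a_i |ref>`` in the basis."""
        det, sign = self.ref, 1.0
        for p in holes:  # a_i acts first in a_a^+ a_b^+ a_j a_i
            det, s = _annihilate(det, p)
            sign *= s
        for p in reversed(particles):
            det, s = _create(det, p)
            sign *= s
        return self.index[det], sign

    def similarity_transformed(self, t1=None, t2=None) -> np.ndarray:
        """Dense ``exp(-T) (H - E_nuc-shifted) exp(T)`` with T = T1 + T2."""
        T = np.zeros_like(self.hamiltonian)
        no, L = self.ints.n_electrons, self.ints.n_orbitals
        if t1 is not None:
            m = np.zeros((L, L), complex)
            m[no:, :no] = t1
            T += one_body_matrix(m, self.dets)
        if t2 is not None:
            w = np.zeros((L,) * 4, complex)
            w[no:, no:, :no, :no] = t2
            T += two_body_matrix(w, self.dets)
        return expm(-T) @ self.hamiltonian @ expm(T)

    def cc_residuals(self, t1=None, t2=None):
        """Projections ``<mu| e^-T H e^T |ref>`` for singles and doubles."""
        M = self.similarity_transformed(t1, t2)
        col = M[:, self.index[self.ref]]
        no, L = self.ints.n_electrons, self.ints.n_orbitals
        nv = L - no
        energy = col[self.index[self.ref]]
        r1 = np.zeros((nv, no), complex)
        for i in range(no):
            for a in range(nv):
                row, sign = self.excitation_index([i], [no + a])
                r1[a, i] = sign * col[row]
        r2 = np.zeros((nv, nv, no, no), complex)
        for i in range(no):
            for j in range(no):
                if i == j:
                    continue
                for a in range(nv):
                    for b in range(nv):
                        if a == b:
                            continue
                        row, sign = self.excitation_index(
                            [i, j], [no + a, no + b]
                        )
                        r2[a, b, i, j] = sign * col[row]
        return energy, r1, r2

    def hamilton_function(self, lam_row: np.ndarray, t1=None, t2=None) -> complex:
        """Bivariational ``<ref|(1 + Lambda) e^-T H e^T|ref>`` for given bra."""
        M = self.similarity_transformed(t1, t2)
        return lam_row @ M[:, self.index[self.ref]]

    def lambda_row(self, l1=None, l2=None) -> np.ndarray:
        """Row vector of ``<ref|(1 + Lambda)`` in the determinant basis."""
        no, L = self.ints.n_electrons, self.ints.n_orbitals
        row = np.zeros(len(self.dets), complex)
        row[self.index[self.ref]] = 1.0
        Lm = np.zeros_like(self.hamiltonian)
        if l1 is not None:
            m = np.zeros((L, L), complex)
            m[:no, no:] = l1
            Lm += one_body_matrix(m, self.dets)
        if l2 is not None:
            w = np.zeros((L,) * 4, complex)
            w[:no, :no, no:, no:] = l2
            Lm += two_body_matrix(w, self.dets)
        e = np.zeros(len(self.dets))
        e[self.index[self.ref]] = 1.0
        return row + Lm.T @ e

    def propagate(self, psi0: np.ndarray, field, t_grid: np.ndarray,
                  rtol: float = 1e-11, atol: float = 1e-12) -> np.ndarray:
        """Integrate ``i psi' = H(t) psi``; returns real dipole expectations.

        ``field`` maps time to the 3-vector E(t); the interaction is the
        length-gauge ``-E(t) . mu``.  Output has shape (len(t_grid), 3).
        """

        def rhs(t, y):
            psi = y.view(complex)
            E = field(t)
            H = self.hamiltonian - np.einsum("i,ijk->jk", E, self.dipole_mats)
            return (-1j * (H @ psi)).view(float)

        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            np.ascontiguousarray(psi0, dtype=complex).view(float),
            t_eval=t_grid,
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"dense propagation failed: {sol.message}")
        psis = sol.y.T.copy().view(complex)
        dips = np.einsum("ti,xij,tj->tx", psis.conj(), self.dipole_mats, psis)
        return dips.real
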