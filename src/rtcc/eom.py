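"""Bivariational equations of motion for TDCCSD, TDCC2(-b), TDOMP2, TDNOMP2.

All methods share one structure: a Hamilton function ``H(tau, lambda; t)``
— the bivariational expectation value of the (field-dressed) Hamiltonian —
whose derivatives generate the dynamics,

    i d(tau^mu)/dt   = + dH/d(lambda_mu)        (amplitude equations)
    i d(lambda_mu)/dt = - dH/d(tau^mu)          (conjugate amplitudes)

with the rank-0 pair (tau0, lambda0) carrying phase and normalization:
lambda0 = 1 is constant (intermediate normalization) and tau0 is integrated
but ignored for expectation values.

For TDCCSD the singles are absorbed by T1-dressing the integrals, so the
Hamilton function is a flat polynomial in the dressed integrals and t2; the
lambda1 equation follows by chain rule through the dressing.  TDCC2 keeps
the CCSD singles equations but truncates the doubles commutator to the
one-body operator f + V(t) (untransformed for CC2, built from fully
T1-dressed integrals for the CC2-b variant of Kats et al.).  TDOMP2/TDNOMP2
replace singles by an orbital rotation: the state carries accumulated
orbital coefficients, integrals are transformed to the co-moving frame at
every evaluation, and the rotation velocity solves a linear system whose
matrix is built from the one-body density blocks (singular exactly when an
occupied-block eigenvalue meets a virtual-block eigenvalue).

Effective densities are the exact gradients of the Hamilton function with
respect to the integrals, so expectation values, the orbital gradient and
the lambda equations are all consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import IntegralSet, dress_two_body
from .terms import T, TermTable, antisymmetrize, expand_fock

METHODS = ("ccsd", "cc2", "cc2b", "omp2", "nomp2")


class InvalidStateError(ValueError):
    pass


class OrbitalSingularityError(RuntimeError):
    """The orbital-rotation linear system is (near-)singular."""


# ---------------------------------------------------------------------------
# term tables (index convention: ijkl... occupied, abcd... virtual)

# energy functional <ref| H~ + [H~, T2] |ref> (nuclear repulsion added later)
_E_TERMS = [
    T(1.0, ("h", "ij"), ("I", "ij")),
    T(0.5, ("v", "ijkl"), ("I", "ik"), ("I", "jl")),
    T(0.25, ("v", "ijab"), ("t2", "abij")),
]

# CCSD/CC2 singles residual <ai| e^-T2 H~ e^T2 |ref>, dressed integrals
_R1_TERMS = expand_fock(
    [
        T(1.0, ("f", "ai")),
        T(1.0, ("f", "kc"), ("t2", "acik")),
        T(0.5, ("v", "kacd"), ("t2", "cdki")),
        T(-0.5, ("v", "klci"), ("t2", "cakl")),
    ]
)

# CCSD doubles residual: CCD-form equations in the T1-dressed frame
_R2_CCSD_TERMS = (
    [T(1.0, ("v", "abij"))]
    + expand_fock(antisymmetrize([T(1.0, ("f", "bc"), ("t2", "acij"))], "a", "b"))
    + expand_fock(antisymmetrize([T(-1.0, ("f", "kj"), ("t2", "abik"))], "i", "j"))
    + [
        T(0.5, ("v", "klij"), ("t2", "abkl")),
        T(0.5, ("v", "abcd"), ("t2", "cdij")),
    ]
    + antisymmetrize(
        antisymmetrize([T(1.0, ("v", "kbcj"), ("t2", "acik"))], "a", "b"), "i", "j"
    )
    + [T(0.25, ("v", "klcd"), ("t2", "cdij"), ("t2", "abkl"))]
    + antisymmetrize(
        [T(1.0, ("v", "klcd"), ("t2", "acik"), ("t2", "bdjl"))], "i", "j"
    )
    + antisymmetrize(
        [T(-0.5, ("v", "klcd"), ("t2", "dcik"), ("t2", "ablj"))], "i", "j"
    )
    + antisymmetrize(
        [T(-0.5, ("v", "klcd"), ("t2", "aclk"), ("t2", "dbij"))], "a", "b"
    )
)

# CC2 doubles residual: v~ plus the commutator with a one-body operator 'g'
_R2_G_TERMS = (
    [T(1.0, ("v", "abij"))]
    + antisymmetrize([T(1.0, ("g", "bc"), ("t2", "acij"))], "a", "b")
    + antisymmetrize([T(-1.0, ("g", "kj"), ("t2", "abik"))], "i", "j")
)

# CC2-b / OMP2 doubles residual: same commutator with the Fock matrix of the
# (T1- or kappa-) transformed integrals
_R2_FT_TERMS = (
    [T(1.0, ("v", "abij"))]
    + expand_fock(antisymmetrize([T(1.0, ("f", "bc"), ("t2", "acij"))], "a", "b"))
    + expand_fock(antisymmetrize([T(-1.0, ("f", "kj"), ("t2", "abik"))], "i", "j"))
)


def _with_lambda(terms, name, subs, factor=1.0):
    """Contract a residual table against its conjugate amplitudes."""
    return [
        type(t)(t.coef * factor, ((name, subs),) + t.factors) for t in terms
    ]


E_TABLE = TermTable("", _E_TERMS)
R1_TABLE = TermTable("ai", _R1_TERMS)
R2_TABLES = {
    "ccsd": TermTable("abij", _R2_CCSD_TERMS),
    "cc2": TermTable("abij", _R2_G_TERMS),
    "cc2b": TermTable("abij", _R2_FT_TERMS),
    "omp2": TermTable("abij", _R2_FT_TERMS),
    "nomp2": TermTable("abij", _R2_FT_TERMS),
}

_L1R1 = _with_lambda(_R1_TERMS, "l1", "ia")
H_TABLES = {
    m: TermTable(
        "",
        _E_TERMS
        + (_L1R1 if m in ("ccsd", "cc2", "cc2b") else [])
        + _with_lambda(
            {
                "ccsd": _R2_CCSD_TERMS,
                "cc2": _R2_G_TERMS,
                "cc2b": _R2_FT_TERMS,
                "omp2": _R2_FT_TERMS,
                "nomp2": _R2_FT_TERMS,
            }[m],
            "l2",
            "ijab",
            0.25,
        ),
    )
    for m in METHODS
}


# ---------------------------------------------------------------------------
# state container


@dataclass
class ClusterState:
    """Time-dependent wave-function parameters for one method."""

    method: str
    n_occ: int
    n_orb: int
    tau0: complex = 0.0 + 0.0j
    t1: np.ndarray | None = None  # (nv, no)
    t2: np.ndarray | None = None  # (nv, nv, no, no)
    l1: np.ndarray | None = None  # (no, nv)
    l2: np.ndarray | None = None  # (no, no, nv, nv); None for omp2 (= t2*)
    Q: np.ndarray | None = None  # (L, L) right orbital coefficients
    QL: np.ndarray | None = None  # left coefficients (nomp2 only)

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidStateError(
                f"unknown method {self.method!r}; valid: {METHODS}"
            )
        nv = self.n_orb - self.n_occ
        if self.t2 is None:
            self.t2 = np.zeros((nv, nv, self.n_occ, self.n_occ), complex)
        if self.method in ("ccsd", "cc2", "cc2b"):
            if self.t1 is None:
                self.t1 = np.zeros((nv, self.n_occ), complex)
            if self.l1 is None:
                self.l1 = np.zeros((self.n_occ, nv), complex)
            if self.l2 is None:
                self.l2 = np.zeros((self.n_occ, self.n_occ, nv, nv), complex)
        if self.method in ("omp2", "nomp2") and self.Q is None:
            self.Q = np.eye(self.n_orb, dtype=complex)
        if self.method == "nomp2":
            if self.QL is None:
                self.QL = np.eye(self.n_orb, dtype=complex)
            if self.l2 is None:
                self.l2 = self.t2.conj().transpose(2, 3, 0, 1).copy()

    @property
    def n_virt(self) -> int:
        return self.n_orb - self.n_occ

    def lambda2(self) -> np.ndarray:
        if self.l2 is not None:
            return self.l2
        return self.t2.conj().transpose(2, 3, 0, 1)

    def _fields(self) -> list[str]:
        return {
            "ccsd": ["tau0", "t1", "t2", "l1", "l2"],
            "cc2": ["tau0", "t1", "t2", "l1", "l2"],
            "cc2b": ["tau0", "t1", "t2", "l1", "l2"],
            "omp2": ["tau0", "t2", "Q"],
            "nomp2": ["tau0", "t2", "l2", "Q", "QL"],
        }[self.method]

    def pack(self) -> np.ndarray:
        parts = []
        for name in self._fields():
            val = getattr(self, name)
            parts.append(
                np.atleast_1d(np.asarray(val, dtype=complex)).ravel()
            )
        return np.concatenate(parts)

    def unpack(self, vec: np.ndarray) -> "ClusterState":
        new = ClusterState(self.method, self.n_occ, self.n_orb)
        pos = 0
        for name in self._fields():
            ref = np.atleast_1d(np.asarray(getattr(self, name)))
            size = ref.size
            chunk = vec[pos : pos + size].reshape(ref.shape)
            pos += size
            if name == "tau0":
                new.tau0 = complex(chunk[0])
            else:
                setattr(new, name, chunk.copy())
        if pos != vec.size:
            raise ValueError("packed vector size mismatch")
        if self.method == "omp2":
            new.l2 = None
        return new

    def copy(self) -> "ClusterState":
        return self.unpack(self.pack())


# ---------------------------------------------------------------------------
# dressed operand assembly


def _ops_common(state: ClusterState, no: int, L: int) -> dict:
    nv = L - no
    t2f = np.zeros((L,) * 4, complex)
    t2f[no:, no:, :no, :no] = state.t2
    l2f = np.zeros((L,) * 4, complex)
    l2f[:no, :no, no:, no:] = state.lambda2()
    ops = {"I": np.eye(L), "t2": t2f, "l2": l2f}
    if state.l1 is not None:
        l1f = np.zeros((L, L), complex)
        l1f[:no, no:] = state.l1
        ops["l1"] = l1f
    return ops


class _Frame:
    """Dressed integrals plus everything needed for chain-rule gradients."""

    def __init__(self, state: ClusterState, ints: IntegralSet, field_matrix):
        no, L = state.n_occ, state.n_orb
        self.no, self.L = no, L
        h_full = ints.h if field_matrix is None else ints.h + field_matrix
        self.h_raw, self.v_raw = h_full, ints.v
        if state.method in ("ccsd", "cc2", "cc2b"):
            x = np.zeros((L, L), complex)
            x[no:, :no] = state.t1
            self.A = np.eye(L) - x
            self.B = np.eye(L) + x
            self.identity_frame = False
            ht = self.A @ h_full @ self.B
            vt = dress_two_body(ints.v, self.A, self.B)
        else:
            self.B = state.Q
            self.A = state.QL if state.method == "nomp2" else state.Q.conj().T
            self.identity_frame = True  # gradients taken at kappa = 0
            ht = self.A @ h_full @ self.B
            vt = dress_two_body(ints.v, self.A, self.B)
            self.h_raw, self.v_raw = ht, vt
        self.ops = _ops_common(state, no, L)
        self.ops["h"] = ht
        self.ops["v"] = vt
        if state.method == "cc2":
            o = slice(0, no)
            self.ops["g"] = h_full + np.einsum(
                "piqi->pq", ints.v[:, o, :, o]
            )

    def transform_gradient(self, D1: np.ndarray, D2: np.ndarray) -> np.ndarray:
        """d(Hamilton function)/d(generator x[mu, nu]) by one-index rule.

        For the T1 frame the generator is the singles block itself (the
        dressing is linear in x); for the orbital frame the gradient is taken
        at kappa = 0 on the already-transformed integrals.
        """
        h, v = self.h_raw, self.v_raw
        if self.identity_frame:
            # gradient at kappa = 0 on the already-transformed integrals
            Ah, hB = h, h
            w1 = w2 = w3 = w4 = v
        else:
            A, B = self.A, self.B
            Ah, hB = A @ h, h @ B
            vB3 = np.einsum("tr,pqts->pqrs", B, v, optimize=False)
            vB34 = np.einsum("ts,pqrt->pqrs", B, vB3, optimize=False)
            w1 = np.einsum("qt,ptrs->pqrs", A, vB34, optimize=False)
            w2 = np.einsum("pt,tqrs->pqrs", A, vB34, optimize=False)
            vA12 = np.einsum(
                "qt,ptrs->pqrs",
                A,
                np.einsum("pt,tqrs->pqrs", A, v, optimize=False),
                optimize=True,
            )
            w3 = np.einsum("ts,pqrt->pqrs", B, vA12, optimize=False)
            w4 = np.einsum("tr,pqts->pqrs", B, vA12, optimize=False)
        G = Ah.T @ D1 - D1 @ hB.T
        G -= np.einsum("mqrs,nqrs->mn", D2, w1, optimize=False)
        G -= np.einsum("pmrs,pnrs->mn", D2, w2, optimize=False)
        G += np.einsum("pqns,pqms->mn", D2, w3, optimize=False)
        G += np.einsum("pqrn,pqrm->mn", D2, w4, optimize=False)
        return G


def _antisym4(g: np.ndarray) -> np.ndarray:
    return (
        g
        - g.transpose(1, 0, 2, 3)
        - g.transpose(0, 1, 3, 2)
        + g.transpose(1, 0, 3, 2)
    )


# ---------------------------------------------------------------------------
# derivatives


def residuals(state: ClusterState, ints: IntegralSet, field_matrix=None):
    """Energy functional and amplitude residuals (right-hand sides).

    Returns ``(energy, r1, r2, frame)``; ``r1`` is None for the
    orbital-rotation methods.
    """
    fr = _Frame(state, ints, field_matrix)
    no, L = fr.no, fr.L
    energy = complex(E_TABLE.value(fr.ops, no, L)) + ints.e_nuc
    r2 = R2_TABLES[state.method].value(fr.ops, no, L)
    r1 = None
    if state.method in ("ccsd", "cc2", "cc2b"):
        r1 = R1_TABLE.value(fr.ops, no, L)
    return energy, r1, r2, fr


def hamilton_function(state, ints: IntegralSet, field_matrix=None) -> complex:
    """Full bivariational Hamilton function (energy observable)."""
    fr = _Frame(state, ints, field_matrix)
    return complex(
        H_TABLES[state.method].value(fr.ops, fr.no, fr.L)
    ) + ints.e_nuc


def lambda_residuals(state, ints: IntegralSet, field_matrix=None, frame=None):
    """Gradients of the Hamilton function w.r.t. t1/t2 (lambda equations).

    Returns ``(g1, g2)`` where ``g1[a, i] = dH/dt1[a, i]`` (None when the
    method has no singles) and ``g2[a, b, i, j] = dH/d tau^mu`` for the
    distinct double excitation mu = (ab, ij).
    """
    fr = frame or _Frame(state, ints, field_matrix)
    no, L = fr.no, fr.L
    table = H_TABLES[state.method]
    G2 = table.vjp(fr.ops, no, L, "t2")[no:, no:, :no, :no]
    g2 = _antisym4(G2)
    g1 = None
    if state.method in ("ccsd", "cc2", "cc2b"):
        D1 = table.vjp(fr.ops, no, L, "h")
        D2 = table.vjp(fr.ops, no, L, "v")
        g1 = fr.transform_gradient(D1, D2)[no:, :no]
    return g1, g2


def effective_densities(state, ints: IntegralSet, frame=None):
    """One- and two-body effective densities in the state's dressed frame.

    gamma[p, q] = <a_p^+ a_q> and Gamma[p, q, r, s] = <a_p^+ a_q^+ a_s a_r>
    such that <H> = sum h~ gamma + 1/4 sum v~ Gamma (+ e_nuc).
    """
    fr = frame or _Frame(state, ints, None)
    table = H_TABLES[state.method]
    D1 = table.vjp(fr.ops, fr.no, fr.L, "h")
    D2 = table.vjp(fr.ops, fr.no, fr.L, "v")
    return D1, _antisym4(D2)


def expectation_value(state, ints: IntegralSet, op1, op2=None) -> complex:
    """Bivariational expectation of a one-(plus optional two-)body operator.

    Operator matrices are given in the fixed reference basis and are dressed
    into the state's frame internally.
    """
    fr = _Frame(state, ints, None)
    table = H_TABLES[state.method]
    D1 = table.vjp(fr.ops, fr.no, fr.L, "h")
    val = np.einsum("pq,pq->", D1, fr.A @ np.asarray(op1, complex) @ fr.B)
    if state.method == "cc2":
        Dg = table.vjp(fr.ops, fr.no, fr.L, "g")
        val += np.einsum("pq,pq->", Dg, np.asarray(op1, complex))
    if op2 is not None:
        D2 = table.vjp(fr.ops, fr.no, fr.L, "v")
        val += np.einsum(
            "pqrs,pqrs->", D2, dress_two_body(np.asarray(op2, complex), fr.A, fr.B)
        )
    return complex(val)


def dipole_expectation(state, ints: IntegralSet) -> np.ndarray:
    """Complex dipole expectation vector; the observable is its real part."""
    fr = _Frame(state, ints, None)
    table = H_TABLES[state.method]
    D1 = table.vjp(fr.ops, fr.no, fr.L, "h")
    vals = np.array(
        [
            np.einsum("pq,pq->", D1, fr.A @ m @ fr.B)
            for m in ints.dipole
        ]
    )
    if state.method == "cc2":
        Dg = table.vjp(fr.ops, fr.no, fr.L, "g")
        vals += np.array(
            [np.einsum("pq,pq->", Dg, m) for m in ints.dipole]
        )
    return vals


def _solve_kappa_block(gA, gB, rhs, cond_limit=1e12):
    """Solve i (gA K - K gB) = rhs for K, with singularity diagnostics."""
    nA, nB = gA.shape[0], gB.shape[0]
    M = 1j * (
        np.kron(gA, np.eye(nB)) - np.kron(np.eye(nA), gB.T)
    )
    svals = np.linalg.svd(M, compute_uv=False)
    if svals[-1] == 0.0 or svals[0] / svals[-1] > cond_limit:
        raise OrbitalSingularityError(
            "orbital-rotation system singular: smallest singular value "
            f"{svals[-1]:.3e}"
        )
    return np.linalg.solve(M, rhs.ravel()).reshape(nA, nB)


def derivative(state: ClusterState, ints: IntegralSet, field_matrix=None):
    """Time derivative of every dynamical parameter (returns a ClusterState).

    The returned object holds d/dt of each field of ``state`` (same layout),
    so it can be scaled and added by the integrator.
    """
    energy, r1, r2, fr = residuals(state, ints, field_matrix)
    no, L = fr.no, fr.L
    d = ClusterState(state.method, no, L)
    d.tau0 = -1j * energy
    d.t2 = -1j * r2
    if state.method in ("ccsd", "cc2", "cc2b"):
        if state.t1 is None:
            raise InvalidStateError("CC state lacks singles amplitudes")
        d.t1 = -1j * r1
        g1, g2 = lambda_residuals(state, ints, field_matrix, frame=fr)
        d.l1 = 1j * g1.T
        d.l2 = 1j * g2.transpose(2, 3, 0, 1)
        return d
    if state.method == "nomp2":
        _, g2 = lambda_residuals(state, ints, field_matrix, frame=fr)
        d.l2 = 1j * g2.transpose(2, 3, 0, 1)
    else:
        d.l2 = None
    # orbital rotation velocity from the density linear system
    table = H_TABLES[state.method]
    D1 = table.vjp(fr.ops, no, L, "h")
    D2 = table.vjp(fr.ops, no, L, "v")
    G = fr.transform_gradient(D1, D2)
    gamma_m = D1.T  # matrix with <Omega> = tr(Omega gamma_m)
    g_oo, g_vv = gamma_m[:no, :no], gamma_m[no:, no:]
    k_ov = _solve_kappa_block(g_oo, g_vv, G[no:, :no].T)
    if state.method == "omp2":
        k_vo = -k_ov.conj().T
    else:
        k_vo = _solve_kappa_block(g_vv, g_oo, G[:no, no:].T)
    kdot = np.zeros((L, L), complex)
    kdot[:no, no:] = k_ov
    kdot[no:, :no] = k_vo
    d.Q = state.Q @ kdot
    if state.method == "nomp2":
        d.QL = -kdot @ state.QL
    return d


# ---------------------------------------------------------------------------
# method-specific entry points (thin wrappers enforcing the method tag)


def _require(state: ClusterState, *methods: str) -> None:
    if state.method not in methods:
        raise InvalidStateError(
            f"state method {state.method!r} not in {methods}"
        )


def ccsd_derivative(state, ints, field_matrix=None):
    _require(state, "ccsd")
    return derivative(state, ints, field_matrix)


def cc2_derivative(state, ints, field_matrix=None, variant_b=False):
    _require(state, "cc2b" if variant_b else "cc2")
    return derivative(state, ints, field_matrix)


def omp2_derivative(state, ints, field_matrix=None):
    _require(state, "omp2")
    return derivative(state, ints, field_matrix)


def nomp2_derivative(state, ints, field_matrix=None):
    _require(state, "nomp2")
    return derivative(state, ints, field_matrix)


def omp2_densities(state, ints):
    """DensityPair (gamma, Gamma) for the orbital-adaptive methods."""
    _require(state, "omp2", "nomp2")
    return effective_densities(state, ints)
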