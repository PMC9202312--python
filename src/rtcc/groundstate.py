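"""Stationary states: CC2/CCSD amplitudes via DIIS, OMP2 via orbital steps.

The CC solvers iterate the amplitude equations with quasi-Newton updates
based on Fock-diagonal denominators and DIIS acceleration, then solve the
(linear) lambda equations the same way.  The OMP2 solver alternates MP2-like
amplitude updates with orbital-rotation steps using the diagonal
approximation of the orbital Hessian, with a minimum-denominator level
shift guarding small gaps.  Residual norms are converged to 1e-10 by
default throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .eom import ClusterState, derivative, hamilton_function, lambda_residuals, residuals, H_TABLES, _Frame
from .system import IntegralSet, build_fock

DEFAULT_TOL = 1e-10


class ConvergenceError(RuntimeError):
    def __init__(self, message, residual_history):
        super().__init__(message)
        self.residual_history = list(residual_history)


@dataclass
class GroundStateResult:
    method: str
    state: ClusterState
    energy: float
    residual_norms: list = field(default_factory=list)
    iterations: int = 0

    def save_npz(self, path):
        np.savez(
            path,
            method=self.method,
            energy=self.energy,
            residuals=np.array(self.residual_norms),
            **{
                k: getattr(self.state, k)
                for k in ("t1", "t2", "l1", "l2", "Q")
                if getattr(self.state, k) is not None
            },
        )


class _DIIS:
    """Direct inversion in the iterative subspace over flattened vectors."""

    def __init__(self, max_vecs: int = 8):
        self.max_vecs = max_vecs
        self.params: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def step(self, param: np.ndarray, error: np.ndarray) -> np.ndarray:
        self.params.append(param.copy())
        self.errors.append(error.copy())
        if len(self.params) > self.max_vecs:
            self.params.pop(0)
            self.errors.pop(0)
        n = len(self.params)
        if n < 2:
            return param
        B = np.empty((n + 1, n + 1), complex)
        B[:n, :n] = [
            [np.vdot(ei, ej) for ej in self.errors] for ei in self.errors
        ]
        B[n, :], B[:, n], B[n, n] = -1.0, -1.0, 0.0
        rhs = np.zeros(n + 1, complex)
        rhs[n] = -1.0
        try:
            coeff = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            coeff, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            coeff = coeff[:n]
        return sum(c * p for c, p in zip(coeff, self.params))


def _denominators(f: np.ndarray, no: int):
    """Orbital-energy denominators from the Fock diagonal.

    D1[a, i] = eps_i - eps_a, D2[a, b, i, j] = eps_i + eps_j - eps_a - eps_b.
    """
    eps = np.real(np.diag(f))
    eo, ev = eps[:no], eps[no:]
    d1 = eo[None, :] - ev[:, None]
    d2 = (
        eo[None, None, :, None]
        + eo[None, None, None, :]
        - ev[:, None, None, None]
        - ev[None, :, None, None]
    )
    return d1, d2


def mp2_amplitudes(
    ints: IntegralSet, tol: float = DEFAULT_TOL, max_iter: int = 200
) -> np.ndarray:
    """First-order doubles amplitudes, iterated when the Fock is non-diagonal."""
    no, L = ints.n_electrons, ints.n_orbitals
    f = build_fock(ints)
    _, d2 = _denominators(f, no)
    if np.abs(d2).min() < 1e-8:
        raise ZeroDivisionError(
            "vanishing occupied-virtual gap: MP2 denominators diverge"
        )
    state = ClusterState("omp2", no, L)
    diis = _DIIS()
    history = []
    for _ in range(max_iter):
        _, _, r2, _ = residuals(state, ints)
        history.append(float(np.linalg.norm(r2)))
        if history[-1] < tol:
            return state.t2
        t2 = state.t2 + r2 / d2
        t2 = diis.step(t2.ravel(), (r2 / d2).ravel()).reshape(t2.shape)
        state = ClusterState("omp2", no, L, t2=t2)
    raise ConvergenceError("MP2 amplitudes did not converge", history)


def solve_cc_ground_state(
    ints: IntegralSet,
    model: str = "ccsd",
    tol: float = DEFAULT_TOL,
    max_iter: int = 200,
    diis_size: int = 8,
    use_diis: bool = True,
) -> GroundStateResult:
    """Converge t and lambda amplitudes of CCSD / CC2 / CC2-b."""
    if model not in ("ccsd", "cc2", "cc2b"):
        raise ValueError(f"model must be ccsd, cc2 or cc2b, got {model!r}")
    no, L = ints.n_electrons, ints.n_orbitals
    f = build_fock(ints)
    d1, d2 = _denominators(f, no)
    if np.abs(d2).min() < 1e-8:
        raise ZeroDivisionError("vanishing occupied-virtual gap")
    state = ClusterState(model, no, L, t2=mp2_amplitudes(ints, tol=max(tol, 1e-12)))
    history = []
    diis = _DIIS(diis_size)
    for it in range(max_iter):
        _, r1, r2, _ = residuals(state, ints)
        res = float(np.sqrt(np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2))
        history.append(res)
        if res < tol:
            break
        t1 = state.t1 + r1 / d1
        t2 = state.t2 + r2 / d2
        packed = np.concatenate([t1.ravel(), t2.ravel()])
        err = np.concatenate([(r1 / d1).ravel(), (r2 / d2).ravel()])
        if use_diis:
            packed = diis.step(packed, err)
        t1 = packed[: t1.size].reshape(t1.shape)
        t2 = packed[t1.size :].reshape(t2.shape)
        state = ClusterState(model, no, L, t1=t1, t2=t2)
    else:
        raise ConvergenceError(f"{model} amplitudes did not converge", history)

    # lambda equations (linear in lambda; same quasi-Newton + DIIS scheme)
    state.l1 = state.t1.conj().T.copy()
    state.l2 = state.t2.conj().transpose(2, 3, 0, 1).copy()
    diis_l = _DIIS(diis_size)
    for it_l in range(max_iter):
        g1, g2 = lambda_residuals(state, ints)
        res = float(np.sqrt(np.linalg.norm(g1) ** 2 + np.linalg.norm(g2) ** 2))
        history.append(res)
        if res < tol:
            break
        l1 = state.l1 + (g1 / d1).T
        l2 = state.l2 + (g2 / d2).transpose(2, 3, 0, 1)
        packed = np.concatenate([l1.ravel(), l2.ravel()])
        err = np.concatenate([(g1 / d1).ravel(), (g2 / d2).ravel()])
        if use_diis:
            packed = diis_l.step(packed, err)
        state.l1 = packed[: l1.size].reshape(l1.shape)
        state.l2 = packed[l1.size :].reshape(l2.shape)
    else:
        raise ConvergenceError(f"{model} lambda equations did not converge", history)

    energy = float(np.real(hamilton_function(state, ints)))
    return GroundStateResult(model, state, energy, history, it + 1)


def solve_omp2_ground_state(
    ints: IntegralSet,
    tol: float = DEFAULT_TOL,
    max_iter: int = 500,
    level_shift: float = 1e-3,
    orbital_damping: float = 1.0,
) -> GroundStateResult:
    """Orbital-optimized MP2 with diagonal-Hessian orbital updates.

    Alternates a quasi-Newton doubles update with an orbital-rotation step
    ``kappa = -g / max(2 gap, shift)`` absorbed into the accumulated
    coefficients, until both the amplitude residual and the orbital gradient
    vanish.  The returned state's orbital basis holds the converged rotation.
    """
    no, L = ints.n_electrons, ints.n_orbitals
    state = ClusterState("omp2", no, L)
    history = []
    for it in range(max_iter):
        fr = _Frame(state, ints, None)
        f = fr.ops["h"] + np.einsum(
            "piqi->pq", fr.ops["v"][:, :no, :, :no]
        )
        d1, d2 = _denominators(f, no)
        if np.abs(d2).min() < 1e-8:
            raise ZeroDivisionError("vanishing occupied-virtual gap")
        _, _, r2, fr = residuals(state, ints)
        table = H_TABLES["omp2"]
        D1 = table.vjp(fr.ops, no, L, "h")
        D2 = table.vjp(fr.ops, no, L, "v")
        G = fr.transform_gradient(D1, D2)
        grad = G[no:, :no] - G[:no, no:].conj().T  # dE/d kappa_ai, E real
        res = float(np.sqrt(np.linalg.norm(r2) ** 2 + np.linalg.norm(grad) ** 2))
        history.append(res)
        if res < tol:
            break
        t2 = state.t2 + r2 / d2
        denom = np.maximum(-2.0 * d1, level_shift)  # 2 (eps_a - eps_i)
        kv = -orbital_damping * grad / denom
        km = np.zeros((L, L), complex)
        km[no:, :no] = kv
        km[:no, no:] = -kv.conj().T
        state = ClusterState("omp2", no, L, t2=t2, Q=state.Q @ expm(km))
    else:
        raise ConvergenceError("OMP2 did not converge", history)
    energy = float(np.real(hamilton_function(state, ints)))
    return GroundStateResult("omp2", state, energy, history, it + 1)
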