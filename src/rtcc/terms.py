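"""Einsum term algebra for spin-orbital many-body expressions.

Every working equation in this package (energy functionals, amplitude
residuals, lambda equations, effective densities, orbital gradients) is
expressed once as a list of :class:`Term` objects — an index-string table
mapping each tensor contraction to an ``np.einsum`` call.  A term is a
scalar coefficient times a product of factors, each factor being a named
operand with a subscript string.  Index letters encode the orbital space:
``ijklmnIJKLMN`` are occupied, ``abcdefgABCDEFG`` are virtual, so operands
stored as full ``L``-dimensional tensors are sliced into blocks before
contraction (occupied orbitals first, then virtual — the single index
convention used throughout).

Because the Hamilton function is a scalar table, its exact gradients with
respect to any operand (amplitudes, one- and two-electron integrals) follow
mechanically from the vector–Jacobian rule for einsum: the derivative with
respect to one factor is the contraction of all remaining factors.  This is
how the lambda equations of motion and the effective density matrices are
obtained without a second hand-derived set of equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OCC_LETTERS = set("ijklmnIJKLMN")
VIRT_LETTERS = set("abcdefgABCDEFG")

_slice_cache: dict = {}


def _block_slices(subs: str, n_occ: int, n_orb: int) -> tuple:
    key = (subs, n_occ, n_orb)
    cached = _slice_cache.get(key)
    if cached is not None:
        return cached
    out = []
    for ch in subs:
        if ch in OCC_LETTERS:
            out.append(slice(0, n_occ))
        elif ch in VIRT_LETTERS:
            out.append(slice(n_occ, n_orb))
        else:  # pragma: no cover - guarded by table construction
            raise ValueError(f"unknown index letter {ch!r}")
    _slice_cache[key] = tuple(out)
    return _slice_cache[key]


def _block_shape(subs: str, n_occ: int, n_orb: int) -> tuple:
    return tuple(n_occ if ch in OCC_LETTERS else n_orb - n_occ for ch in subs)


_plan_cache: dict = {}


def _pairwise_plan(spec: str) -> list[str]:
    """Left-to-right pairwise contraction plan for a 3+ operand einsum."""
    inputs, out = spec.split("->")
    subs = inputs.split(",")
    plan = []
    cur = subs[0]
    for k in range(1, len(subs)):
        nxt = subs[k]
        keep = set(out) | set("".join(subs[k + 1 :]))
        inter = "".join(
            dict.fromkeys(ch for ch in cur + nxt if ch in keep)
        ) if k < len(subs) - 1 else out
        plan.append(f"{cur},{nxt}->{inter}")
        cur = inter
    return plan


def _einsum(spec: str, *arrays):
    """Small-tensor einsum avoiding the path-optimizer overhead."""
    if not arrays:
        raise ValueError("einsum with no operands")
    if len(arrays) <= 2:
        return np.einsum(spec, *arrays, optimize=False)
    plan = _plan_cache.get(spec)
    if plan is None:
        plan = _pairwise_plan(spec)
        _plan_cache[spec] = plan
    acc = arrays[0]
    for step, arr in zip(plan, arrays[1:]):
        acc = np.einsum(step, acc, arr, optimize=False)
    return acc


@dataclass(frozen=True)
class Term:
    """``coef * prod_k operand[name_k][subs_k]`` with implicit summation."""

    coef: complex
    factors: tuple[tuple[str, str], ...]

    def rename(self, mapping: dict[str, str]) -> "Term":
        facs = tuple(
            (name, "".join(mapping.get(ch, ch) for ch in subs))
            for name, subs in self.factors
        )
        return Term(self.coef, facs)

    def scaled(self, c: complex) -> "Term":
        return Term(self.coef * c, self.factors)


def T(coef: complex, *factors: tuple[str, str]) -> Term:
    for _, subs in factors:
        if len(set(subs)) != len(subs):
            raise ValueError(f"repeated index inside one factor: {subs!r}")
    return Term(coef, tuple(factors))


def antisymmetrize(terms: list[Term], p: str, q: str) -> list[Term]:
    """Apply the antisymmetrizer P(pq): M -> M - M(p<->q)."""
    swap = {p: q, q: p}
    return list(terms) + [t.rename(swap).scaled(-1.0) for t in terms]


def expand_fock(terms: list[Term], fock_name: str = "f", target: str = "h") -> list[Term]:
    """Replace each ``fock_name`` factor by ``h + sum_m v[p,m,q,m]``.

    The occupied trace is written with an explicit identity operand ``I`` so
    that every factor keeps distinct index letters (required by the VJP rule).
    """
    out: list[Term] = []
    for term in terms:
        pending = [term]
        while pending:
            t = pending.pop()
            for k, (name, subs) in enumerate(t.factors):
                if name == fock_name:
                    used = set("".join(s for _, s in t.factors))
                    fresh = [c for c in "IJKLMN" if c not in used]
                    m, n = fresh[0], fresh[1]
                    p, q = subs
                    rest = t.factors[:k] + t.factors[k + 1 :]
                    pending.append(Term(t.coef, rest + ((target, p + q),)))
                    pending.append(
                        Term(t.coef, rest + (("v", p + m + q + n), ("I", m + n)))
                    )
                    break
            else:
                out.append(t)
    return out


class TermTable:
    """A sum of terms with a fixed output subscript string (blocked shape)."""

    def __init__(self, out: str, terms: list[Term]):
        self.out = out
        self.terms = list(terms)
        for t in self.terms:
            letters = [c for _, subs in t.factors for c in subs]
            for ch in self.out:
                if letters.count(ch) != 1:
                    raise ValueError(f"output index {ch!r} malformed in {t}")
        self._value_plan = [
            (
                t.coef,
                ",".join(subs for _, subs in t.factors) + "->" + self.out,
                t.factors,
            )
            for t in self.terms
        ]
        self._vjp_plans: dict[str, list] = {}

    def value(self, ops: dict[str, np.ndarray], n_occ: int, n_orb: int):
        acc = None
        for coef, spec, factors in self._value_plan:
            arrays = [
                ops[name][_block_slices(subs, n_occ, n_orb)]
                for name, subs in factors
            ]
            val = coef * _einsum(spec, *arrays)
            acc = val if acc is None else acc + val
        if acc is None:
            shape = _block_shape(self.out, n_occ, n_orb)
            return np.zeros(shape, complex) if shape else 0.0 + 0.0j
        return acc

    def vjp(self, ops: dict[str, np.ndarray], n_occ: int, n_orb: int, wrt: str):
        """Gradient of the (scalar) table with respect to operand ``wrt``.

        Returns a full ``L``-dimensional tensor of the same rank as ``wrt``;
        contributions from different terms land in the blocks named by their
        subscripts.  Multiple occurrences of ``wrt`` within one term (e.g.
        quadratic amplitude terms) are summed, as the product rule requires.
        """
        if self.out != "":
            raise ValueError("vjp defined for scalar tables only")
        plan = self._vjp_plans.get(wrt)
        if plan is None:
            plan = []
            for t in self.terms:
                for k, (name, subs) in enumerate(t.factors):
                    if name != wrt:
                        continue
                    others = t.factors[:k] + t.factors[k + 1 :]
                    spec = ",".join(sb for _, sb in others) + "->" + subs
                    plan.append((t.coef, spec, others, subs))
            self._vjp_plans[wrt] = plan
        rank = ops[wrt].ndim
        grad = np.zeros((n_orb,) * rank, complex)
        for coef, spec, others, subs in plan:
            arrays = [
                ops[nm][_block_slices(sb, n_occ, n_orb)] for nm, sb in others
            ]
            grad[_block_slices(subs, n_occ, n_orb)] += coef * _einsum(
                spec, *arrays
            )
        return grad

    def __len__(self):
        return len(self.terms)
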