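"""Second-quantized system data: integrals, orbital transforms, providers.

The electronic Hamiltonian is held in a fixed orthonormal spin-orbital basis
as ``H = sum_pq h[p,q] a_p^+ a_q + 1/4 sum v[p,q,r,s] a_p^+ a_q^+ a_s a_r``
with ``v`` the antisymmetrized two-electron integrals
``v[p,q,r,s] = <pq||rs> = u[p,q,r,s] - u[p,q,s,r]`` (physicists' notation,
Hartree atomic units).  Creation indices are the leading tensor axes.
Occupied orbitals of the reference determinant come first, then virtuals;
no canonicity of the orbitals is assumed anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import expm


@dataclass
class IntegralSet:
    """All Hamiltonian and dipole matrix elements in one orbital basis."""

    n_electrons: int
    h: np.ndarray  # (L, L) one-electron integrals
    u: np.ndarray  # (L, L, L, L) <pq|rs>
    dipole: np.ndarray  # (3, L, L) Cartesian dipole matrices
    e_nuc: float = 0.0
    v: np.ndarray = field(default=None)  # antisymmetrized <pq||rs>

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=complex)
        self.u = np.asarray(self.u, dtype=complex)
        self.dipole = np.asarray(self.dipole, dtype=complex)
        if self.v is None:
            self.v = antisymmetrize_two_body(self.u)

    @property
    def n_orbitals(self) -> int:
        return self.h.shape[0]

    @property
    def occ_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_orbitals, dtype=bool)
        mask[: self.n_electrons] = True
        return mask

    def with_field(self, field_matrix: np.ndarray) -> "IntegralSet":
        """Absorb a one-body interaction into ``h`` (length-gauge coupling)."""
        return replace(self, h=self.h + field_matrix, u=self.u, v=self.v)

    def reference_energy(self) -> float:
        """Energy of the reference determinant, including nuclear repulsion."""
        o = slice(0, self.n_electrons)
        e = np.einsum("ii->", self.h[o, o]) + 0.5 * np.einsum(
            "ijij->", self.v[o, o, o, o]
        )
        return e + self.e_nuc

    def fock(self) -> np.ndarray:
        return build_fock(self)

    def validate(self, atol: float = 1e-10) -> None:
        """Assert the tensor symmetries every IntegralSet must satisfy."""
        L = self.n_orbitals
        if self.h.shape != (L, L) or self.u.shape != (L, L, L, L):
            raise ValueError("inconsistent integral shapes")
        if self.dipole.shape != (3, L, L):
            raise ValueError("dipole must hold three Cartesian components")
        if not np.allclose(self.h, self.h.conj().T, atol=atol):
            raise ValueError("h is not Hermitian")
        if not np.allclose(self.u, self.u.transpose(1, 0, 3, 2), atol=atol):
            raise ValueError("u lacks particle-exchange symmetry")
        if not np.allclose(self.u, self.u.transpose(2, 3, 0, 1).conj(), atol=atol):
            raise ValueError("u is not Hermitian")
        if not np.allclose(self.v, self.u - self.u.transpose(0, 1, 3, 2), atol=atol):
            raise ValueError("v is not the antisymmetrization of u")
        for m in self.dipole:
            if not np.allclose(m, m.conj().T, atol=atol):
                raise ValueError("dipole component is not Hermitian")
        if not 0 < self.n_electrons <= L:
            raise ValueError("electron count out of range")

    def save_npz(self, path) -> None:
        np.savez(
            path,
            h=self.h,
            u=self.u,
            dipole=self.dipole,
            e_nuc=self.e_nuc,
            n_electrons=self.n_electrons,
        )

    @classmethod
    def load_npz(cls, path) -> "IntegralSet":
        data = np.load(path)
        return cls(
            n_electrons=int(data["n_electrons"]),
            h=data["h"],
            u=data["u"],
            dipole=data["dipole"],
            e_nuc=float(data["e_nuc"]),
        )


def antisymmetrize_two_body(u: np.ndarray) -> np.ndarray:
    """``v[p,q,r,s] = u[p,q,r,s] - u[p,q,s,r]``."""
    u = np.asarray(u)
    if u.ndim != 4 or len(set(u.shape)) != 1:
        raise ValueError("u must be a rank-4 tensor with equal dimensions")
    return u - u.transpose(0, 1, 3, 2)


def build_fock(ints: IntegralSet) -> np.ndarray:
    """Fock matrix ``f[p,q] = h[p,q] + sum_i v[p,i,q,i]`` over occupied i."""
    o = slice(0, ints.n_electrons)
    return ints.h + np.einsum("piqi->pq", ints.v[:, o, :, o])


@dataclass
class OrbitalTransform:
    """Exponential one-body similarity transform of the integrals.

    kind ``t1``: nilpotent singles dressing, ``shift`` is the (nv, no)
    amplitude block placed in the virtual-row/occupied-column block.
    kind ``unitary-kappa``: ``shift`` is the (nv, no) block of an
    anti-Hermitian generator (the occupied-row block is ``-shift^+``).
    kind ``kappa``: general (non-unitary) generator given as a full (L, L)
    matrix with occupied-virtual and virtual-occupied blocks.
    """

    kind: str
    shift: np.ndarray

    def generator(self, n_occ: int, n_orb: int) -> np.ndarray:
        x = np.zeros((n_orb, n_orb), complex)
        o, v = slice(0, n_occ), slice(n_occ, n_orb)
        if self.kind == "t1":
            x[v, o] = self.shift
        elif self.kind == "unitary-kappa":
            x[v, o] = self.shift
            x[o, v] = -self.shift.conj().T
        elif self.kind == "kappa":
            x = np.array(self.shift, dtype=complex)
            if x.shape != (n_orb, n_orb):
                raise ValueError("kappa kind expects a full (L, L) generator")
        else:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        return x

    def matrices(self, n_occ: int, n_orb: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, B) with transformed one-body ``h~ = A h B``."""
        x = self.generator(n_occ, n_orb)
        if self.kind == "t1":  # x is nilpotent: exp(+-x) terminates
            eye = np.eye(n_orb)
            return eye - x, eye + x
        return expm(-x), expm(x)


def dress_one_body(m: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return A @ m @ B


def dress_two_body(u: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    w = np.einsum("pt,tqrs->pqrs", A, u, optimize=False)
    w = np.einsum("qt,ptrs->pqrs", A, w, optimize=False)
    w = np.einsum("tr,pqts->pqrs", B, w, optimize=False)
    return np.einsum("ts,pqrt->pqrs", B, w, optimize=False)


def transform_integrals(ints: IntegralSet, xf: OrbitalTransform) -> IntegralSet:
    """Similarity-transform all integrals: ``h~ = e^-X h e^X`` etc.

    For the ``t1`` kind this is the standard singles dressing; for
    ``unitary-kappa`` the transformed ``h~`` stays Hermitian; for the general
    ``kappa`` kind Hermiticity is not guaranteed and ``validate`` would fail.
    """
    A, B = xf.matrices(ints.n_electrons, ints.n_orbitals)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise FloatingPointError("non-finite orbital transform")
    u = dress_two_body(ints.u, A, B)
    return IntegralSet(
        n_electrons=ints.n_electrons,
        h=dress_one_body(ints.h, A, B),
        u=u,
        dipole=np.stack([dress_one_body(m, A, B) for m in ints.dipole]),
        e_nuc=ints.e_nuc,
        v=dress_two_body(ints.v, A, B),
    )


# ---------------------------------------------------------------------------
# synthetic fixtures


def _symmetrize_two_body(w: np.ndarray) -> np.ndarray:
    """Project onto particle-exchange + Hermitian (real) symmetry."""
    w = (w + w.transpose(1, 0, 3, 2)) / 2.0
    return (w + w.transpose(2, 3, 0, 1)) / 2.0


def make_fixture(
    seed: int,
    n_occ: int,
    n_virt: int,
    coupling_scale: float = 0.1,
    gap: float = 1.0,
    offdiag_scale: float = 0.05,
    e_nuc: float = 0.5,
) -> IntegralSet:
    """Random Hermitian model system with all IntegralSet invariants.

    ``h`` is a diagonally dominant real symmetric matrix with occupied levels
    below and virtual levels above a gap of ``gap`` Hartree, so perturbative
    methods are well conditioned; ``coupling_scale`` scales the two-electron
    elements.  Deterministic per seed (real integrals throughout, matching
    the closed-shell molecular setting where lambda = t* holds for OMP2).
    """
    if n_occ < 1 or n_virt < 1:
        raise ValueError("need at least one occupied and one virtual orbital")
    rng = np.random.default_rng(seed)
    L = n_occ + n_virt
    eps = np.concatenate(
        [
            -gap / 2 - rng.uniform(0.2, 1.0, n_occ),
            gap / 2 + rng.uniform(0.2, 1.0, n_virt),
        ]
    )
    h = np.diag(np.sort(eps))
    noise = rng.normal(scale=offdiag_scale, size=(L, L))
    h = h + (noise + noise.T) / 2.0
    u = coupling_scale * _symmetrize_two_body(rng.normal(size=(L,) * 4))
    dip = rng.normal(scale=0.5, size=(3, L, L))
    dip = (dip + dip.transpose(0, 2, 1)) / 2.0
    ints = IntegralSet(
        n_electrons=n_occ, h=h, u=u, dipole=dip, e_nuc=float(e_nuc)
    )
    ints.validate()
    return ints


def spatial_to_spinorbital(
    h: np.ndarray,
    u: np.ndarray,
    dipole: np.ndarray,
    n_electrons: int,
    e_nuc: float = 0.0,
) -> IntegralSet:
    """Expand closed-shell spatial integrals to the spin-orbital basis.

    ``u`` is ``<pq|rs>`` over spatial orbitals.  Spin orbitals are
    interleaved (``2P + sigma``), which preserves the occupied-first ordering
    for a closed-shell reference with ``n_electrons/2`` doubly occupied
    spatial orbitals.  Elements vanish unless spin labels match pairwise.
    """
    if n_electrons % 2:
        raise ValueError("closed-shell expansion needs an even electron count")
    h = np.asarray(h)
    n = h.shape[0]
    L = 2 * n
    d = np.eye(2)
    h_so = np.kron(h, d)
    u_so = np.einsum(
        "PQRS,pr,qs->PpQqRrSs", np.asarray(u), d, d, optimize=True
    ).reshape(L, L, L, L)
    dip_so = np.stack([np.kron(np.asarray(m), d) for m in np.asarray(dipole)])
    return IntegralSet(
        n_electrons=n_electrons, h=h_so, u=u_so, dipole=dip_so, e_nuc=e_nuc
    )


# ---------------------------------------------------------------------------
# providers


def load_integrals_json(path) -> IntegralSet:
    """File-based provider: closed-shell spatial integrals stored as JSON."""
    payload = json.loads(Path(path).read_text())
    return spatial_to_spinorbital(
        h=np.array(payload["h"], dtype=float),
        u=np.array(payload["u"], dtype=float),
        dipole=np.array(payload["dipole"], dtype=float),
        n_electrons=int(payload["n_electrons"]),
        e_nuc=float(payload["e_nuc"]),
    )


def h2_sto3g() -> IntegralSet:
    """Bundled minimal two-electron molecular system (H2, STO-3G, R=1.4 a0)."""
    return load_integrals_json(Path(__file__).parent / "data" / "h2_sto3g.json")


def read_xyz(path) -> list[tuple[str, tuple[float, float, float]]]:
    """Parse an XYZ geometry file (symbol + Cartesian coordinates, Angstrom)."""
    lines = Path(path).read_text().splitlines()
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError("first XYZ line must hold the atom count") from exc
    atoms = []
    for line in lines[2 : 2 + natoms]:  # line 2 is the comment line
        sym, x, y, z = line.split()[:4]
        atoms.append((sym, (float(x), float(y), float(z))))
    if len(atoms) != natoms:
        raise ValueError("XYZ file ended before the declared atom count")
    return atoms


def pyscf_integrals(xyz_path, basis: str) -> IntegralSet:
    """Adapter computing RHF molecular-orbital integrals with pyscf.

    Requires the optional pyscf package; the bundled fixtures and the JSON
    provider cover all tests without it.
    """
    try:
        from pyscf import gto, scf, ao2mo
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "pyscf is not installed; use make_fixture or the JSON provider"
        ) from exc
    atoms = read_xyz(xyz_path)
    mol = gto.M(
        atom=[(s, xyz) for s, xyz in atoms], basis=basis, unit="Angstrom"
    )
    mf = scf.RHF(mol).run()
    C = mf.mo_coeff
    hcore = C.T @ mf.get_hcore() @ C
    n = C.shape[1]
    eri_chem = ao2mo.restore(1, ao2mo.full(mol, C), n)
    u = eri_chem.transpose(0, 2, 1, 3)  # (pr|qs) -> <pq|rs>
    dip_ao = mol.intor("int1e_r")
    dip = np.stack([-(C.T @ m @ C) for m in dip_ao])  # electronic part
    return spatial_to_spinorbital(
        hcore, u, dip, n_electrons=mol.nelectron, e_nuc=mol.energy_nuc()
    )
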