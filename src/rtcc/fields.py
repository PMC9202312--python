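"""External electric-field protocols and the length-gauge interaction.

Two protocols drive all simulations: a delta kick — a box function of one
integrator step with time-integral ``E_max`` along the polarization vector,
exciting every dipole-allowed transition at once — and a ramped cosine,
``E_max n (t / T_ramp) cos(w t)`` during a linear ramp of one optical cycle
and ``E_max n cos(w t)`` afterwards, used for (hyper)polarizability runs.
The interaction matrix is the electric-dipole, length-gauge coupling
``-E(t) . mu`` in the orbital basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = ("none", "delta_kick", "ramped_cosine")


@dataclass
class FieldSpec:
    kind: str = "none"
    strength: float = 1e-3  # E_max in atomic units
    polarization: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    omega: float = 0.0  # carrier frequency (ramped_cosine)
    kick_width: float = 0.01  # box width = one integrator step
    ramp_cycles: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}; valid: {KINDS}")
        if self.strength < 0:
            raise ValueError("field strength must be non-negative")
        n = np.asarray(self.polarization, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("polarization vector must be non-zero")
        self.polarization = n / norm

    @property
    def ramp_duration(self) -> float:
        if self.omega == 0:
            raise ValueError("ramped_cosine needs a non-zero frequency")
        return self.ramp_cycles * 2.0 * np.pi / self.omega


def field_value(spec: FieldSpec, t: float) -> np.ndarray:
    """Electric-field 3-vector at time ``t`` (atomic units)."""
    if spec.kind == "none":
        return np.zeros(3)
    if spec.kind == "delta_kick":
        # box of height E_max / width so the impulse area equals E_max
        if 0.0 <= t < spec.kick_width:
            return (spec.strength / spec.kick_width) * spec.polarization
        return np.zeros(3)
    if spec.kind == "ramped_cosine":
        T_ramp = spec.ramp_duration
        env = spec.strength * min(t / T_ramp, 1.0) if t >= 0 else 0.0
        return env * np.cos(spec.omega * t) * spec.polarization
    raise ValueError(f"unknown field kind {spec.kind!r}")


def interaction_matrix(
    spec: FieldSpec, t: float, dipole: np.ndarray
) -> np.ndarray:
    """Length-gauge interaction ``-sum_i E_i(t) mu_i`` in the orbital basis."""
    E = field_value(spec, t)
    if not np.any(E):
        return np.zeros(dipole.shape[1:], dtype=complex)
    return -np.einsum("i,ipq->pq", E, dipole)
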