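"""Optical properties from simulated dipole trajectories.

Linear absorption: after a weak delta kick along ``n``, the damped Fourier
transform of the induced dipole gives the polarizability column

    alpha_jj(w) = (1/E_kick) Int mu_j^ind(t) exp(-gamma t) exp(i w t) dt,

and the spectral function ``S(w) = (4 pi w / 3c) Im alpha(w)`` shows
Lorentzian lines of half-width gamma at the dipole-allowed excitation
energies.  The exponential damping suppresses the finite-signal artifacts
of the FFT; the grid resolution is 2 pi / T (no zero padding).

Frequency-dependent polarizabilities and first hyperpolarizabilities: with
a ramped cosine field of strength E along axis j, the dipole expands as
``mu = mu0 + mu1 E + (1/2) mu2 E^2 + ...`` with ``mu1 = alpha cos(wt)`` and
``mu2 = (1/2)[beta_OR + beta_SHG cos(2wt)]`` in a transparent region.  The
response functions are isolated by four-point central differences over the
field strength (+-E, +-2E) and alpha, beta_OR, beta_SHG follow from a
linear least-squares fit on the post-ramp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .fields import FieldSpec

HARTREE_EV = 27.211386
SPEED_OF_LIGHT_AU = 137.035999084


class InvalidProtocolError(ValueError):
    pass


@dataclass
class SpectrumResult:
    omega_au: np.ndarray
    omega_ev: np.ndarray
    S: np.ndarray
    gamma: float
    alpha_im: np.ndarray
    peaks: list = field(default_factory=list)  # (position_eV, height)

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["omega_au", "omega_ev", "S"])
            for wa, we, s in zip(self.omega_au, self.omega_ev, self.S):
                w.writerow([f"{wa:.10g}", f"{we:.10g}", f"{s:.12e}"])


@dataclass
class ResponseResult:
    omega: float
    alpha: float
    beta_or: float | None
    beta_shg: float | None
    fit_residual_mu1: float
    fit_residual_mu2: float | None
    strengths: tuple

    def as_dict(self):
        return {
            "omega": self.omega,
            "alpha": self.alpha,
            "beta_or": self.beta_or,
            "beta_shg": self.beta_shg,
            "fit_residual_mu1": self.fit_residual_mu1,
            "fit_residual_mu2": self.fit_residual_mu2,
            "strengths": list(self.strengths),
        }


def absorption_spectrum(
    traj,
    kick: FieldSpec,
    permanent_dipole=None,
    gamma: float = 0.00921,
) -> SpectrumResult:
    """Damped-FFT absorption spectrum from a delta-kick trajectory.

    ``gamma`` (default 0.00921 a.u. = 0.251 eV) broadens each excitation
    into a Lorentzian of half-width gamma.  The alpha normalization divides
    by the impulse area (the kick strength), so the spectrum is invariant to
    the box-height convention of the discretized delta pulse.
    """
    if kick.kind != "delta_kick":
        raise InvalidProtocolError(
            "absorption spectra require a delta-kick trajectory"
        )
    if gamma <= 0:
        raise ValueError("damping gamma must be positive")
    times = np.asarray(traj.times)
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt):
        raise ValueError("spectrum needs a uniform time grid")
    mu0 = traj.dipole[0] if permanent_dipole is None else permanent_dipole
    signal = (traj.dipole - mu0) @ kick.polarization
    damped = signal * np.exp(-gamma * (times - times[0]))
    n = len(times)
    # alpha(w) = dt * sum_k mu_k exp(+i w t_k) / E  -> inverse FFT convention
    alpha = n * dt * np.fft.ifft(damped) / kick.strength
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    keep = omega >= 0
    omega, alpha = omega[keep], alpha[keep]
    order = np.argsort(omega)
    omega, alpha = omega[order], alpha[order]
    S = (4.0 * np.pi * omega / (3.0 * SPEED_OF_LIGHT_AU)) * alpha.imag
    return SpectrumResult(
        omega_au=omega,
        omega_ev=omega * HARTREE_EV,
        S=S,
        gamma=gamma,
        alpha_im=alpha.imag,
    )


def detect_peaks(
    spec: SpectrumResult, min_height_fraction: float = 0.02
) -> list[tuple[float, float]]:
    """Local maxima of S above a fraction of the global maximum, in eV.

    Resolution limited: lines closer than the Lorentzian width merge into a
    single detected peak.
    """
    if len(spec.S) == 0 or np.all(spec.S <= 0):
        return []
    idx, _ = find_peaks(spec.S, height=min_height_fraction * spec.S.max())
    peaks = [(float(spec.omega_ev[i]), float(spec.S[i])) for i in idx]
    spec.peaks = peaks
    return peaks


def _component(traj, axis: int) -> np.ndarray:
    return np.asarray(traj.dipole)[:, axis]


def response_from_signals(
    signals: dict,
    omega: float,
    strength: float,
    axis: int = 2,
    ramp_cycles: float = 1.0,
    fit_beta: bool = True,
) -> ResponseResult:
    """Extract alpha and beta(OR/SHG) from a +-E/+-2E trajectory family.

    ``signals`` maps the strength multiplier m in {1, -1, 2, -2, 0} to the
    trajectory driven by a ramped cosine of strength ``m * strength``; the
    m = 0 entry may be a trajectory or the constant permanent dipole value.
    The ramp cycle is excluded from the fit window.
    """
    needed = [1, -1] + ([2, -2, 0] if fit_beta else [2, -2])
    for m in needed:
        if m not in signals:
            raise ValueError(
                f"missing strength multiplier {m}: the four-point stencil "
                "needs +-E and +-2E trajectories"
            )
    t = np.asarray(signals[1].times)
    for m in (-1, 2, -2):
        if not np.allclose(np.asarray(signals[m].times), t):
            raise ValueError("trajectory time grids differ")
    mu_p1, mu_m1 = _component(signals[1], axis), _component(signals[-1], axis)
    mu_p2, mu_m2 = _component(signals[2], axis), _component(signals[-2], axis)
    E = strength
    mu1 = (8.0 * (mu_p1 - mu_m1) - (mu_p2 - mu_m2)) / (12.0 * E)

    window = t >= ramp_cycles * 2.0 * np.pi / omega
    if window.sum() < 8:
        raise ValueError("fit window too short; propagate more cycles")
    tw = t[window]
    basis1 = np.cos(omega * tw)[:, None]
    coef1, res1, rank1, _ = np.linalg.lstsq(basis1, mu1[window], rcond=None)
    if rank1 < 1:
        raise np.linalg.LinAlgError("rank-deficient linear-response fit")
    alpha = float(coef1[0])
    resid1 = float(np.linalg.norm(basis1 @ coef1 - mu1[window]))

    beta_or = beta_shg = resid2 = None
    if fit_beta:
        mu0 = signals[0]
        mu0_v = (
            _component(mu0, axis)
            if hasattr(mu0, "dipole")
            else float(mu0) * np.ones_like(t)
        )
        mu2 = (
            16.0 * (mu_p1 + mu_m1) - (mu_p2 + mu_m2) - 30.0 * mu0_v
        ) / (12.0 * E**2)
        basis2 = np.column_stack(
            [0.5 * np.ones_like(tw), 0.5 * np.cos(2.0 * omega * tw)]
        )
        coef2, _, rank2, _ = np.linalg.lstsq(basis2, mu2[window], rcond=None)
        if rank2 < 2:
            raise np.linalg.LinAlgError(
                "rank-deficient hyperpolarizability fit"
            )
        beta_or, beta_shg = float(coef2[0]), float(coef2[1])
        resid2 = float(np.linalg.norm(basis2 @ coef2 - mu2[window]))
    return ResponseResult(
        omega=omega,
        alpha=alpha,
        beta_or=beta_or,
        beta_shg=beta_shg,
        fit_residual_mu1=resid1,
        fit_residual_mu2=resid2,
        strengths=(strength, 2 * strength),
    )


def isotropic_polarizability(alpha_xx, alpha_yy=None, alpha_zz=None) -> float:
    """``alpha_iso = (alpha_xx + alpha_yy + alpha_zz) / 3``."""
    if alpha_yy is None or alpha_zz is None:
        raise ValueError("all three diagonal components are required")
    return (alpha_xx + alpha_yy + alpha_zz) / 3.0
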