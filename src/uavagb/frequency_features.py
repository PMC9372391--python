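"""Frequency-domain variables: harmonic decomposition of plot spectra.

A six-band plot spectrum r_1..r_6 (ascending wavelength, 1-based band
index j) is expressed as a constant plus sine/cosine terms,

    r_j = A0/2 + sum_t [ A_t cos(2*pi*t*j/n) + B_t sin(2*pi*t*j/n) ],

with n = 6 and decomposition orders t = 1..6.  The emitted parameters are
the constant A0/2 = mean(r), the cosine/sine coefficients

    A_t = (2/n) sum_j r_j cos(2*pi*t*j/n),
    B_t = (2/n) sum_j r_j sin(2*pi*t*j/n),

the amplitudes C_t = sqrt(A_t^2 + B_t^2) and phases phi_t — 25 scalars in
all.  The phase is the two-argument arctangent of (A_t, B_t): writing the
harmonic as C_t sin(2*pi*t*j/n + phi_t) requires tan(phi) = A_t/B_t, and
atan2 resolves the quadrant and the B_t = 0 case (which provably occurs at
t = 6, where B_6 = 0 identically).  phi_t is defined as 0 when C_t = 0.

With n = 6 samples, orders above the Nyquist order fold back: A_{6-t} =
A_t, B_{6-t} = -B_t, hence C_5 = C_1 and C_4 = C_2, and the sixth order
reduces to A_6 = 2 * mean(r), B_6 = 0.  All six orders are emitted anyway
— the aliased high orders are rescaled copies of low-order information and
mean reflectance, and they take part in correlation screening and the
39-variable candidate set like any other feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_BANDS = 6
N_ORDERS = 6

#: C_t below this is treated as zero amplitude (phase defined as 0)
_ZERO_AMP = 1e-12


@dataclass
class HarmonicSet:
    """Constant, cosine/sine coefficients, amplitudes and phases."""

    a0_half: float
    A: np.ndarray  # (6,) cosine coefficients, orders t=1..6
    B: np.ndarray  # (6,) sine coefficients
    C: np.ndarray  # (6,) amplitudes, >= 0
    phi: np.ndarray  # (6,) phases in radians

    def to_vector(self) -> np.ndarray:
        """The 25 parameters in :func:`harmonic_feature_names` order."""
        return np.concatenate([[self.a0_half], self.A, self.B, self.C,
                               self.phi])


def harmonic_decompose(spectrum: np.ndarray) -> HarmonicSet:
    """Decompose a six-band spectrum into its 25 harmonic parameters.

    ``spectrum`` must be ordered by ascending wavelength; bands are indexed
    j = 1..6 in that order.
    """
    r = np.asarray(spectrum, dtype=np.float64)
    if r.shape != (N_BANDS,):
        raise ValueError(f"spectrum must be a 6-vector, got shape {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("spectrum must be finite")
    j = np.arange(1, N_BANDS + 1)
    t = np.arange(1, N_ORDERS + 1)
    ang = 2.0 * np.pi * np.outer(t, j) / N_BANDS  # (t, j)
    A = (2.0 / N_BANDS) * (np.cos(ang) @ r)
    B = (2.0 / N_BANDS) * (np.sin(ang) @ r)
    C = np.hypot(A, B)
    phi = np.where(C > _ZERO_AMP, np.arctan2(A, B), 0.0)
    return HarmonicSet(a0_half=float(r.mean()), A=A, B=B, C=C, phi=phi)


def harmonic_feature_names() -> list[str]:
    """Fixed order of the 25 harmonic feature-table columns."""
    return (["A0half"]
            + [f"A{t}" for t in range(1, N_ORDERS + 1)]
            + [f"B{t}" for t in range(1, N_ORDERS + 1)]
            + [f"C{t}" for t in range(1, N_ORDERS + 1)]
            + [f"PHI{t}" for t in range(1, N_ORDERS + 1)])
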