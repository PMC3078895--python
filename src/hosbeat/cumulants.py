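"""Sample cumulant diagonal slices of an ECG beat.

For a zero-mean sequence x of length L the 2nd-, 3rd- and 4th-order
cumulant diagonal slices at lag tau are estimated as

    c2(tau)       = (1/L) sum_i x_i x_{i+tau}
    c3(tau,tau)   = (1/L) sum_i x_i x_{i+tau}^2
    c4(tau,tau,tau) = (1/L) sum_i x_i x_{i+tau}^3 - 3 c2(tau) c2(0)

with the sum running over index pairs that stay inside the window (no
wraparound or zero padding) and biased 1/L normalisation at every lag,
which tapers large-lag estimates toward zero.  Each beat is mean-centered
first, so the cumulants are exactly blind to additive constants; cumulants
of order k scale as a^k under amplitude scaling by a, and orders 3 and 4
vanish in expectation for Gaussian inputs — the properties that make them
robust features for beat morphology.

Lags cover tau = -100..100, so each cumulant vector has the same length as
the beat and feeds the Hermite modelling stage unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import Beat, N_SAMPLES, R_INDEX

MAX_LAG = R_INDEX
LAGS = np.arange(-MAX_LAG, MAX_LAG + 1)


@dataclass(frozen=True)
class CumulantVector:
    """Diagonal-slice cumulant of one beat: 201 values over lags -100..100,
    units mV^order."""

    order: int
    values: np.ndarray

    def __post_init__(self):
        if self.order not in (2, 3, 4):
            raise ValueError("cumulant order must be 2, 3 or 4")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SAMPLES,):
            raise ValueError(f"cumulant vector must have {N_SAMPLES} lags")
        if not np.all(np.isfinite(v)):
            raise ValueError("cumulant values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def lags(self) -> np.ndarray:
        return LAGS


def center(x) -> np.ndarray:
    """Remove the sample mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot center an empty sequence")
    return x - x.mean()


def _lagged_moment(x: np.ndarray, y: np.ndarray, tau: int) -> float:
    """(1/L) sum_i x_i * y_{i+tau}, indices restricted to the window."""
    L = len(x)
    if tau >= 0:
        s = x[: L - tau] @ y[tau:]
    else:
        s = x[-tau:] @ y[: L + tau]
    return float(s) / L


def moment2(x, tau: int) -> float:
    """Biased lagged second moment (autocovariance of a centered sequence)."""
    x = np.asarray(x, dtype=float)
    if abs(tau) > len(x) - 1:
        raise ValueError(f"lag {tau} out of range for length {len(x)}")
    return _lagged_moment(x, x, tau)


def diagonal_slice(x, order: int, lags=None) -> np.ndarray:
    """Cumulant diagonal slice of a zero-mean sequence of any length.

    Evaluates c2(tau), c3(tau,tau) or c4(tau,tau,tau) at the requested lags
    (default -100..100) with biased 1/L normalisation.
    """
    x = np.asarray(x, dtype=float)
    lags = LAGS if lags is None else np.asarray(lags, dtype=int)
    if np.abs(lags).max() > len(x) - 1:
        raise ValueError("lag out of range for sequence length")
    if order == 2:
        return np.array([_lagged_moment(x, x, t) for t in lags])
    if order == 3:
        x2 = x * x
        return np.array([_lagged_moment(x, x2, t) for t in lags])
    if order == 4:
        x3 = x * x * x
        m2 = np.array([_lagged_moment(x, x, t) for t in lags])
        m2_0 = _lagged_moment(x, x, 0)
        m4 = np.array([_lagged_moment(x, x3, t) for t in lags])
        return m4 - 3.0 * m2 * m2_0
    raise ValueError("cumulant order must be 2, 3 or 4")


def _check_beat_input(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (N_SAMPLES,):
        raise ValueError(f"expected a centered {N_SAMPLES}-sample beat, got shape {x.shape}")
    return x


def cumulant2(x) -> CumulantVector:
    """Second-order cumulant slice (autocovariance) of a centered beat."""
    return CumulantVector(order=2, values=diagonal_slice(_check_beat_input(x), 2))


def cumulant3(x) -> CumulantVector:
    """Third-order cumulant diagonal slice of a centered beat."""
    return CumulantVector(order=3, values=diagonal_slice(_check_beat_input(x), 3))


def cumulant4(x) -> CumulantVector:
    """Fourth-order cumulant diagonal slice of a centered beat."""
    return CumulantVector(order=4, values=diagonal_slice(_check_beat_input(x), 4))


def cumulant_set(beat: Beat) -> tuple[CumulantVector, CumulantVector, CumulantVector]:
    """Center the beat once, then estimate the order-2/3/4 cumulant slices.

    Centering acts on the beat's waveform; the symbolic baseline offset
    drops out identically, so the cumulant set of an amplitude-shifted beat
    is bit-identical to that of the original.
    """
    x = center(beat.waveform)
    return cumulant2(x), cumulant3(x), cumulant4(x)
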