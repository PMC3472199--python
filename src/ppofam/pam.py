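"""Dayhoff/PAM substitution machinery.

The Dayhoff model treats amino-acid substitution as a reversible Markov chain.
One *PAM* (point accepted mutation) unit corresponds to an expected 1% of
sites substituted. This module builds the 1-PAM transition matrix from the
vendored Dayhoff exchangeabilities and equilibrium frequencies, exposes
``pam_matrix(n)`` (the n-step chain), the expected observed-difference curve
``expected_difference(n)``, and simulation helpers used both by the synthetic
family generator and by estimator-bias tests.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from ._dayhoff_data import AA_ORDER, DAYHOFF_EXCHANGEABILITIES, DAYHOFF_FREQUENCIES

AA = AA_ORDER
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_AA = 20

#: Maximum PAM distance (in PAM units, i.e. substitutions/site * 100) the
#: numeric inversion will report before declaring a pair saturated.
PAM_MAX = 500


def _rate_matrix() -> np.ndarray:
    """Reversible rate matrix Q scaled to 0.01 expected substitutions/site."""
    pi = np.asarray(DAYHOFF_FREQUENCIES, dtype=float)
    pi = pi / pi.sum()
    R = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            R[i, j] = R[j, i] = DAYHOFF_EXCHANGEABILITIES[k]
            k += 1
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # scale: expected rate -sum(pi_i * Q_ii) == 0.01 (one PAM step)
    rate = -np.dot(pi, np.diag(Q))
    return Q * (0.01 / rate)


@lru_cache(maxsize=1)
def equilibrium_frequencies() -> np.ndarray:
    pi = np.asarray(DAYHOFF_FREQUENCIES, dtype=float)
    return pi / pi.sum()


@lru_cache(maxsize=1)
def pam1_matrix() -> np.ndarray:
    """The 1-PAM transition probability matrix (rows sum to 1)."""
    return expm(_rate_matrix())


@lru_cache(maxsize=None)
def pam_matrix(n: int) -> np.ndarray:
    """Transition matrix after ``n`` PAM steps (n >= 0)."""
    if n < 0:
        raise ValueError("PAM step count must be non-negative")
    return np.linalg.matrix_power(pam1_matrix(), n)


@lru_cache(maxsize=1)
def _difference_curve() -> np.ndarray:
    """D[n] = expected proportion of observed differences after n PAM steps."""
    pi = equilibrium_frequencies()
    P = np.eye(N_AA)
    P1 = pam1_matrix()
    out = np.empty(PAM_MAX + 1)
    for n in range(PAM_MAX + 1):
        out[n] = 1.0 - float(np.dot(pi, np.diag(P)))
        P = P @ P1
    return out


def expected_difference(n: int) -> float:
    """Expected p-distance between two sequences n PAM steps apart."""
    if n <= PAM_MAX:
        return float(_difference_curve()[n])
    pi = equilibrium_frequencies()
    return 1.0 - float(np.dot(pi, np.diag(pam_matrix(n))))


def saturation_threshold() -> float:
    """Largest invertible observed difference (the curve's value at PAM_MAX)."""
    return float(_difference_curve()[-1])


def dayhoff_distance(p: float) -> float:
    """Invert the Dayhoff expected-difference curve.

    Parameters
    ----------
    p : observed proportion of differing sites (p-distance).

    Returns
    -------
    Evolutionary distance in substitutions per site (PAM/100). Monotone in
    ``p``; 0 maps to 0. Raises :class:`SaturationError` once ``p`` reaches
    the plateau of the curve (``saturation_threshold()``).
    """
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    curve = _difference_curve()
    if p >= curve[-1]:
        raise SaturationError(
            f"p-distance {p:.4f} is at or beyond the Dayhoff saturation "
            f"plateau ({curve[-1]:.4f})"
        )
    if p == 0.0:
        return 0.0
    n = int(np.searchsorted(curve, p, side="right")) - 1
    # linear interpolation between integer PAM steps
    frac = (p - curve[n]) / (curve[n + 1] - curve[n])
    return (n + frac) / 100.0


class SaturationError(ValueError):
    """Raised when an observed difference cannot be inverted to a distance."""


# ---------------------------------------------------------------------------
# simulation helpers


def sample_equilibrium(length: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a sequence (as residue indices) from the Dayhoff equilibrium."""
    return rng.choice(N_AA, size=length, p=equilibrium_frequencies())


def evolve(seq: np.ndarray, n_steps: int, rng: np.random.Generator,
           allowed: np.ndarray | None = None) -> np.ndarray:
    """Evolve index-encoded ``seq`` by ``n_steps`` PAM units.

    Uses the exact n-step transition matrix (one categorical draw per site,
    identical in law to n sequential 1-PAM draws). When ``allowed`` (a boolean
    mask over the 20 residues) is given, each row of the transition matrix is
    conditioned on landing inside the allowed set — used by the family
    generator to confine background sites to a reduced alphabet.
    """
    if n_steps == 0:
        return seq.copy()
    P = pam_matrix(n_steps)
    if allowed is not None:
        P = P * allowed[None, :]
        P = P / P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    u = rng.random(seq.shape[0])
    out = np.empty_like(seq)
    for s in np.unique(seq):
        mask = seq == s
        out[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return np.minimum(out, N_AA - 1)


def indices_to_str(seq: np.ndarray) -> str:
    return "".join(AA[i] for i in seq)


def str_to_indices(s: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in s], dtype=np.int64)
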