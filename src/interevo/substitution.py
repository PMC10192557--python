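"""Empirical amino-acid substitution models.

A time-reversible 20-state model is specified by symmetric exchangeabilities
``S`` and stationary frequencies ``pi``.  The instantaneous rate matrix is

    Q[i, j] = S[i, j] * pi[j]   (i != j),

with the diagonal chosen so rows sum to zero, rescaled so that the expected
number of substitutions per unit branch length, ``-sum_i pi_i * Q[i, i]``,
equals 1.  Transition probabilities ``P(t) = expm(Q t)`` are computed exactly
through the symmetric eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``,
which is symmetric for any reversible Q.

The JTT model (Jones, Taylor & Thornton 1992) ships with the package as a
plain-text data file; see :func:`jtt`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Canonical amino-acid order used throughout (the order of jtt.dat / PAML .dat files).
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Characters treated as missing data in alignment columns.
MISSING_CHARS = frozenset("-X?.")

_EIG_CLIP = 1e-12  # magnitude below which negative P(t) entries are treated as roundoff


@dataclass
class AAModel:
    """Reversible 20-state amino-acid model with precomputed spectral form.

    Parameters
    ----------
    exchangeabilities:
        Symmetric non-negative (20, 20) matrix; the diagonal is ignored.
    frequencies:
        Stationary distribution pi (length 20, positive, sums to 1 after
        normalization here).
    name:
        Free-form label recorded in outputs.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    name: str = "custom"
    alphabet: str = AA_ALPHABET
    rate_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20):
            raise ValueError(f"exchangeabilities must be 20x20, got {S.shape}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale

        self.exchangeabilities = S
        self.frequencies = pi
        self.rate_matrix = Q

        # spectral decomposition of the pi-symmetrized rate matrix
        sqrt_pi = np.sqrt(pi)
        B = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # enforce exact symmetry against roundoff
        self._eigval, self._eigvec = np.linalg.eigh(B)
        self._sqrt_pi = sqrt_pi

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Return the row-stochastic transition matrix P(t) = expm(Q t).

        Branch length ``t`` is in expected substitutions per site; ``t < 0``
        raises ``ValueError``.  Entries that come out of the eigendecomposition
        a few ulps below zero are clipped and the rows renormalized.
        """
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        V = self._eigvec
        expd = np.exp(self._eigval * t)
        P = (V * expd[None, :]) @ V.T
        P = P / self._sqrt_pi[:, None] * self._sqrt_pi[None, :]
        if P.min() < -_EIG_CLIP * max(1.0, t):
            raise FloatingPointError("transition matrix has significantly negative entries")
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def state_index(self, ch: str) -> int | None:
        """Index of an amino-acid character, or None for missing (gap/X)."""
        c = ch.upper()
        if c in MISSING_CHARS:
            return None
        idx = self.alphabet.find(c)
        if idx < 0:
            raise ValueError(f"character {ch!r} is not an amino acid or gap/X")
        return idx

    def permuted_frequencies(self, rng: np.random.Generator) -> "AAModel":
        """Same exchangeabilities with randomly permuted stationary frequencies.

        Useful as a deliberately misspecified control model.
        """
        perm = rng.permutation(self.n_states)
        return AAModel(self.exchangeabilities, self.frequencies[perm],
                       name=f"{self.name}+freq-permuted")


def _read_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = [ln for ln in (l.strip() for l in text.splitlines())
            if ln and not ln.startswith("#")]
    values = [float(tok) for ln in rows for tok in ln.split()]
    if len(values) != 190 + 20:
        raise ValueError(f"model file must hold 190 exchangeabilities + 20 frequencies, "
                         f"got {len(values)} numbers")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[190:])
    return S, pi


def jtt() -> AAModel:
    """The JTT empirical amino-acid model, loaded from the shipped data file."""
    text = resources.files("interevo.data").joinpath("jtt.dat").read_text()
    S, pi = _read_dat(text)
    return AAModel(S, pi, name="JTT")
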