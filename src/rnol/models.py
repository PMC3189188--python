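"""Continuous-time Markov substitution models.

A :class:`SubstitutionModel` couples a time-reversible rate matrix Q with
stationary frequencies, optional discrete-gamma rate variation and an
optional invariant-site proportion.  Q is scaled so one unit of branch
length equals one expected substitution per site at stationarity, which
makes branch lengths comparable across models.

Available models: the empirical JTT amino-acid model (published constants
embedded in :mod:`rnol._jtt`), a Poisson (equal-rates) protein model, and
the Kimura two-parameter nucleotide model.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from rnol._jtt import AA_ORDER, JTT_EXCHANGE_LOWER, JTT_FREQS

__all__ = ["SubstitutionModel", "jtt_model", "poisson_protein_model", "k2p_model",
           "discrete_gamma_rates"]

NT_ORDER = "ACGT"


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-gamma categories.

    Gamma with shape ``alpha`` and mean 1; category means computed from the
    incomplete gamma function (the standard discretisation).
    """
    if alpha <= 0 or k < 1:
        raise ValueError("alpha > 0 and k >= 1 required")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # P(X <= x) for shape alpha+1 gives the partial expectation of shape alpha
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """A reversible CTMC over a residue alphabet.

    Parameters
    ----------
    alphabet : str
        Residue codes in matrix order.
    exchangeabilities : (n, n) array
        Symmetric, non-negative; diagonal ignored.
    freqs : (n,) array
        Stationary frequencies, summing to 1.
    gamma_shape, gamma_categories :
        Optional discrete-gamma rate variation (mean-1 category rates).
    pinv :
        Optional proportion of invariant sites in [0, 1).
    """

    def __init__(self, alphabet: str, exchangeabilities, freqs,
                 gamma_shape: Optional[float] = None, gamma_categories: int = 4,
                 pinv: float = 0.0, name: str = "custom"):
        self.alphabet = alphabet
        self.n_states = len(alphabet)
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if S.shape != (self.n_states, self.n_states):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("frequencies must sum to 1 (got %r)" % pi.sum())
        if np.any(pi <= 0):
            raise ValueError("frequencies must be positive")
        if not (0.0 <= pinv < 1.0):
            raise ValueError("pinv must be in [0, 1)")
        self.freqs = pi / pi.sum()
        Q = S * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale: 1 expected substitution per site per unit branch length
        mu = -(self.freqs * np.diag(Q)).sum()
        self.Q = Q / mu
        self.name = name
        self.pinv = float(pinv)
        self.gamma_shape = gamma_shape
        self.gamma_categories = int(gamma_categories)
        if gamma_shape is not None:
            self.rates = discrete_gamma_rates(gamma_shape, self.gamma_categories)
        else:
            self.rates = np.ones(1)
        # eigendecomposition of the pi^(1/2)-symmetrised generator
        sq = np.sqrt(self.freqs)
        B = (self.Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0
        w, U = np.linalg.eigh(B)
        self._eigval = w
        self._left = U.T * sq[None, :]
        self._right = U / sq[:, None]

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._right * np.exp(self._eigval * rate * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> list[np.ndarray]:
        """One P(t) per rate category."""
        return [self.transition_matrix(t, r) for r in self.rates]

    def expected_identity(self, t: float) -> float:
        """Probability a site is identical across a path of length ``t``,
        at stationarity (rate mixture and pinv included)."""
        acc = 0.0
        for r in self.rates:
            P = self.transition_matrix(t, r)
            acc += (self.freqs * np.diag(P)).sum() / len(self.rates)
        return self.pinv + (1.0 - self.pinv) * acc

    def encode(self, seq: str) -> np.ndarray:
        idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out = self._lookup()[idx]
        if np.any(out == 255):
            bad = sorted(set(seq) - set(self.alphabet))
            raise ValueError("residues outside model alphabet: %s" % bad)
        return out

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.alphabet[c] for c in codes)

    def _lookup(self) -> np.ndarray:
        if not hasattr(self, "_lut"):
            lut = np.full(128, 255, dtype=np.uint8)
            for i, ch in enumerate(self.alphabet):
                lut[ord(ch)] = i
            self._lut = lut
        return self._lut

    def __repr__(self):
        extras = []
        if self.gamma_shape is not None:
            extras.append("gamma(%g, k=%d)" % (self.gamma_shape, self.gamma_categories))
        if self.pinv:
            extras.append("pinv=%g" % self.pinv)
        return "<SubstitutionModel %s%s>" % (self.name,
                                             (" " + " ".join(extras)) if extras else "")


def _jtt_exchange_matrix() -> np.ndarray:
    S = np.zeros((20, 20))
    it = iter(JTT_EXCHANGE_LOWER)
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return S


def jtt_model(gamma_shape: Optional[float] = None, gamma_categories: int = 4,
              pinv: float = 0.0) -> SubstitutionModel:
    """The empirical JTT amino-acid replacement model."""
    return SubstitutionModel(AA_ORDER, _jtt_exchange_matrix(), JTT_FREQS,
                             gamma_shape=gamma_shape,
                             gamma_categories=gamma_categories,
                             pinv=pinv, name="JTT")


def poisson_protein_model(**kw) -> SubstitutionModel:
    """Equal-rates, equal-frequency amino-acid model."""
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(AA_ORDER, S, np.full(20, 0.05), name="Poisson", **kw)


def k2p_model(kappa: float = 2.0, **kw) -> SubstitutionModel:
    """Kimura two-parameter nucleotide model (transition/transversion
    ratio ``kappa``, uniform base frequencies)."""
    S = np.ones((4, 4))
    np.fill_diagonal(S, 0.0)
    # transitions: A<->G (0,2), C<->T (1,3)
    S[0, 2] = S[2, 0] = kappa
    S[1, 3] = S[3, 1] = kappa
    return SubstitutionModel(NT_ORDER, S, np.full(4, 0.25), name="K2P", **kw)
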