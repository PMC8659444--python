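"""Bandt–Pompe ordinal patterns and permutation entropy (PE).

PE quantifies the complexity of a time series through the distribution of
rank orderings ("ordinal patterns") of overlapping delay vectors.  For an
embedding dimension ``m`` and delay ``tau``, each vector
``(x[t], x[t+tau], ..., x[t+(m-1)tau])`` is mapped to the permutation that
sorts it ascending (ties broken by order of appearance), and PE is the
Shannon entropy of the empirical pattern distribution in bits::

    PE_m = -sum_i p_i * log2(p_i)

A perfectly monotone series has PE 0; iid continuous noise approaches the
maximum ``log2(m!)``.  Because patterns depend only on ranks, PE is exactly
invariant under strictly monotone transforms of the signal, which is what
makes it robust to amplitude drift and calibration differences between EEG
channels.  Low PE in a pre-ictal window signals increased regularity of the
underlying dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeConfig",
    "OrdinalPatternDistribution",
    "ordinal_pattern_index",
    "ordinal_distribution",
    "permutation_entropy",
    "pe_feature_matrix",
]


@dataclass(frozen=True)
class PeConfig:
    """Parameters of the ordinal embedding.

    m : embedding dimension (number of samples per ordinal vector), >= 2.
    tau : embedding delay in samples, >= 1.
    normalize : divide the entropy by log2(m!) so results lie in [0, 1].
    """

    m: int = 3
    tau: int = 1
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"embedding delay tau must be >= 1, got {self.tau}")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.m)

    def check_length(self, n: int) -> None:
        """Warn when a series is too short to populate the pattern space."""
        if n < 10 * self.n_patterns:
            warnings.warn(
                f"series of length {n} gives sparse coverage of the "
                f"{self.n_patterns} ordinal patterns (m={self.m})",
                stacklevel=3,
            )


@dataclass
class OrdinalPatternDistribution:
    """Empirical counts over the m! ordinal patterns of one series.

    ``counts[i]`` is the number of delay vectors whose sorting permutation
    has lexicographic index ``i``.
    """

    m: int
    tau: int
    counts: np.ndarray
    n_vectors: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (math.factorial(self.m),):
            raise ValueError("counts must have length m!")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.n_vectors = int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_vectors

    def entropy(self, normalize: bool = True) -> float:
        """Shannon entropy in bits; 0*log(0) terms are dropped."""
        p = self.probabilities
        p = p[p > 0]
        h = float(-(p * np.log2(p)).sum())
        if normalize:
            h /= math.log2(math.factorial(self.m))
        return h + 0.0  # avoid IEEE -0.0 for single-pattern series


def ordinal_pattern_index(v: np.ndarray) -> int:
    """Lexicographic index in [0, m!) of the permutation sorting ``v``.

    The permutation lists the positions of the values in ascending order;
    equal values keep their order of appearance (stable ranking), so
    (2, 2, 1) maps to the permutation (2, 0, 1).
    """
    v = np.asarray(v)
    if v.ndim != 1:
        raise ValueError("pattern vector must be one-dimensional")
    perm = np.argsort(v, kind="stable")
    return _lehmer_index(perm)


def _lehmer_index(perm: np.ndarray) -> int:
    """Lexicographic rank of a permutation of 0..m-1 (Lehmer code)."""
    m = len(perm)
    idx = 0
    for i in range(m):
        smaller_later = int(np.sum(perm[i + 1 :] < perm[i]))
        idx += smaller_later * math.factorial(m - 1 - i)
    return idx


def _pattern_indices(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Lexicographic pattern index of every overlapping delay vector of x."""
    n = x.shape[-1]
    n_vec = n - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau} "
            f"(needs at least {(m - 1) * tau + 1})"
        )
    # delay-embedding matrix [..., n_vec, m] as a strided view (no copy)
    emb = np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1, axis=-1)
    emb = emb[..., ::tau]
    perms = np.argsort(emb, axis=-1, kind="stable")
    # vectorized Lehmer code
    idx = np.zeros(perms.shape[:-1], dtype=np.int64)
    for i in range(m):
        smaller_later = (perms[..., i + 1 :] < perms[..., i : i + 1]).sum(axis=-1)
        idx += smaller_later * math.factorial(m - 1 - i)
    return idx


def ordinal_distribution(x: np.ndarray, cfg: PeConfig = PeConfig()) -> OrdinalPatternDistribution:
    """Count ordinal patterns over all overlapping delay vectors of ``x``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional series")
    cfg.check_length(len(x))
    idx = _pattern_indices(x, cfg.m, cfg.tau)
    counts = np.bincount(idx, minlength=cfg.n_patterns)
    return OrdinalPatternDistribution(m=cfg.m, tau=cfg.tau, counts=counts)


def permutation_entropy(x: np.ndarray, cfg: PeConfig = PeConfig()) -> float:
    """Permutation entropy of ``x`` in bits (or in [0,1] if normalized)."""
    return ordinal_distribution(x, cfg).entropy(normalize=cfg.normalize)


def pe_feature_matrix(windows, cfg: PeConfig = PeConfig()):
    """PE of every (window, channel) pair.

    Parameters
    ----------
    windows : sequence of LabeledWindow
        Homogeneous windows (same channel count and sample length).
    cfg : PeConfig

    Returns
    -------
    X : ndarray [n_windows, n_channels]
        ``X[i, c]`` is the PE of channel ``c`` (montage order) of window i.
    y : ndarray of str
        Window labels aligned with the rows of ``X``.
    """
    if len(windows) == 0:
        raise ValueError("no windows given")
    shapes = {w.data.shape for w in windows}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous window shapes: {sorted(shapes)}")
    data = np.stack([np.asarray(w.data, dtype=float) for w in windows])
    cfg.check_length(data.shape[-1])
    idx = _pattern_indices(data, cfg.m, cfg.tau)  # [n_win, n_ch, n_vec]
    n_vec = idx.shape[-1]
    norm = math.log2(cfg.n_patterns) if cfg.normalize else 1.0
    X = np.empty(idx.shape[:2], dtype=float)
    for i in range(idx.shape[0]):
        for c in range(idx.shape[1]):
            p = np.bincount(idx[i, c], minlength=cfg.n_patterns) / n_vec
            p = p[p > 0]
            X[i, c] = -(p * np.log2(p)).sum() / norm + 0.0
    y = np.array([w.label for w in windows])
    return X, y
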