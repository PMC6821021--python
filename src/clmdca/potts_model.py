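"""The Potts (Markov random field) parameter container and coupling scores.

A Potts model over L aligned columns with a q-letter alphabet assigns every
sequence x the probability

    P(x) = (1/Z) exp{ sum_i h_i(x_i) + sum_{i<j} e_ij(x_i, x_j) },

with singleton fields h_i(a) and pair couplings e_ij(a, b).  Couplings are
stored once per unordered pair {i, j} with i < j; accessing the pair the
other way round transposes the shared matrix, so e_ij(a, b) = e_ji(b, a) is
structural rather than enforced numerically.

The contact-ranking statistic is the Frobenius coupling strength

    J_ij = sqrt( sum_{a,b} e_ij(a, b)^2 ),

which is gauge-dependent: by default it is computed after shifting the model
to the zero-sum gauge (every pair matrix has zero row and column means, the
shifts being absorbed into the fields so the distribution is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def pair_index(i: int, j: int, length: int) -> int:
    """Lexicographic index of the unordered pair {i, j}, i < j, in 0..P-1."""
    if not 0 <= i < j < length:
        raise IndexError(f"invalid pair ({i}, {j}) for length {length}")
    return i * (2 * length - i - 1) // 2 + (j - i - 1)


def pair_list(length: int) -> np.ndarray:
    """All (i, j) with i < j in lexicographic order; shape (P, 2)."""
    return np.array([(i, j) for i in range(length) for j in range(i + 1, length)])


@dataclass
class PottsParameters:
    """Singleton fields and pair couplings of one Potts model.

    Attributes
    ----------
    h : ndarray of shape (L, q)
        Fields h_i(a) in log-potential units.
    e : ndarray of shape (L*(L-1)//2, q, q)
        Coupling matrices e_ij in lexicographic pair order, i < j.
    """

    h: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64)
        self.e = np.asarray(self.e, dtype=np.float64)
        if self.h.ndim != 2:
            raise ValueError("h must be an (L, q) matrix")
        length, q = self.h.shape
        if length < 2 or q < 2:
            raise ValueError(f"need L >= 2 and q >= 2, got L={length}, q={q}")
        n_pairs = length * (length - 1) // 2
        if self.e.shape != (n_pairs, q, q):
            raise ValueError(
                f"e must have shape ({n_pairs}, {q}, {q}), got {self.e.shape}"
            )
        if not (np.isfinite(self.h).all() and np.isfinite(self.e).all()):
            raise ValueError("parameters must be finite")

    # -- construction -----------------------------------------------------
    @classmethod
    def zeros(cls, length: int, q: int) -> "PottsParameters":
        if length < 2 or q < 2:
            raise ValueError(f"need L >= 2 and q >= 2, got L={length}, q={q}")
        n_pairs = length * (length - 1) // 2
        return cls(np.zeros((length, q)), np.zeros((n_pairs, q, q)))

    # -- basic queries -----------------------------------------------------
    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.e.shape[0]

    def coupling(self, i: int, j: int) -> np.ndarray:
        """The q x q matrix e_ij(a, b); for i > j returns the transpose view."""
        if i == j:
            raise IndexError("diagonal pairs are not stored")
        if i < j:
            return self.e[pair_index(i, j, self.length)]
        return self.e[pair_index(j, i, self.length)].T

    def copy(self) -> "PottsParameters":
        return PottsParameters(self.h.copy(), self.e.copy())

    # -- flat-vector view for optimisers ----------------------------------
    @property
    def n_parameters(self) -> int:
        return self.h.size + self.e.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.h.ravel(), self.e.ravel()])

    @classmethod
    def from_vector(cls, vec, length: int, q: int) -> "PottsParameters":
        vec = np.asarray(vec, dtype=np.float64)
        nh = length * q
        h = vec[:nh].reshape(length, q)
        e = vec[nh:].reshape(length * (length - 1) // 2, q, q)
        return cls(h, e)

    def coupling_block_matrix(self) -> np.ndarray:
        """Dense symmetric (L*q, L*q) block matrix W with W[(i,a),(j,b)] = e_ij(a,b).

        Diagonal blocks are zero.  Convenient for vectorised energy sums:
        the per-sequence field F_i(a) = h_i(a) + sum_{k != i} e_ik(a, x_k)
        is h.ravel() + onehot(x) @ W.
        """
        length, q = self.length, self.q
        w = np.zeros((length, q, length, q))
        pairs = pair_list(length)
        w[pairs[:, 0], :, pairs[:, 1], :] = self.e
        w[pairs[:, 1], :, pairs[:, 0], :] = self.e.transpose(0, 2, 1)
        return w.reshape(length * q, length * q)


def init_parameters(length: int, q: int, init: str = "zeros") -> PottsParameters:
    if init != "zeros":
        raise ValueError(f"unknown initialisation: {init!r}")
    return PottsParameters.zeros(length, q)


def sequence_energy(params: PottsParameters, seq) -> float:
    """Unnormalised log-probability sum_i h_i(x_i) + sum_{i<j} e_ij(x_i, x_j)."""
    seq = np.asarray(seq)
    if seq.shape != (params.length,):
        raise ValueError(f"sequence length {seq.shape} != L={params.length}")
    if seq.min() < 0 or seq.max() >= params.q:
        raise ValueError("symbol code out of range for this model")
    pairs = pair_list(params.length)
    field_part = params.h[np.arange(params.length), seq].sum()
    pair_part = params.e[np.arange(params.n_pairs), seq[pairs[:, 0]], seq[pairs[:, 1]]].sum()
    return float(field_part + pair_part)


def zero_sum_gauge(params: PottsParameters) -> PottsParameters:
    """Return an equivalent model whose pair matrices have zero row/column means.

    The gauge shift moves the row means into h_i and the column means into
    h_j, so per-sequence energies (and hence the distribution) are preserved
    exactly.  Idempotent.
    """
    out = params.copy()
    row_means = params.e.mean(axis=2)          # (P, q)  mean over b
    col_means = params.e.mean(axis=1)          # (P, q)  mean over a
    totals = params.e.mean(axis=(1, 2))        # (P,)
    out.e = (
        params.e
        - row_means[:, :, None]
        - col_means[:, None, :]
        + totals[:, None, None]
    )
    pairs = pair_list(params.length)
    np.add.at(out.h, pairs[:, 0], row_means - totals[:, None])
    np.add.at(out.h, pairs[:, 1], col_means)
    return out


def frobenius_scores(
    params: PottsParameters, gauge: bool = True, apc: bool = False
) -> np.ndarray:
    """Symmetric L x L matrix of Frobenius coupling strengths J_ij.

    Parameters
    ----------
    gauge : bool
        Shift to the zero-sum gauge before taking norms (default).  The raw
        norm of the stored matrices is used when False.
    apc : bool
        Apply the average-product correction to the score matrix.  Off by
        default; the plain Frobenius norm is the reference statistic.
    """
    p = zero_sum_gauge(params) if gauge else params
    norms = np.sqrt((p.e ** 2).sum(axis=(1, 2)))
    length = params.length
    scores = np.zeros((length, length))
    pairs = pair_list(length)
    scores[pairs[:, 0], pairs[:, 1]] = norms
    scores[pairs[:, 1], pairs[:, 0]] = norms
    if apc:
        col = scores.sum(axis=0) / (length - 1)
        mean = scores.sum() / (length * (length - 1))
        scores = scores - np.outer(col, col) / mean
        np.fill_diagonal(scores, 0.0)
    return scores
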