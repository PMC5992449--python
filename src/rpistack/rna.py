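"""RNA feature encoding: k-mer sparse occurrence matrix reduced by SVD.

An RNA sequence of length ``L`` is scanned left to right with a window of
``k`` nucleotides, producing a binary occurrence matrix with one row per
possible k-mer (``4**k`` rows, lexicographic over ``A < C < G < U``) and one
column per window (``L - k + 1`` columns); each column holds a single 1 in
the row of the k-mer observed at that position.  The matrix is then collapsed
to a fixed-length vector by a rank-1 singular value decomposition: the
leading left singular vector scaled by the leading singular value, which
lives in the ``4**k``-dimensional k-mer space regardless of sequence length.
At the default ``k = 4`` this yields the 256-dimensional RNA descriptor used
throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import RNA_ALPHABET, SequenceRecord

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


def kmer_index(kmer: str) -> int:
    """Lexicographic row index of a k-mer under A < C < G < U."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


@dataclass(frozen=True)
class KmerSparseMatrix:
    """Binary 4^k x (L-k+1) k-mer occurrence matrix for one RNA sequence."""

    k: int
    L: int
    M: sp.csc_matrix

    @property
    def n_windows(self) -> int:
        return self.L - self.k + 1


def build_kmer_matrix(seq: SequenceRecord | str, k: int = 4) -> KmerSparseMatrix:
    """Build the k-mer occurrence matrix of an RNA sequence.

    Column ``j`` (0-based) has its single 1 in the row indexing the k-mer
    that starts at position ``j``.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if isinstance(seq, SequenceRecord) and seq.kind != "rna":
        raise ValueError("build_kmer_matrix expects an RNA record")
    if k < 1:
        raise ValueError("k must be positive")
    L = len(s)
    if L < k:
        raise ValueError(
            f"sequence length {L} is shorter than the minimum length k={k}"
        )
    n_cols = L - k + 1
    rows = np.empty(n_cols, dtype=np.int64)
    idx = kmer_index(s[:k])
    rows[0] = idx
    mask = 4 ** (k - 1)
    for j in range(1, n_cols):
        # rolling update: drop the leading base, append the next one
        idx = (idx % mask) * 4 + _BASE_INDEX[s[j + k - 1]]
        rows[j] = idx
    M = sp.csc_matrix(
        (np.ones(n_cols), (rows, np.arange(n_cols))), shape=(4**k, n_cols)
    )
    return KmerSparseMatrix(k=k, L=L, M=M)


def svd_reduce(m: KmerSparseMatrix) -> np.ndarray:
    """Collapse a k-mer matrix to sigma_1 * u_1, its best rank-1 left factor.

    The sign is fixed so the largest-magnitude component is positive, making
    the output deterministic (singular vectors are otherwise defined only up
    to sign).  The leading left pair is obtained from the symmetric
    eigendecomposition of the small 4^k x 4^k Gram matrix M M^T, which is
    exactly reproducible run to run (iterative sparse SVD solvers are not).
    """
    M = m.M
    gram = (M @ M.T).toarray()
    evals, evecs = np.linalg.eigh(gram)
    s1 = np.sqrt(max(evals[-1], 0.0))
    u1 = evecs[:, -1]
    vec = s1 * u1
    peak = np.argmax(np.abs(vec))
    if vec[peak] < 0:
        vec = -vec
    return vec


def encode_rna(seq: SequenceRecord | str, k: int = 4) -> np.ndarray:
    """Encode an RNA sequence as a 4^k-dimensional vector (256 at k=4)."""
    return svd_reduce(build_kmer_matrix(seq, k=k))
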