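"""k-mer composition feature vectors and PCA projection.

A sequence is encoded by the fraction of each k-mer over the 20-letter
amino-acid alphabet: the block for a given k has length 20**k and its i-th
entry is the fraction of windows equal to the i-th k-mer in lexicographic
order over ``ACDEFGHIKLMNPQRSTVWY``.  Hybrid vectors concatenate blocks for
several k in ascending order; the combination {1, 2, 4} (amino-acid,
dipeptide and tetrapeptide composition, 160 420 dimensions) is the default
used by the classifier benchmarks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA

from .seqio import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class FeatureVector:
    """Concatenated k-mer composition blocks, one block per chosen k."""

    ks: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = sum(20**k for k in self.ks)
        if len(self.values) != expected:
            raise ValueError(f"expected length {expected}, got {len(self.values)}")

    def block(self, k: int) -> np.ndarray:
        """The composition block for one k value."""
        off = 0
        for kk in self.ks:
            size = 20**kk
            if kk == k:
                return self.values[off : off + size]
            off += size
        raise KeyError(k)


def kmer_composition(seq: SequenceRecord | str, k: int) -> np.ndarray:
    """Fraction of each k-mer in the sequence (length-20**k block).

    Windows containing the ambiguity letter X are excluded from both the
    numerator and the denominator.  A sequence shorter than k (or with no
    valid window) yields an all-zero block and a warning.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    block = np.zeros(20**k)
    codes = np.array([_AA_INDEX.get(c, -1) for c in residues], dtype=np.int64)
    n = len(codes) - k + 1
    if n < 1:
        logger.warning("sequence shorter than k=%d; returning zero block", k)
        return block
    # index of window starting at i: base-20 value of its residue codes
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        idx = idx * 20 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    if not valid.any():
        logger.warning("no valid k=%d windows (all contain X); returning zero block", k)
        return block
    counts = np.bincount(idx[valid], minlength=20**k).astype(float)
    return counts / valid.sum()


def hybrid_features(seq: SequenceRecord | str, ks: Iterable[int]) -> FeatureVector:
    """Concatenation of k-mer composition blocks in ascending k order."""
    ks = tuple(sorted(set(ks)))
    if not ks:
        raise ValueError("ks must be non-empty")
    values = np.concatenate([kmer_composition(seq, k) for k in ks])
    return FeatureVector(ks=ks, values=values)


def feature_matrix(seqs: Sequence[SequenceRecord | str], ks: Iterable[int], sparse_output: bool = True):
    """Stacked hybrid feature vectors for many sequences.

    Returns a CSR matrix by default; composition vectors are extremely
    sparse for k=4 (at most len(seq)-3 non-zeros out of 160 000).
    """
    ks = tuple(sorted(set(ks)))
    rows = [hybrid_features(s, ks).values for s in seqs]
    mat = np.vstack(rows) if rows else np.zeros((0, sum(20**k for k in ks)))
    return sparse.csr_matrix(mat) if sparse_output else mat


def pca_project(vectors: Sequence[FeatureVector] | np.ndarray, n_components: int = 2):
    """Project feature vectors onto principal components.

    Returns (projected coordinates, explained-variance fractions).  Constant
    data has zero variance everywhere; in that case zero projections are
    returned with a warning.
    """
    if isinstance(vectors, np.ndarray):
        X = vectors
    else:
        X = np.vstack([v.values for v in vectors])
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(dim, count)")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        warnings.warn("constant data: zero variance, returning zero projections")
        return np.zeros((X.shape[0], n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(X)
    return proj, pca.explained_variance_ratio_
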