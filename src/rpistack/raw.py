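"""Raw composition features: RNA 4-mer and protein conjoint-triad frequencies.

These are the classic sequence-composition descriptors used by RPISeq-style
predictors: normalised sliding-window 4-mer frequencies for the RNA (256
values, same lexicographic indexing as the k-mer matrix encoder) and
conjoint-triad frequencies for the protein, where each residue is first
reduced to one of 7 physicochemical classes and 3-mer class frequencies are
counted over the 7^3 = 343 possible triads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord
from .rna import kmer_index

#: The 7-class conjoint-triad reduction of the amino-acid alphabet.
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

_CLASS_OF = {aa: ci for ci, grp in enumerate(CONJOINT_CLASSES) for aa in grp}


@dataclass(frozen=True)
class RawPairFeatures:
    """Concatenable raw features for one pair: 256 RNA + 343 protein values."""

    rna_freq: np.ndarray
    protein_freq: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.rna_freq, self.protein_freq])


def rna_4mer_freq(seq: SequenceRecord | str) -> np.ndarray:
    """Normalised sliding-window 4-mer frequencies (256 values, sum 1)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    k = 4
    if len(s) < k:
        raise ValueError(f"sequence length {len(s)} < {k}")
    counts = np.zeros(4**k)
    for j in range(len(s) - k + 1):
        counts[kmer_index(s[j : j + k])] += 1
    return counts / counts.sum()


def protein_triad_freq(seq: SequenceRecord | str) -> np.ndarray:
    """Normalised conjoint-triad frequencies (343 values, sum 1)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if len(s) < 3:
        raise ValueError(f"sequence length {len(s)} < 3")
    classes = [_CLASS_OF[a] for a in s]
    counts = np.zeros(7**3)
    for j in range(len(classes) - 2):
        idx = classes[j] * 49 + classes[j + 1] * 7 + classes[j + 2]
        counts[idx] += 1
    return counts / counts.sum()


def raw_pair_features(
    rna: SequenceRecord | str, protein: SequenceRecord | str
) -> RawPairFeatures:
    """Raw composition features for one candidate RNA-protein pair."""
    return RawPairFeatures(
        rna_freq=rna_4mer_freq(rna), protein_freq=protein_triad_freq(protein)
    )
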