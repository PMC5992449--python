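"""Encode one RNA and one protein into their fixed-length feature vectors.

The RNA becomes a 256-vector: its binary 4-mer occurrence matrix (one row
per possible 4-mer, one column per sequence window) collapsed to the leading
singular vector scaled by the leading singular value.  The protein becomes a
240-vector of pseudo-Zernike moment magnitudes of its logistic-squashed
PSSM; here the PSSM is the offline BLOSUM62 pseudo-profile.
"""

import numpy as np

from rpistack import (
    SequenceRecord, build_kmer_matrix, encode_protein, encode_rna, pseudo_pssm,
)

rna = SequenceRecord(
    id="rna1",
    seq="ACGUGGACUCAAGUACGUCCGAUAGCUUAGGCAUCGAUCGGGACUCAUAAGCU",
    kind="rna",
)
m = build_kmer_matrix(rna, k=4)
print(f"k-mer matrix: {m.M.shape[0]} x {m.M.shape[1]} "
      f"({m.n_windows} windows, every column sums to 1)")
v_rna = encode_rna(rna)
print(f"RNA feature vector: length {v_rna.size}, "
      f"norm {np.linalg.norm(v_rna):.3f} "
      f"(= leading singular value of the matrix)")

protein = SequenceRecord(
    id="prot1",
    seq="MKVLHWKRDEACDEFGHIKLMNPQRSTVWYAAGGVVILFPYMTSHNQWRKDEC",
    kind="protein",
)
pssm = pseudo_pssm(protein)
v_prot = encode_protein(pssm)
print(f"PSSM: {pssm.length} x 20; protein feature vector: length "
      f"{v_prot.size}, all magnitudes >= 0 ({v_prot.min():.3f} min)")
print(f"pair vector for a candidate pair: {v_rna.size} + {v_prot.size} = "
      f"{v_rna.size + v_prot.size} values")
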