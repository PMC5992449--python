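"""Pair-level feature assembly and the end-to-end predictor.

A candidate pair is described by two feature blocks:

* the 496-dimensional pair vector — 256 RNA values (k-mer matrix reduced by
  SVD) concatenated with 240 protein values (pseudo-Zernike moment
  magnitudes of the PSSM) — consumed by the stacked auto-encoder branch;
* the 599-dimensional raw composition vector — 256 RNA 4-mer frequencies
  plus 343 protein conjoint-triad frequencies — consumed by the RPISeq-style
  forest.

Per-sequence encodings are computed once and reused across pairs.  PSSMs
come from a directory of PSI-BLAST ASCII files, a preloaded mapping, or the
offline BLOSUM62 pseudo-profile.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import joblib
import numpy as np

from . import ensemble as ens
from .io import PSSM, InteractionPair, SequenceRecord, check_pairs_resolve, read_pssm
from .protein import encode_protein, pseudo_pssm
from .raw import protein_triad_freq, rna_4mer_freq
from .rna import encode_rna

PAIR_DIM = 256 + 240  # RNA SVD block + protein moment block
RAW_DIM = 256 + 343  # RNA 4-mer block + protein conjoint-triad block


def resolve_pssms(
    proteins: Sequence[SequenceRecord],
    pssms: "Mapping[str, PSSM] | str | Path | None" = None,
) -> Dict[str, PSSM]:
    """Produce one PSSM per protein from a mapping, a directory, or offline.

    A directory is searched for ``<id>.pssm`` files; ``None`` falls back to
    the BLOSUM62 pseudo-profile for every protein.
    """
    if pssms is None:
        return {p.id: pseudo_pssm(p) for p in proteins}
    if isinstance(pssms, (str, Path)):
        out = {}
        for p in proteins:
            f = Path(pssms) / f"{p.id}.pssm"
            if not f.exists():
                raise FileNotFoundError(f"no PSSM file for {p.id!r} at {f}")
            out[p.id] = read_pssm(f)
        return out
    missing = [p.id for p in proteins if p.id not in pssms]
    if missing:
        raise KeyError(f"missing PSSMs for proteins: {missing[:5]}")
    return dict(pssms)


def build_pair_features(
    pairs: Sequence[InteractionPair],
    rnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    pssms: "Mapping[str, PSSM] | str | Path | None" = None,
    k: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrices (n x 486 pair block, n x 599 raw block) for pairs."""
    check_pairs_resolve(pairs, rnas, proteins)
    rna_by_id = {r.id: r for r in rnas}
    prot_by_id = {p.id: p for p in proteins}
    pssm_by_id = resolve_pssms(proteins, pssms)

    rna_svd = {rid: encode_rna(rec, k=k) for rid, rec in rna_by_id.items()}
    rna_raw = {rid: rna_4mer_freq(rec) for rid, rec in rna_by_id.items()}
    prot_pzm = {pid: encode_protein(pssm_by_id[pid]) for pid in prot_by_id}
    prot_raw = {pid: protein_triad_freq(rec) for pid, rec in prot_by_id.items()}

    X_pair = np.stack(
        [np.concatenate([rna_svd[p.rna_id], prot_pzm[p.protein_id]]) for p in pairs]
    )
    X_raw = np.stack(
        [np.concatenate([rna_raw[p.rna_id], prot_raw[p.protein_id]]) for p in pairs]
    )
    assert X_pair.shape[1] == PAIR_DIM and X_raw.shape[1] == RAW_DIM
    return X_pair, X_raw


def labels_of(pairs: Sequence[InteractionPair]) -> np.ndarray:
    labels = [p.label for p in pairs]
    if any(l is None for l in labels):
        raise ValueError("pairs are unlabelled")
    return np.asarray(labels, dtype=int)


def cross_validate_pairs(
    pairs: Sequence[InteractionPair],
    rnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    cfg: Optional[ens.EnsembleConfig] = None,
    pssms: "Mapping[str, PSSM] | str | Path | None" = None,
    n_folds: int = 5,
    seed: int = 0,
) -> Dict[str, ens.MetricsReport]:
    """Encode pairs and run the stratified k-fold ensemble evaluation."""
    X_pair, X_raw = build_pair_features(pairs, rnas, proteins, pssms)
    return ens.cross_validate(
        X_pair, X_raw, labels_of(pairs), cfg=cfg, n_folds=n_folds, seed=seed
    )


class RPIPredictor:
    """Train-once, predict-many interface around the full pipeline."""

    def __init__(self, cfg: Optional[ens.EnsembleConfig] = None, seed: int = 0):
        self.cfg = cfg or ens.EnsembleConfig()
        self.seed = seed
        self._fitted: Optional[ens.FittedPipeline] = None

    def fit(
        self,
        pairs: Sequence[InteractionPair],
        rnas: Sequence[SequenceRecord],
        proteins: Sequence[SequenceRecord],
        pssms=None,
    ) -> "RPIPredictor":
        X_pair, X_raw = build_pair_features(pairs, rnas, proteins, pssms)
        self._fitted = ens.fit_pipeline(
            X_pair, X_raw, labels_of(pairs), self.cfg, seed=self.seed
        )
        return self

    def predict_proba(
        self,
        pairs: Sequence[InteractionPair],
        rnas: Sequence[SequenceRecord],
        proteins: Sequence[SequenceRecord],
        pssms=None,
    ) -> np.ndarray:
        if self._fitted is None:
            raise ValueError("predictor is not fitted")
        X_pair, X_raw = build_pair_features(pairs, rnas, proteins, pssms)
        return self._fitted.predict(X_pair, X_raw)

    def save(self, path: str | Path) -> None:
        joblib.dump({"cfg": self.cfg, "seed": self.seed, "fitted": self._fitted}, path)

    @classmethod
    def load(cls, path: str | Path) -> "RPIPredictor":
        state = joblib.load(path)
        obj = cls(cfg=state["cfg"], seed=state["seed"])
        obj._fitted = state["fitted"]
        return obj
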