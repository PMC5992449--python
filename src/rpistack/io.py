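"""Reading and writing of sequences, interaction-pair tables and PSSM profiles.

All downstream feature code assumes the normalised representations produced
here: RNA over the alphabet ``{A, C, G, U}`` (DNA-style ``T`` is silently
converted to ``U``), proteins over the 20 canonical one-letter codes, and
position-specific scoring matrices (PSSMs) with columns in the library-wide
alphabetical amino-acid order :data:`AA_ORDER`.  Ambiguity codes are rejected
rather than imputed; callers that want to tolerate dirty input can drop the
offending records themselves.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Library-wide amino-acid column order (alphabetical one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: RNA alphabet in the lexicographic order used by the k-mer indexers.
RNA_ALPHABET = "ACGU"

_RNA_SET = frozenset(RNA_ALPHABET)
_AA_SET = frozenset(AA_ORDER)


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single normalised RNA or protein sequence."""

    id: str
    seq: str
    kind: str  # "rna" or "protein"

    def __post_init__(self) -> None:
        if self.kind not in ("rna", "protein"):
            raise ValueError(f"kind must be 'rna' or 'protein', got {self.kind!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = _RNA_SET if self.kind == "rna" else _AA_SET
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.kind} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class InteractionPair:
    """A candidate protein-RNA pair, optionally labelled (1 = interacting)."""

    protein_id: str
    rna_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class PSSM:
    """An L x 20 evolutionary profile with columns in :data:`AA_ORDER`."""

    scores: "pd.DataFrame | object"  # numpy array, see __post_init__

    def __post_init__(self) -> None:
        import numpy as np

        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if not np.all(np.isfinite(arr)):
            raise ValueError("PSSM contains non-finite scores")
        object.__setattr__(self, "scores", arr)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def _normalize_seq(raw: str, kind: str) -> str:
    s = raw.upper().replace(" ", "")
    if kind == "rna":
        s = s.replace("T", "U")
    return s


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    RNA entries have lowercase letters uppercased and ``T`` mapped to ``U``.
    Any residue outside the target alphabet after normalisation raises a
    :class:`FormatError` naming the record and position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_seq(str(rec.seq), kind)
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq, kind=kind))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (inverse of :func:`read_fasta` on clean data)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_pairs(path: str | Path) -> list[InteractionPair]:
    """Read a TSV pair table with columns protein_id, rna_id and optional label.

    Either every row carries a 0/1 label or none does; a mixture is an error,
    as is any label value outside {0, 1}.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "rna_id"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: pair table needs columns protein_id, rna_id "
            f"(got {list(df.columns)})"
        )
    has_label = "label" in df.columns
    pairs: list[InteractionPair] = []
    for i, row in df.iterrows():
        label: Optional[int] = None
        if has_label:
            raw = row["label"]
            if pd.isna(raw):
                raise FormatError(
                    f"{path}: row {i + 1} has no label but other rows do"
                )
            if str(raw).strip() not in ("0", "1"):
                raise FormatError(
                    f"{path}: row {i + 1} label {raw!r} is not 0 or 1"
                )
            label = int(str(raw).strip())
        pairs.append(
            InteractionPair(
                protein_id=str(row["protein_id"]),
                rna_id=str(row["rna_id"]),
                label=label,
            )
        )
    if not pairs:
        raise FormatError(f"{path}: empty pair table")
    return pairs


def write_pairs(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    """Write pairs as the TSV dialect accepted by :func:`read_pairs`."""
    pairs = list(pairs)
    labelled = [p.label is not None for p in pairs]
    if any(labelled) and not all(labelled):
        raise ValueError("cannot mix labelled and unlabelled pairs in one table")
    rows = {
        "protein_id": [p.protein_id for p in pairs],
        "rna_id": [p.rna_id for p in pairs],
    }
    if all(labelled) and pairs:
        rows["label"] = [p.label for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def check_pairs_resolve(
    pairs: Sequence[InteractionPair],
    rnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
) -> None:
    """Raise if any pair references a sequence id that was not loaded."""
    rna_ids = {r.id for r in rnas}
    prot_ids = {p.id for p in proteins}
    for p in pairs:
        if p.rna_id not in rna_ids:
            raise FormatError(f"pair references unknown RNA id {p.rna_id!r}")
        if p.protein_id not in prot_ids:
            raise FormatError(
                f"pair references unknown protein id {p.protein_id!r}"
            )


# --- PSI-BLAST ASCII PSSM ---------------------------------------------------
#
# The dialect written by ``psiblast -out_ascii_pssm``: two header lines, a
# line of 40 column letters (20 log-odds + 20 percentage columns), then one
# row per residue starting with its position and letter.  Only the first
# (log-odds) block is read; the percentage block, if present, is ignored.


def read_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file into the library column order."""
    import numpy as np

    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not toks:
            continue
        if header_cols is None:
            if all(t.isalpha() and len(t) == 1 for t in toks) and len(toks) >= 20:
                file_order = toks[:20]
                if sorted(file_order) != sorted(AA_ORDER):
                    raise FormatError(
                        f"{path}: line {lineno}: column letters are not the "
                        f"20 canonical amino acids"
                    )
                header_cols = file_order
            continue
        # residue row: "<pos> <aa> <20 log-odds> [<20 pct> ...]"
        if not toks[0].isdigit():
            continue  # trailing K/lambda statistics block
        if len(toks) < 22:
            raise FormatError(
                f"{path}: line {lineno} (residue {toks[0]}): expected 20 "
                f"scores, found {len(toks) - 2}"
            )
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: unparsable score ({exc})"
            ) from exc
        rows.append(scores)
    if header_cols is None:
        raise FormatError(f"{path}: no PSSM column header line found")
    if not rows:
        raise FormatError(f"{path}: truncated file, no residue rows")
    mat = np.asarray(rows, dtype=float)
    # remap the file's column order onto AA_ORDER
    perm = [header_cols.index(a) for a in AA_ORDER]
    return PSSM(scores=mat[:, perm])


def write_pssm(
    pssm: PSSM, seq: str, path: str | Path, column_order: str = AA_ORDER
) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (for fixtures and caching).

    ``column_order`` controls the on-disk column order, exercising the
    remapping performed by :func:`read_pssm`.
    """
    import numpy as np

    if len(seq) != pssm.length:
        raise ValueError("sequence length does not match PSSM length")
    perm = [AA_ORDER.index(a) for a in column_order]
    mat = np.asarray(pssm.scores)[:, perm]
    buf = _io.StringIO()
    buf.write("\n")
    buf.write("Last position-specific scoring matrix computed\n")
    buf.write("    " + "  ".join(column_order) + "\n")
    for i, (aa, row) in enumerate(zip(seq, mat), start=1):
        cells = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:6.2f}"
                         for v in row)
        buf.write(f"{i:5d} {aa} {cells}\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class MetricsRow:
    """One evaluated fold (or a summary row) of classification metrics."""

    fold: str
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float


def write_report(rows: Iterable[MetricsRow], path: str | Path) -> None:
    """Write per-fold metrics plus summary rows as CSV."""
    df = pd.DataFrame([vars(r) for r in rows])
    df.to_csv(path, index=False, float_format="%.6f")
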