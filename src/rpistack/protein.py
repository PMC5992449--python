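"""Protein feature encoding: pseudo-Zernike moments of the PSSM.

A protein's evolutionary profile (PSSM, one row per residue, one column per
amino acid) is treated as a grey-level image: scores are squashed through the
logistic function into (0, 1), the L x 20 grid is mapped onto the unit disk,
and pseudo-Zernike moments up to order ``n = 30`` are computed.  Moment
magnitudes ``|A_nm|`` are invariant to rotations of the image, giving a
compact descriptor that is robust to the overall arrangement of the profile;
the first 240 magnitudes in (n ascending, m ascending) order form the
protein feature vector.

Profiles come either from PSI-BLAST (:func:`pssm_from_psiblast`, 3 iterations
against a protein database at E-value 0.001) or, fully offline, from
:func:`pseudo_pssm`, which substitutes each residue's BLOSUM62 row.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from math import factorial
from pathlib import Path

import numpy as np
from scipy.special import eval_jacobi, expit

from .io import AA_ORDER, PSSM, SequenceRecord, read_pssm

DEFAULT_MAX_ORDER = 30
DEFAULT_N_FEATURES = 240


@dataclass(frozen=True)
class DiskImage:
    """A pixel grid mapped onto the unit disk.

    ``pixels`` holds the grey values, ``x``/``y`` the mapped centre
    coordinates of each pixel, and ``mask`` marks pixels whose centre lies at
    radius <= 1.  ``area`` is the area of one pixel in mapped coordinates, so
    that sums over in-mask pixels approximate integrals over the disk.
    """

    pixels: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    area: float

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def theta(self) -> np.ndarray:
        return np.arctan2(self.y, self.x)


def grid_to_disk(pixels: np.ndarray) -> DiskImage:
    """Map an H x W pixel grid onto the unit disk.

    Each axis is affinely mapped to [-1, 1] about the grid centroid (pixel
    centres at ``-1 + 2(j + 1/2)/W``), so the grid's bounding box is the
    square circumscribing the unit disk and corner pixels fall outside the
    mask.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D pixel grid")
    H, W = pixels.shape
    ys = -1.0 + 2.0 * (np.arange(H) + 0.5) / H
    xs = -1.0 + 2.0 * (np.arange(W) + 0.5) / W
    X, Y = np.meshgrid(xs, ys)
    mask = X**2 + Y**2 <= 1.0
    return DiskImage(pixels=pixels, x=X, y=Y, mask=mask, area=(2.0 / W) * (2.0 / H))


def normalize_pssm(pssm: PSSM) -> DiskImage:
    """Squash PSSM scores through the logistic function and map to the disk.

    A log-odds score x becomes 1 / (1 + exp(-x)); a zero profile therefore
    maps to a uniform 0.5 grey image.
    """
    return grid_to_disk(expit(np.asarray(pssm.scores, dtype=float)))


def radial_polynomial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Pseudo-Zernike radial polynomial R_nm evaluated stably.

    Uses the Jacobi-polynomial representation
    ``R_nm(rho) = rho**m * P_{n-m}^{(0, 2m+1)}(2 rho - 1)``, whose three-term
    recurrence avoids the catastrophic cancellation of the alternating
    factorial sum at high order.
    """
    if not (0 <= m <= n):
        raise ValueError("need 0 <= m <= n")
    rho = np.asarray(rho, dtype=float)
    return rho**m * eval_jacobi(n - m, 0, 2 * m + 1, 2.0 * rho - 1.0)


def radial_polynomial_factorial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Direct factorial-sum evaluation of R_nm (low-order reference only).

    ``R_nm(rho) = sum_s (-1)^s (2n+1-s)! / [s! (n-m-s)! (n+m+1-s)!]
    rho^(n-s)``; numerically unusable near n = 30 but exact at low order.
    """
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for s in range(n - m + 1):
        c = (-1) ** s * factorial(2 * n + 1 - s) / (
            factorial(s) * factorial(n - m - s) * factorial(n + m + 1 - s)
        )
        out = out + c * rho ** (n - s)
    return out


def pseudo_zernike_moments(
    img: DiskImage, max_order: int = DEFAULT_MAX_ORDER
) -> np.ndarray:
    """Complex pseudo-Zernike moments A_nm for 0 <= m <= n <= max_order.

    Discrete approximation of ``A_nm = (n+1)/pi * integral over the disk of
    f(rho, theta) * conj(V_nm)`` with basis ``V_nm = R_nm(rho) e^{i m theta}``;
    all ``m <= n`` are admitted (pseudo-Zernike has no parity constraint).
    Returns a (max_order+1) x (max_order+1) complex array with entry [n, m];
    entries with m > n are zero and meaningless.
    """
    if max_order < 0:
        raise ValueError("max_order must be non-negative")
    f = img.pixels[img.mask].ravel()
    rho = img.rho[img.mask].ravel()
    theta = img.theta[img.mask].ravel()
    A = np.zeros((max_order + 1, max_order + 1), dtype=complex)
    for m in range(max_order + 1):
        phase = np.exp(-1j * m * theta)  # conj(e^{i m theta})
        fp = f * phase
        for n in range(m, max_order + 1):
            R = radial_polynomial(n, m, rho)
            A[n, m] = (n + 1) / np.pi * img.area * np.sum(fp * R)
    return A


def moment_magnitudes(A: np.ndarray) -> np.ndarray:
    """|A_nm| flattened in (n ascending, m ascending) enumeration order."""
    N = A.shape[0] - 1
    return np.array([abs(A[n, m]) for n in range(N + 1) for m in range(n + 1)])


def reconstruct_from_moments(A: np.ndarray, img: DiskImage) -> np.ndarray:
    """Reconstruct a real image on ``img``'s grid from its moment table.

    Inverse of the moment transform for a real-valued image: contributions
    with m > 0 are doubled to account for the implicit conjugate moments.
    Returns a full-grid array; values outside the mask are zero.
    """
    N = A.shape[0] - 1
    rho = img.rho[img.mask].ravel()
    theta = img.theta[img.mask].ravel()
    rec = np.zeros(rho.shape, dtype=float)
    for m in range(N + 1):
        phase = np.exp(1j * m * theta)
        for n in range(m, N + 1):
            term = A[n, m] * radial_polynomial(n, m, rho) * phase
            rec += (1.0 if m == 0 else 2.0) * term.real
    out = np.zeros_like(img.pixels, dtype=float)
    out[img.mask] = rec
    return out


def encode_protein(
    pssm: PSSM,
    max_order: int = DEFAULT_MAX_ORDER,
    n_features: int = DEFAULT_N_FEATURES,
) -> np.ndarray:
    """Encode a protein PSSM as the first ``n_features`` moment magnitudes.

    Order <= 30 yields 496 magnitudes; the fixed (n asc, m asc) enumeration
    truncated to 240 gives the default protein descriptor.
    """
    mags = moment_magnitudes(pseudo_zernike_moments(normalize_pssm(pssm), max_order))
    if mags.size < n_features:
        raise ValueError(
            f"only {mags.size} moments available at max_order={max_order}, "
            f"need {n_features}"
        )
    return mags[:n_features]


# --- PSSM sources -----------------------------------------------------------

_BLOSUM62_ROWS: dict[str, np.ndarray] | None = None


def _blosum62_rows() -> dict[str, np.ndarray]:
    global _BLOSUM62_ROWS
    if _BLOSUM62_ROWS is None:
        from Bio.Align import substitution_matrices

        B = substitution_matrices.load("BLOSUM62")
        _BLOSUM62_ROWS = {
            a: np.array([float(B[a][b]) for b in AA_ORDER]) for a in AA_ORDER
        }
    return _BLOSUM62_ROWS


def pseudo_pssm(seq: SequenceRecord) -> PSSM:
    """Substitution-matrix profile: row i is residue i's BLOSUM62 row.

    A deterministic, database-free stand-in for a PSI-BLAST profile; it
    carries composition and position information but no true evolutionary
    signal beyond the substitution matrix.
    """
    if seq.kind != "protein":
        raise ValueError("pseudo_pssm expects a protein record")
    rows = _blosum62_rows()
    return PSSM(scores=np.stack([rows[a] for a in seq.seq]))


def pssm_from_psiblast(
    seq: SequenceRecord,
    db: str | Path,
    n_iterations: int = 3,
    evalue: float = 0.001,
    executable: str = "psiblast",
) -> PSSM:
    """Run PSI-BLAST (3 iterations, E-value 0.001 by default) for a profile.

    Requires the ``psiblast`` executable and a formatted protein database
    such as SwissProt.  On failure the error message points at
    :func:`pseudo_pssm` as the offline fallback.
    """
    if seq.kind != "protein":
        raise ValueError("pssm_from_psiblast expects a protein record")
    if shutil.which(executable) is None:
        raise FileNotFoundError(
            f"{executable!r} not found on PATH; use pseudo_pssm() for an "
            f"offline substitution-matrix profile instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        query.write_text(f">{seq.id}\n{seq.seq}\n")
        out_pssm = Path(tmp) / "profile.pssm"
        cmd = [
            executable,
            "-query", str(query),
            "-db", str(db),
            "-num_iterations", str(n_iterations),
            "-evalue", str(evalue),
            "-out_ascii_pssm", str(out_pssm),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not out_pssm.exists():
            raise RuntimeError(
                f"psiblast failed for {seq.id!r} "
                f"({proc.stderr.strip() or 'no PSSM produced'}); "
                f"use pseudo_pssm() for an offline fallback"
            )
        pssm = read_pssm(out_pssm)
    if pssm.length != len(seq):
        raise RuntimeError(
            f"psiblast PSSM length {pssm.length} does not match "
            f"sequence length {len(seq)} for {seq.id!r}"
        )
    return pssm
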