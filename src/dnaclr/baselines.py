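"""Tetranucleotide-frequency (TNF) embeddings and their kernel projection (TNF-K).

TNF is the 256-dim frequency vector of overlapping 4-mers (lexicographic
A < C < G < T order). TNF-K projects TNF onto the null space of a linear
constraint system encoding DNA characteristics — reverse-complement strand
symmetry, 3-mer overlap consistency between adjacent 4-mers, and the unit-sum
constraint — which removes the redundant directions of the raw frequencies
and leaves a 103-dimensional representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.linalg import null_space

from .exceptions import DegenerateInputError, DnaclrError
from .io import reverse_complement

BASES = "ACGT"
KMER_SIZE = 4
N_KMERS = 4 ** KMER_SIZE  # 256

KMERS = ["".join(p) for p in product(BASES, repeat=KMER_SIZE)]
KMER_INDEX = {k: i for i, k in enumerate(KMERS)}

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
_BASE_CODE[ord("N")] = -1


class KernelConstructionError(DnaclrError):
    """The constraint system did not yield the expected null-space dimension."""


def tnf(seq: str) -> np.ndarray:
    """256-dim tetranucleotide frequency vector of `seq` (given strand only).

    Overlapping windows; windows containing N are skipped. Raises
    DegenerateInputError when no valid window exists.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < KMER_SIZE:
        raise DegenerateInputError("sequence shorter than 4 bp")
    w = (
        codes[:-3] * 64
        + codes[1:-2] * 16
        + codes[2:-1] * 4
        + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    w = w[valid]
    if w.size == 0:
        raise DegenerateInputError("no 4-mer window free of N")
    counts = np.bincount(w, minlength=N_KMERS).astype(float)
    return counts / counts.sum()


@dataclass(frozen=True)
class KernelProjection:
    """Orthonormal basis (columns) of the TNF constraint null space."""

    matrix: np.ndarray  # (256, output_dim)
    output_dim: int


def _constraint_matrix() -> np.ndarray:
    rows = []
    # (a) strand symmetry: f(m) = f(rc(m)) for every 4-mer m
    for m in KMERS:
        r = np.zeros(N_KMERS)
        r[KMER_INDEX[m]] += 1.0
        r[KMER_INDEX[reverse_complement(m)]] -= 1.0
        rows.append(r)
    # (b) 3-mer overlap consistency: for each 3-mer w, the frequency of w as a
    # prefix of a 4-mer equals its frequency as a suffix
    for w in ("".join(p) for p in product(BASES, repeat=3)):
        r = np.zeros(N_KMERS)
        for x in BASES:
            r[KMER_INDEX[w + x]] += 1.0
            r[KMER_INDEX[x + w]] -= 1.0
        rows.append(r)
    # (c) frequencies sum to a constant
    rows.append(np.ones(N_KMERS))
    return np.vstack(rows)


def build_tnfk_kernel(expected_dim: int = 103) -> KernelProjection:
    """Build the TNF-K projection as an orthonormal null-space basis.

    The independent-constraint count is resolved numerically (matrix rank), so
    redundant rows in the stacked system are harmless. Raises
    KernelConstructionError when the null-space dimension differs from
    `expected_dim` (pass None to skip the check).
    """
    A = _constraint_matrix()
    basis = null_space(A)
    dim = basis.shape[1]
    if expected_dim is not None and dim != expected_dim:
        raise KernelConstructionError(
            f"null-space dimension {dim} != expected {expected_dim}; "
            "the constraint set needs revisiting"
        )
    return KernelProjection(matrix=basis, output_dim=dim)


def tnfk(seq: str, kernel: KernelProjection) -> np.ndarray:
    """Mean-centered TNF projected through the kernel (length = output_dim)."""
    v = tnf(seq)
    return (v - v.mean()) @ kernel.matrix


def tnf_matrix(seqs: list[str]) -> np.ndarray:
    return np.vstack([tnf(s) for s in seqs])


def tnfk_matrix(seqs: list[str], kernel: KernelProjection | None = None) -> np.ndarray:
    if kernel is None:
        kernel = build_tnfk_kernel()
    return np.vstack([tnfk(s, kernel) for s in seqs])
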