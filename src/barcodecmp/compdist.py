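"""Compression-based genetic distances: NCD and IBD.

Both distances approximate the (non-computable) universal similarity
metric by replacing Kolmogorov complexity with compressed sizes from
:mod:`barcodecmp.compressor`:

    NCD(x, y) = (C(xy) - min(C(x), C(y))) / max(C(x), C(y))
    IBD(x, y) = 1 - (C(x) - C(x|y)) / C(xy)

Neither is exactly symmetric at the compressor level (C(xy) != C(yx) and
C(x|y) is directional), so the all-pairs matrix stores the mean of the
two orientations and forces the diagonal to zero, which is what the
distance-based tree algorithms downstream require.

Gap characters are stripped before compression: the point of the method
is that it needs no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from barcodecmp.compressor import compress_size, concat_size, conditional_size, encode_dna
from barcodecmp.seqdata import SequenceSet

__all__ = ["DistanceMatrix", "ncd", "ibd", "compression_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labelled sequences."""

    labels: list[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(np.isnan(self.values)):
            raise ValueError("distance matrix contains NaN")

    def __len__(self) -> int:
        return len(self.labels)

    def to_phylip(self) -> str:
        """Square PHYLIP distance-matrix format."""
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"


def ncd(x: str, y: str) -> float:
    """Normalized compression distance of two raw DNA strings (one orientation)."""
    cx = compress_size(x)
    cy = compress_size(y)
    cxy = concat_size(x, y)
    m = max(cx, cy)
    if m <= 0:
        raise ValueError("degenerate compressor output: nonpositive size")
    return (cxy - min(cx, cy)) / m


def ibd(x: str, y: str) -> float:
    """Information-based distance of two raw DNA strings (one orientation)."""
    cx = compress_size(x)
    cxy = concat_size(x, y)
    if cxy <= 0:
        raise ValueError("degenerate compressor output: nonpositive size")
    return 1.0 - (cx - conditional_size(x, y)) / cxy


def compression_matrix(seqs: SequenceSet, method: str = "NCD") -> DistanceMatrix:
    """All-pairs NCD or IBD matrix of a sequence set.

    Sequences are ungapped before compression; per-sequence plain sizes
    are computed once and reused across pairs.
    """
    method = method.upper()
    if method not in ("NCD", "IBD"):
        raise ValueError(f"unknown compression distance {method!r}")
    n = len(seqs)
    if n < 3:
        raise ValueError("need at least 3 sequences to build a distance matrix")

    codes = [encode_dna(s.ungapped) for s in seqs]
    plain = np.array([compress_size(c) for c in codes], dtype=float)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = codes[i], codes[j]
            cij = concat_size(ci, cj)
            cji = concat_size(cj, ci)
            if method == "NCD":
                m = max(plain[i], plain[j])
                mn = min(plain[i], plain[j])
                v = 0.5 * ((cij - mn) / m + (cji - mn) / m)
            else:
                v = 0.5 * (
                    (1.0 - (plain[i] - conditional_size(ci, cj)) / cij)
                    + (1.0 - (plain[j] - conditional_size(cj, ci)) / cji)
                )
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels=seqs.labels, values=d, method=method)
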