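"""Dictionary-based DNA compressor used to approximate Kolmogorov complexity.

Compression-based distances need three size functionals of an underlying
compressor: the plain compressed size ``C(x)``, the size of the compressed
concatenation ``C(xy)``, and the conditional size ``C(x|y)`` where the match
dictionary is preloaded from ``y``.  The compressor here is a deterministic
exact-match LZ77 parser over 2-bit-coded nucleotides with an unbounded
window: at each position the longest match against the already-processed
text (plus the dictionary, in conditional mode) is substituted by a
pointer, and everything else is emitted as literals.

No bitstream is ever produced; only the exact size in bits of the token
sequence is accounted, with a fixed cost model:

* literal A/C/G/T: 1 flag bit + 2 code bits;
* literal other byte (N, gaps, IUPAC ambiguity codes): 1 flag bit +
  1 escape bit + 8 raw bits;
* match: 1 flag bit + Elias-gamma(offset) + Elias-gamma(length), with a
  minimum match length of 4 and ties in length broken toward the smallest
  offset.

Sizes are reported in bits; the compression distances are ratios of sizes,
so the unit (bits vs bytes) cancels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["compress_size", "concat_size", "conditional_size", "encode_dna"]

#: minimum match length substituted by a pointer
MIN_MATCH = 4

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i
    _LUT[_c + 32] = _i  # lowercase


def encode_dna(s: str) -> np.ndarray:
    """Map a DNA string to a uint8 array: A,C,G,T -> 0..3, anything else 255."""
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@njit(cache=True)
def _gamma_bits(v):
    # Elias-gamma code length for integer v >= 1: 2*floor(log2 v) + 1
    bits = 0
    while v > 0:
        v >>= 1
        bits += 1
    return 2 * bits - 1


@njit(cache=True)
def _parse_bits(buf, start):
    """Bit size of the greedy LZ parse of buf[start:], window = buf[0:pos].

    head/chain implement per-4-mer hash chains (most recent position first,
    i.e. smallest offset first), so keeping only strictly longer matches
    realises the smallest-offset tie-break.
    """
    n = buf.shape[0]
    head = np.full(256, -1, dtype=np.int64)
    chain = np.full(n, -1, dtype=np.int64)

    # index every 4-mer of the dictionary part
    for i in range(start - MIN_MATCH + 1):
        key = 0
        ok = True
        for j in range(MIN_MATCH):
            c = buf[i + j]
            if c > 3:
                ok = False
                break
            key = (key << 2) | c
        if ok:
            chain[i] = head[key]
            head[key] = i

    bits = 0
    i = start
    while i < n:
        best_len = 0
        best_pos = -1
        if i + MIN_MATCH <= n:
            key = 0
            ok = True
            for j in range(MIN_MATCH):
                c = buf[i + j]
                if c > 3:
                    ok = False
                    break
                key = (key << 2) | c
            if ok:
                p = head[key]
                while p >= 0:
                    # extend; the 4-mer is known equal
                    l = MIN_MATCH
                    while i + l < n and buf[p + l] == buf[i + l]:
                        l += 1
                    if l > best_len:
                        best_len = l
                        best_pos = p
                    p = chain[p]
        if best_len >= MIN_MATCH:
            bits += 1 + _gamma_bits(i - best_pos) + _gamma_bits(best_len)
            end = i + best_len
        else:
            c = buf[i]
            if c <= 3:
                bits += 3
            else:
                bits += 10
            end = i + 1
        # index the positions consumed by this token
        while i < end:
            if i + MIN_MATCH <= n:
                key = 0
                ok = True
                for j in range(MIN_MATCH):
                    c = buf[i + j]
                    if c > 3:
                        ok = False
                        break
                    key = (key << 2) | c
                if ok:
                    chain[i] = head[key]
                    head[key] = i
            i += 1
    return bits


def _as_codes(x) -> np.ndarray:
    if isinstance(x, str):
        if not x:
            raise ValueError("cannot compress an empty sequence")
        return encode_dna(x)
    arr = np.asarray(x, dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("cannot compress an empty sequence")
    return arr


def compress_size(x) -> int:
    """Size in bits of the LZ parse of ``x`` (a DNA string or code array)."""
    return int(_parse_bits(_as_codes(x), 0))


def concat_size(x, y) -> int:
    """Size in bits of the parse of the concatenation ``x . y``."""
    cx = _as_codes(x)
    cy = _as_codes(y)
    return int(_parse_bits(np.concatenate([cx, cy]), 0))


def conditional_size(x, y) -> int:
    """Size in bits of ``x`` parsed with the match dictionary built from ``y``.

    Only the bits of x's tokens are counted; match search ranges over y and
    the already-emitted prefix of x.
    """
    cx = _as_codes(x)
    cy = _as_codes(y)
    return int(_parse_bits(np.concatenate([cy, cx]), cy.shape[0]))
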