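"""Low-level sequence identity kernels.

Two routes to the same quantity (fraction of identical aligned positions
over the alignment length):

* :func:`dp_identity` -- exact global alignment under the package's scoring
  model (match +1, mismatch -1, gap -1); score ties prefer more matches,
  then a shorter alignment, so the result is symmetric and deterministic.
  Used for small inputs and for sequences of unequal length.
* packed 2-bit Hamming kernels -- for collections of equal-length sequences
  produced by a substitution process the optimal alignment is gap-free, so
  identity reduces to ``1 - hamming/L``.  These kernels carry the bulk of
  the pipeline's comparisons.

All kernels are deterministic; ties in "best hit" scans are resolved by
scan order (callers sort their targets to encode the tie-break they need).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# A=0 C=1 G=2 T=3; anything else (IUPAC ambiguity etc.) maps to 255 and
# disqualifies the fast path.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

BASES_PER_WORD = 32  # 2 bits per base in a uint64


def encode(seqs: "list[str] | np.ndarray") -> np.ndarray:
    """Encode equal-length ACGT strings as a (n, L) uint8 code matrix.

    Raises ``ValueError`` on unequal lengths or non-ACGT characters.
    """
    if isinstance(seqs, np.ndarray) and seqs.dtype == np.uint8:
        return seqs
    n = len(seqs)
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    for s in seqs:
        if len(s) != L:
            raise ValueError("sequences of unequal length; fast path needs uniform length")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _LUT[buf].reshape(n, L)
    if (codes == 255).any():
        raise ValueError("non-ACGT character; fast path needs plain ACGT sequences")
    return codes


def decode(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    if codes.size == 0:
        return []
    chars = _CODE_TO_BASE[codes]
    return [row.tobytes().decode("ascii") for row in chars]


def pack(codes: np.ndarray) -> np.ndarray:
    """Pack a (n, L) 0..3 code matrix into (n, W) uint64, 32 bases per word."""
    n, L = codes.shape
    W = (L + BASES_PER_WORD - 1) // BASES_PER_WORD
    out = np.zeros((n, W), dtype=np.uint64)
    chunk = 1 << 18  # bound intermediates to a few MB per block
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        for w in range(W):
            seg = codes[lo:hi, w * BASES_PER_WORD : (w + 1) * BASES_PER_WORD].astype(
                np.uint64
            )
            shifts = (2 * np.arange(seg.shape[1], dtype=np.uint64))[None, :]
            out[lo:hi, w] = (seg << shifts).sum(axis=1, dtype=np.uint64)
    return out


@njit(cache=False, inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + ((x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=False, inline="always")
def _ham_words(a, b, limit):
    """Hamming distance between packed rows a and b; early abandon above limit."""
    h = np.uint64(0)
    lim = np.uint64(limit)
    five = np.uint64(0x5555555555555555)
    for w in range(a.shape[0]):
        d = a[w] ^ b[w]
        m = (d | (d >> np.uint64(1))) & five
        h += _popcount64(m)
        if h > lim:
            return int(h)
    return int(h)


@njit(cache=False)
def hamming_pair(a, b):
    """Exact Hamming distance between two packed rows."""
    return _ham_words(a, b, np.uint64(1 << 62))


@njit(cache=False)
def best_hits(queries, targets, limit):
    """For each packed query row, the best (minimum-Hamming) target.

    Targets are scanned in array order with *strict* improvement, so ties go
    to the earliest target.  ``limit`` bounds the useful distance: hits worse
    than ``limit`` are reported as distance ``limit + 1`` (index -1).
    Returns (best_idx int64[n], best_ham int64[n]).
    """
    nq = queries.shape[0]
    nt = targets.shape[0]
    best_idx = np.full(nq, -1, dtype=np.int64)
    best_ham = np.full(nq, limit + 1, dtype=np.int64)
    for i in range(nq):
        cur = limit + 1
        cur_j = -1
        for j in range(nt):
            h = _ham_words(queries[i], targets[j], cur - 1)
            if h < cur:
                cur = h
                cur_j = j
                if cur == 0:
                    break
        best_idx[i] = cur_j
        best_ham[i] = cur
    return best_idx, best_ham


@njit(cache=False)
def greedy_assign_packed(packed, limit):
    """Greedy centroid clustering over packed rows in the given order.

    Row i joins the existing centroid with the smallest Hamming distance
    <= ``limit`` (ties -> earliest-created centroid), else founds a new
    centroid.  Returns (labels int64[n], centroid_rows int64[n_clusters]).
    """
    n = packed.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    cent_rows = np.empty(n, dtype=np.int64)
    n_cent = 0
    for i in range(n):
        cur = limit + 1
        cur_c = -1
        for c in range(n_cent):
            h = _ham_words(packed[i], packed[cent_rows[c]], cur - 1)
            if h < cur:
                cur = h
                cur_c = c
                if cur == 0:
                    break
        if cur_c >= 0:
            labels[i] = cur_c
        else:
            cent_rows[n_cent] = i
            labels[i] = n_cent
            n_cent += 1
    return labels, cent_rows[:n_cent]


@njit(cache=False)
def _dp_matches_alen(a, b):
    """Global alignment DP: match +1, mismatch -1, gap -1.

    Among equally scoring alignments the one with most matches, then the
    shortest alignment, is taken (all three objectives are additive, so the
    lexicographic DP is exact); this makes the reported identity symmetric
    in its arguments.  Returns (matches, alignment_length).
    """
    la = a.shape[0]
    lb = b.shape[0]
    score = np.empty((la + 1, lb + 1), dtype=np.int32)
    match = np.empty((la + 1, lb + 1), dtype=np.int32)
    alen = np.empty((la + 1, lb + 1), dtype=np.int32)
    for i in range(la + 1):
        score[i, 0] = -i
        match[i, 0] = 0
        alen[i, 0] = i
    for j in range(lb + 1):
        score[0, j] = -j
        match[0, j] = 0
        alen[0, j] = j
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            hit = 1 if ai == b[j - 1] else 0
            ds = score[i - 1, j - 1] + (1 if hit else -1)
            dm = match[i - 1, j - 1] + hit
            dl = alen[i - 1, j - 1] + 1
            us = score[i - 1, j] - 1
            um = match[i - 1, j]
            ul = alen[i - 1, j] + 1
            ls = score[i, j - 1] - 1
            lm = match[i, j - 1]
            ll = alen[i, j - 1] + 1
            # keep the lexicographic best of (score, matches, -alen)
            bs, bm, bl = ds, dm, dl
            if us > bs or (us == bs and (um > bm or (um == bm and ul < bl))):
                bs, bm, bl = us, um, ul
            if ls > bs or (ls == bs and (lm > bm or (lm == bm and ll < bl))):
                bs, bm, bl = ls, lm, ll
            score[i, j] = bs
            match[i, j] = bm
            alen[i, j] = bl
    return match[la, lb], alen[la, lb]


def dp_identity(a: str, b: str) -> float:
    """Exact global-alignment identity between two sequences."""
    if not a or not b:
        raise ValueError("empty sequence")
    ca = _LUT[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
    cb = _LUT[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    m, alen = _dp_matches_alen(ca.astype(np.uint8), cb.astype(np.uint8))
    return m / alen


def strict_limit(L: int, threshold: float) -> int:
    """Largest Hamming distance h with (L - h)/L > threshold (may be -1)."""
    h = int(np.floor(L * (1.0 - threshold)))
    while h >= 0 and not (L - h) / L > threshold:
        h -= 1
    return h


def inclusive_limit(L: int, threshold: float) -> int:
    """Largest Hamming distance h with (L - h)/L >= threshold (may be -1)."""
    h = int(np.floor(L * (1.0 - threshold) + 1e-9))
    while h >= 0 and not (L - h) / L >= threshold:
        h -= 1
    return h


def greedy_cluster_ham1(codes: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy clustering at Hamming distance <= 1 via exact half indexing.

    Two equal-length sequences at distance <= 1 share at least one exact
    half, so candidate centroids come from two dictionary probes; the
    candidate set is then resolved exactly (min distance, earliest-created
    centroid on ties).  Equivalent to the generic greedy scan, much faster.

    ``order`` gives the processing order (row indices).  Returns
    (labels aligned to ``codes`` rows, centroid row indices).
    """
    n, L = codes.shape
    half = L // 2
    left_idx: dict[bytes, list[int]] = {}
    right_idx: dict[bytes, list[int]] = {}
    cent_rows: list[int] = []
    cent_mat = np.empty((n, L), dtype=np.uint8)
    labels = np.full(n, -1, dtype=np.int64)
    for row in order:
        seq = codes[row]
        lk = seq[:half].tobytes()
        rk = seq[half:].tobytes()
        cand = left_idx.get(lk, [])
        cr = right_idx.get(rk)
        if cr is not None:
            cand = cand + cr
        best_c = -1
        if cand:
            cand_arr = np.unique(np.asarray(cand, dtype=np.int64))
            diffs = (cent_mat[cand_arr] != seq[None, :]).sum(axis=1)
            ok = diffs <= 1
            if ok.any():
                c_ok = cand_arr[ok]
                d_ok = diffs[ok]
                dmin = d_ok.min()
                best_c = int(c_ok[d_ok == dmin].min())
        if best_c >= 0:
            labels[row] = best_c
        else:
            c = len(cent_rows)
            cent_mat[c] = seq
            cent_rows.append(int(row))
            labels[row] = c
            left_idx.setdefault(lk, []).append(c)
            right_idx.setdefault(rk, []).append(c)
    return labels, np.asarray(cent_rows, dtype=np.int64)
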