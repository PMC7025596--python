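"""Ungapped banded alignment primitives shared by clustering and annotation.

The read-overlap criterion used throughout the package is: two reads overlap
when some ungapped diagonal segment of length >= ``min_span`` aligns them at
identity >= ``min_identity``.  Identity thresholds are compared in exact
integer arithmetic (scaled by 10**6) so that the accept/reject decision is
bit-reproducible and can be checked against a brute-force enumeration.

For a segment of span ``s`` with ``m`` matches the integer score is

    w = SCALE * m - round(SCALE * min_identity) * s

so ``w >= 0``  <=>  ``m / s >= min_identity`` and the best-scoring segment of
span >= min_span exists iff the pair overlaps.  The reported edge carries the
identity, span, diagonal offset and strand of that maximum-score segment.

Gaps are not modelled: the simulator introduces substitutions only, and at the
identity levels involved (>= 90%) indel-containing overlaps would be rejected
by any scoring scheme consistent with the thresholds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SCALE = 1_000_000

#: byte -> 2-bit code; A=0 C=1 G=2 T=3, anything else (incl. N) = 4 (never matches)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)[::-1]


def identity_scaled(min_identity: float) -> int:
    return int(round(min_identity * SCALE))


@njit(cache=True)
def _best_segment(a, b, min_span, id_scaled):  # pragma: no cover - numba
    """Maximum-score ungapped segment between code arrays ``a`` and ``b``.

    Returns (w, matches, span, diag, start_in_a).  ``w`` is NEG_SENTINEL when
    no diagonal provides min_span aligned columns.  ``diag`` is the offset of
    b's origin in a's coordinates (a[i] pairs with b[i - diag]).
    """
    la = a.shape[0]
    lb = b.shape[0]
    NEG = np.int64(-(1 << 62))
    best_w = NEG
    best_m = np.int64(0)
    best_s = np.int64(0)
    best_d = np.int64(0)
    best_start = np.int64(0)
    prefix = np.empty(max(la, lb) + 1, dtype=np.int64)
    for d in range(-(lb - min_span), la - min_span + 1):
        i0 = d if d > 0 else 0
        i1 = min(la, lb + d)
        n = i1 - i0
        if n < min_span:
            continue
        prefix[0] = 0
        for t in range(n):
            ai = a[i0 + t]
            bi = b[i0 + t - d]
            match = np.int64(1) if (ai == bi and ai < 4) else np.int64(0)
            prefix[t + 1] = prefix[t] + SCALE * match - id_scaled
        run_min = np.int64(1 << 62)
        run_arg = np.int64(-1)
        for e in range(min_span, n + 1):
            cand_idx = e - min_span
            if prefix[cand_idx] < run_min:
                run_min = prefix[cand_idx]
                run_arg = cand_idx
            w = prefix[e] - run_min
            if w > best_w:
                span = np.int64(e - run_arg)
                best_w = w
                best_s = span
                best_m = (w + id_scaled * span) // SCALE
                best_d = np.int64(d)
                best_start = np.int64(i0 + run_arg)
    return best_w, best_m, best_s, best_d, best_start


@njit(cache=True)
def _verify_pairs(seqs, rcs, pairs, min_span, id_scaled):  # pragma: no cover - numba
    """Evaluate the overlap criterion for candidate read pairs.

    ``seqs``/``rcs`` are (n, L) code matrices; ``pairs`` is (m, 2) indices.
    Returns per-pair arrays: accepted, score w, matches, span, strand
    (0 = same, 1 = opposite) and diagonal offset of the winning segment
    (for opposite strand the offset refers to revcomp(b) aligned to a).
    """
    m = pairs.shape[0]
    accepted = np.zeros(m, dtype=np.bool_)
    w_out = np.empty(m, dtype=np.int64)
    match_out = np.zeros(m, dtype=np.int64)
    span_out = np.zeros(m, dtype=np.int64)
    strand_out = np.zeros(m, dtype=np.int8)
    diag_out = np.zeros(m, dtype=np.int64)
    for p in range(m):
        i = pairs[p, 0]
        j = pairs[p, 1]
        wf, mf, sf, df, _ = _best_segment(seqs[i], seqs[j], min_span, id_scaled)
        wr, mr, sr, dr, _ = _best_segment(seqs[i], rcs[j], min_span, id_scaled)
        if wr > wf:
            w_out[p] = wr
            match_out[p] = mr
            span_out[p] = sr
            strand_out[p] = 1
            diag_out[p] = dr
        else:
            w_out[p] = wf
            match_out[p] = mf
            span_out[p] = sf
            strand_out[p] = 0
            diag_out[p] = df
        if w_out[p] >= 0:
            accepted[p] = True
    return accepted, w_out, match_out, span_out, strand_out, diag_out


def best_segment(a_codes: np.ndarray, b_codes: np.ndarray, min_span: int,
                 min_identity: float):
    """Best ungapped segment between two encoded sequences on the given strands.

    Returns ``None`` when no segment of span >= min_span reaches min_identity,
    else a dict with matches, span, identity, diag, start and score.
    """
    w, m, s, d, start = _best_segment(
        np.ascontiguousarray(a_codes), np.ascontiguousarray(b_codes),
        min_span, identity_scaled(min_identity))
    if w < 0:
        return None
    return {
        "matches": int(m),
        "span": int(s),
        "identity": int(m) / int(s),
        "diag": int(d),
        "start": int(start),
        "score": int(w),
    }


def lossless_prefilter_k(min_span: int, max_span: int, min_identity: float) -> int:
    """Largest k such that every qualifying ungapped segment contains an exact
    shared k-mer (pigeonhole over the mismatch positions).

    A segment of span s qualifying at ``min_identity`` has at most
    ``s - ceil(min_identity * s)`` mismatches, which split it into runs of
    exact matches, the longest of which has at least
    ``ceil(matches / (mismatches + 1))`` bases.  The minimum of that bound
    over all admissible spans is a safe k for a shared-k-mer prefilter.
    """
    id_sc = identity_scaled(min_identity)
    k = 1 << 30
    for s in range(min_span, max_span + 1):
        min_matches = -((-id_sc * s) // SCALE)  # ceil
        max_mismatch = s - min_matches
        guaranteed_run = -((-min_matches) // (max_mismatch + 1))  # ceil
        k = min(k, guaranteed_run)
    return k


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All N-free k-mers of an encoded sequence as uint64 packed integers."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    ok = np.ones(n, dtype=bool)
    vals = np.zeros(n, dtype=np.uint64)
    for off in range(k):
        window = codes[off:off + n]
        ok &= valid[off:off + n]
        vals = (vals << np.uint64(2)) | window.astype(np.uint64)
    return vals[ok]


def strand_union_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Deduplicated k-mer set of an encoded sequence, both strands pooled.

    Two reads that share an exact k-mer on any strand combination have
    intersecting strand-union sets, which is what the overlap prefilter needs.
    """
    fwd = kmer_codes(codes, k)
    rev = kmer_codes(revcomp_codes(codes), k)
    return np.unique(np.concatenate([fwd, rev]))


@njit(cache=True)
def _diag_best(a, b, d, min_span, id_scaled, prefix):  # pragma: no cover - numba
    """Kadane-style best segment (span >= min_span) on one diagonal."""
    la = a.shape[0]
    lb = b.shape[0]
    i0 = d if d > 0 else 0
    i1 = min(la, lb + d)
    n = i1 - i0
    NEG = np.int64(-(1 << 62))
    if n < min_span:
        return NEG, np.int64(0), np.int64(0)
    prefix[0] = 0
    for t in range(n):
        ai = a[i0 + t]
        bi = b[i0 + t - d]
        match = np.int64(1) if (ai == bi and ai < 4) else np.int64(0)
        prefix[t + 1] = prefix[t] + SCALE * match - id_scaled
    best_w = NEG
    best_m = np.int64(0)
    best_s = np.int64(0)
    run_min = np.int64(1 << 62)
    run_arg = np.int64(-1)
    for e in range(min_span, n + 1):
        cand_idx = e - min_span
        if prefix[cand_idx] < run_min:
            run_min = prefix[cand_idx]
            run_arg = cand_idx
        w = prefix[e] - run_min
        if w > best_w:
            span = np.int64(e - run_arg)
            best_w = w
            best_s = span
            best_m = (w + id_scaled * span) // SCALE
    return best_w, best_m, best_s


@njit(cache=True)
def _all_pairs_edges(seqs, rcs, k, min_span, id_scaled):  # pragma: no cover
    """All-to-all overlap detection with a lossless shared-k-mer diagonal mark.

    Any segment qualifying at (min_span, id_scaled) contains an exact k-run
    on its own diagonal (pigeonhole over mismatches), so scanning only the
    diagonals on which the two reads share a k-mer misses no qualifying pair.
    Returns parallel arrays (i, j, w, matches, span, strand, diag).
    """
    n, L = seqs.shape
    nk = L - k + 1
    mask = (np.uint32(1) << np.uint32(2 * k)) - np.uint32(1)
    # forward and reverse-complement k-mer codes per read, with N validity
    fk = np.zeros((n, nk), dtype=np.uint32)
    rk = np.zeros((n, nk), dtype=np.uint32)
    fval = np.zeros((n, nk), dtype=np.bool_)
    rval = np.zeros((n, nk), dtype=np.bool_)
    for i in range(n):
        val = np.uint32(0)
        run = 0
        for p in range(L):
            c = seqs[i, p]
            if c >= 4:
                run = 0
                val = np.uint32(0)
            else:
                val = ((val << np.uint32(2)) | np.uint32(c)) & mask
                run += 1
            if p >= k - 1 and run >= k:
                fk[i, p - k + 1] = val
                fval[i, p - k + 1] = True
        val = np.uint32(0)
        run = 0
        for p in range(L):
            c = rcs[i, p]
            if c >= 4:
                run = 0
                val = np.uint32(0)
            else:
                val = ((val << np.uint32(2)) | np.uint32(c)) & mask
                run += 1
            if p >= k - 1 and run >= k:
                rk[i, p - k + 1] = val
                rval[i, p - k + 1] = True

    table_size = 1 << (2 * k)
    head = np.full(table_size, -1, dtype=np.int32)
    nxt = np.empty(nk, dtype=np.int32)
    used = np.empty(nk, dtype=np.int64)
    ndiag = 2 * L - 1
    mark_same = np.zeros(ndiag, dtype=np.bool_)
    mark_opp = np.zeros(ndiag, dtype=np.bool_)
    touched_same = np.empty(ndiag, dtype=np.int64)
    touched_opp = np.empty(ndiag, dtype=np.int64)
    prefix = np.empty(L + 1, dtype=np.int64)

    cap = 4096
    out_i = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    out_w = np.empty(cap, dtype=np.int64)
    out_m = np.empty(cap, dtype=np.int64)
    out_s = np.empty(cap, dtype=np.int64)
    out_strand = np.empty(cap, dtype=np.int8)
    out_d = np.empty(cap, dtype=np.int64)
    n_out = 0

    for i in range(n):
        nu = 0
        for p in range(nk):
            if fval[i, p]:
                slot = np.int64(fk[i, p])
                nxt[p] = head[slot]
                if head[slot] == -1:
                    used[nu] = slot
                    nu += 1
                head[slot] = p
        for j in range(i + 1, n):
            nts = 0
            nto = 0
            for p in range(nk):
                if fval[j, p]:
                    q = head[np.int64(fk[j, p])]
                    while q != -1:
                        d = q - p
                        if not mark_same[d + L - 1]:
                            mark_same[d + L - 1] = True
                            touched_same[nts] = d
                            nts += 1
                        q = nxt[q]
                if rval[j, p]:
                    q = head[np.int64(rk[j, p])]
                    while q != -1:
                        d = q - p
                        if not mark_opp[d + L - 1]:
                            mark_opp[d + L - 1] = True
                            touched_opp[nto] = d
                            nto += 1
                        q = nxt[q]
            if nts == 0 and nto == 0:
                continue
            NEG = np.int64(-(1 << 62))
            best_w = NEG
            best_m = np.int64(0)
            best_s = np.int64(0)
            best_strand = np.int8(0)
            best_d = np.int64(0)
            for t in range(nts):
                d = touched_same[t]
                w, m, s = _diag_best(seqs[i], seqs[j], d, min_span,
                                     id_scaled, prefix)
                if w > best_w or (w == best_w and best_strand == 1):
                    best_w, best_m, best_s = w, m, s
                    best_strand = np.int8(0)
                    best_d = d
                mark_same[d + L - 1] = False
            for t in range(nto):
                d = touched_opp[t]
                w, m, s = _diag_best(seqs[i], rcs[j], d, min_span,
                                     id_scaled, prefix)
                if w > best_w:
                    best_w, best_m, best_s = w, m, s
                    best_strand = np.int8(1)
                    best_d = d
                mark_opp[d + L - 1] = False
            if best_w >= 0:
                if n_out == cap:
                    cap *= 2
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_i[:n_out]
                    out_i = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_j[:n_out]
                    out_j = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_w[:n_out]
                    out_w = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_m[:n_out]
                    out_m = tmp
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_s[:n_out]
                    out_s = tmp
                    tmp8 = np.empty(cap, dtype=np.int8)
                    tmp8[:n_out] = out_strand[:n_out]
                    out_strand = tmp8
                    tmp = np.empty(cap, dtype=np.int64)
                    tmp[:n_out] = out_d[:n_out]
                    out_d = tmp
                out_i[n_out] = i
                out_j[n_out] = j
                out_w[n_out] = best_w
                out_m[n_out] = best_m
                out_s[n_out] = best_s
                out_strand[n_out] = best_strand
                out_d[n_out] = best_d
                n_out += 1
        for t in range(nu):
            head[used[t]] = -1
    return (out_i[:n_out], out_j[:n_out], out_w[:n_out], out_m[:n_out],
            out_s[:n_out], out_strand[:n_out], out_d[:n_out])
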