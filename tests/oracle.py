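"""Independent brute-force oracle for the ungapped overlap criterion.

Enumerates every diagonal of every strand combination with plain numpy and
evaluates max_{s<=e-min_span} (SCALE*matches - id_scaled*span) directly from
the definition.  No k-mer filtering, no diagonal marking, no numba — this is
the reference the fast engine must agree with exactly.
"""

import numpy as np

SCALE = 1_000_000

_MAP = {"A": 0, "C": 1, "G": 2, "T": 3}


def enc(seq: str) -> np.ndarray:
    return np.array([_MAP.get(c, 4) for c in seq.upper()], dtype=np.int64)


def rc(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, 4)[::-1]


def best_score(a: str, b: str, min_span: int, min_identity: float):
    """Best integer score over all qualifying-span segments, or None."""
    id_sc = int(round(min_identity * SCALE))
    ac = enc(a)
    best = None
    for bc in (enc(b), rc(enc(b))):
        la, lb = len(ac), len(bc)
        match = (ac[:, None] == bc[None, :]) & (ac[:, None] < 4)
        for d in range(-(lb - min_span), la - min_span + 1):
            diag = np.diagonal(match, offset=-d)
            n = diag.shape[0]
            if n < min_span:
                continue
            p = np.concatenate([[0], np.cumsum(diag)])
            q = SCALE * p - id_sc * np.arange(n + 1)
            run_min = np.minimum.accumulate(q)
            w = int((q[min_span:] - run_min[:n + 1 - min_span]).max())
            if best is None or w > best:
                best = w
    return best


def best_score_exhaustive(a: str, b: str, min_span: int, min_identity: float):
    """Triple-loop enumeration of every (strand, diagonal, s, e) segment.

    O(L^3) — only for tiny sequences; cross-checks `best_score` itself.
    """
    id_sc = int(round(min_identity * SCALE))
    ac = enc(a)
    best = None
    for bc in (enc(b), rc(enc(b))):
        la, lb = len(ac), len(bc)
        for d in range(-(lb - 1), la):
            i0, i1 = max(0, d), min(la, lb + d)
            n = i1 - i0
            if n < min_span:
                continue
            m = [int(ac[i0 + t] == bc[i0 + t - d] and ac[i0 + t] < 4)
                 for t in range(n)]
            for s in range(n - min_span + 1):
                run = 0
                for e in range(s + 1, n + 1):
                    run += m[e - 1]
                    if e - s < min_span:
                        continue
                    w = SCALE * run - id_sc * (e - s)
                    if best is None or w > best:
                        best = w
    return best


def overlap_accepted(a: str, b: str, min_span: int, min_identity: float) -> bool:
    w = best_score(a, b, min_span, min_identity)
    return w is not None and w >= 0
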