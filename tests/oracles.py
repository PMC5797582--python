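"""Independent reference implementations used only to check the package.

These deliberately avoid the package's search machinery: the repeat
oracle scans every diagonal exhaustively (no k-mer seeding) with its own
run-length chaining code; the hypergeometric oracle sums the tail with
exact rational arithmetic; the interval oracle is a naive double loop.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _windows_on_vector(match: list[bool], min_length: int, p: float, min_anchor: int = 8):
    """Qualifying windows of one diagonal: anchor runs >= min_anchor chained
    while overall identity >= p, with a re-merge pass; pure-Python RLE."""
    runs = []
    i, n = 0, len(match)
    while i < n:
        if match[i]:
            j = i
            while j < n and match[j]:
                j += 1
            if j - i >= min_anchor:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return []
    cum = [0]
    for m in match:
        cum.append(cum[-1] + (1 if m else 0))

    def ident(s, e):
        return (cum[e] - cum[s]) / (e - s)

    chains = [list(runs[0])]
    for s, e in runs[1:]:
        if ident(chains[-1][0], e) >= p - 1e-12:
            chains[-1][1] = e
        else:
            chains.append([s, e])
    changed = True
    while changed and len(chains) > 1:
        changed = False
        out = [chains[0]]
        for c in chains[1:]:
            if ident(out[-1][0], c[1]) >= p - 1e-12:
                out[-1][1] = c[1]
                changed = True
            else:
                out.append(c)
        chains = out
    return [(s, e, cum[e] - cum[s]) for s, e in chains if e - s >= min_length]


def brute_force_repeat_pairs(seq: str, min_length: int = 500, min_identity: float = 0.95):
    """All repeat pairs of one sequence by exhaustive diagonal scan.

    Returns tuples (a_start, a_end, b_start, b_end, orientation) with the
    same canonical ordering as the package (a before b; each
    reverse-complement pair reported once).
    """
    seq = seq.upper()
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    not_n = arr != ord("N")
    out = []
    w = min_length
    # forward: y = x shifted by d > 0
    for d in range(1, L - min_length + 1):
        x, y = arr[: L - d], arr[d:]
        match = (x == y) & not_n[: L - d] & not_n[d:]
        cum = np.concatenate(([0], np.cumsum(match)))
        if len(match) < w or (cum[w:] - cum[:-w]).max(initial=0) < min_identity * w - 1:
            continue
        for s, e, _m in _windows_on_vector(match.tolist(), min_length, min_identity):
            out.append((s, e, s + d, e + d, "forward"))
    # reverse-complement: compare x against revcomp(x), all offsets
    rc = np.frombuffer(_revcomp(seq).encode(), dtype=np.uint8)
    rc_not_n = rc != ord("N")
    seen = set()
    for d in range(-(L - min_length), L - min_length + 1):
        t0, t1 = max(0, -d), min(L, L - d)
        if t1 - t0 < min_length:
            continue
        x, y = arr[t0:t1], rc[t0 + d : t1 + d]
        match = (x == y) & not_n[t0:t1] & rc_not_n[t0 + d : t1 + d]
        cum = np.concatenate(([0], np.cumsum(match)))
        if len(match) < w or (cum[w:] - cum[:-w]).max(initial=0) < min_identity * w - 1:
            continue
        for s, e, _m in _windows_on_vector(match.tolist(), min_length, min_identity):
            a = (t0 + s, t0 + e)
            bs, be = L - (t0 + e + d), L - (t0 + s + d)
            b = (bs, be)
            if a == b:
                continue
            if a > b:
                a, b = b, a
            key = (a, b)
            if key in seen:
                continue
            seen.add(key)
            out.append((a[0], a[1], b[0], b[1], "reverse_complement"))
    out.sort()
    return out


def pairs_match(
    oracle_pairs, impl_pairs, slack: int = 5
) -> bool:
    """One-to-one matching of oracle and implementation pairs within slack."""
    if len(oracle_pairs) != len(impl_pairs):
        return False
    impl = [(p.a_start, p.a_end, p.b_start, p.b_end, p.orientation) for p in impl_pairs]
    used = [False] * len(impl)
    for o in oracle_pairs:
        found = False
        for i, q in enumerate(impl):
            if used[i] or q[4] != o[4]:
                continue
            if all(abs(q[j] - o[j]) <= slack for j in range(4)):
                used[i] = True
                found = True
                break
        if not found:
            return False
    return True


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k), X ~ Hypergeometric(N population, K marked, n drawn)."""
    if k <= max(0, n + K - N):
        return Fraction(1)
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return Fraction(num, math.comb(N, n))


def naive_missed_genes(features, gaps, min_overlap: int = 1):
    """Interval-intersection by double loop: gene ids overlapping >= min_overlap
    bp of any gap on the same replicon."""
    missed = set()
    for f in features:
        for g in gaps:
            if g.replicon != f.replicon:
                continue
            ov = min(f.end, g.end) - max(f.start, g.start)
            if ov >= min_overlap:
                missed.add(f.gene_id)
    return missed


def exhaustive_accumulation_means(matrix: np.ndarray):
    """Exact mean pan/core curves over all n! genome orderings, plus the
    per-ordering values (for standard errors)."""
    import itertools

    n = matrix.shape[1]
    pans, cores = [], []
    for order in itertools.permutations(range(n)):
        sub = matrix[:, list(order)]
        pans.append(np.logical_or.accumulate(sub, axis=1).sum(axis=0))
        cores.append(np.logical_and.accumulate(sub, axis=1).sum(axis=0))
    pans = np.array(pans, dtype=float)
    cores = np.array(cores, dtype=float)
    return pans.mean(axis=0), cores.mean(axis=0), pans, cores
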