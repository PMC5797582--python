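"""Intra-genomic repeat detection and assembly-difficulty classification.

Bacterial genome assembly difficulty is governed by the number of repeated
sequences (IS elements, rDNA operons) and the length of the longest repeat.
This module finds all pairs of distinct loci whose ungapped alignment meets
length and identity thresholds (defaults: >=500 bp at >=95% identity), and
classifies genomes into three difficulty tiers:

* class I   — few repeats; longest is the multi-copy rDNA operon (~6-7 kb);
* class II  — many repeats (>100 pairs) but none longer than the rDNA operon;
* class III — repeats longer than the rDNA operon; hard to assemble even
  with long reads unless a size-selection step is used.

Detection is a k-mer seeded self-comparison: exact seed matches nominate
diagonals, each diagonal is scanned for maximal high-identity segments
(Ruzzo–Tompa all-maximal-scoring-segments with match score ``1 - p`` and
mismatch score ``-p``, so a segment scores positive iff its identity
exceeds ``p``). The mutation processes that create bacterial repeats
(IS transposition, rDNA duplication) leave near-identical copies, so an
ungapped per-diagonal scan recovers them; indel-containing repeats longer
than the seed spacing are reported as split segments.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records import SequenceRecord, validate_dna

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatPair:
    """Two distinct loci aligning above the length/identity thresholds.

    Coordinates are 0-based half-open on the forward strand of each
    replicon; ``locus_a`` starts at or before ``locus_b`` (canonical order)
    when both loci are on the same replicon.
    """

    replicon: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "forward" | "reverse_complement"
    aln_length: int
    identity: float
    replicon_b: str | None = None  # None: same replicon as locus_a

    @property
    def locus_a(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def locus_b(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)


@dataclass(frozen=True)
class RepeatProfile:
    """Per-genome repeat summary: the two axes of the difficulty plot."""

    genome_id: str
    n_pairs: int
    max_len: int
    complexity_class: str


def classify_complexity(
    n_pairs: int,
    max_len: int,
    rdna_ceiling: int = 7000,
    count_threshold: int = 100,
) -> str:
    """Assign an assembly-difficulty class from repeat count and max length.

    class III if the longest repeat exceeds the rDNA-operon ceiling
    (default 7 kb); else class II if there are more than ``count_threshold``
    repeat pairs; else class I.
    """
    if n_pairs < 0 or max_len < 0:
        raise ValueError("n_pairs and max_len must be non-negative")
    if max_len > rdna_ceiling:
        return "III"
    if n_pairs > count_threshold:
        return "II"
    return "I"


def summarize_repeats(pairs: list[RepeatPair], genome_id: str, **class_kwargs) -> RepeatProfile:
    """Collapse a genome's repeat pairs to (count, longest, class)."""
    n_pairs = len(pairs)
    max_len = max((p.aln_length for p in pairs), default=0)
    return RepeatProfile(
        genome_id=genome_id,
        n_pairs=n_pairs,
        max_len=max_len,
        complexity_class=classify_complexity(n_pairs, max_len, **class_kwargs),
    )


# --- diagonal segment machinery -------------------------------------------

_N_RUN_BREAK = 10
_MIN_ANCHOR = 8  # shortest exact-match run that can seed or join a chain


def chain_match_runs(
    match: np.ndarray,
    min_length: int,
    min_identity: float,
    min_anchor: int = _MIN_ANCHOR,
) -> list[tuple[int, int, int]]:
    """Qualifying windows (start, end, n_matches) of a per-diagonal match vector.

    Maximal exact-match runs of at least ``min_anchor`` bp are chained
    greedily left to right: a chain absorbs the next anchor iff the
    spanned window (chain start to anchor end) keeps an overall identity
    of at least ``min_identity``. Windows therefore start and end on an
    anchor and can bridge local mutation clusters, but cannot creep into
    flanking random sequence (whose ~25% identity dilutes the window
    below threshold immediately). Chains shorter than ``min_length`` are
    dropped.
    """
    m = match.astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m, [0]))))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_anchor
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        return []
    cum = np.concatenate(([0], np.cumsum(m)))

    def identity(s: int, e: int) -> float:
        return (cum[e] - cum[s]) / (e - s)

    chains: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        s, e = int(s), int(e)
        if identity(chains[-1][0], e) >= min_identity - 1e-12:
            chains[-1][1] = e
        else:
            chains.append([s, e])
    # merge pass: a cumulative dip can break a chain early even though the
    # full spanned window qualifies; re-join adjacent chains while the
    # combined window keeps threshold identity
    changed = True
    while changed and len(chains) > 1:
        changed = False
        merged: list[list[int]] = [chains[0]]
        for nxt in chains[1:]:
            if identity(merged[-1][0], nxt[1]) >= min_identity - 1e-12:
                merged[-1][1] = nxt[1]
                changed = True
            else:
                merged.append(nxt)
        chains = merged
    return [
        (cs, ce, int(cum[ce] - cum[cs]))
        for cs, ce in chains
        if ce - cs >= min_length
    ]


def _n_break_mask(seq_arr: np.ndarray) -> np.ndarray:
    """Positions lying inside runs of >= _N_RUN_BREAK consecutive Ns."""
    is_n = seq_arr == ord("N")
    if not is_n.any():
        return np.zeros(len(seq_arr), dtype=bool)
    mask = np.zeros(len(seq_arr), dtype=bool)
    # run-length scan over N positions
    idx = np.flatnonzero(is_n)
    run_start = idx[0]
    prev = idx[0]
    for i in list(idx[1:]) + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        if prev - run_start + 1 >= _N_RUN_BREAK:
            mask[run_start : prev + 1] = True
        if i is not None:
            run_start = prev = i
    return mask


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _seed_diagonals(x: str, y: str, k: int, same: bool, max_occ: int = 2000) -> set[int]:
    """Diagonals d = j - i holding at least one exact k-mer match x[i:i+k] == y[j:j+k].

    For a self-comparison (``same``) only d > 0 is reported (canonical order;
    d = 0 is the trivial self-match).
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(x) - k + 1):
        kmer = x[i : i + k]
        if "N" in kmer:
            continue
        index[kmer].append(i)
    diags: set[int] = set()
    if same:
        for positions in index.values():
            if len(positions) < 2 or len(positions) > max_occ:
                continue
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    diags.add(positions[bi] - positions[ai])
    else:
        for j in range(len(y) - k + 1):
            kmer = y[j : j + k]
            if "N" in kmer:
                continue
            hits = index.get(kmer)
            if hits is None or len(hits) > max_occ:
                continue
            for i in hits:
                diags.add(j - i)
    return diags


def _diagonal_windows(
    xa: np.ndarray,
    ya: np.ndarray,
    xbreak: np.ndarray,
    ybreak: np.ndarray,
    d: int,
    min_length: int,
    min_identity: float,
) -> list[tuple[int, int, int]]:
    """Qualifying windows (x_start, x_end, n_matches) on diagonal d (y = x + d)."""
    t0 = max(0, -d)
    t1 = min(len(xa), len(ya) - d)
    if t1 - t0 < min_length:
        return []
    xs = xa[t0:t1]
    ys = ya[t0 + d : t1 + d]
    match = (xs == ys) & (xs != ord("N")) & (ys != ord("N"))
    brk = xbreak[t0:t1] | ybreak[t0 + d : t1 + d]
    out: list[tuple[int, int, int]] = []
    if brk.any():
        # alignments break at runs of >= 10 Ns: process between-barrier spans
        match = match & ~brk
        b = np.flatnonzero(np.concatenate(([True], brk, [True])))
        spans = [(int(b[i]), int(b[i + 1]) - 1) for i in range(len(b) - 1)]
    else:
        spans = [(0, len(match))]
    for lo, hi in spans:
        if hi - lo < min_length:
            continue
        for s, e, m in chain_match_runs(match[lo:hi], min_length, min_identity):
            out.append((t0 + lo + s, t0 + lo + e, m))
    return out


def _drop_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose both loci are contained in a longer pair's loci."""
    kept: list[RepeatPair] = []
    pairs = sorted(pairs, key=lambda p: -p.aln_length)
    for p in pairs:
        contained = False
        for q in kept:
            if (
                q.orientation == p.orientation
                and q.replicon == p.replicon
                and q.replicon_b == p.replicon_b
                and q.a_start <= p.a_start
                and p.a_end <= q.a_end
                and q.b_start <= p.b_start
                and p.b_end <= q.b_end
            ):
                contained = True
                break
        if not contained:
            kept.append(p)
    return kept


def _self_pairs(
    rec: SequenceRecord, min_length: int, min_identity: float, k: int
) -> list[RepeatPair]:
    seq = rec.seq.upper()
    L = len(seq)
    arr = _seq_to_arr(seq)
    brk = _n_break_mask(arr)
    pairs: list[RepeatPair] = []

    # forward orientation: y = x, diagonals d > 0
    for d in sorted(_seed_diagonals(seq, seq, k, same=True)):
        for s, e, m in _diagonal_windows(arr, arr, brk, brk, d, min_length, min_identity):
            pairs.append(
                RepeatPair(
                    replicon=rec.id,
                    a_start=s,
                    a_end=e,
                    b_start=s + d,
                    b_end=e + d,
                    orientation="forward",
                    aln_length=e - s,
                    identity=m / (e - s),
                )
            )

    # reverse-complement orientation: compare seq against its revcomp
    rc = revcomp(seq)
    rc_arr = _seq_to_arr(rc)
    rc_brk = brk[::-1].copy()
    seen: set[tuple] = set()
    for d in sorted(_seed_diagonals(seq, rc, k, same=False)):
        for s, e, m in _diagonal_windows(arr, rc_arr, brk, rc_brk, d, min_length, min_identity):
            # window [s+d, e+d) on the revcomp maps to [L-e-d, L-s-d) forward
            bs, be = L - e - d, L - s - d
            a, b = (s, e), (bs, be)
            if a == b:  # perfect palindrome aligned onto itself
                continue
            if a > b:
                a, b = b, a
            key = (a, b)
            if key in seen:  # each inverted repeat is found from both loci
                continue
            seen.add(key)
            pairs.append(
                RepeatPair(
                    replicon=rec.id,
                    a_start=a[0],
                    a_end=a[1],
                    b_start=b[0],
                    b_end=b[1],
                    orientation="reverse_complement",
                    aln_length=e - s,
                    identity=m / (e - s),
                )
            )
    return _drop_contained(pairs)


def _cross_pairs(
    ra: SequenceRecord, rb: SequenceRecord, min_length: int, min_identity: float, k: int
) -> list[RepeatPair]:
    """Repeat pairs between two different replicons (combined scope)."""
    sa, sb = ra.seq.upper(), rb.seq.upper()
    aa, ab = _seq_to_arr(sa), _seq_to_arr(sb)
    brka, brkb = _n_break_mask(aa), _n_break_mask(ab)
    Lb = len(sb)
    pairs: list[RepeatPair] = []
    rc_sb = revcomp(sb)
    for orientation, target, tarr, tbrk in (
        ("forward", sb, ab, brkb),
        ("reverse_complement", rc_sb, _seq_to_arr(rc_sb), brkb[::-1].copy()),
    ):
        for d in sorted(_seed_diagonals(sa, target, k, same=False)):
            for s, e, m in _diagonal_windows(aa, tarr, brka, tbrk, d, min_length, min_identity):
                if orientation == "forward":
                    bs, be = s + d, e + d
                else:
                    bs, be = Lb - e - d, Lb - s - d
                pairs.append(
                    RepeatPair(
                        replicon=ra.id,
                        a_start=s,
                        a_end=e,
                        b_start=bs,
                        b_end=be,
                        orientation=orientation,
                        aln_length=e - s,
                        identity=m / (e - s),
                        replicon_b=rb.id,
                    )
                )
    return _drop_contained(pairs)


def find_repeat_pairs(
    genome: list[SequenceRecord],
    min_length: int = 500,
    min_identity: float = 0.95,
    scope: str = "per_replicon",
    k: int = 21,
    rotate: bool = False,
) -> list[RepeatPair]:
    """Find all repeat pairs in a genome meeting both thresholds.

    Parameters
    ----------
    genome
        Replicon sequences; multi-record input = chromosome plus plasmids.
    min_length
        Minimum alignment length in bp (default 500).
    min_identity
        Minimum fraction of matching columns (default 0.95).
    scope
        ``per_replicon`` searches each replicon against itself only;
        ``combined`` additionally compares replicon pairs.
    k
        Seed k-mer size; must not exceed ``min_length``.
    rotate
        Virtually double circular replicons to catch origin-spanning
        repeats (off by default; deposited records are scanned linearly).

    Returns
    -------
    list of RepeatPair, sorted by (replicon, a_start, b_start). The trivial
    full-length self-match of each replicon is excluded; k copies of one
    element yield C(k, 2) pairs.
    """
    if not genome:
        raise ValueError("no sequences")
    if k > min_length:
        raise ValueError(f"seed size k={k} exceeds min_length={min_length}")
    if scope not in ("per_replicon", "combined"):
        raise ValueError(f"unknown scope {scope!r}")
    validate_dna(genome)

    pairs: list[RepeatPair] = []
    for rec in genome:
        if rotate and rec.topology == "circular":
            pairs.extend(_rotated_self_pairs(rec, min_length, min_identity, k))
        else:
            pairs.extend(_self_pairs(rec, min_length, min_identity, k))
    if scope == "combined":
        for i in range(len(genome)):
            for j in range(i + 1, len(genome)):
                pairs.extend(_cross_pairs(genome[i], genome[j], min_length, min_identity, k))
    pairs.sort(key=lambda p: (p.replicon, p.replicon_b or "", p.a_start, p.b_start, p.orientation))
    return pairs


def _rotated_self_pairs(
    rec: SequenceRecord, min_length: int, min_identity: float, k: int
) -> list[RepeatPair]:
    """Self-comparison on the virtually doubled sequence of a circular replicon.

    Coordinates are reduced modulo the replicon length; the d = L shifted
    self-match and duplicate images are removed. Loci spanning the origin
    keep an end coordinate > L (interpret modulo L).
    """
    L = len(rec.seq)
    doubled = SequenceRecord(id=rec.id, seq=rec.seq + rec.seq, topology="linear")
    raw = _self_pairs(doubled, min_length, min_identity, k)
    seen: set[tuple] = set()
    out: list[RepeatPair] = []
    for p in raw:
        if p.aln_length >= L:  # trivial wrap-around self-match
            continue
        a = (p.a_start % L, p.a_start % L + p.aln_length)
        b = (p.b_start % L, p.b_start % L + p.aln_length)
        if a == b:
            continue
        if a > b:
            a, b = b, a
        key = (a, b, p.orientation)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            replace(p, a_start=a[0], a_end=a[1], b_start=b[0], b_end=b[1])
        )
    out.sort(key=lambda p: (p.a_start, p.b_start))
    return out


def species_repeat_summary(
    profiles: list[RepeatProfile], species_of: dict[str, str]
) -> pd.DataFrame:
    """Per-species repeat burden: mean pair count and class histogram.

    Species represented by a single genome are excluded. Class percentages
    are computed over all retained genomes (the union of multi-genome
    species), mirroring the per-class header of the difficulty overview.
    """
    if not profiles:
        raise ValueError("no repeat profiles given")
    missing = [p.genome_id for p in profiles if p.genome_id not in species_of]
    if missing:
        raise ValueError(f"genomes without species assignment: {missing}")
    df = pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in profiles],
            "species": [species_of[p.genome_id] for p in profiles],
            "n_pairs": [p.n_pairs for p in profiles],
            "complexity_class": [p.complexity_class for p in profiles],
        }
    )
    counts = df["species"].value_counts()
    df = df[df["species"].map(counts) >= 2]
    if df.empty:
        raise ValueError("no species with more than one genome")
    rows = []
    n_total = len(df)
    for species, grp in df.groupby("species", sort=True):
        row = {
            "species": species,
            "n_genomes": len(grp),
            "mean_n_pairs": float(grp["n_pairs"].mean()),
        }
        for cls in ("I", "II", "III"):
            row[f"class_{cls}"] = int((grp["complexity_class"] == cls).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    for cls in ("I", "II", "III"):
        out[f"pct_class_{cls}"] = 100.0 * out[f"class_{cls}"].sum() / n_total
    return out
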