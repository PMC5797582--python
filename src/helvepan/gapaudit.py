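"""Draft-assembly completeness audit against a complete reference.

Short-read assemblies of repeat-rich genomes leave the repeated regions —
and the genes inside them — uncovered. Given the draft contigs mapped to
the complete reference (SAM), this module computes per-base coverage,
extracts the zero-coverage gaps, and reports every annotated gene falling
in a gap, cross-classified by feature kind (CDS vs pseudogene) and
pan-genome category (core / accessory / unique).

Coverage counts primary alignments only (secondary and supplementary
records would double-count a contig); reference-consuming CIGAR
operations (M, =, X, D, N) contribute. Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pysam

from .records import GeneFeature, GenomeAnnotation


@dataclass(frozen=True)
class CoverageGap:
    replicon: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapAuditReport:
    gaps: list[CoverageGap]
    n_gaps: int
    mean_gap_len: float
    uncovered_fraction: float
    reference_length: int
    missed_genes: list[tuple[GeneFeature, str]]  # (feature, category)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # kind -> category -> n

    def summary(self) -> dict:
        return {
            "n_gaps": self.n_gaps,
            "mean_gap_len": self.mean_gap_len,
            "uncovered_fraction": self.uncovered_fraction,
            "reference_length": self.reference_length,
            "n_missed_genes": len(self.missed_genes),
            "counts": self.counts,
        }


def coverage_from_alignments(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    reference_lengths: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-base coverage per replicon from primary alignments.

    ``alignments`` may be a SAM/BAM path, an open AlignmentFile, or an
    iterable of records. Unmapped, secondary and supplementary records are
    skipped; deletions/skips in the CIGAR consume reference and count as
    covered by the spanning alignment.
    """
    cov = {name: np.zeros(length, dtype=np.int32) for name, length in reference_lengths.items()}
    opened = None
    if isinstance(alignments, str):
        opened = pysam.AlignmentFile(alignments, check_sq=False)
        records: Iterable[pysam.AlignedSegment] = opened
    else:
        records = alignments
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name not in cov:
                raise ValueError(f"SAM target {name!r} absent from reference")
            # get_blocks() returns (start, end) for reference-consuming runs
            # split at N/D? pysam blocks split at N only; D consumes reference
            # within an aligned block, so span the full reference footprint.
            start = rec.reference_start
            end = rec.reference_end
            cov[name][start:end] += 1
    finally:
        if opened is not None:
            opened.close()
    return cov


def coverage_from_bed(
    path: str, reference_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-base coverage from a BED-like file (replicon, start, end[, depth])."""
    cov = {name: np.zeros(length, dtype=np.int32) for name, length in reference_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, start, end = fields[0], int(fields[1]), int(fields[2])
            depth = int(fields[3]) if len(fields) > 3 else 1
            if name not in cov:
                raise ValueError(f"BED replicon {name!r} absent from reference")
            cov[name][start:end] += depth
    return cov


def zero_coverage_gaps(
    coverage: dict[str, np.ndarray], min_gap_len: int = 1
) -> list[CoverageGap]:
    """Maximal runs of zero coverage, sorted by (replicon, start)."""
    gaps: list[CoverageGap] = []
    for name in sorted(coverage):
        vec = coverage[name]
        zero = np.concatenate(([False], vec == 0, [False]))
        edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_gap_len:
                gaps.append(CoverageGap(name, int(s), int(e)))
    return gaps


def audit(
    gaps: list[CoverageGap],
    annotation: GenomeAnnotation,
    categories: dict[str, str],
    reference_lengths: dict[str, int],
    min_overlap: int = 1,
) -> GapAuditReport:
    """Report the genes hit by zero-coverage gaps.

    A gene is missed iff it overlaps at least ``min_overlap`` bp of some
    gap. Genes absent from the category map are reported as "unassigned".
    The headline counts cover CDS and pseudogene features; rRNA/tRNA/other
    features are listed among the missed genes but tallied separately.
    """
    by_repl: dict[str, list[CoverageGap]] = {}
    for g in gaps:
        by_repl.setdefault(g.replicon, []).append(g)
    for lst in by_repl.values():
        lst.sort(key=lambda g: g.start)

    missed: list[tuple[GeneFeature, str]] = []
    for feat in annotation.features:
        overlap = 0
        for gap in by_repl.get(feat.replicon, ()):
            if gap.start >= feat.end:
                break
            overlap = max(overlap, min(feat.end, gap.end) - max(feat.start, gap.start))
        if overlap >= min_overlap:
            missed.append((feat, categories.get(feat.gene_id, "unassigned")))

    counts: dict[str, dict[str, int]] = {}
    for feat, cat in missed:
        kind = feat.kind if feat.kind in ("CDS", "pseudogene") else "other"
        counts.setdefault(kind, {}).setdefault(cat, 0)
        counts[kind][cat] += 1

    total_len = sum(reference_lengths.values())
    gap_total = sum(g.length for g in gaps)
    return GapAuditReport(
        gaps=sorted(gaps, key=lambda g: (g.replicon, g.start)),
        n_gaps=len(gaps),
        mean_gap_len=gap_total / len(gaps) if gaps else 0.0,
        uncovered_fraction=gap_total / total_len if total_len else 0.0,
        reference_length=total_len,
        missed_genes=missed,
        counts=counts,
    )


def run_gap_audit(
    sam_path: str,
    reference_lengths: dict[str, int],
    annotation: GenomeAnnotation,
    categories: dict[str, str],
    min_gap_len: int = 1,
    min_overlap: int = 1,
) -> GapAuditReport:
    """SAM -> coverage -> gaps -> audited report, in one call."""
    cov = coverage_from_alignments(sam_path, reference_lengths)
    gaps = zero_coverage_gaps(cov, min_gap_len=min_gap_len)
    return audit(gaps, annotation, categories, reference_lengths, min_overlap=min_overlap)
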