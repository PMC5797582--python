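"""Strain-resolved attribution of metagenome reads mapped to a genome panel.

A natural whey starter culture is a mixture of a few lactic acid
bacteria; mapping its reads against a panel of reference genomes (aligner
in report-all mode, so secondary alignments carry the multi-target
information) yields, per read, the set of panel genomes it hits. From
these target sets this module derives:

* a species-level composition — a read hitting m distinct genomes
  contributes 1/m to each, summed by species (no genome-count or
  genome-size correction at species level);
* group-exclusive counts — reads whose every target belongs to one genome
  group (e.g. the newly sequenced strains vs the public references),
  normalized by group size to correct for unequal numbers of targets;
* per-genome unique-read counts — reads hitting exactly one genome, the
  signal that resolves strains (near-identical strains show ~0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pysam


@dataclass(frozen=True)
class PanelEntry:
    genome_id: str
    species: str
    group: str  # e.g. "FAM" | "NCBI" | "other"
    total_length: int = 0


@dataclass
class ReferencePanel:
    entries: dict[str, PanelEntry]

    @classmethod
    def from_tsv(cls, path: str) -> "ReferencePanel":
        entries = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "genome_id":
                    continue
                gid, species, group = fields[0], fields[1], fields[2]
                length = int(fields[3]) if len(fields) > 3 else 0
                if gid in entries:
                    raise ValueError(f"duplicate genome_id {gid!r} in panel")
                entries[gid] = PanelEntry(gid, species, group, length)
        return cls(entries)

    def species_of(self, genome_id: str) -> str:
        return self.entries[genome_id].species

    def group_of(self, genome_id: str) -> str:
        return self.entries[genome_id].group

    def genomes_in_group(self, group: str) -> list[str]:
        return [g for g, e in self.entries.items() if e.group == group]

    @property
    def groups(self) -> list[str]:
        return sorted({e.group for e in self.entries.values()})


@dataclass
class AttributionResult:
    species_counts: dict[str, float]  # fractional read counts
    species_fractions: dict[str, float]  # includes "unmapped"
    group_exclusive: dict[str, dict[str, float]]  # group -> {raw, normalized}
    unique_per_genome: dict[str, int]
    n_mapped: int = 0
    n_unmapped: int = 0


def load_alignments(
    sam: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    replicon_to_genome: dict[str, str] | None = None,
    by_fragment: bool = False,
) -> tuple[dict[str, set[str]], int]:
    """Per-read sets of distinct target genomes, plus the unmapped count.

    Unmapped and supplementary records are dropped; secondary alignments
    are retained (they carry the multi-target information). Duplicate hits
    of one read to the same genome collapse to one target. If
    ``replicon_to_genome`` is given, SAM reference names are mapped
    through it (several replicons per genome); otherwise the reference
    name is the genome id. With ``by_fragment``, mate suffixes ("/1",
    "/2") are stripped and mates merged by intersecting their target sets
    (a fragment must be compatible with a genome on both ends).
    """
    opened = None
    if isinstance(sam, str):
        opened = pysam.AlignmentFile(sam, check_sq=False)
        records: Iterable[pysam.AlignedSegment] = opened
    else:
        records = sam

    targets: dict[str, set[str]] = {}
    mate_sets: dict[str, dict[int, set[str]]] = {}
    unmapped_ids: set[str] = set()
    try:
        for rec in records:
            name = rec.query_name
            mate = 2 if rec.is_read2 else 1
            if by_fragment and name and (name.endswith("/1") or name.endswith("/2")):
                mate = int(name[-1])
                name = name[:-2]
            if rec.is_supplementary:
                continue
            if rec.is_unmapped:
                unmapped_ids.add(name)
                continue
            ref = rec.reference_name
            genome = replicon_to_genome.get(ref) if replicon_to_genome else ref
            if genome is None:
                raise ValueError(f"SAM target {ref!r} not in replicon-to-genome map")
            if by_fragment:
                mate_sets.setdefault(name, {}).setdefault(mate, set()).add(genome)
            else:
                targets.setdefault(name, set()).add(genome)
    finally:
        if opened is not None:
            opened.close()

    if by_fragment:
        for name, per_mate in mate_sets.items():
            sets = list(per_mate.values())
            merged = set.intersection(*sets) if len(sets) > 1 else sets[0]
            if merged:
                targets[name] = merged
            else:
                unmapped_ids.add(name)

    n_unmapped = len(unmapped_ids - targets.keys())
    return targets, n_unmapped


def species_composition(
    read_targets: dict[str, set[str]],
    panel: ReferencePanel,
    n_unmapped: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fractional species counts and fractions (unmapped as its own slice).

    A read hitting m distinct genomes contributes 1/m to each genome's
    species; the sum over species equals the number of mapped reads
    exactly, whatever the multi-mapping structure.
    """
    counts: dict[str, float] = {}
    for read, genomes in read_targets.items():
        if not genomes:
            continue
        w = 1.0 / len(genomes)
        for g in genomes:
            if g not in panel.entries:
                raise ValueError(f"genome {g!r} not in panel")
            sp = panel.species_of(g)
            counts[sp] = counts.get(sp, 0.0) + w
    total = sum(counts.values()) + n_unmapped
    fractions = {sp: c / total for sp, c in counts.items()} if total else {}
    if total:
        fractions["unmapped"] = n_unmapped / total
    return counts, fractions


def group_exclusive_counts(
    read_targets: dict[str, set[str]],
    panel: ReferencePanel,
) -> dict[str, dict[str, float]]:
    """Reads mapping exclusively within one genome group, raw and
    normalized by the number of genomes in the group."""
    out: dict[str, dict[str, float]] = {}
    group_sizes = {grp: len(panel.genomes_in_group(grp)) for grp in panel.groups}
    for grp, size in group_sizes.items():
        if size == 0:
            raise ValueError(f"group {grp!r} has no genomes")
    raw = {grp: 0 for grp in group_sizes}
    for genomes in read_targets.values():
        if not genomes:
            continue
        groups = {panel.group_of(g) for g in genomes}
        if len(groups) == 1:
            raw[next(iter(groups))] += 1
    for grp, count in raw.items():
        out[grp] = {"raw": float(count), "normalized": count / group_sizes[grp]}
    return out


def unique_read_counts(
    read_targets: dict[str, set[str]],
    panel: ReferencePanel,
) -> dict[str, int]:
    """Per genome, the number of reads hitting exactly that one genome."""
    counts = {g: 0 for g in panel.entries}
    for genomes in read_targets.values():
        if len(genomes) == 1:
            g = next(iter(genomes))
            if g not in counts:
                raise ValueError(f"genome {g!r} not in panel")
            counts[g] += 1
    return counts


def attribute(
    read_targets: dict[str, set[str]],
    panel: ReferencePanel,
    n_unmapped: int = 0,
) -> AttributionResult:
    """Full attribution: species composition, group-exclusive and unique counts."""
    counts, fractions = species_composition(read_targets, panel, n_unmapped)
    return AttributionResult(
        species_counts=counts,
        species_fractions=fractions,
        group_exclusive=group_exclusive_counts(read_targets, panel),
        unique_per_genome=unique_read_counts(read_targets, panel),
        n_mapped=sum(1 for t in read_targets.values() if t),
        n_unmapped=n_unmapped,
    )
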