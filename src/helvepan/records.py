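"""Shared lightweight record types used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One replicon (chromosome or plasmid) of a genome.

    ``topology`` is informational: repeat detection treats circular
    replicons as linear by default (see :func:`helvepan.repeats.find_repeat_pairs`).
    """

    id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)


def validate_dna(records: list[SequenceRecord]) -> None:
    """Raise if any record contains characters outside {A,C,G,T,N}."""
    for rec in records:
        bad = set(rec.seq.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTN characters: "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A located gene on a replicon; coordinates are 0-based half-open."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str  # "+" | "-"
    kind: str  # "CDS" | "pseudogene" | "rRNA" | "tRNA" | "other"
    product: str = ""
    protein: str | None = None  # amino-acid sequence, CDS only

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """A genome's full feature set, keyed for per-replicon lookup."""

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)

    def by_replicon(self) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            out.setdefault(f.replicon, []).append(f)
        for feats in out.values():
            feats.sort(key=lambda f: (f.start, f.end))
        return out

    def of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]
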