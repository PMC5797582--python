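"""Reading and writing the flat formats the pipeline exchanges.

FASTA goes through Biopython; annotations are accepted either as GFF3 or
as a flat gene table (TSV: gene_id, replicon, start, end, strand, kind,
product) with 0-based half-open coordinates. GFF3 coordinates (1-based
inclusive) are converted on the way in and out.
"""

from __future__ import annotations

import json

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import GeneFeature, GenomeAnnotation, SequenceRecord
from .repeats import RepeatPair, RepeatProfile


def read_fasta(path: str, topology: str = "linear") -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), topology=topology)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(path: str, records: list[SequenceRecord] | dict[str, str]) -> None:
    if isinstance(records, dict):
        bio = [BioSeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    else:
        bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, path, "fasta")


def read_protein_fasta(path: str) -> list[tuple[str, str]]:
    """Protein FASTA with headers = gene ids."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


# --- annotations -----------------------------------------------------------

_GFF_KINDS = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


def read_gff3(path: str, genome_id: str = "") -> GenomeAnnotation:
    """Minimal GFF3 reader: CDS / pseudogene / rRNA / tRNA features with an
    ID or locus_tag attribute; everything else becomes kind "other"."""
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype in ("region", "gene"):  # container features
                continue
            kind = _GFF_KINDS.get(ftype, "other")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag") or f"{seqid}:{start}-{end}"
            if gid in seen:
                continue
            seen.add(gid)
            feats.append(
                GeneFeature(
                    gene_id=gid,
                    replicon=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    kind=kind,
                    product=attr.get("product", ""),
                )
            )
    return GenomeAnnotation(genome_id=genome_id or path, features=feats)


def write_gff3(path: str, annotation: GenomeAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            ftype = f.kind if f.kind in _GFF_KINDS else "misc_feature"
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon}\thelvepan\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gene_table(path: str, genome_id: str = "") -> GenomeAnnotation:
    """Flat gene table: gene_id, replicon, start, end, strand, kind[, product]."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            f = line.split("\t")
            feats.append(
                GeneFeature(
                    gene_id=f[0],
                    replicon=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    strand=f[4],
                    kind=f[5],
                    product=f[6] if len(f) > 6 else "",
                )
            )
    return GenomeAnnotation(genome_id=genome_id or path, features=feats)


def read_category_map(path: str) -> dict[str, str]:
    """TSV gene_id -> core | accessory | unique."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, cat = line.split("\t")[:2]
            out[gid] = cat
    return out


# --- repeat TSVs -----------------------------------------------------------

REPEAT_COLUMNS = [
    "replicon",
    "a_start",
    "a_end",
    "b_start",
    "b_end",
    "orientation",
    "length",
    "identity",
]


def write_repeat_pairs(path: str, pairs: list[RepeatPair]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPEAT_COLUMNS) + "\n")
        for p in pairs:
            repl = p.replicon if p.replicon_b in (None, p.replicon) else f"{p.replicon}|{p.replicon_b}"
            fh.write(
                f"{repl}\t{p.a_start}\t{p.a_end}\t{p.b_start}\t{p.b_end}\t"
                f"{p.orientation}\t{p.aln_length}\t{p.identity:.4f}\n"
            )


def write_repeat_profile(path: str, profile: RepeatProfile) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tn_pairs\tmax_len\tcomplexity_class\n")
        fh.write(
            f"{profile.genome_id}\t{profile.n_pairs}\t{profile.max_len}\t"
            f"{profile.complexity_class}\n"
        )


def read_repeat_profile(path: str) -> RepeatProfile:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("genome_id")]
    f = lines[0].rstrip("\n").split("\t")
    return RepeatProfile(f[0], int(f[1]), int(f[2]), f[3])


def write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_domain_hits(path: str):
    """Domain-hit TSV (query, domain, e_value[, frame]) -> DomainHit list."""
    from .enrichment import DomainHit

    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("query\t"):
                continue
            f = line.split("\t")
            frame = int(f[3]) if len(f) > 3 and f[3] not in ("", "n/a") else None
            hits.append(DomainHit(f[0], f[1], float(f[2]), frame))
    return hits
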