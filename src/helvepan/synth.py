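"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study conditions end to end: genomes with
planted repeat families of controlled copy number, length and identity;
families of related strains sharing a core gene set plus accessory and
strain-unique genes, with an optional fraction of frameshifted
pseudogenes; GO annotation inputs with a planted term enriched among
pseudogenes; and strain-mixture read sets with sequencing error, plus a
toy exact-match aligner so the read-attribution stage can be tested
without an external aligner.

All randomness flows from one integer seed per spec; outputs are
byte-identical across runs for a fixed seed. The mutation model is
substitution-only (except the single-base deletion that creates a
frameshift pseudogene), which keeps expected sequence identities
analytic: two copies independently mutated at rate ``m`` from a common
template diverge by ``~2m`` in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import GeneFeature, GenomeAnnotation, SequenceRecord
from .repeats import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


# --- planted-repeat genomes ------------------------------------------------


@dataclass(frozen=True)
class RepeatPlantSpec:
    """Blueprint for a genome with planted repeat families.

    ``families`` is a list of (copies, length_bp, per_copy_mutation_rate);
    the first copy of each family is the unmutated template.
    """

    backbone_length: int
    families: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c * ln for c, ln, _ in self.families)
        if total > self.backbone_length / 2:
            raise ValueError(
                f"planted repeats ({total} bp) exceed half the backbone "
                f"({self.backbone_length} bp)"
            )


def make_repeat_genome(
    spec: RepeatPlantSpec, max_tries: int = 1000
) -> tuple[SequenceRecord, list[dict]]:
    """Random backbone with repeat copies planted at non-overlapping loci.

    Returns the sequence and a truth table of planted loci (one record per
    copy: family, copy, start, end, mutation rate). A family of c copies
    is expected to yield C(c, 2) repeat pairs in downstream detection.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_dna(rng, spec.backbone_length))
    occupied: list[tuple[int, int]] = []
    truth: list[dict] = []
    for fam_idx, (copies, length, rate) in enumerate(spec.families):
        if length > spec.backbone_length:
            raise ValueError("repeat copy longer than backbone")
        template = _random_dna(rng, length)
        for copy_idx in range(copies):
            placed = False
            for _ in range(max_tries):
                start = int(rng.integers(0, spec.backbone_length - length + 1))
                end = start + length
                if all(end <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place copy {copy_idx} of family {fam_idx} "
                    f"without overlap after {max_tries} tries"
                )
            occupied.append((start, end))
            copy_seq = template if copy_idx == 0 else _mutate(rng, template, rate)
            seq[start:end] = copy_seq
            truth.append(
                {
                    "family": fam_idx,
                    "copy": copy_idx,
                    "start": start,
                    "end": end,
                    "mutation_rate": rate,
                }
            )
    truth.sort(key=lambda r: r["start"])
    record = SequenceRecord(id=f"synthrep_seed{spec.seed}", seq="".join(seq))
    return record, truth


# --- strain families -------------------------------------------------------


@dataclass(frozen=True)
class StrainFamilySpec:
    """Blueprint for a family of related strain genomes.

    Cluster counts are the *designed* pan-genome partition: ``n_core``
    clusters present in every strain, ``n_accessory`` in a random subset of
    2..n-1 strains, and ``n_unique_per_strain`` private to each strain.
    ``within_mutation`` is the per-copy nucleotide substitution rate from
    the cluster template (default 0.01, i.e. ~2% pairwise nucleotide
    divergence between members). ``pseudogene_fraction`` of each strain's
    genes are frameshifted by a single-base deletion and re-annotated as
    pseudogenes.
    """

    n_strains: int = 5
    n_core: int = 100
    n_accessory: int = 60
    n_unique_per_strain: int = 8
    gene_len_mean: float = 900.0
    gene_len_sd: float = 150.0
    within_mutation: float = 0.01
    pseudogene_fraction: float = 0.0
    spacer_len: int = 100
    seed: int = 0


@dataclass
class StrainFamily:
    """A generated strain family plus the truth needed to audit the pipeline."""

    spec: StrainFamilySpec
    strains: list[str]
    genomes: dict[str, SequenceRecord]
    annotations: dict[str, GenomeAnnotation]
    genes_nt: dict[str, dict[str, str]]  # strain -> gene_id -> gene-oriented DNA
    pseudogenes: dict[str, list[str]] = field(default_factory=dict)
    cluster_of: dict[str, str] = field(default_factory=dict)  # gene_id -> cluster
    designed_presence: dict[str, set[str]] = field(default_factory=dict)

    def proteins(self) -> dict[str, list[tuple[str, str]]]:
        """Intact-CDS proteins per strain (pseudogenes excluded)."""
        out: dict[str, list[tuple[str, str]]] = {}
        for strain in self.strains:
            out[strain] = [
                (f.gene_id, f.protein)
                for f in self.annotations[strain].features
                if f.kind == "CDS" and f.protein
            ]
        return out

    def truth_partition(self) -> tuple[int, int, int]:
        """(core, accessory, unique) cluster counts over intact CDS copies.

        Pseudogenization removes a copy from its cluster's presence set, so
        these counts can differ from the designed partition when
        ``pseudogene_fraction`` > 0.
        """
        pseudo = {g for lst in self.pseudogenes.values() for g in lst}
        presence: dict[str, set[str]] = {}
        for strain in self.strains:
            for f in self.annotations[strain].features:
                if f.kind != "CDS" or f.gene_id in pseudo:
                    continue
                presence.setdefault(self.cluster_of[f.gene_id], set()).add(strain)
        n = len(self.strains)
        core = sum(1 for s in presence.values() if len(s) == n)
        unique = sum(1 for s in presence.values() if len(s) == 1)
        accessory = len(presence) - core - unique
        return core, accessory, unique


def _random_gene(rng: np.random.Generator, length_bp: int) -> str:
    """Random CDS: ATG, internal non-stop codons, one terminal stop."""
    n_codons = max(10, int(round(length_bp / 3)))
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate_cds(rng: np.random.Generator, gene: str, rate: float) -> str:
    """Substitution-mutate a CDS without creating internal stops.

    The terminal stop codon is never touched; a substitution that would
    create an internal stop codon is redrawn (and skipped if no safe base
    exists), so the encoded protein keeps its full length.
    """
    if rate <= 0:
        return gene
    seq = list(gene)
    n = len(seq)
    for i in np.flatnonzero(rng.random(n) < rate):
        i = int(i)
        if i >= n - 3:  # terminal stop codon
            continue
        codon_start = 3 * (i // 3)
        for b in rng.permutation(list("ACGT")):
            if b == seq[i]:
                continue
            trial = seq[codon_start : codon_start + 3]
            trial[i - codon_start] = b
            if "".join(trial) not in _STOPS:
                seq[i] = b
                break
    return "".join(seq)


def _translate(cds: str) -> str:
    """Translate a CDS with the bacterial code; terminal stop stripped."""
    from Bio.Seq import Seq

    aa = str(Seq(cds).translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def _frameshift(rng: np.random.Generator, gene: str) -> str:
    """Delete one base at a random internal codon (the pseudogene model)."""
    n_codons = len(gene) // 3
    codon = int(rng.integers(1, n_codons - 1))
    pos = 3 * codon + int(rng.integers(0, 3))
    return gene[:pos] + gene[pos + 1 :]


def make_strain_family(spec: StrainFamilySpec) -> StrainFamily:
    """Generate a strain family with a designed pan-genome partition."""
    if spec.n_strains < 2:
        raise ValueError("need at least two strains")
    if spec.n_accessory and spec.n_strains < 3:
        raise ValueError("accessory clusters need n_strains >= 3")
    rng = np.random.default_rng(spec.seed)
    strains = [f"S{i + 1:02d}" for i in range(spec.n_strains)]

    # design clusters and their presence sets
    clusters: list[tuple[str, str, list[str]]] = []  # (cluster_id, template, strains)
    cid = 0

    def new_cluster(members: list[str]) -> None:
        nonlocal cid
        length = max(90.0, rng.normal(spec.gene_len_mean, spec.gene_len_sd))
        clusters.append((f"fam{cid:04d}", _random_gene(rng, int(length)), members))
        cid += 1

    for _ in range(spec.n_core):
        new_cluster(list(strains))
    for _ in range(spec.n_accessory):
        size = int(rng.integers(2, spec.n_strains))  # 2 .. n-1
        members = list(rng.choice(strains, size=size, replace=False))
        new_cluster(members)
    for strain in strains:
        for _ in range(spec.n_unique_per_strain):
            new_cluster([strain])

    designed_presence = {cid_: set(members) for cid_, _, members in clusters}

    # materialize per-strain gene copies
    family = StrainFamily(
        spec=spec,
        strains=strains,
        genomes={},
        annotations={},
        genes_nt={},
        pseudogenes={s: [] for s in strains},
        designed_presence=designed_presence,
    )
    per_strain_genes: dict[str, list[tuple[str, str, str]]] = {s: [] for s in strains}
    counter = {s: 0 for s in strains}
    for cluster_id, template, members in clusters:
        for strain in strains:
            if strain not in members:
                continue
            counter[strain] += 1
            gene_id = f"{strain}_g{counter[strain]:04d}"
            gene = _mutate_cds(rng, template, spec.within_mutation)
            per_strain_genes[strain].append((gene_id, cluster_id, gene))
            family.cluster_of[gene_id] = cluster_id

    # assemble genomes: shuffled gene order, random strands, random spacers
    for strain in strains:
        genes = per_strain_genes[strain]
        order = rng.permutation(len(genes))
        parts: list[str] = []
        feats: list[GeneFeature] = []
        nt: dict[str, str] = {}
        pos = 0
        n_pseudo = int(round(spec.pseudogene_fraction * len(genes)))
        pseudo_idx = set(rng.choice(len(genes), size=n_pseudo, replace=False).tolist())
        for oi in order:
            gene_id, cluster_id, gene = genes[int(oi)]
            spacer = _random_dna(rng, max(20, int(rng.normal(spec.spacer_len, 20))))
            parts.append(spacer)
            pos += len(spacer)
            if int(oi) in pseudo_idx:
                gene = _frameshift(rng, gene)
                kind, protein = "pseudogene", None
                family.pseudogenes[strain].append(gene_id)
            else:
                kind, protein = "CDS", _translate(gene)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = gene if strand == "+" else revcomp(gene)
            parts.append(inserted)
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    replicon=strain,
                    start=pos,
                    end=pos + len(gene),
                    strand=strand,
                    kind=kind,
                    product=cluster_id,
                    protein=protein,
                )
            )
            nt[gene_id] = gene
            pos += len(gene)
        parts.append(_random_dna(rng, spec.spacer_len))
        family.genomes[strain] = SequenceRecord(id=strain, seq="".join(parts))
        feats.sort(key=lambda f: f.start)
        family.annotations[strain] = GenomeAnnotation(genome_id=strain, features=feats)
        family.genes_nt[strain] = nt
    return family


# --- draft-assembly gap cases ---------------------------------------------


@dataclass(frozen=True)
class GapCaseSpec:
    """A reference genome, its annotation, and a draft with deleted blocks."""

    genome_length: int = 50_000
    n_genes: int = 40
    gene_length: int = 900
    n_deleted_blocks: int = 4
    deleted_fraction: float = 0.1
    seed: int = 0


@dataclass
class GapCase:
    reference: SequenceRecord
    annotation: GenomeAnnotation
    contigs: list[tuple[str, int, int]]  # (name, ref_start, ref_end)
    deleted: list[tuple[int, int]]  # truth gaps, sorted, non-overlapping
    categories: dict[str, str]  # gene_id -> core | accessory | unique

    @property
    def deleted_fraction(self) -> float:
        return sum(e - s for s, e in self.deleted) / len(self.reference.seq)


def make_gap_case(spec: GapCaseSpec) -> GapCase:
    """Reference + annotation + draft contigs with known deleted blocks.

    The draft is the reference minus ``n_deleted_blocks`` non-overlapping
    blocks totalling ``deleted_fraction`` of the genome; the surviving
    segments become contigs that map back at their original coordinates.
    Genes are placed at regular intervals and assigned random pan-genome
    categories so the audit's cross-classification can be verified.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    reference = SequenceRecord(id="ref", seq=_random_dna(rng, L))

    feats = []
    step = L // spec.n_genes
    cats = {}
    for i in range(spec.n_genes):
        start = i * step + int(rng.integers(0, max(1, step - spec.gene_length)))
        end = min(start + spec.gene_length, L)
        gid = f"ref_g{i + 1:04d}"
        kind = "pseudogene" if rng.random() < 0.15 else "CDS"
        feats.append(
            GeneFeature(gid, "ref", start, end, "+" if rng.random() < 0.5 else "-", kind)
        )
        cats[gid] = str(rng.choice(["core", "accessory", "unique"]))
    annotation = GenomeAnnotation(genome_id="ref", features=feats)

    # deleted blocks: equal sizes, placed without overlap
    block_len = int(round(spec.deleted_fraction * L / spec.n_deleted_blocks))
    deleted: list[tuple[int, int]] = []
    for _ in range(spec.n_deleted_blocks):
        for _ in range(1000):
            s = int(rng.integers(0, L - block_len))
            e = s + block_len
            if all(e < ds or s > de for ds, de in deleted):  # keep blocks separated
                deleted.append((s, e))
                break
        else:
            raise ValueError("could not place deletion blocks")
    deleted.sort()

    contigs = []
    prev = 0
    for i, (s, e) in enumerate(deleted + [(L, L)]):
        if s > prev:
            contigs.append((f"contig{i + 1:03d}", prev, s))
        prev = e
    return GapCase(reference, annotation, contigs, deleted, cats)


def write_contig_sam(path: str, case: GapCase) -> None:
    """Write the draft contigs as perfect full-length alignments (SAM)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": case.reference.id, "LN": len(case.reference.seq)}],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for name, s, e in case.contigs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = case.reference.seq[s:e]
            a.reference_id = 0
            a.reference_start = s
            a.cigarstring = f"{e - s}M"
            a.mapping_quality = 60
            a.flag = 0
            out.write(a)


# --- strain-mixture reads --------------------------------------------------


@dataclass(frozen=True)
class MixtureSpec:
    """Read mixture from several strains at controlled proportions."""

    proportions: tuple[float, ...]
    n_reads: int = 10_000
    read_length: int = 151
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str  # with sequencing errors applied
    clean_seq: str  # error-free genomic substring
    source: str  # strain the read was drawn from
    position: int


def make_mixture_reads(
    spec: MixtureSpec, genomes: dict[str, SequenceRecord]
) -> list[SimulatedRead]:
    """Draw reads from strains per proportions; i.i.d. substitution errors."""
    names = list(genomes)
    if len(names) != len(spec.proportions):
        raise ValueError("one proportion per genome required")
    for name in names:
        if spec.read_length > len(genomes[name].seq):
            raise ValueError(f"read length exceeds genome {name!r}")
    rng = np.random.default_rng(spec.seed)
    sources = rng.choice(len(names), size=spec.n_reads, p=list(spec.proportions))
    reads: list[SimulatedRead] = []
    for i, si in enumerate(sources):
        g = genomes[names[int(si)]]
        pos = int(rng.integers(0, len(g.seq) - spec.read_length + 1))
        clean = g.seq[pos : pos + spec.read_length]
        seq = _mutate(rng, clean, spec.error_rate)
        reads.append(
            SimulatedRead(
                read_id=f"read{i + 1:06d}",
                seq=seq,
                clean_seq=clean,
                source=names[int(si)],
                position=pos,
            )
        )
    return reads


def align_trivially(
    reads: list[SimulatedRead],
    genomes: dict[str, SequenceRecord],
    sam_path: str | None = None,
) -> dict[str, set[str]]:
    """Toy exact-match aligner: a read hits every genome containing its
    error-free sequence on either strand.

    Returns the per-read set of genomes hit; if ``sam_path`` is given, also
    writes SAM records (the first hit of a read is primary, further hits
    secondary) so the attribution stage can be exercised through its SAM
    reader. Reads hitting no genome appear as unmapped records.
    """
    hits: dict[str, set[str]] = {}
    placements: dict[str, list[tuple[str, int, bool]]] = {}
    for read in reads:
        targets: set[str] = set()
        where: list[tuple[str, int, bool]] = []
        rc = revcomp(read.clean_seq)
        for gid, rec in genomes.items():
            p = rec.seq.find(read.clean_seq)
            if p >= 0:
                targets.add(gid)
                where.append((gid, p, False))
                continue
            p = rec.seq.find(rc)
            if p >= 0:
                targets.add(gid)
                where.append((gid, p, True))
        hits[read.read_id] = targets
        placements[read.read_id] = where

    if sam_path is not None:
        import pysam

        names = list(genomes)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g, "LN": len(genomes[g].seq)} for g in names],
        }
        ref_index = {g: i for i, g in enumerate(names)}
        with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
            for read in reads:
                where = placements[read.read_id]
                if not where:
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = read.read_id
                    a.query_sequence = read.seq
                    a.flag = 4  # unmapped
                    out.write(a)
                    continue
                for rank, (gid, pos, is_rc) in enumerate(where):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = read.read_id
                    a.query_sequence = read.seq if rank == 0 else None
                    a.reference_id = ref_index[gid]
                    a.reference_start = pos
                    a.cigarstring = f"{len(read.seq)}M"
                    a.mapping_quality = 0
                    a.flag = (16 if is_rc else 0) | (256 if rank > 0 else 0)
                    out.write(a)
    return hits


def write_fastq(path: str, reads: list[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# --- planted GO enrichment inputs ------------------------------------------


@dataclass(frozen=True)
class EnrichmentPlantSpec:
    """Domain-hit inputs with one GO term planted among the pseudogenes.

    The planted term annotates ``planted_frac_interest`` of the interest
    genes (pseudogenes) and ``planted_frac_background`` of the rest — the
    defaults (0.8 vs 0.1) give a design odds ratio of 36. Null terms
    annotate every gene with a per-term probability drawn uniformly from
    ``null_frac_range`` regardless of interest status.
    """

    n_cds: int = 240
    n_pseudo: int = 60
    planted_frac_interest: float = 0.8
    planted_frac_background: float = 0.1
    n_null_terms: int = 12
    null_frac_range: tuple[float, float] = (0.05, 0.3)
    qualifying_e: float = 1e-12
    seed: int = 0


@dataclass
class EnrichmentPlant:
    hits: list[tuple[str, str, float]]  # (query, domain, e_value)
    domain2go: dict[str, set[str]]
    dag_edges: list[tuple[str, str]]  # child -> parent (is_a)
    universe: list[str]
    interest: list[str]
    planted_term: str


def make_enrichment_inputs(spec: EnrichmentPlantSpec) -> EnrichmentPlant:
    """Fabricate hit tables, a domain->GO map and a flat BP DAG with one
    planted term enriched in the interest set."""
    rng = np.random.default_rng(spec.seed)
    cds = [f"cds{i + 1:04d}" for i in range(spec.n_cds)]
    pseudo = [f"pseudo{i + 1:04d}" for i in range(spec.n_pseudo)]
    universe = cds + pseudo
    root = "GO:0008150"
    planted = "GO:7777777"
    null_terms = [f"GO:{1000000 + i:07d}" for i in range(spec.n_null_terms)]
    edges = [(t, root) for t in null_terms + [planted]]
    domain_of = {t: f"PF{i + 1:05d}" for i, t in enumerate(null_terms + [planted])}
    domain2go = {d: {t} for t, d in domain_of.items()}

    hits: list[tuple[str, str, float]] = []

    def add_hit(gene: str, term: str) -> None:
        e = spec.qualifying_e * float(10 ** -rng.uniform(0, 3))
        hits.append((gene, domain_of[term], e))

    for term in null_terms:
        frac = rng.uniform(*spec.null_frac_range)
        for gene in universe:
            if rng.random() < frac:
                add_hit(gene, term)
    for gene in pseudo:
        if rng.random() < spec.planted_frac_interest:
            add_hit(gene, planted)
    for gene in cds:
        if rng.random() < spec.planted_frac_background:
            add_hit(gene, planted)
    rng.shuffle(hits)
    return EnrichmentPlant(
        hits=hits,
        domain2go=domain2go,
        dag_edges=edges,
        universe=universe,
        interest=pseudo,
        planted_term=planted,
    )
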