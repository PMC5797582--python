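"""Pan/core/accessory/unique genome profiling across strain genomes.

Protein-coding genes are clustered across genomes at a sequence-identity
threshold (default 95%, the blastp identity used for bacterial
pan-genomes) without paralog splitting, so several members from one
genome may share a cluster. The resulting presence/absence matrix is
partitioned into the core genome (clusters in every strain), the
accessory genome (a proper subset of >= 2 strains) and strain-unique
clusters, and summarized with randomized accumulation curves and COG
functional cross-tabulations.

The clusterer is a greedy representative-based single pass in the CD-HIT
tradition: proteins are sorted by length (descending, gene-id tie-break)
and each joins the first existing cluster whose representative it matches
at >= ``min_identity`` over >= ``min_coverage`` of the longer sequence,
else founds a new cluster. A presence/absence table produced by an
external pan-genome pipeline (Roary-dialect CSV) can be imported
directly, bypassing the internal clusterer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

COG_LETTERS = "JKLDVTMNUOCGEFHIPQS"


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)
    representative: str  # gene_id of the founding (longest) member

    @property
    def presence(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PresenceAbsenceMatrix:
    """Boolean clusters x genomes matrix."""

    matrix: np.ndarray  # bool, shape (n_clusters, n_genomes)
    cluster_ids: list[str]
    genome_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise ValueError("matrix shape does not match id lists")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)


@dataclass
class PangenomePartition:
    core: list[str]
    accessory: list[str]
    unique: dict[str, list[str]]  # genome_id -> cluster_ids

    @property
    def n_unique(self) -> int:
        return sum(len(v) for v in self.unique.values())

    @property
    def pan_size(self) -> int:
        return len(self.core) + len(self.accessory) + self.n_unique

    def summary(self) -> dict:
        return {
            "pan": self.pan_size,
            "core": len(self.core),
            "accessory": len(self.accessory),
            "unique": self.n_unique,
            "unique_per_genome": {g: len(v) for g, v in sorted(self.unique.items())},
        }


@dataclass
class AccumulationCurve:
    """Mean pan/core sizes as genomes are added in random order."""

    mean_pan: np.ndarray  # index k-1 = mean over iterations at k genomes
    mean_core: np.ndarray
    n_iterations: int
    seed: int
    per_iteration_pan: np.ndarray | None = None  # (iterations, n)
    per_iteration_core: np.ndarray | None = None


def global_identity(a: str, b: str) -> float:
    """Identity of the end-to-end alignment of two sequences.

    Computed as 1 - edit_distance / max(len); the denominator is a lower
    bound on the number of alignment columns, so this slightly
    underestimates identity for indel-rich pairs — conservative for
    thresholding.
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_proteins(
    genomes: dict[str, list[tuple[str, str]]],
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> list[GeneCluster]:
    """Greedy incremental clustering of proteins across genomes.

    ``genomes`` maps genome_id -> [(gene_id, protein_sequence)]. Proteins
    are processed longest-first (gene_id tie-break); each joins the first
    cluster (creation order) whose representative it matches at
    >= ``min_identity`` over >= ``min_coverage`` of the longer sequence.
    No paralog splitting: multiple genes of one genome may join a cluster.
    """
    entries: list[tuple[str, str, str]] = []  # (genome, gene, protein)
    for genome_id, genes in genomes.items():
        for gene_id, protein in genes:
            if not protein:
                raise ValueError(f"empty protein for gene {gene_id!r}")
            entries.append((genome_id, gene_id, protein))
    if not entries:
        raise ValueError("no proteins to cluster")
    entries.sort(key=lambda t: (-len(t[2]), t[1]))

    clusters: list[GeneCluster] = []
    rep_seqs: list[str] = []
    # coarse k-mer prefilter: candidate clusters sharing a seed with the query
    kmer_index: dict[str, set[int]] = {}
    KMER = 8

    def kmers(seq: str) -> set[str]:
        step = max(1, (len(seq) - KMER) // 32)  # sample up to ~32 seeds
        return {seq[i : i + KMER] for i in range(0, max(1, len(seq) - KMER + 1), step)}

    for genome_id, gene_id, protein in entries:
        candidates: set[int] = set()
        for km in kmers(protein):
            candidates |= kmer_index.get(km, set())
        joined = False
        for ci in sorted(candidates):
            rep = rep_seqs[ci]
            longer = max(len(rep), len(protein))
            if min(len(rep), len(protein)) < min_coverage * longer:
                continue
            if global_identity(protein, rep) >= min_identity - 1e-12:
                clusters[ci].members.append((genome_id, gene_id))
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(
                GeneCluster(
                    cluster_id=f"cluster{ci + 1:05d}",
                    members=[(genome_id, gene_id)],
                    representative=gene_id,
                )
            )
            rep_seqs.append(protein)
            for i in range(len(protein) - KMER + 1):
                kmer_index.setdefault(protein[i : i + KMER], set()).add(ci)
    return clusters


def presence_absence(
    clusters: list[GeneCluster], genome_ids: list[str] | None = None
) -> PresenceAbsenceMatrix:
    if genome_ids is None:
        genome_ids = sorted({g for c in clusters for g in c.presence})
    idx = {g: i for i, g in enumerate(genome_ids)}
    mat = np.zeros((len(clusters), len(genome_ids)), dtype=bool)
    for ri, c in enumerate(clusters):
        for g in c.presence:
            mat[ri, idx[g]] = True
    return PresenceAbsenceMatrix(mat, [c.cluster_id for c in clusters], list(genome_ids))


def read_roary_csv(path: str) -> PresenceAbsenceMatrix:
    """Import a Roary-dialect gene_presence_absence.csv.

    Column 1 is the cluster (gene) name; genome columns follow the 14
    fixed metadata columns of the Roary layout. A slimmer layout with the
    cluster column followed directly by genome columns is also accepted.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError("empty presence/absence file")
    header = rows[0]
    roary_fixed = 14  # Gene, Non-unique Gene name, Annotation, ... Avg group size nuc
    first_genome = roary_fixed if len(header) > roary_fixed and header[2] == "Annotation" else 1
    genome_ids = header[first_genome:]
    cluster_ids, mat = [], []
    for row in rows[1:]:
        if not row:
            continue
        cluster_ids.append(row[0])
        mat.append([bool(cell.strip()) for cell in row[first_genome:]])
    return PresenceAbsenceMatrix(np.array(mat, dtype=bool), cluster_ids, genome_ids)


def write_presence_absence_csv(matrix: PresenceAbsenceMatrix, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Gene"] + matrix.genome_ids)
        for cid, row in zip(matrix.cluster_ids, matrix.matrix):
            w.writerow([cid] + ["1" if x else "" for x in row])


def partition(matrix: PresenceAbsenceMatrix) -> PangenomePartition:
    """Split clusters into core / accessory / unique by presence count."""
    sums = matrix.matrix.sum(axis=1)
    if (sums == 0).any():
        empty = [matrix.cluster_ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"clusters present in no genome: {empty[:5]}")
    n = matrix.n_genomes
    core, accessory = [], []
    unique: dict[str, list[str]] = {g: [] for g in matrix.genome_ids}
    for i, cid in enumerate(matrix.cluster_ids):
        s = int(sums[i])
        if s == n:
            core.append(cid)
        elif s == 1:
            g = matrix.genome_ids[int(np.flatnonzero(matrix.matrix[i])[0])]
            unique[g].append(cid)
        else:
            accessory.append(cid)
    return PangenomePartition(core=core, accessory=accessory, unique=unique)


def accumulation_curves(
    matrix: PresenceAbsenceMatrix,
    n_iterations: int = 10,
    seed: int = 0,
    keep_iterations: bool = False,
) -> AccumulationCurve:
    """Randomized pan/core accumulation curves.

    For each iteration the genomes are added in a uniformly random order;
    pan[k] counts clusters present in at least one of the first k genomes,
    core[k] those present in all first k. Means are taken across
    iterations; the k = n endpoints equal |pan| and |core| exactly,
    independent of ordering.
    """
    n = matrix.n_genomes
    if n < 2:
        raise ValueError("need at least two genomes")
    rng = np.random.default_rng(seed)
    pans = np.zeros((n_iterations, n))
    cores = np.zeros((n_iterations, n))
    mat = matrix.matrix
    for it in range(n_iterations):
        order = rng.permutation(n)
        cum_any = np.logical_or.accumulate(mat[:, order], axis=1)
        cum_all = np.logical_and.accumulate(mat[:, order], axis=1)
        pans[it] = cum_any.sum(axis=0)
        cores[it] = cum_all.sum(axis=0)
    return AccumulationCurve(
        mean_pan=pans.mean(axis=0),
        mean_core=cores.mean(axis=0),
        n_iterations=n_iterations,
        seed=seed,
        per_iteration_pan=pans if keep_iterations else None,
        per_iteration_core=cores if keep_iterations else None,
    )


def assign_cog(
    hit_table: list[tuple[str, str, float, str]] | pd.DataFrame,
    e_max: float = 0.001,
) -> dict[str, str]:
    """Best-hit COG assignment: smallest e-value wins, hits above ``e_max``
    ignored; genes with no qualifying hit map to "none".

    ``hit_table`` rows are (gene_id, subject, e_value, cog_letters); ties
    at identical e-value resolve to the first row in input order.
    """
    if isinstance(hit_table, pd.DataFrame):
        rows = list(hit_table.itertuples(index=False, name=None))
    else:
        rows = list(hit_table)
    best: dict[str, tuple[float, int, str]] = {}
    seen: dict[str, None] = {}
    for lineno, row in enumerate(rows):
        try:
            gene_id, _subject, e_value, letters = row[0], row[1], float(row[2]), str(row[3])
        except (IndexError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed COG hit row {lineno + 1}: {row!r}") from exc
        seen[gene_id] = None
        if e_value > e_max:
            continue
        cur = best.get(gene_id)
        if cur is None or (e_value, lineno) < (cur[0], cur[1]):
            best[gene_id] = (e_value, lineno, letters)
    out = {g: "none" for g in seen}
    out.update({g: (letters if letters else "none") for g, (_, _, letters) in best.items()})
    return out


def cog_crosstab(
    part: PangenomePartition,
    clusters: list[GeneCluster],
    assignments: dict[str, str],
) -> pd.DataFrame:
    """COG class x pan-genome column counts and percentages.

    Each cluster is categorized via its representative's assignment; a
    multi-letter assignment contributes once to each letter. The "none"
    assignments make up the "Not in COG category" row. Percentages are
    over the cluster total of each column.
    """
    rep_of = {c.cluster_id: c.representative for c in clusters}
    columns = {
        "core": list(part.core),
        "accessory": list(part.accessory),
        "unique": [cid for lst in part.unique.values() for cid in lst],
    }
    letters = list(COG_LETTERS)
    rows = {ltr: {} for ltr in letters}
    rows["none"] = {}
    for col, cids in columns.items():
        counts = {ltr: 0 for ltr in letters}
        none = 0
        for cid in cids:
            assigned = assignments.get(rep_of.get(cid, ""), "none")
            if assigned in ("", "none"):
                none += 1
                continue
            seen_any = False
            for ltr in assigned:
                if ltr in counts:
                    counts[ltr] += 1
                    seen_any = True
            if not seen_any:
                none += 1
        total = len(cids)
        for ltr in letters:
            rows[ltr][col] = counts[ltr]
            rows[ltr][f"{col}_pct"] = 100.0 * counts[ltr] / total if total else 0.0
        rows["none"][col] = none
        rows["none"][f"{col}_pct"] = 100.0 * none / total if total else 0.0
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cog_class"
    return df
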