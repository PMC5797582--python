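"""GO-term enrichment of pseudogenes against a CDS + pseudogene universe.

Pseudogene sequences are six-frame translated (frameshifted genes carry
their protein domains in shifted frames), domain hits are filtered at a
strict e-value cutoff, mapped to GO terms via a pfam2go-style table, and
propagated up the GO DAG (true-path rule). Each biological-process term
is then tested for overrepresentation among the pseudogenes with a
one-sided Fisher exact test (hypergeometric tail); the "elim"
decorrelation variant removes the genes of already-significant child
terms from their ancestors before testing, which suppresses the cascade
of significant ancestors a single enriched leaf term otherwise produces.

No multiple-testing correction is applied to the ranking — terms are
ranked by raw p — but a Benjamini–Hochberg FDR column is emitted for
information.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom

BP_ROOT = "GO:0008150"
NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass(frozen=True)
class SixFrameTranslation:
    source_id: str
    frames: tuple[str, str, str, str, str, str]


def six_frame_translate(seq: str, source_id: str = "") -> SixFrameTranslation:
    """Translate all six reading frames with the bacterial genetic code.

    Frames 1-3 are offsets 0,1,2 of the forward strand; frames 4-6 are
    offsets 0,1,2 of the reverse complement. Internal stops are kept as
    '*'; alternative start codons are translated as their table-11 amino
    acid rather than forced to methionine.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = Seq(seq.upper())
    rev = fwd.reverse_complement()
    frames = []
    for strand_seq in (fwd, rev):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate(table=11)))
    return SixFrameTranslation(source_id=source_id, frames=tuple(frames))


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    domain_id: str
    e_value: float
    frame: int | None = None  # 1..6, None if not frame-resolved


def filter_hits(hits: list[DomainHit], e_threshold: float = 1e-10) -> list[DomainHit]:
    """Keep hits with e-value strictly below the threshold; collapse the
    same (query, domain) found in several frames to one record."""
    kept: dict[tuple[str, str], DomainHit] = {}
    for h in hits:
        if h.e_value <= 0:
            raise ValueError(f"non-positive e-value for {h.query_id}/{h.domain_id}")
        if h.e_value >= e_threshold:
            continue
        key = (h.query_id, h.domain_id)
        if key not in kept or h.e_value < kept[key].e_value:
            kept[key] = h
    return list(kept.values())


class GoDag:
    """A GO is_a DAG restricted to (id, name, namespace, is_a) semantics."""

    def __init__(self, graph: nx.DiGraph):
        # edges run child -> parent
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("GO graph contains a cycle")
        self.graph = graph

    @classmethod
    def from_obo(cls, path: str) -> "GoDag":
        import obonet

        g = obonet.read_obo(path)  # edges child -> parent, keyed by relation
        out = nx.DiGraph()
        for node, data in g.nodes(data=True):
            ns = NAMESPACE_ALIASES.get(data.get("namespace", ""), data.get("namespace", ""))
            out.add_node(node, name=data.get("name", node), namespace=ns)
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                out.add_edge(child, parent)
        return cls(out)

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        names: dict[str, str] | None = None,
        namespace: str = "BP",
    ) -> "GoDag":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        for n in g.nodes:
            g.nodes[n]["name"] = (names or {}).get(n, n)
            g.nodes[n]["namespace"] = namespace
        return cls(g)

    @classmethod
    def from_edge_tsv(cls, path: str) -> "GoDag":
        """3-column TSV: child_id <tab> parent_id <tab> namespace."""
        g = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                child, parent = fields[0], fields[1]
                ns = fields[2] if len(fields) > 2 else "BP"
                g.add_edge(child, parent)
                g.nodes[child].setdefault("namespace", ns)
                g.nodes[parent].setdefault("namespace", ns)
        for n in g.nodes:
            g.nodes[n].setdefault("name", n)
            g.nodes[n].setdefault("namespace", "BP")
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a (the term itself excluded)."""
        return nx.descendants(self.graph, term)  # edges child -> parent

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.graph.nodes)
        return [n for n in self.graph.nodes if self.namespace(n) == namespace]


def read_domain2go(path: str) -> dict[str, set[str]]:
    """Parse a pfam2go-style mapping.

    Accepts both the GO-consortium line format
    ``Pfam:PF00001 7tm_1 > GO:... ; GO:0004930`` and a plain 2-column TSV
    ``PF00001<tab>GO:0004930``.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            if ">" in line and ";" in line:
                left, right = line.split(">", 1)
                domain = left.split()[0].split(":")[-1]
                go_id = right.rsplit(";", 1)[1].strip()
            else:
                fields = line.split("\t")
                if len(fields) < 2:
                    continue
                domain, go_id = fields[0].split(":")[-1], fields[1].strip()
            mapping.setdefault(domain, set()).add(go_id)
    return mapping


def annotate_go(
    hits: list[DomainHit],
    domain2go: dict[str, set[str]],
    dag: GoDag,
    namespace: str = "BP",
) -> dict[str, set[str]]:
    """Per-gene GO annotation with true-path propagation.

    Direct terms from the gene's domains are unioned, restricted to the
    requested namespace, and closed over is_a ancestors. Terms absent from
    the DAG are skipped with a warning.
    """
    annot: dict[str, set[str]] = {}
    warned: set[str] = set()
    for h in hits:
        terms = domain2go.get(h.domain_id, ())
        for t in terms:
            if t not in dag:
                if t not in warned:
                    warnings.warn(f"GO id {t} not in DAG; skipped", stacklevel=2)
                    warned.add(t)
                continue
            if dag.namespace(t) != namespace:
                continue
            s = annot.setdefault(h.query_id, set())
            s.add(t)
            s |= {a for a in dag.ancestors(t) if dag.namespace(a) == namespace}
    return annot


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    annotated_universe: int
    annotated_interest: int
    universe_size: int
    interest_size: int
    expected: float
    p_value: float
    algorithm: str  # "classic" | "elim"


def _fisher_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K annotated, n drawn).

    Clamped away from exact zero: the true tail is always positive, but
    extreme tables underflow double precision.
    """
    p = float(hypergeom.sf(k - 1, N, K, n))
    return max(p, np.finfo(float).tiny)


def go_enrichment(
    universe: dict[str, set[str]],
    interest: set[str],
    dag: GoDag,
    algorithm: str = "classic",
    elim_alpha: float = 0.01,
    namespace: str = "BP",
) -> list[EnrichmentResult]:
    """Test each GO term for overrepresentation in the interest set.

    ``universe`` maps every gene (CDS + pseudogene) to its propagated GO
    terms; genes without annotation may be present with an empty set and
    do not enter any term's table but do count toward the universe size.
    ``interest`` (the pseudogenes) must be a subset of the universe.

    classic: independent one-sided Fisher test per term.
    elim: terms are processed children-before-parents; when a term is
    significant at ``elim_alpha``, its annotated genes are removed from
    the annotation of all its ancestors before those are tested.
    """
    if not interest:
        raise ValueError("empty interest set")
    stray = interest - universe.keys()
    if stray:
        raise ValueError(f"interest genes outside universe: {sorted(stray)[:5]}")
    if algorithm not in ("classic", "elim"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    term_genes: dict[str, set[str]] = {}
    for gene, terms in universe.items():
        for t in terms:
            if t in dag and dag.namespace(t) == namespace:
                term_genes.setdefault(t, set()).add(gene)

    N = len(universe)
    n = len(interest)
    results: list[EnrichmentResult] = []

    if algorithm == "classic":
        test_sets = term_genes
    else:
        # children before parents: topological order of the child->parent DAG
        sub = dag.graph.subgraph([t for t in term_genes if t in dag]).copy()
        order = [t for t in nx.topological_sort(sub)] + [
            t for t in term_genes if t not in sub
        ]
        eliminated: dict[str, set[str]] = {t: set() for t in term_genes}
        test_sets = {}
        for t in order:
            genes = term_genes[t] - eliminated.get(t, set())
            test_sets[t] = genes
            K = len(genes)
            k = len(genes & interest)
            if K and _fisher_tail(k, K, n, N) < elim_alpha:
                for anc in dag.ancestors(t):
                    if anc in eliminated:
                        eliminated[anc] |= term_genes[t]

    for t, genes in test_sets.items():
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & interest)
        results.append(
            EnrichmentResult(
                term_id=t,
                name=dag.name(t),
                annotated_universe=K,
                annotated_interest=k,
                universe_size=N,
                interest_size=n,
                expected=K * n / N,
                p_value=_fisher_tail(k, K, n, N),
                algorithm=algorithm,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj.tolist()


def results_table(
    classic: list[EnrichmentResult],
    elim: list[EnrichmentResult] | None = None,
) -> pd.DataFrame:
    """Ranked enrichment table with classic p, optional elim p, and BH FDR."""
    df = pd.DataFrame(
        {
            "term": [r.term_id for r in classic],
            "name": [r.name for r in classic],
            "annotated": [r.annotated_universe for r in classic],
            "significant": [r.annotated_interest for r in classic],
            "expected": [r.expected for r in classic],
            "p_classic": [r.p_value for r in classic],
        }
    )
    if elim is not None:
        p_elim = {r.term_id: r.p_value for r in elim}
        df["p_elim"] = [p_elim.get(t, np.nan) for t in df["term"]]
    df["bh_fdr"] = bh_fdr(df["p_classic"].tolist())
    sort_col = "p_elim" if elim is not None else "p_classic"
    return df.sort_values(sort_col, kind="stable").reset_index(drop=True)
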