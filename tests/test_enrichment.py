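"""Six-frame translation, hit filtering, GO annotation and Fisher/elim tests."""

import numpy as np
import pytest

from helvepan import synth
from helvepan.enrichment import (
    DomainHit,
    GoDag,
    annotate_go,
    bh_fdr,
    filter_hits,
    go_enrichment,
    read_domain2go,
    six_frame_translate,
)
from helvepan.repeats import revcomp

import oracles


class TestSixFrame:
    def test_forward_frames_of_toy_gene(self):
        t = six_frame_translate("ATGAAATAA")
        assert t.frames[0] == "MK*"
        assert t.frames[3] == "LFH"  # revcomp TTATTTCAT, offset 0

    def test_frame_lengths(self):
        t = six_frame_translate("ATGAAACCCGG")  # 11 bp
        assert [len(f) for f in t.frames] == [3, 3, 3, 3, 3, 3]

    def test_revcomp_identity(self):
        seq = "ATGGCTAAAGGGTTTCCC"
        assert (
            six_frame_translate(revcomp(seq)).frames[0]
            == six_frame_translate(seq).frames[3]
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")

    def test_frameshifted_pseudogene_domain_visible_in_shifted_frame(self):
        # frame 1 of the intact gene reappears in frame 2/3 downstream of a
        # 1 bp deletion - the reason pseudogenes are six-frame translated
        rng = np.random.default_rng(0)
        gene = synth._random_gene(rng, 300)
        broken = gene[:90] + gene[91:]
        intact_tail = six_frame_translate(gene).frames[0][40:90]
        frames = six_frame_translate(broken).frames
        assert any(intact_tail in f for f in frames[1:3])


class TestFilterHits:
    def test_strict_threshold(self):
        hits = [
            DomainHit("q", "d1", 1e-10),
            DomainHit("q", "d2", 9.9e-11),
            DomainHit("q", "d3", 1e-3),
        ]
        kept = filter_hits(hits)
        assert [(h.domain_id) for h in kept] == ["d2"]

    def test_multi_frame_duplicates_collapse(self):
        hits = [
            DomainHit("q", "d1", 1e-12, frame=2),
            DomainHit("q", "d1", 1e-14, frame=5),
        ]
        kept = filter_hits(hits)
        assert len(kept) == 1
        assert kept[0].e_value == 1e-14

    def test_non_positive_e_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([DomainHit("q", "d", 0.0)])


class TestGoDag:
    def _dag(self):
        return GoDag.from_edges(
            [("GO:c1", "GO:p"), ("GO:c2", "GO:p"), ("GO:p", "GO:root")]
        )

    def test_ancestors(self):
        dag = self._dag()
        assert dag.ancestors("GO:c1") == {"GO:p", "GO:root"}

    def test_cycle_rejected(self):
        import networkx as nx

        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            GoDag(g)

    def test_obo_parsing(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: child term\nnamespace: biological_process\n"
            "is_a: GO:0008150 ! biological_process\n\n"
            "[Term]\nid: GO:0008150\nname: biological_process\n"
            "namespace: biological_process\n"
        )
        dag = GoDag.from_obo(str(obo))
        assert "GO:0000001" in dag
        assert dag.namespace("GO:0000001") == "BP"
        assert dag.ancestors("GO:0000001") == {"GO:0008150"}

    def test_edge_tsv(self, tmp_path):
        p = tmp_path / "dag.tsv"
        p.write_text("GO:a\tGO:b\tBP\nGO:b\tGO:r\tBP\n")
        dag = GoDag.from_edge_tsv(str(p))
        assert dag.ancestors("GO:a") == {"GO:b", "GO:r"}

    def test_pfam2go_both_dialects(self, tmp_path):
        p = tmp_path / "pfam2go.txt"
        p.write_text(
            "!version date: 2017/01/01\n"
            "Pfam:PF00001 7tm_1 > GO:G-protein coupled receptor activity ; GO:0004930\n"
            "PF00002\tGO:0007186\n"
        )
        m = read_domain2go(str(p))
        assert m == {"PF00001": {"GO:0004930"}, "PF00002": {"GO:0007186"}}


class TestAnnotate:
    def test_true_path_propagation(self):
        dag = GoDag.from_edges([("GO:t", "GO:p"), ("GO:p", "GO:r")])
        annot = annotate_go([DomainHit("g1", "D", 1e-12)], {"D": {"GO:t"}}, dag)
        assert annot["g1"] == {"GO:t", "GO:p", "GO:r"}

    def test_unknown_term_warns_and_skips(self):
        dag = GoDag.from_edges([("GO:t", "GO:r")])
        with pytest.warns(UserWarning, match="GO:xx"):
            annot = annotate_go([DomainHit("g1", "D", 1e-12)], {"D": {"GO:xx"}}, dag)
        assert annot == {}

    def test_two_domains_same_term_set_semantics(self):
        dag = GoDag.from_edges([("GO:t", "GO:r")])
        hits = [DomainHit("g1", "D1", 1e-12), DomainHit("g1", "D2", 1e-12)]
        annot = annotate_go(hits, {"D1": {"GO:t"}, "D2": {"GO:t"}}, dag)
        assert annot["g1"] == {"GO:t", "GO:r"}


class TestEnrichment:
    def _flat_dag(self, terms):
        return GoDag.from_edges([(t, "GO:root") for t in terms])

    def test_classic_p_matches_exact_hypergeometric(self):
        # universe 100 (interest 20); term annotates 10, 8 of them interest
        dag = self._flat_dag(["GO:T"])
        universe = {}
        for i in range(100):
            g = f"g{i}"
            universe[g] = set()
        interest = {f"g{i}" for i in range(20)}
        annotated = [f"g{i}" for i in range(8)] + [f"g{i}" for i in range(20, 22)]
        for g in annotated:
            universe[g] = {"GO:T", "GO:root"}
        res = go_enrichment(universe, interest, dag)
        r = next(x for x in res if x.term_id == "GO:T")
        exact = float(oracles.hypergeom_tail_exact(8, 10, 20, 100))
        assert r.p_value == pytest.approx(exact, rel=1e-12)

    def test_term_annotating_everything_gives_p_one(self):
        dag = self._flat_dag(["GO:T"])
        universe = {f"g{i}": {"GO:T", "GO:root"} for i in range(30)}
        res = go_enrichment(universe, {"g0", "g1"}, dag)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_interest_equal_universe_gives_p_one(self):
        dag = self._flat_dag(["GO:T"])
        universe = {f"g{i}": ({"GO:T", "GO:root"} if i < 5 else set()) for i in range(10)}
        res = go_enrichment(universe, set(universe), dag)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_empty_interest_rejected(self):
        dag = self._flat_dag(["GO:T"])
        with pytest.raises(ValueError):
            go_enrichment({"g": {"GO:T"}}, set(), dag)

    def test_interest_outside_universe_rejected(self):
        dag = self._flat_dag(["GO:T"])
        with pytest.raises(ValueError):
            go_enrichment({"g": {"GO:T"}}, {"zz"}, dag)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dag = self._flat_dag(["GO:T"])
        N = int(rng.integers(20, 300))
        n = int(rng.integers(2, N // 2))
        K = int(rng.integers(1, N))
        genes = [f"g{i}" for i in range(N)]
        annotated = set(rng.choice(genes, K, replace=False))
        interest = set(rng.choice(genes, n, replace=False))
        universe = {g: ({"GO:T", "GO:root"} if g in annotated else set()) for g in genes}
        res = go_enrichment(universe, interest, dag)
        r = next(x for x in res if x.term_id == "GO:T")
        k = len(annotated & interest)
        exact = float(oracles.hypergeom_tail_exact(k, K, n, N))
        assert r.p_value == pytest.approx(exact, rel=1e-12)

    def test_propagation_monotonicity(self):
        plant = synth.make_enrichment_inputs(synth.EnrichmentPlantSpec(seed=3))
        dag = GoDag.from_edges(plant.dag_edges)
        hits = [DomainHit(q, d, e) for q, d, e in plant.hits]
        annot = annotate_go(filter_hits(hits), plant.domain2go, dag)
        universe = {g: annot.get(g, set()) for g in plant.universe}
        res = go_enrichment(universe, set(plant.interest), dag)
        counts = {r.term_id: r.annotated_universe for r in res}
        for term in counts:
            for child in dag.children(term):
                if child in counts:
                    assert counts[term] >= counts[child]

    def test_elim_reports_no_more_significant_than_classic(self):
        plant = synth.make_enrichment_inputs(synth.EnrichmentPlantSpec(seed=4))
        dag = GoDag.from_edges(plant.dag_edges)
        hits = [DomainHit(q, d, e) for q, d, e in plant.hits]
        annot = annotate_go(filter_hits(hits), plant.domain2go, dag)
        universe = {g: annot.get(g, set()) for g in plant.universe}
        interest = set(plant.interest)
        for alpha in (0.01, 0.05):
            n_classic = sum(
                r.p_value < alpha for r in go_enrichment(universe, interest, dag)
            )
            n_elim = sum(
                r.p_value < alpha
                for r in go_enrichment(universe, interest, dag, algorithm="elim")
            )
            assert n_elim <= n_classic

    def test_planted_term_ranks_first(self):
        plant = synth.make_enrichment_inputs(synth.EnrichmentPlantSpec(seed=6))
        dag = GoDag.from_edges(plant.dag_edges)
        hits = [DomainHit(q, d, e) for q, d, e in plant.hits]
        annot = annotate_go(filter_hits(hits), plant.domain2go, dag)
        universe = {g: annot.get(g, set()) for g in plant.universe}
        res = go_enrichment(universe, set(plant.interest), dag)
        top3 = [r.term_id for r in res[:3]]
        assert plant.planted_term in top3


def test_bh_fdr_monotone_and_bounded():
    p = [0.001, 0.02, 0.03, 0.5, 0.9]
    adj = bh_fdr(p)
    assert all(a >= b for a, b in zip(adj, p))
    assert all(0 < a <= 1 for a in adj)
    order = np.argsort(p)
    assert all(adj[order[i]] <= adj[order[i + 1]] for i in range(len(p) - 1))
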