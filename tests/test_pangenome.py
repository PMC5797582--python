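"""Clustering, partitioning, accumulation curves, and COG cross-tabulation."""

import numpy as np
import pandas as pd
import pytest

from helvepan import synth
from helvepan.pangenome import (
    PresenceAbsenceMatrix,
    accumulation_curves,
    assign_cog,
    cluster_proteins,
    cog_crosstab,
    global_identity,
    partition,
    presence_absence,
    read_roary_csv,
    write_presence_absence_csv,
)

import oracles


def _matrix(rows, genomes):
    return PresenceAbsenceMatrix(
        np.array(rows, dtype=bool),
        [f"c{i}" for i in range(len(rows))],
        genomes,
    )


class TestClusterProteins:
    def test_identical_protein_across_genomes_forms_one_cluster(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        genomes = {g: [(f"{g}_1", prot)] for g in ("A", "B", "C")}
        clusters = cluster_proteins(genomes)
        assert len(clusters) == 1
        assert clusters[0].presence == {"A", "B", "C"}

    def test_ninety_percent_identity_splits_at_95_threshold(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(list(aa), 200))
        mutated = list(base)
        for i in rng.choice(200, 20, replace=False):  # 10% divergence
            mutated[i] = aa[(aa.index(mutated[i]) + 1) % 20]
        genomes = {"A": [("a1", base)], "B": [("b1", "".join(mutated))]}
        assert len(cluster_proteins(genomes)) == 2
        assert len(cluster_proteins(genomes, min_identity=0.85)) == 1

    def test_paralogs_not_split(self):
        prot = "MSTNPKPQRKTKRNTNRRPQDVKFPGG" * 4
        genomes = {
            "A": [("a1", prot), ("a2", prot)],
            "B": [("b1", prot)],
            "C": [("c1", prot)],
        }
        clusters = cluster_proteins(genomes)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4
        assert clusters[0].presence == {"A", "B", "C"}

    def test_short_fragment_fails_coverage(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 4
        genomes = {"A": [("a1", prot)], "B": [("b1", prot[: len(prot) // 2])]}
        assert len(cluster_proteins(genomes)) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_proteins({})

    def test_deterministic_under_genome_permutation(self, small_strain_family):
        prots = small_strain_family.proteins()
        c1 = cluster_proteins(prots)
        c2 = cluster_proteins(dict(reversed(list(prots.items()))))
        key = lambda cs: sorted(tuple(sorted(c.members)) for c in cs)
        assert key(c1) == key(c2)

    def test_synthetic_family_recovery(self, small_strain_family):
        fam = small_strain_family
        clusters = cluster_proteins(fam.proteins())
        part = partition(presence_absence(clusters))
        assert (len(part.core), len(part.accessory), part.n_unique) == fam.truth_partition()
        # membership, not just counts: clusters equal the designed families
        got = {tuple(sorted(g for _, g in c.members)) for c in clusters}
        want = {}
        for gid, cid in fam.cluster_of.items():
            want.setdefault(cid, []).append(gid)
        assert got == {tuple(sorted(v)) for v in want.values()}


class TestPartition:
    def test_three_genome_example(self):
        mat = _matrix(
            [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 1]],
            ["g1", "g2", "g3"],
        )
        part = partition(mat)
        assert len(part.core) == 1 and len(part.accessory) == 1 and part.n_unique == 2
        assert part.unique["g1"] == ["c2"] and part.unique["g3"] == ["c3"]

    def test_all_core(self):
        part = partition(_matrix([[1, 1], [1, 1]], ["a", "b"]))
        assert len(part.accessory) == 0 and part.n_unique == 0
        assert part.pan_size == len(part.core) == 2

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            partition(_matrix([[1, 1], [0, 0]], ["a", "b"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        rows = rng.random((int(rng.integers(5, 60)), n)) < rng.uniform(0.2, 0.9)
        rows = rows[rows.sum(axis=1) > 0]
        if not len(rows):
            return
        mat = _matrix(rows, [f"g{i}" for i in range(n)])
        part = partition(mat)
        assert len(part.core) + len(part.accessory) + part.n_unique == len(rows)


class TestAccumulation:
    def test_identical_genomes_flat_curves(self):
        mat = _matrix([[1, 1, 1]] * 7, ["a", "b", "c"])
        curve = accumulation_curves(mat, n_iterations=5, seed=0)
        assert np.all(curve.mean_pan == 7) and np.all(curve.mean_core == 7)

    def test_two_genome_endpoint_exact(self):
        # 3 shared, 2 unique to A, 1 unique to B
        rows = [[1, 1]] * 3 + [[1, 0]] * 2 + [[0, 1]]
        curve = accumulation_curves(_matrix(rows, ["A", "B"]), n_iterations=4, seed=1)
        assert curve.mean_pan[-1] == 6 and curve.mean_core[-1] == 3

    def test_monotonicity_and_start_equality(self):
        rng = np.random.default_rng(3)
        rows = (rng.random((40, 6)) < 0.6)
        rows = rows[rows.sum(axis=1) > 0]
        curve = accumulation_curves(_matrix(rows, [f"g{i}" for i in range(6)]), 20, seed=2)
        assert np.all(np.diff(curve.mean_pan) >= 0)
        assert np.all(np.diff(curve.mean_core) <= 0)
        assert curve.mean_pan[0] == curve.mean_core[0]

    def test_reproducible_given_seed(self):
        rows = (np.random.default_rng(4).random((30, 5)) < 0.5)
        rows = rows[rows.sum(axis=1) > 0]
        mat = _matrix(rows, [f"g{i}" for i in range(5)])
        c1 = accumulation_curves(mat, 10, seed=7)
        c2 = accumulation_curves(mat, 10, seed=7)
        assert np.array_equal(c1.mean_pan, c2.mean_pan)

    def test_monte_carlo_matches_exhaustive_orderings(self):
        # 3-genome toy: 2 core, 1 accessory in {g1,g2}, 1 unique each
        rows = [[1, 1, 1]] * 2 + [[1, 1, 0]] + [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        mat = _matrix(rows, ["g1", "g2", "g3"])
        exact_pan, exact_core, pans, cores = oracles.exhaustive_accumulation_means(
            mat.matrix
        )
        curve = accumulation_curves(mat, n_iterations=1000, seed=5, keep_iterations=True)
        for k in range(3):
            se = pans[:, k].std(ddof=1) / np.sqrt(1000)
            assert abs(curve.mean_pan[k] - exact_pan[k]) <= 3 * se + 1e-9
            se_c = cores[:, k].std(ddof=1) / np.sqrt(1000)
            assert abs(curve.mean_core[k] - exact_core[k]) <= 3 * se_c + 1e-9


class TestCog:
    def test_smallest_e_value_wins(self):
        rows = [("g1", "s1", 1e-5, "L"), ("g1", "s2", 1e-9, "K")]
        assert assign_cog(rows)["g1"] == "K"

    def test_above_cutoff_means_none(self):
        assert assign_cog([("g1", "s1", 0.01, "J")])["g1"] == "none"

    def test_tie_breaks_to_first_row(self):
        rows = [("g1", "s1", 1e-8, "M"), ("g1", "s2", 1e-8, "V")]
        assert assign_cog(rows)["g1"] == "M"

    def test_malformed_row_reports_line(self):
        with pytest.raises(ValueError, match="row 2"):
            assign_cog([("g1", "s1", 1e-8, "M"), ("g2", "s1")])

    def test_crosstab_letters_and_none(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        genomes = {g: [(f"{g}_1", prot)] for g in ("A", "B")}
        clusters = cluster_proteins(genomes)
        part = partition(presence_absence(clusters))
        rep = clusters[0].representative
        tab = cog_crosstab(part, clusters, {rep: "KL"})
        assert tab.loc["K", "core"] == 1 and tab.loc["L", "core"] == 1
        assert tab.loc["K", "core_pct"] == 100.0
        tab_none = cog_crosstab(part, clusters, {})
        assert tab_none.loc["none", "core"] == 1


class TestRoaryIO:
    def test_roundtrip_slim_csv(self, tmp_path):
        rows = [[1, 0, 1], [1, 1, 1], [0, 1, 0]]
        mat = _matrix(rows, ["gA", "gB", "gC"])
        path = tmp_path / "pa.csv"
        write_presence_absence_csv(mat, str(path))
        back = read_roary_csv(str(path))
        assert back.genome_ids == mat.genome_ids
        assert np.array_equal(back.matrix, mat.matrix)

    def test_roary_full_layout(self, tmp_path):
        header = (
            '"Gene","Non-unique Gene name","Annotation","No. isolates","No. sequences",'
            '"Avg sequences per isolate","Genome Fragment","Order within Fragment",'
            '"Accessory Fragment","Accessory Order with Fragment","QC",'
            '"Min group size nuc","Max group size nuc","Avg group size nuc",'
            '"strain1","strain2"'
        )
        lines = [header, '"clu1","","hyp","2","2","1","","","","","","","","","g1","g2"',
                 '"clu2","","hyp","1","1","1","","","","","","","","","g3",""']
        path = tmp_path / "gene_presence_absence.csv"
        path.write_text("\n".join(lines) + "\n")
        mat = read_roary_csv(str(path))
        assert mat.genome_ids == ["strain1", "strain2"]
        part = partition(mat)
        assert len(part.core) == 1 and part.n_unique == 1


def test_global_identity_edge_cases():
    assert global_identity("PEPTIDE", "PEPTIDE") == 1.0
    assert global_identity("PEPTIDE", "") == 0.0
    assert global_identity("AAAA", "AAAT") == pytest.approx(0.75)
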