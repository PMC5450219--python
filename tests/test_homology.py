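import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bhlh_survey.homology import (
    call_orthologs, chromosome_distribution, cluster_redundant,
    ortholog_summary, read_locations, smith_waterman,
)
from bhlh_survey.io_formats import ProteinRecord, ValidationError

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def rec(pid, seq, species=""):
    return ProteinRecord(id=pid, sequence=seq, species=species)


def brute_force_local(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Exhaustive local alignment score by recursion over edit operations.

    First gap residue costs gap_open, each additional gap_extend (the
    convention of the implementation under test).
    """
    best_seen = 0.0

    def extend(i, j, score, state):
        nonlocal best_seen
        best_seen = max(best_seen, score)
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + BLOSUM62[a[i]][b[j]], "M")
        if i < len(a):
            cost = gap_extend if state == "I" else gap_open
            extend(i + 1, j, score - cost, "I")
        if j < len(b):
            cost = gap_extend if state == "J" else gap_open
            extend(i, j + 1, score - cost, "J")

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i, j, 0.0, "M")
    return best_seen


class TestSmithWaterman:
    def test_identical_sequences_full_identity(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVH"[:70]
        result = smith_waterman(rec("a", seq), rec("b", seq))
        assert result.aligned_length == 70
        assert result.identities == 70
        assert result.percent_identity == pytest.approx(100.0)

    def test_disjoint_alphabets_empty_alignment(self):
        result = smith_waterman(rec("a", "AAAAAAAA"), rec("b", "WWWWWWWW"))
        assert result.aligned_length == 0
        assert result.percent_identity == 0.0
        assert result.score <= 0

    def test_score_symmetric(self):
        a, b = "MKRWLL" * 5, "MKKWIL" * 5
        assert smith_waterman(rec("a", a), rec("b", b)).score == \
               pytest.approx(smith_waterman(rec("b", b), rec("a", a)).score)

    def test_score_equals_brute_force_on_tiny_sequences(self):
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(6):
            a = "".join(aas[c] for c in rng.integers(0, 20, int(rng.integers(4, 9))))
            b = "".join(aas[c] for c in rng.integers(0, 20, int(rng.integers(4, 9))))
            got = smith_waterman(rec("a", a), rec("b", b)).score
            expected = brute_force_local(a, b)
            assert got == pytest.approx(max(expected, 0.0), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            ProteinRecord(id="a", sequence="")


DOMAIN = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"


class TestCallOrthologs:
    def test_identical_70aa_match_retained(self):
        wheat = [rec("w1", DOMAIN[:70])]
        refs = [rec("at1", DOMAIN[:70], species="arabidopsis")]
        table = call_orthologs(wheat, refs)
        assert len(table) == 1
        assert table.iloc[0]["partner_id"] == "at1"

    def test_60aa_exact_match_rejected_61_accepted(self):
        refs60 = [rec("at1", DOMAIN[:60], species="arabidopsis")]
        refs61 = [rec("at1", DOMAIN[:61], species="arabidopsis")]
        assert len(call_orthologs([rec("w", DOMAIN[:60])], refs60)) == 0
        assert len(call_orthologs([rec("w", DOMAIN[:61])], refs61)) == 1

    def test_identity_filter_is_exclusive_at_80(self):
        # 20 internal mismatches over 100 columns -> exactly 80.0% -> rejected
        base = (DOMAIN * 2)[:100]
        aas = "ACDEFGHIKLMNPQRSTVWY"
        variant = list(base)
        for pos in range(2, 98, 5):   # 20 positions, ends untouched
            variant[pos] = aas[(aas.index(variant[pos]) + 7) % 20]
        table = call_orthologs([rec("w", base)],
                               [rec("at", "".join(variant), species="arabidopsis")])
        assert len(table) == 0

    def test_monotone_in_identity_threshold(self):
        wheat = [rec("w1", DOMAIN), rec("w2", DOMAIN[:40] + "W" * 38)]
        refs = [rec("at1", DOMAIN, species="arabidopsis")]
        loose = call_orthologs(wheat, refs, min_identity=50.0)
        strict = call_orthologs(wheat, refs, min_identity=90.0)
        assert set(strict["wheat_id"]) <= set(loose["wheat_id"])

    def test_planted_ortholog_sets_recovered(self):
        rng = np.random.default_rng(4)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rand = lambda n: "".join(aas[c] for c in rng.integers(0, 20, n))
        shared = [rand(80) for _ in range(3)]
        wheat = (
            [rec(f"wA{i}", s) for i, s in enumerate(shared[:1])]     # A only
            + [rec(f"wR{i}", s) for i, s in enumerate(shared[1:2])]  # rice only
            + [rec(f"wB{i}", s) for i, s in enumerate(shared[2:])]   # both
            + [rec("wNone", rand(80))]
        )
        refs = (
            [rec("atA", shared[0], species="arabidopsis"),
             rec("atB", shared[2], species="arabidopsis"),
             rec("atX", rand(80), species="arabidopsis"),
             rec("osR", shared[1], species="rice"),
             rec("osB", shared[2], species="rice"),
             rec("osX", rand(80), species="rice")]
        )
        summary = ortholog_summary(call_orthologs(wheat, refs))
        assert summary == {"arabidopsis_only": 1, "rice_only": 1,
                           "both": 1, "total": 3}


class TestClusterRedundant:
    def test_identical_pair_collapses(self):
        reps, members = cluster_redundant([rec("a", DOMAIN), rec("b", DOMAIN)])
        assert len(reps) == 1
        assert members == {"a": "a", "b": "a"}

    def test_all_dissimilar_stay_separate(self):
        rng = np.random.default_rng(9)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        records = [rec(f"r{i}", "".join(aas[c] for c in rng.integers(0, 20, 60)))
                   for i in range(5)]
        reps, _ = cluster_redundant(records)
        assert len(reps) == 5

    def test_longest_sequence_is_representative(self):
        longer = rec("short_id_z", DOMAIN + "AAAA")
        shorter = rec("a_first", DOMAIN)
        reps, members = cluster_redundant([shorter, longer])
        assert [r.id for r in reps] == ["short_id_z"]
        assert members["a_first"] == "short_id_z"

    def test_cluster_count_matches_union_find_oracle(self):
        # families built so that within-family identity ~1 and between ~ random
        rng = np.random.default_rng(10)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        records, edges = [], []
        idx = 0
        for fam in range(4):
            base = "".join(aas[c] for c in rng.integers(0, 20, 80))
            size = int(rng.integers(1, 5))
            fam_ids = []
            for k in range(size):
                seq = list(base)
                if k:  # one substitution: identity 79/80 > 0.95
                    pos = int(rng.integers(80))
                    seq[pos] = aas[(aas.index(seq[pos]) + 1) % 20]
                records.append(rec(f"m{idx}", "".join(seq)))
                fam_ids.append(f"m{idx}")
                idx += 1
            edges.extend(itertools.combinations(fam_ids, 2))
        # union-find on the planted identity structure
        parent = {r.id: r.id for r in records}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        expected = len({find(r.id) for r in records})
        reps, _ = cluster_redundant(records)
        assert len(reps) == expected

    def test_deterministic_given_input_order_rule(self):
        records = [rec("b", DOMAIN), rec("a", DOMAIN), rec("c", DOMAIN[:50])]
        reps1, m1 = cluster_redundant(records)
        reps2, m2 = cluster_redundant(list(reversed(records)))
        assert [r.id for r in reps1] == [r.id for r in reps2]
        assert m1 == m2


class TestChromosomeDistribution:
    def _locations(self, tmp_path):
        path = tmp_path / "loc.tsv"
        path.write_text(
            "gene\tchromosome\tstart\tend\n"
            "g1\t3B\t100\t200\n"
            "g2\t3B\t300\t500\n"
            "g3\t3B\t700\t900\n"
            "g4\t1A\t10\t20\n"
            "g5\tscaffold123\t5\t50\n"
        )
        return read_locations(path)

    def test_empty_gene_list_all_zero(self, tmp_path):
        counts, unmapped = chromosome_distribution(self._locations(tmp_path), [])
        assert sum(counts.values()) == 0 and unmapped == []

    def test_argmax_chromosome(self, tmp_path):
        counts, _ = chromosome_distribution(
            self._locations(tmp_path), ["g1", "g2", "g3", "g4"])
        assert max(counts, key=counts.get) == "3B"
        assert counts["1A"] == 1

    def test_counts_plus_unmapped_conserve_input(self, tmp_path):
        genes = ["g1", "g2", "g5", "missing1", "missing2"]
        counts, unmapped = chromosome_distribution(self._locations(tmp_path), genes)
        assert sum(counts.values()) + len(unmapped) == len(genes)
        assert counts["scaffold"] == 1
        assert set(unmapped) == {"missing1", "missing2"}

    def test_bad_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tchromosome\tstart\tend\ng1\t1A\t20\t10\n")
        with pytest.raises(ValidationError):
            read_locations(path)
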