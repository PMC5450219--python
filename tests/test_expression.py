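import numpy as np
import pandas as pd
import pytest

from bhlh_survey.expression import (
    cluster_subgroups, detect_blocks, normalize, qpcr_agreement,
)
from bhlh_survey.io_formats import ExpressionMatrix, ValidationError
from bhlh_survey.synthetic_data import ExpressionSpec, generate_expression


def small_matrix():
    frame = pd.DataFrame(
        [[4.0, 8.0, 2.0],
         [1.0, 2.0, 3.0],
         [2.0, 2.0, 2.0],   # reference
         [2.0, 6.0, 2.0]],  # reference
        index=["gA", "gB", "ref1", "ref2"],
        columns=["s1", "s2", "s3"],
    )
    tissue = {"s1": "root", "s2": "leaf", "s3": "root"}
    return ExpressionMatrix(values=frame, sample_tissue=tissue)


class TestNormalize:
    def test_stage_one_reference_division(self):
        nm = normalize(small_matrix(), ["ref1", "ref2"])
        # sample s1 reference mean = 2.0, gene gA FPKM 4.0 -> intermediate 2.0
        assert nm.intermediate.loc["gA", "s1"] == pytest.approx(2.0)
        assert nm.intermediate.loc["gA", "s2"] == pytest.approx(2.0)
        assert "ref1" not in nm.values.index

    def test_rows_standardized_mean_zero_sd_one(self, expression_data):
        _, matrix, ref_ids, _, _ = expression_data
        nm = normalize(matrix, ref_ids)
        means = nm.values.mean(axis=1)
        sds = nm.values.std(axis=1, ddof=1)
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_constant_row_flagged_and_zeroed(self):
        m = small_matrix()
        m.values.loc["gA"] = [3.0, 6.0, 3.0]  # equal to 1.5x reference mean
        nm = normalize(m, ["ref1", "ref2"])
        assert nm.constant_genes == ["gA"]
        assert (nm.values.loc["gA"] == 0.0).all()

    def test_destandardization_round_trip(self, expression_data):
        _, matrix, ref_ids, _, _ = expression_data
        nm = normalize(matrix, ref_ids)
        means = nm.intermediate.mean(axis=1)
        sds = nm.intermediate.std(axis=1, ddof=1)
        restored = nm.values.mul(sds, axis=0).add(means, axis=0)
        assert np.allclose(restored, nm.intermediate, atol=1e-9)

    def test_sample_scale_equivariance(self):
        m = small_matrix()
        nm = normalize(m, ["ref1", "ref2"])
        scaled = m.values.copy()
        scaled["s2"] *= 37.0
        nm_scaled = normalize(
            ExpressionMatrix(values=scaled, sample_tissue=m.sample_tissue),
            ["ref1", "ref2"])
        assert np.allclose(nm.values, nm_scaled.values, atol=1e-12)

    def test_zero_reference_mean_names_sample(self):
        m = small_matrix()
        m.values.loc["ref1", "s3"] = 0.0
        m.values.loc["ref2", "s3"] = 0.0
        with pytest.raises(ValidationError, match="s3"):
            normalize(m, ["ref1", "ref2"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            normalize(small_matrix(), ["nope"])


class TestClusterSubgroups:
    def test_two_separated_blocks_split_perfectly(self):
        spec = ExpressionSpec(n_genes=20, n_tissues=2, samples_per_tissue=3,
                              noise_sd=0.0, seed=2)
        matrix, refs, _, truth = generate_expression(spec)
        nm = normalize(matrix, refs)
        clustering = cluster_subgroups(nm, k=2)
        genes = list(nm.values.index)
        planted = [truth[g] for g in genes]
        got = [clustering.assignments[g] for g in genes]
        mapping = {}
        for p, g in zip(planted, got):
            mapping.setdefault(p, g)
        assert all(mapping[p] == g for p, g in zip(planted, got))

    def test_k_equal_genes_gives_singletons(self, expression_data):
        _, matrix, ref_ids, _, _ = expression_data
        nm = normalize(matrix, ref_ids)
        k = len(nm.values)
        clustering = cluster_subgroups(nm, k=k)
        assert len(set(clustering.assignments.values())) == k

    def test_k_above_gene_count_rejected(self, expression_data):
        _, matrix, ref_ids, _, _ = expression_data
        nm = normalize(matrix, ref_ids)
        with pytest.raises(ValidationError):
            cluster_subgroups(nm, k=len(nm.values) + 1)

    def test_gene_order_invariance(self, expression_data):
        from bhlh_survey.expression import NormalizedMatrix
        _, matrix, ref_ids, _, _ = expression_data
        nm = normalize(matrix, ref_ids)
        clustering = cluster_subgroups(nm, k=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(nm.values))
        nm_perm = NormalizedMatrix(
            values=nm.values.iloc[perm],
            intermediate=nm.intermediate.iloc[perm],
            sample_tissue=nm.sample_tissue)
        permuted = cluster_subgroups(nm_perm, k=4)
        base_partition = {}
        for g, s in clustering.assignments.items():
            base_partition.setdefault(s, set()).add(g)
        perm_partition = {}
        for g, s in permuted.assignments.items():
            perm_partition.setdefault(s, set()).add(g)
        assert set(map(frozenset, base_partition.values())) == \
               set(map(frozenset, perm_partition.values()))


class TestDetectBlocks:
    def test_planted_blocks_dominant_and_specific(self, expression_data):
        spec, matrix, ref_ids, _, truth = expression_data
        nm = normalize(matrix, ref_ids)
        clustering = cluster_subgroups(nm, k=spec.n_tissues)
        blocks = detect_blocks(clustering, nm)
        assert all(b.specific for b in blocks)
        # each block's dominant tissue matches its genes' planted tissue
        for b in blocks:
            genes = clustering.genes_in(b.subgroup)
            planted = {truth[g] for g in genes}
            assert planted == {b.dominant_tissue}

    def test_flat_subgroup_not_specific(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.lognormal(1, 0.05, size=(10, 8)),
                             index=[f"g{i}" for i in range(10)],
                             columns=[f"s{i}" for i in range(8)])
        frame.loc["ref"] = 2.0
        tissue = {f"s{i}": ("root" if i < 4 else "leaf") for i in range(8)}
        nm = normalize(ExpressionMatrix(values=frame, sample_tissue=tissue), ["ref"])
        clustering = cluster_subgroups(nm, k=1)
        blocks = detect_blocks(clustering, nm)
        assert len(blocks) == 1
        assert not blocks[0].specific

    def test_flagged_count_equals_planted_count(self):
        spec = ExpressionSpec(n_genes=70, n_tissues=7, samples_per_tissue=3,
                              noise_sd=0.3, seed=19)
        matrix, refs, _, _ = generate_expression(spec)
        nm = normalize(matrix, refs)
        clustering = cluster_subgroups(nm, k=7)
        blocks = detect_blocks(clustering, nm)
        assert sum(b.specific for b in blocks) == 7


class TestQpcrAgreement:
    def test_identical_vectors_r_one(self):
        frame = pd.DataFrame([[1.0, 5.0, 9.0, 2.0]], index=["g"],
                             columns=list("abcd"))
        tissue = dict.fromkeys("abcd", "t")
        em = ExpressionMatrix(values=frame, sample_tissue=tissue)
        out = qpcr_agreement(em, em)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_anti_proportional_vectors_r_minus_one(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        y = pd.DataFrame([[3.0, 2.0, 1.0]], index=["g"], columns=list("abc"))
        tissue = dict.fromkeys("abc", "t")
        out = qpcr_agreement(
            ExpressionMatrix(values=x, sample_tissue=tissue),
            ExpressionMatrix(values=y, sample_tissue=tissue),
            scale="raw")
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_r_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.lognormal(1, 1, size=(1, 10)), index=["g"],
                         columns=[f"s{i}" for i in range(10)])
        y = x * np.exp(rng.normal(0, 0.3, size=(1, 10)))
        tissue = {f"s{i}": "t" for i in range(10)}
        base = qpcr_agreement(
            ExpressionMatrix(values=x, sample_tissue=tissue),
            ExpressionMatrix(values=y, sample_tissue=tissue),
            scale="raw").iloc[0]["r"]
        rescaled = qpcr_agreement(
            ExpressionMatrix(values=x, sample_tissue=tissue),
            ExpressionMatrix(values=y * 7.5, sample_tissue=tissue),
            scale="raw").iloc[0]["r"]
        assert rescaled == pytest.approx(base)

    def test_too_few_shared_samples_skipped(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        y = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=list("ab"))
        tissue = dict.fromkeys("abc", "t")
        out = qpcr_agreement(
            ExpressionMatrix(values=x, sample_tissue=tissue),
            ExpressionMatrix(values=y, sample_tissue={"a": "t", "b": "t"}))
        assert len(out) == 0
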