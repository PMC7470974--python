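import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from promoterome.diffexp import bh_adjust, nb_test, run_diffexp, size_factors


def nb_matrix(rng, means, n_samples, dispersion=0.1):
    cols = []
    for _ in range(n_samples):
        lam = rng.gamma(1 / dispersion, means * dispersion)
        cols.append(rng.poisson(lam))
    return np.column_stack(cols)


class TestSizeFactors:
    def test_doubled_column(self):
        mat = np.array([[10, 20], [100, 200], [5, 10], [50, 100]], float)
        s = size_factors(mat)
        assert s[1] / s[0] == pytest.approx(2.0)

    def test_identical_columns_are_unit(self):
        mat = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 4))
        np.testing.assert_allclose(size_factors(mat), 1.0)

    def test_matches_hand_median_of_ratios(self):
        mat = np.array([[4, 9], [1, 4], [16, 25], [9, 4], [25, 16]], float)
        s = size_factors(mat)
        geo = np.exp(np.log(mat).mean(axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        np.testing.assert_allclose(s, expected)

    def test_no_all_positive_gene_is_error(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 5], [5, 0]], float))


class TestBH:
    def test_hand_oracle_small(self):
        p = [0.01, 0.02, 0.03]
        np.testing.assert_allclose(bh_adjust(np.array(p)), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_matches_stepup_oracle_and_permutation_invariance(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, oracles.bh_stepup(list(p)), atol=1e-12)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)


class TestNBTest:
    def test_identical_replicates_are_null(self):
        p, lfc = nb_test([30, 35, 40], [30, 35, 40])
        assert lfc == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_condition_swap_symmetry(self, rng):
        a = rng.poisson(80, size=3)
        b = rng.poisson(200, size=3)
        p1, l1 = nb_test(a, b, dispersion=0.1)
        p2, l2 = nb_test(b, a, dispersion=0.1)
        assert l1 == pytest.approx(-l2)
        assert p1 == pytest.approx(p2)

    def test_all_zero_gene(self):
        p, lfc = nb_test([0, 0, 0], [0, 0, 0], dispersion=0.1)
        assert (p, lfc) == (1.0, 0.0)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            nb_test([5], [5, 6])


class TestRunDiffexp:
    def make_frame(self, rng, n_null=4000, n_de=400, lfc=2.0, mean_de=100.0):
        means = np.concatenate([
            rng.uniform(20, 500, size=n_null), np.full(n_de, mean_de)])
        mat_a = nb_matrix(rng, means, 3)
        means_b = means.copy()
        means_b[n_null:] *= 2.0 ** lfc
        mat_b = nb_matrix(rng, means_b, 3)
        df = pd.DataFrame(
            np.column_stack([mat_a, mat_b]),
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
            index=[f"g{i}" for i in range(n_null + n_de)])
        truth = np.array(["null"] * n_null + ["de"] * n_de)
        return df, truth

    def test_null_calibration_and_power(self, rng):
        df, truth = self.make_frame(rng)
        res = run_diffexp(df, {c: c[0] for c in df.columns})
        null_p = res["p_value"].to_numpy()[truth == "null"]
        assert 0.03 <= (null_p < 0.05).mean() <= 0.07
        de_calls = res["call"].to_numpy()[truth == "de"]
        assert (de_calls == "up_B").mean() >= 0.8
        called = res["call"] != "unchanged"
        fdr = (truth[called.to_numpy()] == "null").mean()
        assert fdr <= 0.1

    def test_label_swap_flips_sign(self, rng):
        df, _ = self.make_frame(rng, n_null=300, n_de=50)
        conds = {c: c[0] for c in df.columns}
        res = run_diffexp(df, conds)
        flipped = {c: ("B" if v == "A" else "A") for c, v in conds.items()}
        res2 = run_diffexp(df, flipped)
        np.testing.assert_allclose(res2["log2_fold_change"],
                                   -res["log2_fold_change"], atol=1e-9)
        np.testing.assert_allclose(res2["p_value"], res["p_value"], atol=1e-9)

    def test_needs_two_conditions(self, rng):
        df, _ = self.make_frame(rng, n_null=20, n_de=0)
        with pytest.raises(ValueError, match="two conditions"):
            run_diffexp(df, {c: "A" for c in df.columns})


def test_against_deseq2_cross_check(rng):
    """Independent cross-check: log2 fold changes agree with pyDESeq2 and the
    significant sets overlap strongly on a planted dataset."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    means = np.concatenate([rng.uniform(50, 500, size=220),
                            np.full(30, 150.0)])
    mat_a = nb_matrix(rng, means, 3)
    means_b = means.copy()
    means_b[220:] *= 4.0
    mat_b = nb_matrix(rng, means_b, 3)
    counts = pd.DataFrame(np.column_stack([mat_a, mat_b]),
                          columns=[f"A_{i}" for i in range(3)]
                          + [f"B_{i}" for i in range(3)],
                          index=[f"g{i}" for i in range(250)])
    res = run_diffexp(counts, {c: c[0] for c in counts.columns})

    meta = pd.DataFrame({"condition": [c[0] for c in counts.columns]},
                        index=counts.columns)
    dds = DeseqDataSet(counts=counts.T, metadata=meta,
                       design="~condition", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
    stats.summary()
    ref = stats.results_df

    corr = np.corrcoef(res["log2_fold_change"],
                       ref["log2FoldChange"].to_numpy())[0, 1]
    assert corr > 0.95
    ours = set(res.index[res["adjusted_p"] < 0.05])
    theirs = set(ref.index[ref["padj"] < 0.05])
    jaccard = len(ours & theirs) / max(len(ours | theirs), 1)
    assert jaccard > 0.7
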