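import numpy as np
import pandas as pd
import pytest

from bbbscore.association import (
    correlate,
    correlation_matrix,
    ecm_ranking,
    gene_screen,
    group_compare,
    hypergeometric_ora,
    pca_scores,
    spearman_vs_vector,
)
from bbbscore.enrichment import ScoreTable
from bbbscore.io_formats import ExpressionMatrix
from bbbscore.signatures import GeneSet, SignatureCollection


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), log_transformed=True
    )


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "pearson").rho == pytest.approx(1.0)

    def test_strictly_decreasing_spearman(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        y = np.array([10.0, 3.0, 2.0, -4.0])
        assert correlate(x, y, "spearman").rho == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "y,expected",
        [
            # rank differences d=(−1,1,−1,1,0), Σd²=4 -> 1 − 6·4/120 = 0.8
            ([2, 1, 4, 3, 5], 0.8),
            # rank differences d=(−2,1,1,0,0), Σd²=6 -> 1 − 6·6/120 = 0.7
            ([3, 1, 2, 4, 5], 0.7),
        ],
    )
    def test_hand_computed_five_point_examples(self, y, expected):
        res = correlate([1, 2, 3, 4, 5], y, "spearman")
        assert res.rho == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            correlate([1.0, 2.0], [3.0, 4.0])


class TestCorrelationMatrix:
    def _table(self, rng, n=20):
        df = pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"s{i}" for i in range(n)],
            columns=["a", "b", "c"],
        )
        return ScoreTable(df)

    def test_self_correlation_diagonal_is_one(self, rng):
        t = self._table(rng)
        rho, _ = correlation_matrix(t, t.scores)
        assert np.allclose(np.diag(rho.to_numpy(dtype=float)), 1.0)

    def test_invariant_to_sample_order(self, rng):
        t = self._table(rng)
        shuffled = ScoreTable(t.scores.sample(frac=1.0, random_state=0))
        a, _ = correlation_matrix(t, t.scores)
        b, _ = correlation_matrix(shuffled, t.scores)
        assert np.allclose(a.to_numpy(float), b.to_numpy(float))

    def test_too_few_shared_samples_rejected(self, rng):
        t = self._table(rng)
        refs = t.scores.iloc[:2]
        with pytest.raises(ValueError, match="shared samples"):
            correlation_matrix(t, refs)

    def test_stromal_score_sign_pattern(self, default_cohort):
        # vascular/immune residents track the stromal score; neural lineage
        # cells are enriched in purer samples and anti-track it
        table = default_cohort["table"]
        stromal = default_cohort["estimate"][["stromal"]]
        rho, _ = correlation_matrix(table, stromal, method="pearson")
        for ct in ("endothelial cells", "astrocytes", "pericytes", "microglia"):
            assert rho.loc[ct, "stromal"] > 0
        for ct in ("neurons", "oligodendrocytes"):
            assert rho.loc[ct, "stromal"] < 0


class TestGroupCompare:
    def test_identical_groups_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        stat, p, test = group_compare(values, groups)
        assert test == "anova"
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(10.0, 1.0, 50)
        stat, p, test = group_compare(
            np.r_[a, b], np.repeat(["low", "high"], 50)
        )
        assert test == "welch_t"
        assert p < 1e-6

    def test_three_groups_dispatch_to_anova(self, rng):
        values = rng.normal(size=30)
        _, _, test = group_compare(values, np.repeat(["x", "y", "z"], 10))
        assert test == "anova"

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPCA:
    def test_collinear_data_loads_on_first_component(self, rng):
        base = rng.normal(size=30)
        df = pd.DataFrame(
            {f"c{i}": base * (i + 1) + rng.normal(scale=1e-6, size=30)
             for i in range(6)},
            index=[f"s{i}" for i in range(30)],
        )
        res = pca_scores(ScoreTable(df), k=2)
        assert res.explained_variance_ratio[0] >= 0.999

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(25, 6)), index=[f"s{i}" for i in range(25)],
            columns=list("abcdef"),
        )
        res = pca_scores(ScoreTable(df), k=4)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(4), atol=1e-10)

    def test_matches_eigendecomposition(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(10, 6)), index=[f"s{i}" for i in range(10)],
            columns=list("abcdef"),
        )
        res = pca_scores(ScoreTable(df), k=6)
        z = (df - df.mean()) / df.std(ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(z.to_numpy().T))
        order = np.argsort(evals)[::-1]
        coords_oracle = z.to_numpy() @ evecs[:, order]
        # eigenvectors are sign-ambiguous: align column signs first
        for j in range(6):
            a = res.coordinates.to_numpy()[:, j]
            b = coords_oracle[:, j]
            if np.dot(a, b) < 0:
                b = -b
            assert np.allclose(a, b, atol=1e-8)

    def test_k_larger_than_columns_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            pca_scores(ScoreTable(df), k=4)


class TestGeneScreen:
    def test_gene_equal_to_score_included_with_rho_one(self, rng):
        bbb = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        m = _em(
            np.vstack([bbb.to_numpy(), rng.normal(size=12)]),
            genes=["tracker", "noise"],
            samples=list(bbb.index),
        )
        hits = gene_screen(m, bbb)
        assert "tracker" in hits.index
        assert hits.loc["tracker", "rho"] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        samples = [f"s{i}" for i in range(5)]
        bbb = pd.Series([3.0, 1.0, 2.0, 4.0, 5.0], index=samples)
        m = _em([[1.0, 2.0, 3.0, 4.0, 5.0]], genes=["edge"], samples=samples)
        # spearman rho is exactly 0.7 for this configuration (sum d^2 = 6)
        assert spearman_vs_vector(m, bbb).loc["edge"] == pytest.approx(0.7)
        assert len(gene_screen(m, bbb, rho_threshold=0.7)) == 0
        assert len(gene_screen(m, bbb, rho_threshold=0.69)) == 1

    def test_minus_one_threshold_returns_all_nonconstant(self, rng):
        samples = [f"s{i}" for i in range(8)]
        bbb = pd.Series(rng.normal(size=8), index=samples)
        vals = rng.normal(size=(10, 8))
        vals[3] = 5.0  # constant gene cannot be ranked against the score
        m = _em(vals, samples=samples)
        hits = gene_screen(m, bbb, rho_threshold=-1.0)
        assert len(hits) == 9
        assert "g3" not in hits.index

    def test_sorted_descending(self, default_cohort):
        hits = gene_screen(
            default_cohort["logm"], default_cohort["bbb"], rho_threshold=0.3
        )
        assert (hits["rho"].diff().dropna() <= 1e-12).all()


class TestHypergeometricOra:
    def _run(self, gene_list, universe, sets):
        return hypergeometric_ora(gene_list, universe, sets)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = SignatureCollection([GeneSet("S", tuple(universe[:5]))])
        df = self._run(universe[10:15], universe, sets)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_closed_form_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        sets = SignatureCollection([GeneSet("S", tuple(universe[:5]))])
        df = self._run(universe[:5], universe, sets)
        assert df.loc[0, "p_value"] == pytest.approx(1.0 / 15504.0, rel=1e-9)

    def test_bh_identity_for_equal_raw_p(self):
        universe = [f"g{i}" for i in range(40)]
        sets = SignatureCollection(
            [GeneSet(f"S{k}", tuple(universe[10 * k : 10 * k + 5]))
             for k in range(4)]
        )
        df = self._run(universe[30:35], universe, sets)
        # the three non-overlapping sets share identical raw p
        sub = df[df["overlap"] == 0]
        assert np.allclose(sub["p_adjusted"], sub["p_value"])

    def test_adjusted_at_least_raw_and_in_unit_interval(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = SignatureCollection(
            [GeneSet(f"S{k}", tuple(rng.choice(universe, 8, replace=False)))
             for k in range(6)]
        )
        df = self._run(list(rng.choice(universe, 12, replace=False)), universe, sets)
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()
        assert ((df["p_value"] > 0) & (df["p_value"] <= 1)).all()

    def test_monotone_in_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        gene_list = universe[:6]
        ps = []
        for k in (1, 3, 5):
            s = SignatureCollection(
                [GeneSet("S", tuple(gene_list[:k] + universe[20 : 25 - k]))]
            )
            ps.append(self._run(gene_list, universe, s).loc[0, "p_value"])
        assert ps[0] > ps[1] > ps[2]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            self._run([], [], SignatureCollection([GeneSet("S", ("a",))]))

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not within"):
            self._run(["x"], ["a", "b"], SignatureCollection([GeneSet("S", ("a",))]))


class TestEcmRanking:
    def _setup(self, rng, n_ecm=10):
        samples = [f"s{i}" for i in range(15)]
        bbb = pd.Series(rng.normal(size=15), index=samples)
        vals = rng.normal(size=(n_ecm, 15))
        vals[-1] = -bbb.to_numpy()  # most negatively tracking gene
        genes = [f"e{i}" for i in range(n_ecm)]
        m = _em(vals, genes=genes, samples=samples)
        return m, GeneSet("ecm", tuple(genes), "ecm"), bbb

    def test_row_count(self, rng):
        m, ecm, bbb = self._setup(rng)
        out = ecm_ranking(m, ecm, bbb, top_pos=3, top_neg=2)
        assert len(out) == 5
        assert list(out["direction"]) == ["positive"] * 3 + ["negative"] * 2

    def test_anti_tracking_gene_is_most_negative(self, rng):
        m, ecm, bbb = self._setup(rng)
        out = ecm_ranking(m, ecm, bbb, top_pos=3, top_neg=2)
        assert out.index[-1] == "e9"
        assert out["rho"].iloc[-1] == pytest.approx(-1.0)

    def test_matches_full_sort(self, rng):
        m, ecm, bbb = self._setup(rng, n_ecm=30)
        out = ecm_ranking(m, ecm, bbb, top_pos=20, top_neg=10)
        full = spearman_vs_vector(m, bbb).sort_values(ascending=False)
        assert list(out.index) == list(full.index)
        assert np.allclose(out["rho"], full.to_numpy())

    def test_insufficient_measured_genes_rejected(self, rng):
        m, ecm, bbb = self._setup(rng, n_ecm=4)
        with pytest.raises(ValueError, match="ECM genes"):
            ecm_ranking(m, ecm, bbb, top_pos=3, top_neg=2)
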