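"""Phenotype derivation, decorrelation, silhouette and cluster statistics."""

import numpy as np
import pandas as pd
import pytest

import thermopain as tp
from thermopain.phenotype import ALL_VARS, PHENOTYPE_VARS, _mixed_anova


def table_from(rows):
    return pd.DataFrame(rows, columns=list(PHENOTYPE_VARS))


class TestUvbEffects:
    def test_direct_subtraction(self):
        t = table_from([[-1.0, 0.5, 0.2, 0.2]])
        out = tp.derive_uvb_effects(t)
        assert out["UVBEff_Heat"].iloc[0] == pytest.approx(1.5)
        assert out["UVBEff_Cold"].iloc[0] == 0.0
        # inputs untouched
        assert (out[list(PHENOTYPE_VARS)] == t).all().all()

    def test_identical_measurements_give_zero_effect(self, rng):
        vals = rng.normal(size=10)
        t = table_from(np.column_stack([vals, vals, vals, vals]))
        out = tp.derive_uvb_effects(t)
        assert (out["UVBEff_Heat"] == 0).all()

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError):
            tp.derive_uvb_effects(pd.DataFrame({"zHPT_baseline": [0.0]}))


class TestCorrelationScreen:
    def test_correlated_pair_forms_one_block(self, rng):
        z = rng.normal(size=(500, 2))
        x = z[:, 0]
        y = 0.9 * x + np.sqrt(1 - 0.81) * z[:, 1]
        t = pd.DataFrame({"a": x, "b": y, "c": rng.normal(size=500)})
        screen = tp.correlation_screen(t, threshold=0.8)
        assert screen.blocks == (("a", "b"),)
        assert screen.singles == ("c",)

    def test_independent_columns_give_no_blocks(self, rng):
        t = pd.DataFrame(rng.normal(size=(1000, 6)), columns=list("abcdef"))
        screen = tp.correlation_screen(t, threshold=0.8)
        assert screen.blocks == ()
        assert set(screen.singles) == set("abcdef")

    def test_constant_column_reported_and_excluded(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        screen = tp.correlation_screen(t, threshold=0.8)
        assert screen.excluded_constant == ("b",)

    def test_self_correlation_is_one(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        screen = tp.correlation_screen(t)
        assert screen.correlations.loc["a", "a"] == pytest.approx(1.0)


def exact_r_pair(r, n=82, seed=0):
    """Two columns whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 2))
    z -= z.mean(axis=0)
    # orthonormalize, then mix with the target correlation
    q, _ = np.linalg.qr(z)
    u, v = q[:, 0], q[:, 1]
    x = u
    y = r * u + np.sqrt(1 - r * r) * v
    return pd.DataFrame({"x": x, "y": y})


class TestPcaDecorrelate:
    @pytest.mark.parametrize("r, expected", [
        (0.812, (1.812, 0.188)),
        (0.0, (1.0, 1.0)),
        (0.5, (1.5, 0.5)),
    ])
    def test_two_variable_closed_form(self, r, expected):
        block = tp.pca_decorrelate(exact_r_pair(r), ("x", "y"))
        assert block.eigenvalues == pytest.approx(expected, abs=1e-9)

    def test_retention_rule_strictly_above_one(self):
        assert tp.pca_decorrelate(exact_r_pair(0.812), ("x", "y")).retained \
            == ("PC1_block",)
        # eigenvalues exactly (1, 1): nothing exceeds 1 strictly
        assert tp.pca_decorrelate(exact_r_pair(0.0), ("x", "y")).retained == ()

    def test_eigenvalues_sum_to_block_size(self, rng):
        t = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        block = tp.pca_decorrelate(t, ("a", "b", "c"))
        assert block.eigenvalues.sum() == pytest.approx(3.0)
        assert (np.diff(block.eigenvalues) <= 1e-12).all()

    def test_single_variable_block_rejected(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            tp.pca_decorrelate(t, ("a",))


class TestFeatureMatrix:
    def test_cold_pair_collapses_to_one_component(self):
        spec = tp.CohortSpec.phenotyping_cohort(seed=5)
        table, _ = tp.generate_phenotypes(spec)
        table = tp.derive_uvb_effects(table)
        features, blocks = tp.feature_matrix(table)
        assert features.shape[1] == 5
        assert "PC1_zCPT" in features.columns
        assert blocks[0].variables == ("zCPT_baseline", "zCPT_UVB")

    def test_no_decorrelation_passthrough(self):
        spec = tp.CohortSpec.phenotyping_cohort(seed=5)
        table, _ = tp.generate_phenotypes(spec)
        table = tp.derive_uvb_effects(table)
        features, blocks = tp.feature_matrix(table, decorrelate=False)
        assert list(features.columns) == list(ALL_VARS)
        assert blocks == []


def silhouette_oracle(X, labels):
    """Direct O(n^2) silhouette computation."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    dist = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = dist[i, own & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == c].mean()
                for c in np.unique(labels) if c != labels[i])
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


class TestSilhouette:
    def test_tight_separated_pairs_score_high(self):
        X = np.array([[0, 0], [0, 0.01], [10, 10], [10, 10.01]])
        labels = [0, 0, 1, 1]
        assert tp.silhouette_index(X, labels) > 0.95

    def test_identical_points_follow_zero_convention(self):
        X = np.zeros((6, 2))
        assert tp.silhouette_index(X, [0, 0, 0, 1, 1, 1]) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            tp.silhouette_index(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 50))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, 3, size=n)
            if np.unique(labels).size < 2:
                continue
            assert tp.silhouette_index(X, labels) == pytest.approx(
                silhouette_oracle(X, labels), abs=1e-10)


def anova_oracle(values, groups):
    """Hand-style mixed-ANOVA F values via explicit loops (balanced within)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n, k = values.shape
    gs = sorted(set(groups.tolist()))
    grand = values.mean()
    ss_cluster = sum(
        k * (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
        for g in gs)
    ss_bs = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ss_test = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_cells = sum(
        (groups == g).sum() * (values[groups == g, j].mean() - grand) ** 2
        for g in gs for j in range(k))
    ss_total = ((values - grand) ** 2).sum()
    ss_inter = ss_cells - ss_test - ss_cluster
    ss_eb = ss_bs - ss_cluster
    ss_ew = ss_total - ss_bs - ss_test - ss_inter
    G = len(gs)
    F_test = (ss_test / (k - 1)) / (ss_ew / ((n - G) * (k - 1)))
    F_cluster = (ss_cluster / (G - 1)) / (ss_eb / (n - G))
    F_inter = (ss_inter / ((G - 1) * (k - 1))) / (ss_ew / ((n - G) * (k - 1)))
    return F_test, F_cluster, F_inter


class TestClusterStats:
    def make_table(self, rng, n1=12, n2=8, shift=1.0):
        labels = np.repeat([1, 2], [n1, n2])
        base = rng.normal(size=(n1 + n2, 4))
        base[labels == 2] += shift
        t = table_from(base)
        return tp.derive_uvb_effects(t), labels

    def test_corrected_alpha(self, rng):
        t, labels = self.make_table(rng)
        stats = tp.cluster_stats(t, labels)
        assert stats.alpha_corrected == pytest.approx(0.05 / 6)
        assert stats.alpha_corrected == pytest.approx(0.00833, abs=5e-6)

    def test_anova_matches_hand_computed_sums_of_squares(self, rng):
        values = rng.normal(size=(8, 3))
        groups = np.repeat([1, 2], [5, 3])
        mine = _mixed_anova(values, groups)
        oracle = anova_oracle(values, groups)
        assert mine["F"].to_numpy() == pytest.approx(oracle, abs=1e-10)

    def test_anova_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        values = rng.normal(size=(14, 5))
        groups = np.repeat([1, 2], [8, 6])
        mine = _mixed_anova(values, groups)
        long = (pd.DataFrame(values).assign(subject=range(14), grp=groups)
                .melt(id_vars=["subject", "grp"], var_name="test",
                      value_name="y"))
        ping = pg.mixed_anova(data=long, dv="y", within="test",
                              subject="subject", between="grp")
        by_src = {r["Source"]: r["F"] for _, r in ping.iterrows()}
        assert mine.set_index("effect").loc["test", "F"] == pytest.approx(
            by_src["test"])
        assert mine.set_index("effect").loc["cluster", "F"] == pytest.approx(
            by_src["grp"])
        assert mine.set_index("effect").loc["test:cluster", "F"] == \
            pytest.approx(by_src["Interaction"])

    def test_identical_clusters_show_no_effect(self, rng):
        block = rng.normal(size=(10, 4))
        t = table_from(np.vstack([block, block]))
        t = tp.derive_uvb_effects(t)
        labels = np.repeat([1, 2], 10)
        stats = tp.cluster_stats(t, labels)
        row = stats.anova.set_index("effect").loc["cluster"]
        assert row["F"] == pytest.approx(0.0, abs=1e-20)
        assert row["p"] == pytest.approx(1.0)

    def test_welch_t_and_balanced_sex(self, rng):
        t, labels = self.make_table(rng, shift=2.0)
        sex = np.tile(["f", "m"], 10)
        stats = tp.cluster_stats(t, labels, sex=sex)
        assert (stats.t_tests["p"] < 0.05).any()
        assert not stats.t_tests["df"].apply(float.is_integer).all()
        assert 0 <= stats.sex_p <= 1

    def test_small_cluster_rejected(self, rng):
        t, _ = self.make_table(rng)
        labels = np.array([1] * 19 + [2])
        with pytest.raises(ValueError):
            tp.cluster_stats(t, labels)
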