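"""Correlation/Mantel screens, permutation importance, path model."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmf.drivers import (
    DEFAULT_PATH_SPEC,
    ImportanceConfig,
    PathModel,
    PathModelSpec,
    effects_table,
    fit_path_model,
    importance_screen,
    mantel_screen,
    pearson_matrix,
)
from soilmf.synthetic import PlantedPathConfig, generate_path_dataset


def oracle_effects(edges: dict, source: str, outcome: str) -> dict:
    """Brute-force path enumeration: products of coefficients over all paths."""
    g = nx.DiGraph()
    for (a, b), c in edges.items():
        g.add_edge(a, b, c=c)
    direct = edges.get((source, outcome), 0.0)
    indirect = 0.0
    if source in g and outcome in g:
        for path in nx.all_simple_paths(g, source, outcome):
            if len(path) > 2:
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= edges[(a, b)]
                indirect += prod
    return {"direct": direct, "indirect": indirect, "total": direct + indirect}


class TestPearsonMatrix:
    def test_self_and_negated_columns(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 4.0, 3.0]})
        x["b"] = -x["a"]
        r, p = pearson_matrix(x)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x = pd.DataFrame(rng.random((5, 2)), columns=["u", "v"])
        r, p = pearson_matrix(x)
        u, v = x["u"].to_numpy(), x["v"].to_numpy()
        num = ((u - u.mean()) * (v - v.mean())).sum()
        den = np.sqrt(((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
        expected = num / den
        assert r.loc["u", "v"] == pytest.approx(expected, abs=1e-12)
        t = expected * np.sqrt(3 / (1 - expected**2))
        from scipy import stats

        assert p.loc["u", "v"] == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-10)

    def test_constant_column_flagged_nan(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        r, p = pearson_matrix(x)
        assert np.isnan(r.loc["a", "flat"]) and np.isnan(p.loc["a", "flat"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestMantelScreen:
    def test_linear_indicator_gives_r_one(self):
        idx = [f"p{i}" for i in range(6)]
        div = pd.DataFrame({"shannon": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=idx)
        ind = pd.DataFrame({"TN": 2.0 * div["shannon"] + 1.0}, index=idx)
        res = mantel_screen(div, ind)
        assert res.loc["TN", "r"] == pytest.approx(1.0)

    def test_small_overlap_rejected(self):
        idx = ["p0", "p1", "p2"]
        div = pd.DataFrame({"shannon": [1.0, 2.0, 3.0]}, index=idx)
        ind = pd.DataFrame({"TN": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(ValueError, match="4 shared"):
            mantel_screen(div, ind)

    def test_exhaustive_p_matches_enumeration(self, rng):
        idx = [f"p{i}" for i in range(4)]
        div = pd.DataFrame({"shannon": rng.random(4)}, index=idx)
        ind = pd.DataFrame({"TN": rng.random(4)}, index=idx)
        res = mantel_screen(div, ind)
        z = (div["shannon"] - div["shannon"].mean()) / div["shannon"].std(ddof=1)
        d1 = np.abs(z.to_numpy()[:, None] - z.to_numpy()[None, :])
        zi = (ind["TN"] - ind["TN"].mean()) / ind["TN"].std(ddof=1)
        d2 = np.abs(zi.to_numpy()[:, None] - zi.to_numpy()[None, :])
        iu = np.triu_indices(4, 1)
        observed = np.corrcoef(d1[iu], d2[iu])[0, 1]
        count = 0
        stats_null = []
        for order in itertools.permutations(range(4)):
            perm = d2[np.ix_(order, order)]
            stats_null.append(np.corrcoef(d1[iu], perm[iu])[0, 1])
        count = sum(1 for s in stats_null if s >= observed - 1e-12)
        assert res.loc["TN", "p"] == (1 + count) / 25
        assert bool(res.loc["TN", "exhaustive"])

    def test_null_p_values_roughly_uniform(self):
        """Independent indicator: permutation p is approximately U(0,1)."""
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(12)]
        ps = []
        for rep in range(200):
            div = pd.DataFrame({"shannon": rng.standard_normal(12)}, index=idx)
            ind = pd.DataFrame({"TN": rng.standard_normal(12)}, index=idx)
            res = mantel_screen(div, ind, n_permutations=199, seed=rep)
            ps.append(res.loc["TN", "p"])
        ps = np.sort(ps)
        ecdf_dev = np.max(np.abs(ps - (np.arange(1, 201)) / 200))
        assert ecdf_dev < 0.12  # ~KS bound at n=200 plus add-one discreteness


class TestImportanceScreen:
    def _signal_data(self, seed, n=200, p=10):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)])
        y = pd.Series(x["f0"] + 0.05 * rng.standard_normal(n), index=x.index)
        return x, y

    def test_signal_feature_ranks_first(self):
        x, y = self._signal_data(0)
        res = importance_screen(x, y, ImportanceConfig(n_trees=150, seed=0))
        assert res.ranking[0] == "f0"
        assert "f0" in res.selected
        assert res.r_squared > 0.8

    def test_null_features_have_near_zero_importance(self):
        x, y = self._signal_data(1)
        res = importance_screen(x, y, ImportanceConfig(n_trees=150, seed=1))
        assert res.importances.drop("f0").abs().max() < 0.05

    def test_same_seed_reproducible(self):
        x, y = self._signal_data(2)
        cfg = ImportanceConfig(n_trees=60, seed=3)
        a = importance_screen(x, y, cfg)
        b = importance_screen(x, y, cfg)
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_constant_response_rejected(self):
        x, _ = self._signal_data(4)
        with pytest.raises(ValueError, match="constant"):
            importance_screen(x, pd.Series(1.0, index=x.index))

    def test_too_few_rows_rejected(self):
        x, y = self._signal_data(5, n=6)
        with pytest.raises(ValueError, match="8 rows"):
            importance_screen(x, y)


#: The diversity -> function part of the default DAG (no SMF equation);
#: with zero residuals this subsystem is full rank, while the SMF equation
#: is not (its three parents span only the two exogenous diversities).
UPSTREAM_EDGES = {
    e: c for e, c in PlantedPathConfig().coefficients.items() if e[1] != "SMF"
}


class TestPathModel:
    def test_noiseless_recovery_is_exact(self):
        config = PlantedPathConfig(coefficients=UPSTREAM_EDGES,
                                   residual_sd=0.0, n_samples=100, seed=0)
        data = generate_path_dataset(config)
        fit = fit_path_model(data, PathModelSpec(tuple(UPSTREAM_EDGES)))
        for _, row in fit.edges.iterrows():
            planted = config.coefficients[(row["source"], row["target"])]
            assert row["coefficient"] == pytest.approx(planted, abs=1e-8)
        assert all(abs(r2 - 1) < 1e-10 for r2 in fit.r_squared.values())

    def test_noiseless_full_dag_is_degenerate(self):
        """With zero residuals, SMF's parents are collinear and the fit says so."""
        data = generate_path_dataset(
            PlantedPathConfig(residual_sd=0.0, n_samples=100, seed=0)
        )
        with pytest.raises(ValueError, match="SMF"):
            fit_path_model(data)

    def test_chain_decomposition(self):
        data = generate_path_dataset(
            PlantedPathConfig(coefficients={("X", "M"): 0.5, ("M", "Y"): 0.8},
                              residual_sd=0.1, n_samples=200, seed=1)
        )
        fit = fit_path_model(data, PathModelSpec((("X", "M"), ("M", "Y"))))
        eff = fit.effect("X", "Y")
        a = fit.edges.set_index(["source", "target"]).loc[("X", "M"), "coefficient"]
        b = fit.edges.set_index(["source", "target"]).loc[("M", "Y"), "coefficient"]
        assert eff["direct"] == 0.0
        assert eff["indirect"] == pytest.approx(a * b, abs=1e-12)
        assert eff["total"] == pytest.approx(a * b, abs=1e-12)

    def test_parallel_paths_sum(self):
        # mediators need residual noise: noiseless parallel mediators are
        # exact multiples of X and hence collinear parents of Y
        edges = {("X", "M1"): 0.4, ("M1", "Y"): 0.5, ("X", "M2"): -0.3, ("M2", "Y"): 0.7}
        data = generate_path_dataset(
            PlantedPathConfig(coefficients=edges, residual_sd=0.3, n_samples=300, seed=2)
        )
        fit = fit_path_model(data, PathModelSpec(tuple(edges)))
        coef = fit.edges.set_index(["source", "target"])["coefficient"]
        eff = fit.effect("X", "Y")
        expected = (coef[("X", "M1")] * coef[("M1", "Y")]
                    + coef[("X", "M2")] * coef[("M2", "Y")])
        assert eff["direct"] == 0.0
        assert eff["indirect"] == pytest.approx(expected, abs=1e-12)
        assert eff["indirect"] == pytest.approx(0.4 * 0.5 - 0.3 * 0.7, abs=0.1)

    def test_decomposition_matches_path_enumeration_oracle(self, rng):
        nodes = list("ABCDEF")
        edges = {}
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.5:
                    edges[(a, b)] = float(rng.normal())
        if not edges:
            edges[("A", "B")] = 1.0
        data = generate_path_dataset(
            PlantedPathConfig(coefficients=edges, residual_sd=0.2, n_samples=100, seed=3)
        )
        fit = fit_path_model(data, PathModelSpec(tuple(edges)))
        fitted = {(r["source"], r["target"]): r["coefficient"]
                  for _, r in fit.edges.iterrows()}
        for source in fit._pos:
            for outcome in fit._pos:
                if source == outcome:
                    continue
                mine = fit.effect(source, outcome)
                ref = oracle_effects(fitted, source, outcome)
                for key in ("direct", "indirect", "total"):
                    assert mine[key] == pytest.approx(ref[key], abs=1e-10)
                assert mine["total"] == pytest.approx(
                    mine["direct"] + mine["indirect"], abs=1e-10
                )

    def test_standardize_auto_respects_generator_flag(self):
        data = generate_path_dataset(PlantedPathConfig(seed=4))
        assert PathModel(data).standardize is False
        plain = data.copy()  # attrs are not propagated by copy? ensure unflagged
        plain.attrs = {}
        assert PathModel(plain).standardize is True

    def test_consistency_rmse_decreases_with_n(self):
        """Coefficient RMSE over seeds shrinks as the sample grows."""
        rmse = {}
        for n in (50, 500, 5000):
            errs = []
            for seed in range(5):
                config = PlantedPathConfig(n_samples=n, seed=seed)
                fit = fit_path_model(generate_path_dataset(config))
                for _, row in fit.edges.iterrows():
                    planted = config.coefficients[(row["source"], row["target"])]
                    errs.append((row["coefficient"] - planted) ** 2)
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[50] > rmse[500] > rmse[5000]

    def test_collinear_parents_named(self, rng):
        x = rng.standard_normal(50)
        data = pd.DataFrame({"A": x, "B": x, "Y": x + rng.standard_normal(50)})
        spec = PathModelSpec((("A", "Y"), ("B", "Y")))
        with pytest.raises(ValueError, match="'Y'"):
            fit_path_model(data, spec)

    def test_cyclic_spec_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModelSpec((("A", "B"), ("B", "A")))

    def test_effects_table_requires_outcome_node(self):
        data = generate_path_dataset(PlantedPathConfig(seed=5))
        fit = fit_path_model(data)
        with pytest.raises(KeyError, match="ghost"):
            effects_table(fit, "ghost")
        table = effects_table(fit, "SMF")
        assert set(table.index) == set(DEFAULT_PATH_SPEC.nodes) - {"SMF"}
        assert np.allclose(table["total"], table["direct"] + table["indirect"], atol=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25)
    def test_total_equals_direct_plus_indirect_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list("PQRST")
        edges = {}
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.6:
                    edges[(a, b)] = float(rng.normal())
        if not edges:
            edges[("P", "Q")] = 0.5
        data = generate_path_dataset(
            PlantedPathConfig(coefficients=edges, residual_sd=0.3,
                              n_samples=40, seed=seed)
        )
        fit = fit_path_model(data, PathModelSpec(tuple(edges)))
        for s in fit._pos:
            for o in fit._pos:
                if s != o:
                    eff = fit.effect(s, o)
                    assert eff["total"] == pytest.approx(
                        eff["direct"] + eff["indirect"], abs=1e-10
                    )
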