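import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cmlstate.gene_analysis import (assign_disease_states,
                                    differential_expression,
                                    detect_gene_modules, eigengene_contribution,
                                    expand_driver_network,
                                    find_transition_drivers, gene_set_contribution,
                                    age_adjust, read_gmt, significant_genes,
                                    validate_de_table)
from cmlstate.potentials import PotentialModel
from cmlstate.statespace import StateSpaceModel


@pytest.fixture
def pot():
    """Health-high landscape: c1..c5 = 1.4 .. -0.9, boundaries c2, c4."""
    return PotentialModel(kind="quintic", a=1.0,
                          critical_points=[1.4, 1.1, 0.65, 0.35, -0.9],
                          c_h=1.5)


def _coords(vals, cohorts, weeks=None):
    idx = pd.Index([f"s{i}" for i in range(len(vals))], name="sample")
    coords = pd.DataFrame({"coordinate": vals}, index=idx)
    table = pd.DataFrame({
        "cohort": cohorts,
        "mouse": [f"m{i}" for i in range(len(vals))],
        "week": weeks or list(range(len(vals))),
        "sex": ["M", "F"] * (len(vals) // 2) + ["M"] * (len(vals) % 2),
    }, index=idx)
    return coords, table


class TestStateAssignment:
    def test_basin_interior_labels(self, pot):
        coords, table = _coords([1.3, 0.65, -0.5, 1.45], ["CML"] * 4)
        out = assign_disease_states(coords, pot, table)
        assert list(out.state) == ["Es", "Ts", "Ls", "Es"]

    def test_boundary_goes_to_more_diseased(self, pot):
        coords, table = _coords([1.1, 0.35], ["CML"] * 2)
        out = assign_disease_states(coords, pot, table)
        assert list(out.state) == ["Ts", "Ls"]

    def test_controls_always_healthy(self, pot):
        coords, table = _coords([-0.8, 1.4], ["control", "control"])
        out = assign_disease_states(coords, pot, table)
        assert list(out.state) == ["Hs", "Hs"]

    def test_partition_every_sample_labeled(self, pot):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-1.5, 2.0, 60)
        coords, table = _coords(vals, ["CML"] * 60)
        out = assign_disease_states(coords, pot, table)
        assert out.state.isin(["Es", "Ts", "Ls"]).all()

    def test_cubic_needs_flag(self):
        cubic = PotentialModel(kind="cubic", a=1.0,
                               critical_points=[1.0, 0.3, -0.9])
        coords, table = _coords([0.5, -0.5], ["CML"] * 2)
        with pytest.raises(ValueError):
            assign_disease_states(coords, cubic, table)
        out = assign_disease_states(coords, cubic, table, allow_degraded=True)
        assert list(out.state) == ["Es", "Ls"]

    def test_late_weeks_enriched_for_disease_state(self, small_cohort, pot):
        """Planted dynamics: late CML samples are more often at the late
        disease state than early ones."""
        from cmlstate.synthetic import default_true_potential
        _, counts, table, truth = small_cohort
        cml = table[table.cohort == "CML"]
        x = pd.Series({s: truth["x_per_sample"][s] for s in cml.index},
                      name="coordinate").to_frame()
        out = assign_disease_states(x, default_true_potential(), table)
        early = out[cml.week <= 4]
        late = out[cml.week >= 8]
        assert (late.state == "Ls").mean() > (early.state == "Ls").mean()


def _nb_counts(rng, mu, phi=0.1):
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


class TestDifferentialExpression:
    def _dataset(self, seed=0, n_genes=120, n=10, fold_gene=None, fold=2.0):
        rng = np.random.default_rng(seed)
        base = np.exp(rng.normal(3.0, 1.0, n_genes))
        if fold_gene is not None:
            base[fold_gene] = np.exp(6.0)  # high-mean planted gene
        mu = np.tile(base[:, None], (1, 2 * n))
        if fold_gene is not None:
            mu[fold_gene, n:] *= fold
        counts = _nb_counts(rng, mu, phi=0.05)
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        counts = pd.DataFrame(counts, columns=samples,
                              index=[f"g{i}" for i in range(n_genes)])
        table = pd.DataFrame({
            "sex": ["M", "F"] * n,
            "cohort": ["CML"] * 2 * n,
        }, index=samples)
        return counts, table, samples[:n], samples[n:]

    def test_planted_fold_change_recovered(self):
        counts, table, a, b = self._dataset(seed=1, fold_gene=5, fold=2.0)
        de = differential_expression(counts, table, a, b)
        assert de.loc["g5", "log2FC"] == pytest.approx(1.0, abs=0.3)
        assert de.loc["g5", "padj"] < 0.05

    def test_null_type_one_error(self):
        """Permuted labels on null data: the raw-p significant fraction is
        near alpha."""
        hits, total = 0, 0
        for seed in range(3):
            counts, table, a, b = self._dataset(seed=seed, n_genes=150)
            de = differential_expression(counts, table, a, b)
            hits += (de["p"] < 0.05).sum()
            total += len(de)
        assert hits / total == pytest.approx(0.05, abs=0.035)

    def test_all_zero_gene_excluded(self):
        counts, table, a, b = self._dataset(seed=2, n_genes=30)
        counts.iloc[0] = 0
        de = differential_expression(counts, table, a, b)
        assert "g0" not in de.index

    def test_group_overlap_error(self):
        counts, table, a, b = self._dataset(seed=3, n_genes=10)
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(counts, table, a, a)

    def test_adjusted_p_at_least_raw(self):
        counts, table, a, b = self._dataset(seed=4, n_genes=60)
        de = differential_expression(counts, table, a, b)
        assert (de["padj"] >= de["p"] - 1e-12).all()

    def test_external_table_adapter(self):
        df = pd.DataFrame({"gene": ["g1", "g2"], "log2FC": [1.0, -2.0],
                           "p": [0.01, 0.5], "padj": [0.02, 0.6]})
        out = validate_de_table(df)
        assert list(out.index) == ["g1", "g2"]
        with pytest.raises(ValueError, match="missing"):
            validate_de_table(df.drop(columns=["padj"]))


class TestEigengeneContribution:
    def _model(self, genes, v1, v2):
        gi = pd.Index(genes)
        V = np.column_stack([v1, v2])
        return StateSpaceModel(
            genes=gi, center=pd.Series(0.0, index=gi),
            sample_ids=pd.Index(["s0", "s1"]), U=np.eye(2), S=np.ones(2),
            V=V, disease_axis_index=1)

    @pytest.mark.parametrize("v2,lfc,expected", [
        (1.0, -1.0, "pro-CML"),    # positive loading, downregulated
        (-1.0, 1.0, "pro-CML"),    # negative loading, upregulated
        (1.0, 1.0, "anti-CML"),    # positive loading, upregulated
        (-1.0, -1.0, "anti-CML"),  # negative loading, downregulated
        (0.0, 2.0, "neutral"),
        (1.0, 0.0, "neutral"),
    ])
    def test_quadrant_rule(self, v2, lfc, expected):
        model = self._model(["g0", "g1"], [0.1, 0.2], [v2, 0.5])
        de = pd.DataFrame({"log2FC": [lfc], "p": [0.01], "padj": [0.01]},
                          index=pd.Index(["g0"], name="gene"))
        rec, _ = eigengene_contribution(de, model)
        assert rec.loc["g0", "class"] == expected

    def test_opposite_vectors_cancel(self):
        model = self._model(["g0", "g1"], [0.5, -0.5], [1.0, 1.0])
        de = pd.DataFrame({"log2FC": [1.0, -1.0]},
                          index=pd.Index(["g0", "g1"], name="gene"))
        rec, mean_vec = eigengene_contribution(de, model)
        assert mean_vec == pytest.approx((0.0, 0.0))

    def test_missing_gene_error(self):
        model = self._model(["g0", "g1"], [0.1, 0.2], [0.3, 0.4])
        de = pd.DataFrame({"log2FC": [1.0]},
                          index=pd.Index(["gX"], name="gene"))
        with pytest.raises(ValueError, match="absent"):
            eigengene_contribution(de, model)

    def test_gene_set_contribution_and_gmt(self, tmp_path):
        model = self._model(["g0", "g1"], [1.0, 3.0], [1.0, 1.0])
        de = pd.DataFrame({"log2FC": [-1.0, -2.0]},
                          index=pd.Index(["g0", "g1"], name="gene"))
        rec, _ = eigengene_contribution(de, model)
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("SET_A\tdesc\tg0\tg1\nSET_B\tdesc\tgZ\n")
        sets = read_gmt(gmt)
        out = gene_set_contribution(rec, sets)
        assert out.loc["SET_A", "n_degs"] == 2
        assert out.loc["SET_A", "contribution_mean"] == pytest.approx(1.5)
        assert "SET_B" not in out.index


class TestGeneModules:
    def _expression(self, rng, coords, n_coreg=30, n_noise=40, anti=False):
        n = len(coords)
        latent = np.sin(coords * 2.0) + coords
        rows = {}
        for i in range(n_coreg):
            sign = -1.0 if (anti and i % 2) else 1.0
            rows[f"m{i}"] = sign * latent + 0.4 * rng.standard_normal(n)
        for i in range(n_noise):
            rows[f"n{i}"] = rng.standard_normal(n)
        return pd.DataFrame(rows).T

    def test_planted_module_recovered(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(-1.5, 2.0, 40)
        coords, table = _coords(vals, ["CML"] * 40)
        expr = self._expression(rng, vals)
        expr.columns = coords.index
        mods = detect_gene_modules(expr, coords, {"Ts": [f"m{i}" for i in range(30)]})
        assert len(mods) == 1
        assert mods[0].median_r > 0.25
        assert len(set(mods[0].genes)) >= 25

    def test_noise_genes_form_no_module(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(-1.5, 2.0, 80)
        coords, _ = _coords(vals, ["CML"] * 80)
        expr = self._expression(rng, vals, n_coreg=0, n_noise=40)
        expr.columns = coords.index
        mods = detect_gene_modules(expr, coords, {"Es": [f"n{i}" for i in range(40)]})
        assert mods == []

    def test_anticorrelated_modules_split_directions(self):
        rng = np.random.default_rng(7)
        vals = np.sort(rng.uniform(-1.5, 2.0, 40))
        coords, _ = _coords(vals, ["CML"] * 40)
        expr = self._expression(rng, vals, n_coreg=30, anti=True)
        expr.columns = coords.index
        mods = detect_gene_modules(expr, coords,
                                   {"Ls": [f"m{i}" for i in range(30)]})
        assert len(mods) == 2
        assert {m.direction for m in mods} == {"increasing", "decreasing"}

    def test_invariance_to_gene_order_and_shift(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(-1.5, 2.0, 30)
        coords, _ = _coords(vals, ["CML"] * 30)
        expr = self._expression(rng, vals, n_coreg=12, n_noise=6)
        expr.columns = coords.index
        genes = [f"m{i}" for i in range(12)] + [f"n{i}" for i in range(6)]
        m1 = detect_gene_modules(expr, coords, {"Ts": genes})
        shuffled = expr.loc[rng.permutation(expr.index)] + 5.0
        m2 = detect_gene_modules(shuffled, coords, {"Ts": genes[::-1]})
        assert [sorted(m.genes) for m in m1] == [sorted(m.genes) for m in m2]

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(-1, 1, 20)
        coords, _ = _coords(vals, ["CML"] * 20)
        expr = self._expression(rng, vals, n_coreg=6, n_noise=0)
        expr.columns = coords.index
        expr.loc["m0"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            detect_gene_modules(expr, coords, {"Ts": [f"m{i}" for i in range(6)]})


class TestTransitionDrivers:
    def test_perfect_tracker_is_driver(self, pot):
        rng = np.random.default_rng(10)
        vals = np.linspace(1.35, -0.85, 30)
        coords, _ = _coords(vals, ["CML"] * 30)
        u = pot.potential(vals)
        expr = pd.DataFrame({"exact": u,
                             "flat": np.zeros(30) + 1.0,
                             "noise": rng.standard_normal(30)}).T
        expr.columns = coords.index
        out = find_transition_drivers(expr, coords, pot,
                                      ["exact", "flat", "noise"])
        exact = out[out.gene == "exact"]
        assert exact.driver.all()
        assert np.allclose(np.abs(exact.r), 1.0)
        assert "flat" not in set(out.gene)  # constant gene excluded

    def test_windows_and_sample_counts(self, pot):
        vals = np.concatenate([np.linspace(1.35, 0.7, 10),
                               np.linspace(0.6, -0.85, 12)])
        coords, _ = _coords(vals, ["CML"] * 22)
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.standard_normal((5, 22)),
                            index=[f"g{i}" for i in range(5)],
                            columns=coords.index)
        out = find_transition_drivers(expr, coords, pot, list(expr.index))
        assert set(out.window) == {"T-Es", "T-Ls"}

    def test_too_few_window_samples(self, pot):
        coords, _ = _coords([1.35, -0.85, -0.8], ["CML"] * 3)
        expr = pd.DataFrame(np.ones((2, 3)) * [[1.0], [2.0]],
                            index=["g0", "g1"], columns=coords.index)
        with pytest.raises(ValueError, match="window"):
            find_transition_drivers(expr, coords, pot, ["g0", "g1"])

    def test_planted_drivers_and_analytic_null(self, pot):
        """Potential-shaped genes are recovered; pure-noise false positives
        match the analytic correlation null at the window sample size."""
        rng = np.random.default_rng(12)
        vals = np.concatenate([np.linspace(1.38, 0.66, 15),
                               np.linspace(0.64, -0.88, 15)])
        coords, _ = _coords(vals, ["CML"] * 30)
        u = pot.potential(vals)
        n_planted, n_noise = 20, 200
        # noise scaled to the within-window potential variation so the
        # planted genes track the landscape shape inside each window
        win = (vals >= pot.c(3)) & (vals <= pot.c(1))
        scale = 0.15 * np.std(u[win])
        rows = {f"p{i}": u + scale * rng.standard_normal(30)
                for i in range(n_planted)}
        rows.update({f"z{i}": rng.standard_normal(30)
                     for i in range(n_noise)})
        expr = pd.DataFrame(rows).T
        expr.columns = coords.index
        out = find_transition_drivers(expr, coords, pot, list(expr.index))
        tes = out[out.window == "T-Es"]
        planted_found = tes[tes.gene.str.startswith("p")].driver.sum()
        assert planted_found >= 18
        # analytic null for |r| > 0.5 at n window samples (r^2 ~ Beta)
        n_win = tes.n_samples.iloc[0]
        p_null = scipy.stats.beta.sf(0.25, 0.5, (n_win - 2) / 2)
        fp = tes[tes.gene.str.startswith("z")].driver.sum()
        expected = n_noise * p_null
        assert abs(fp - expected) < 2 * np.sqrt(expected * (1 - p_null)) + 2

    def test_driver_null_rate_over_replicates(self, pot):
        """False-positive rate over repeated noise draws is within 2 SE of
        the analytic null."""
        rng = np.random.default_rng(13)
        vals = np.concatenate([np.linspace(1.38, 0.66, 10),
                               np.linspace(0.64, -0.88, 10)])
        coords, _ = _coords(vals, ["CML"] * 20)
        n_genes, n_rep = 50, 40
        total = 0
        for _ in range(n_rep):
            expr = pd.DataFrame(rng.standard_normal((n_genes, 20)),
                                index=[f"g{i}" for i in range(n_genes)],
                                columns=coords.index)
            out = find_transition_drivers(expr, coords, pot,
                                          list(expr.index))
            tes = out[out.window == "T-Es"]
            total += tes.driver.sum()
        n_win = 10
        # at n = 10 the driver rule needs both |r| > 0.5 and p < 0.05
        r_crit = 0.5
        t_crit = scipy.stats.t.ppf(0.975, n_win - 2)
        r_p = t_crit / np.sqrt(n_win - 2 + t_crit ** 2)
        r_eff = max(r_crit, r_p)
        p_null = scipy.stats.beta.sf(r_eff ** 2, 0.5, (n_win - 2) / 2)
        expected = n_genes * n_rep * p_null
        se = np.sqrt(expected * (1 - p_null))
        assert abs(total - expected) < 2 * se + 2


class TestAgeAdjustAndNetwork:
    def test_age_adjust_noop_and_subtraction(self, small_cohort):
        _, counts, table, _ = small_cohort
        sub = counts.iloc[:80]
        target = {"g00000", "g00001"}
        out = age_adjust(target, sub, table)
        assert out <= target
        # subtracting a superset target leaves nothing unexpected
        de_aging = age_adjust(set(sub.index), sub, table)
        assert (target - out) <= (set(sub.index) - de_aging)

    def test_age_adjust_needs_enough_controls(self, small_cohort):
        _, counts, table, _ = small_cohort
        short = table[table.week <= 3]
        with pytest.raises(ValueError):
            age_adjust({"g00000"}, counts[short.index], short)

    def test_planted_age_drift_genes_removed(self):
        """Genes drifting with age in controls are removed from a target
        DEG set."""
        rng = np.random.default_rng(14)
        weeks = list(range(12))
        samples = [f"c{w}" for w in weeks] + [f"d{w}" for w in weeks]
        n_genes = 40
        base = np.exp(rng.normal(4.0, 0.5, n_genes))
        mu = np.tile(base[:, None], (1, len(samples)))
        wk = np.array(weeks + weeks, dtype=float)
        mu[0] *= np.exp(0.25 * wk)     # strong age drift in gene 0
        counts = pd.DataFrame(_nb_counts(rng, mu, phi=0.05),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=samples)
        table = pd.DataFrame({
            "cohort": ["control"] * 12 + ["CML"] * 12,
            "week": weeks + weeks,
            "sex": ["M", "F"] * 12,
            "mouse": ["c"] * 12 + ["d"] * 12,
        }, index=samples)
        out = age_adjust({"g0", "g1"}, counts, table)
        assert "g0" not in out and "g1" in out

    def test_network_expansion_rules(self):
        edges = pd.DataFrame({"geneA": ["d1", "d1", "x"],
                              "geneB": ["p1", "p2", "y"],
                              "score": [950, 899, 990]})
        out = expand_driver_network({"d1"}, edges)
        assert out == {"d1", "p1"}
        assert expand_driver_network({"d1"}, edges.iloc[:0]) == {"d1"}
        low = edges.assign(score=[899, 899, 899])
        assert expand_driver_network({"d1"}, low) == {"d1"}
        with pytest.raises(ValueError, match="columns"):
            expand_driver_network({"d1"}, pd.DataFrame({"a": [1]}))
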