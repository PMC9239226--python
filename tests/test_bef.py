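import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raresoil.bef import (
    SupportTable,
    bef_regression,
    compare_support_breadth,
    diversity_function_correlations,
    rank_sum_test,
    support_summary,
    supporting_phylotypes,
)
from raresoil.core import CommunityTable
from raresoil.partition import classify_phylotypes


class TestBefRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = bef_regression(x, 2 * x + 1)
        assert np.isclose(fit.slope, 2.0)
        assert np.isclose(fit.intercept, 1.0)
        assert np.isclose(fit.r_squared, 1.0)

    def test_perfect_negative(self):
        x = np.arange(8.0)
        fit = bef_regression(x, -x)
        assert np.isclose(fit.standardized_slope, -1.0)

    def test_standardized_slope_is_sqrt_r2(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        fit = bef_regression(x, y)
        assert np.isclose(abs(fit.standardized_slope), np.sqrt(fit.r_squared))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            bef_regression(np.ones(10), np.arange(10.0))

    def test_type_one_error_quick(self):
        # independent x, y: slope p < 0.05 in roughly 5% of replicates
        rng = np.random.default_rng(0)
        hits = sum(
            bef_regression(rng.normal(size=80), rng.normal(size=80)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.01 <= hits / 400 <= 0.10


class TestDiversityFunctionCorrelations:
    def test_monotone_transform(self, rng):
        d = rng.normal(size=40)
        funcs = pd.DataFrame({"f": np.exp(d)})
        out = diversity_function_correlations({"div": d}, funcs)
        assert np.isclose(out.loc[0, "rho"], 1.0)

    def test_antitone(self, rng):
        d = rng.normal(size=40)
        funcs = pd.DataFrame({"f": -d})
        out = diversity_function_correlations({"div": d}, funcs)
        assert np.isclose(out.loc[0, "rho"], -1.0)

    def test_rank_oracle(self, rng):
        d = rng.normal(size=228)
        f = rng.normal(size=228)
        out = diversity_function_correlations({"d": d}, pd.DataFrame({"f": f}))
        ref = stats.spearmanr(d, f)
        assert np.isclose(out.loc[0, "rho"], ref.statistic, atol=1e-12)
        assert np.isclose(out.loc[0, "p"], ref.pvalue, atol=1e-12)

    def test_constant_excluded(self, rng):
        out = diversity_function_correlations(
            {"d": np.ones(20)}, pd.DataFrame({"f": rng.normal(size=20)})
        )
        assert not out.loc[0, "significant"]
        assert np.isnan(out.loc[0, "rho"])


def build_screen_table(rng, n=228):
    """One community table with engineered phylotypes for the screen."""
    base = rng.integers(1, 50, size=(n, 4))
    signal = np.argsort(np.argsort(rng.normal(size=n))) + 1  # ranks 1..n
    counts = np.column_stack(
        [
            signal,                     # p0: tracks the function perfectly
            signal[::-1],               # p1: perfectly anti-tracks
            np.full(n, 7),              # p2: constant
            base[:, 0] + 1,
        ]
    )
    table = CommunityTable(
        sample_ids=[f"s{i}" for i in range(n)],
        phylotype_ids=["p0", "p1", "p2", "p3"],
        counts=counts,
        group="bacteria",
    )
    return table, signal


class TestSupportingPhylotypes:
    def test_perfect_monotone_supports(self, rng):
        table, signal = build_screen_table(rng)
        classes = classify_phylotypes(table)
        # function whose ranks equal p0's relative-abundance ranks: tiny
        # counts relative to the constant denominators keep ranks intact
        funcs = pd.DataFrame({"f": stats.rankdata(table.counts[:, 0] / table.sample_totals())})
        st = supporting_phylotypes({"bacteria": table}, {"bacteria": classes}, funcs)
        i0 = st.phylotype_ids.index("p0")
        assert np.isclose(st.rho[i0, 0], 1.0)
        assert st.supports[i0, 0]

    def test_negative_not_supporting(self, rng):
        table, signal = build_screen_table(rng)
        classes = classify_phylotypes(table)
        rel0 = table.counts[:, 0] / table.sample_totals()
        funcs = pd.DataFrame({"f": -stats.rankdata(rel0)})
        st = supporting_phylotypes({"bacteria": table}, {"bacteria": classes}, funcs)
        i0 = st.phylotype_ids.index("p0")
        assert st.rho[i0, 0] < 0
        assert not st.supports[i0, 0]

    def test_prevalence_filter_error(self, rng):
        table, _ = build_screen_table(rng, n=20)
        classes = classify_phylotypes(table)
        funcs = pd.DataFrame({"f": rng.normal(size=20)})
        with pytest.raises(ValueError, match="prevalence"):
            supporting_phylotypes(
                {"bacteria": table}, {"bacteria": classes}, funcs, prevalence_min=1.1
            )

    def test_supports_implies_positive_rho(self, rng):
        counts = rng.integers(0, 30, size=(60, 25))
        counts[:, 0] += 1
        table = CommunityTable(
            [f"s{i}" for i in range(60)], [f"p{j}" for j in range(25)], counts, "fungi"
        )
        classes = classify_phylotypes(table)
        funcs = pd.DataFrame(rng.uniform(size=(60, 5)), columns=[f"f{k}" for k in range(5)])
        st = supporting_phylotypes({"fungi": table}, {"fungi": classes}, funcs, p_cut=0.3)
        assert (st.rho[st.supports] > 0).all()
        assert np.array_equal(st.n_functions_supported, st.supports.sum(axis=1))


def toy_support_table():
    # 2 abundant phylotypes supporting 3 functions each, 8 rare supporting 1
    ids = [f"a{i}" for i in range(2)] + [f"r{i}" for i in range(8)]
    labels = ["abundant"] * 2 + ["rare"] * 8
    supports = np.zeros((10, 5), dtype=bool)
    supports[0, :3] = True
    supports[1, :3] = True
    for i in range(8):
        supports[2 + i, i % 5] = True
    return SupportTable(
        phylotype_ids=ids,
        group=["bacteria"] * 10,
        label=labels,
        function_ids=[f"f{k}" for k in range(5)],
        rho=np.where(supports, 0.5, -0.1),
        p=np.where(supports, 0.001, 0.5),
        supports=supports,
        n_functions_supported=supports.sum(axis=1),
    )


class TestSupportSummary:
    def test_enumeration_oracle(self):
        st = toy_support_table()
        summary = support_summary(st)
        pf = summary["per_function"].set_index("function")
        # f0 supporters: a0, a1, r0, r5 -> abundant share 0.5
        assert pf.loc["f0", "n_supporting"] == 4
        assert np.isclose(pf.loc["f0", "share_abundant"], 0.5)
        assert np.isclose(pf.loc["f0", "share_rare"], 0.5)
        # f3 supporters: r3 only
        assert pf.loc["f3", "n_supporting"] == 1
        assert np.isclose(pf.loc["f3", "share_rare"], 1.0)
        # every rare member supports exactly one function
        assert summary["per_subcommunity"]["rare"]["fraction_supporting_any"] == 1.0
        assert summary["per_subcommunity"]["abundant"]["fraction_supporting_any"] == 1.0

    def test_column_sum_aggregation(self, rng):
        st = toy_support_table()
        summary = support_summary(st)
        pf = summary["per_function"].set_index("function")
        assert np.array_equal(
            pf["n_supporting"].to_numpy(), st.supports.sum(axis=0)
        )

    def test_saturation(self):
        st = toy_support_table()
        st.supports[:] = True
        st.n_functions_supported = st.supports.sum(axis=1)
        summary = support_summary(st)
        pf = summary["per_function"]
        assert (pf["proportion_supporting"] == 1.0).all()

    def test_empty_function_flagged(self):
        st = toy_support_table()
        st.supports[:, 4] = False
        st.n_functions_supported = st.supports.sum(axis=1)
        pf = support_summary(st)["per_function"].set_index("function")
        assert pf.loc["f4", "empty"]
        assert pf.loc["f4", "proportion_supporting"] == 0.0


class TestDirectionalRecovery:
    def test_rare_supporters_dominate_when_only_rare_drives_functions(self):
        # beta_rare > 0, beta_abundant = 0: the rare subcommunity must both
        # contribute more supporting phylotypes and support at a higher
        # member fraction than the abundant subcommunity
        from raresoil.multifunctionality import compute_multifunctionality
        from raresoil.simulate import SimulationConfig, generate_dataset

        groups = ("archaea", "bacteria", "fungi", "protist")
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = SimulationConfig(
                n_samples=60,
                n_otus={g: 150 for g in groups},
                group_depths={g: 4000 for g in groups},
                lognormal_shape={g: (0.0, 4.0) for g in groups},
                beta_env=0.2, dropout=0.05,
                beta_rare=0.8, beta_abundant=0.0,
                seed=7000 + s,
            )
            ds = generate_dataset(cfg)
            classes = {g: classify_phylotypes(t) for g, t in ds.tables.items()}
            std = compute_multifunctionality(ds.functions).standardized
            st = supporting_phylotypes(ds.tables, classes, std)
            lab = np.asarray(st.label)
            supp_any = st.n_functions_supported > 0
            wins += int(
                ((lab == "rare") & supp_any).sum() > ((lab == "abundant") & supp_any).sum()
            )
        assert wins >= 18


class TestBreadthComparison:
    def test_identical_distributions(self):
        st = toy_support_table()
        # give both classes the same breadths
        st.n_functions_supported = np.array([1, 2] + [1, 2] * 4)
        res = compare_support_breadth(st)
        assert res["p"] > 0.05

    def test_separated_groups(self):
        ids = [f"a{i}" for i in range(20)] + [f"r{i}" for i in range(20)]
        st = SupportTable(
            phylotype_ids=ids,
            group=["bacteria"] * 40,
            label=["abundant"] * 20 + ["rare"] * 20,
            function_ids=["f0"],
            rho=np.full((40, 1), 0.5),
            p=np.full((40, 1), 0.001),
            supports=np.full((40, 1), True),
            n_functions_supported=np.array([5] * 20 + [1] * 20),
        )
        res = compare_support_breadth(st)
        assert res["mean_abundant"] > res["mean_rare"]
        assert res["p"] < 0.001

    def test_tie_corrected_oracle(self, rng):
        x = rng.integers(1, 5, size=30).astype(float)
        y = rng.integers(1, 6, size=25).astype(float)
        z, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 use_continuity=False, method="asymptotic")
        assert np.isclose(p, ref.pvalue, atol=1e-10)

    def test_empty_class_error(self):
        st = toy_support_table()
        st.label = ["rare"] * 10
        with pytest.raises(ValueError):
            compare_support_breadth(st)
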