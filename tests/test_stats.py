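import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dynconn.stats import (
    ancova_group_effect,
    bh_fdr,
    fdr_annotate,
    partial_spearman,
    sparsity_profile_group_effect,
    subgroup_contrasts,
)

from oracles import ancova_f_normal_equations, bh_stepup, partial_spearman_steps


def make_pheno(n_per_group=6, n_sites=2, seed=0, groups=("MDD", "HC")):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(groups):
        for i in range(n_per_group):
            rows.append(
                {
                    "subject_id": f"s{gi}{i:03d}",
                    "group": g,
                    "age": float(rng.uniform(20, 60)),
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "education": float(rng.uniform(8, 20)),
                    "mean_fd": float(rng.uniform(0.05, 0.3)),
                    "site": f"site{i % n_sites + 1}",
                }
            )
    return pd.DataFrame(rows)


class TestAncova:
    def test_identical_y_gives_f_zero_p_one(self):
        pheno = make_pheno()
        res = ancova_group_effect(np.full(len(pheno), 3.7), pheno)
        assert res.F == 0.0 and res.p == 1.0 and res.direction == 0

    def test_twelve_subject_fixture_matches_normal_equations(self):
        pheno = make_pheno(n_per_group=6, n_sites=2, seed=42)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(12) + (pheno["group"] == "MDD") * 0.8
        res = ancova_group_effect(y.to_numpy(), pheno)

        # independent design build: any coding spanning the same space
        X = np.column_stack(
            [
                np.ones(12),
                pheno["age"],
                (pheno["sex"] == "male").astype(float),
                pheno["education"],
                pheno["mean_fd"],
                (pheno["site"] == "site2").astype(float),
                (pheno["group"] == "MDD").astype(float),
            ]
        )
        F, df2, beta = ancova_f_normal_equations(y.to_numpy(), X, group_idx=6)
        assert res.F == pytest.approx(F, rel=1e-9)
        assert res.df2 == df2
        assert res.direction == np.sign(beta)
        assert res.p == pytest.approx(scipy.stats.f.sf(F, 1, df2), rel=1e-9)

    def test_reduces_to_one_way_anova_without_covariates(self):
        pheno = make_pheno(n_per_group=8, n_sites=1, seed=3)
        rng = np.random.default_rng(11)
        y = rng.standard_normal(16) + (pheno["group"] == "MDD") * 0.5
        res = ancova_group_effect(y.to_numpy(), pheno, covariates=(), site_col=None)
        a = y[pheno["group"] == "MDD"]
        b = y[pheno["group"] == "HC"]
        F, p = scipy.stats.f_oneway(a, b)
        assert res.F == pytest.approx(F, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_power_with_moderate_effect(self):
        # d = 0.5 shift, 100 per group, covariate effects present
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            pheno = make_pheno(n_per_group=100, n_sites=2, seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            y = (
                0.5 * (pheno["group"] == "MDD").to_numpy()
                + 0.02 * pheno["age"].to_numpy()
                + 0.3 * (pheno["sex"] == "male").to_numpy()
                + rng.standard_normal(len(pheno))
            )
            if ancova_group_effect(y, pheno).p < 0.05:
                hits += 1
        assert hits >= 0.90 * n_seeds

    def test_type_one_error_calibration_under_null(self):
        hits = 0
        n_seeds = 500
        for seed in range(n_seeds):
            pheno = make_pheno(n_per_group=30, n_sites=2, seed=seed)
            rng = np.random.default_rng(50_000 + seed)
            y = 0.02 * pheno["age"].to_numpy() + rng.standard_normal(len(pheno))
            if ancova_group_effect(y, pheno).p < 0.05:
                hits += 1
        rate = hits / n_seeds
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_seeds) <= rate <= (
            0.05 + 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        )

    def test_rank_deficient_design_names_collinear_columns(self):
        pheno = make_pheno()
        pheno["education"] = 2.0 * pheno["age"]
        with pytest.raises(ValueError, match="collinear") as err:
            ancova_group_effect(np.arange(len(pheno), dtype=float), pheno)
        assert "education" in str(err.value) or "age" in str(err.value)

    def test_single_group_site_is_not_identified(self):
        pheno = make_pheno(n_per_group=6, n_sites=2)
        pheno.loc[pheno["group"] == "HC", "site"] = "site1"
        pheno.loc[pheno["group"] == "MDD", "site"] = "site2"
        with pytest.raises(ValueError, match="site"):
            ancova_group_effect(np.arange(len(pheno), dtype=float), pheno)


class TestSparsityProfile:
    def test_constant_profile_equals_single_sparsity_test(self):
        pheno = make_pheno(n_per_group=10, seed=5)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(len(pheno))
        table = pd.DataFrame({0.1: y, 0.2: y, 0.3: y})
        avg, per = sparsity_profile_group_effect(table, pheno)
        single = ancova_group_effect(y, pheno)
        assert avg.F == pytest.approx(single.F)
        assert avg.sparsity == "averaged"

    def test_per_sparsity_matches_direct_ancova(self):
        pheno = make_pheno(n_per_group=10, seed=8)
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {s: rng.standard_normal(len(pheno)) for s in (0.1, 0.2, 0.3)}
        )
        avg, per = sparsity_profile_group_effect(table, pheno)
        for res, s in zip(per, table.columns):
            assert res.F == pytest.approx(ancova_group_effect(table[s], pheno).F)
            assert res.sparsity == s
        direct = ancova_group_effect(table.mean(axis=1).to_numpy(), pheno)
        assert avg.F == pytest.approx(direct.F)

    def test_missing_cells_are_an_error(self):
        pheno = make_pheno()
        table = pd.DataFrame({0.1: np.arange(12.0), 0.2: np.arange(12.0)})
        table.iloc[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sparsity_profile_group_effect(table, pheno)


class TestPartialSpearman:
    def test_monotone_function_gives_rho_one(self):
        x = np.linspace(0, 5, 20)
        res = partial_spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert res.p == 0.0

    def test_no_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(40)
        y = 0.4 * x + rng.standard_normal(40)
        res = partial_spearman(x, y)
        rho, p = scipy.stats.spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-10)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_ten_row_fixture_matches_step_by_step_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])
        Z = pd.DataFrame({"z1": np.arange(10.0), "z2": [0, 1] * 5})
        res = partial_spearman(x, y, Z)
        assert res.rho == pytest.approx(
            partial_spearman_steps(x, y, Z.to_numpy()), abs=1e-10
        )
        assert res.n_used == 10

    def test_listwise_deletion_of_missing_values(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6, 7, 8, 9, 10, 11])
        y = np.arange(11, dtype=float)
        res = partial_spearman(x, y)
        assert res.n_used == 10
        assert res.rho == pytest.approx(1.0)

    def test_unconfounded_after_adjustment(self):
        # x and y independent given z; strong z drives both
        rhos = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(400)
            x = 2.0 * z + rng.standard_normal(400)
            y = 2.0 * z + rng.standard_normal(400)
            res = partial_spearman(x, y, pd.DataFrame({"z": z}))
            rhos.append(res.rho)
        assert np.mean(np.abs(rhos)) < 0.05

    def test_constant_variable_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(12), np.arange(12.0))

    def test_too_few_cases_is_an_error(self):
        with pytest.raises(ValueError, match="complete cases"):
            partial_spearman(np.arange(5.0), np.arange(5.0))


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_stepup_example(self):
        assert bh_fdr([0.005, 0.03, 0.04]) == pytest.approx([0.015, 0.04, 0.04])

    def test_matches_oracle_and_exceeds_raw(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        assert adj == pytest.approx(bh_stepup(p), abs=1e-12)
        assert np.all(adj >= p) and np.all(adj <= 1)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(32)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        assert bh_fdr(p)[perm] == pytest.approx(bh_fdr(p[perm]))


def make_subgroup_pheno(n_fedn, n_nonfedn, n_hc, seed=0):
    pheno = make_pheno(n_per_group=1, seed=seed)  # template columns
    rng = np.random.default_rng(seed)
    rows = []
    labels = ["FEDN"] * n_fedn + ["nonFEDN"] * n_nonfedn + ["HC"] * n_hc
    for i, lab in enumerate(labels):
        rows.append(
            {
                "subject_id": f"s{i:03d}",
                "group": "HC" if lab == "HC" else "MDD",
                "fedn_status": lab if lab != "HC" else "not_applicable",
                "age": float(rng.uniform(20, 60)),
                "sex": "male" if rng.random() < 0.5 else "female",
                "education": float(rng.uniform(8, 20)),
                "mean_fd": float(rng.uniform(0.05, 0.3)),
                "site": f"site{i % 2 + 1}",
            }
        )
    return pd.DataFrame(rows)


class TestSubgroups:
    def test_family_of_nine_fdr_adjusted(self):
        pheno = make_subgroup_pheno(10, 10, 10, seed=1)
        rng = np.random.default_rng(2)
        metrics = pd.DataFrame(
            {m: rng.standard_normal(30) for m in ("tv", "tcc", "ctpl")}
        )
        res = subgroup_contrasts(metrics, pheno)
        assert len(res) == 9
        assert all(r.p_fdr >= r.p - 1e-12 for r in res)
        assert {r.contrast for r in res} == {
            "FEDN_vs_nonFEDN", "FEDN_vs_HC", "nonFEDN_vs_HC",
        }

    def test_null_subgroup_labels_reject_at_alpha(self):
        hits = 0
        n_seeds = 150
        for seed in range(n_seeds):
            pheno = make_subgroup_pheno(15, 15, 0, seed=seed)
            rng = np.random.default_rng(90_000 + seed)
            metrics = pd.DataFrame({"tv": rng.standard_normal(30)})
            res = subgroup_contrasts(
                metrics, pheno, pairs=(("FEDN", "nonFEDN"),)
            )
            if res[0].p < 0.05:
                hits += 1
        rate = hits / n_seeds
        assert 0.01 <= rate <= 0.10

    def test_shared_shift_pattern_versus_controls(self):
        # both patient subgroups shifted equally vs HC: the two vs-HC
        # contrasts should be significant, FEDN vs nonFEDN should not
        pattern_hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            pheno = make_subgroup_pheno(25, 25, 25, seed=seed)
            rng = np.random.default_rng(70_000 + seed)
            shift = (pheno["group"] == "MDD").to_numpy() * 1.2
            metrics = pd.DataFrame({"tv": shift + rng.standard_normal(75)})
            res = {r.contrast: r for r in subgroup_contrasts(metrics, pheno)}
            ok = (
                res["FEDN_vs_HC"].p_fdr < 0.05
                and res["nonFEDN_vs_HC"].p_fdr < 0.05
                and res["FEDN_vs_nonFEDN"].p_fdr > 0.05
            )
            pattern_hits += ok
        assert pattern_hits > n_seeds / 2

    def test_site_lacking_both_levels_is_dropped_with_warning(self, caplog):
        pheno = make_subgroup_pheno(8, 8, 8, seed=4)
        # push every FEDN subject out of site2
        pheno.loc[pheno["fedn_status"] == "FEDN", "site"] = "site1"
        rng = np.random.default_rng(5)
        metrics = pd.DataFrame({"tv": rng.standard_normal(24)})
        import logging

        with caplog.at_level(logging.WARNING, logger="dynconn.stats"):
            res = subgroup_contrasts(metrics, pheno, pairs=(("FEDN", "nonFEDN"),))
        assert "dropping site" in caplog.text
        assert res[0].n < 16


def test_fdr_annotate_preserves_order_and_metrics():
    pheno = make_pheno(n_per_group=8, seed=12)
    rng = np.random.default_rng(13)
    results = [
        ancova_group_effect(rng.standard_normal(16), pheno, metric_name=m)
        for m in ("a", "b", "c")
    ]
    annotated = fdr_annotate(results)
    assert [r.metric_name for r in annotated] == ["a", "b", "c"]
    assert np.allclose(
        [r.p_fdr for r in annotated], bh_stepup([r.p for r in results])
    )
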