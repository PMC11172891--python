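"""Tests for the differential-expression pipeline stages."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tearomics import (
    FilterConfig,
    ImputationConfig,
    ProteomeSimConfig,
    SignificanceCurveConfig,
    apply_vsn,
    filter_protein_groups,
    fit_moderated_t,
    fit_vsn,
    impute_downshift,
    run_proteome_pipeline,
    significance_call,
    simulate_proteome,
    stability_flags,
)
from tearomics.proteome import significance_threshold
from tearomics.simulate import child_seed

from conftest import make_annotation, make_protein_table


class TestFilter:
    def _toy(self):
        # 6 proteins x 8 samples (4 patients, 4 controls; alternating F/M)
        ann = make_annotation(4, 4)
        vals = np.full((6, 8), 20.0)
        vals[1, :] = np.nan  # nothing observed anywhere
        vals[2, 4:] = np.nan  # observed only in patients
        vals[3, ::2] = np.nan  # missing in all female samples
        table = make_protein_table(
            vals,
            peptide_counts=[1, 5, 5, 5, 5, 2],
            contaminant=[False, False, False, False, True, False],
            sample_ids=list(ann.sample_ids),
        )
        return table, ann

    def test_rule_by_rule_against_brute_force(self):
        table, ann = self._toy()
        cfg = FilterConfig(min_peptides=2, min_ids_per_group=2,
                           min_ids_female=2, min_ids_male=2)
        filtered, log = filter_protein_groups(table, ann, cfg)

        # independent brute-force application of the four rules
        obs = ~table.intensities.isna()
        pat = list(ann.samples_in(group="patient"))
        ctl = list(ann.samples_in(group="control"))
        fem = list(ann.samples_in(sex="female"))
        mal = list(ann.samples_in(sex="male"))
        expected = []
        for pid in table.protein_ids:
            if table.peptide_counts[pid] < 2:
                continue
            if table.contaminant[pid]:
                continue
            if obs.loc[pid, pat].sum() < 2 or obs.loc[pid, ctl].sum() < 2:
                continue
            if obs.loc[pid, fem].sum() < 2 or obs.loc[pid, mal].sum() < 2:
                continue
            expected.append(pid)
        assert list(filtered.protein_ids) == expected
        assert log["removed_min_peptides"] == 1
        assert log["removed_contaminant"] == 1
        assert log["removed_group_ids"] == 2  # all-missing + patients-only
        assert log["removed_sex_ids"] == 1

    def test_single_peptide_removed_first(self):
        table, ann = self._toy()
        _, log = filter_protein_groups(table, ann, FilterConfig(
            min_peptides=2, min_ids_per_group=0, min_ids_female=0, min_ids_male=0))
        assert log["removed_min_peptides"] == 1

    def test_group_identification_rule(self):
        """A protein seen in 7/16 controls but all patients fails the 8-per-group rule."""
        ann = make_annotation(16, 16)
        vals = np.full((1, 32), 20.0)
        vals[0, 16 + 7:] = np.nan  # 16 patient obs, 7 control obs
        table = make_protein_table(vals, sample_ids=list(ann.sample_ids))
        filtered, log = filter_protein_groups(table, ann, FilterConfig(
            min_ids_female=0, min_ids_male=0))
        assert filtered.n_proteins == 0
        assert log["removed_group_ids"] == 1

    def test_idempotent(self, default_proteome):
        table, ann, _ = default_proteome
        once, log1 = filter_protein_groups(table, ann)
        twice, log2 = filter_protein_groups(once, ann)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        assert log2["surviving"] == log1["surviving"]

    def test_threshold_exceeding_stratum_errors(self):
        table, ann = self._toy()
        with pytest.raises(ValueError, match="patients"):
            filter_protein_groups(table, ann, FilterConfig(min_ids_per_group=5))


class TestVSN:
    def _affine_table(self, seed=0, n_p=300, n_s=8):
        rng = np.random.default_rng(seed)
        ref = 2 ** rng.normal(20, 2, n_p)
        alpha = rng.uniform(0, 1e4, n_s)
        beta = rng.uniform(0.5, 2.0, n_s)
        X = ref[:, None] * beta[None, :] + alpha[None, :]
        return make_protein_table(X, scale="raw")

    def test_affine_samples_collapse_to_reference(self):
        """Exact affine transforms of one profile normalize to SD ~ 0."""
        table = self._affine_table()
        model = fit_vsn(table)
        out = apply_vsn(model, table)
        assert out.scale == "log2"
        assert out.intensities.std(axis=1).max() <= 1e-6

    def test_rank_preservation(self):
        table = self._affine_table(seed=1)
        model = fit_vsn(table)
        out = apply_vsn(model, table)
        for s in table.sample_ids:
            raw_rank = table.intensities[s].rank()
            norm_rank = out.intensities[s].rank()
            pd.testing.assert_series_equal(raw_rank, norm_rank)

    @pytest.mark.filterwarnings("ignore:vsn calibration did not converge")
    def test_stabilizes_heteroskedastic_noise(self):
        """Additive raw-scale noise: |residual|-vs-intensity trend shrinks vs plain log2."""
        rng = np.random.default_rng(4)
        n_p, n_s = 500, 10
        mu = 2 ** rng.uniform(12, 22, n_p)
        X = mu[:, None] * np.exp(rng.normal(0, 0.05, (n_p, n_s))) \
            + rng.normal(0, 2000, (n_p, n_s))
        X = np.clip(X, 1.0, None)
        table = make_protein_table(X, scale="raw")

        def trend(mat):
            resid = np.abs(mat - mat.mean(axis=1, keepdims=True)).mean(axis=1)
            level = mat.mean(axis=1)
            return abs(np.polyfit(level, resid, 1)[0] * level.std())

        log2_mat = np.log2(X)
        vsn_mat = apply_vsn(fit_vsn(table), table).intensities.to_numpy()
        assert trend(vsn_mat) < trend(log2_mat)

    def test_negative_intensity_rejected(self):
        table = self._affine_table()
        table.intensities.iloc[0, 0] = -5.0
        with pytest.raises(ValueError, match="negative"):
            fit_vsn(table)


class TestImputation:
    def test_no_missing_identity(self):
        table = make_protein_table(np.random.default_rng(0).normal(20, 2, (50, 6)))
        out = impute_downshift(table, ImputationConfig(), cycle_seed=1)
        pd.testing.assert_frame_equal(out, table.intensities)

    def test_downshift_moments(self):
        """mu=20, sigma=2: imputed draws have mean ~15.0 and SD ~0.6."""
        rng = np.random.default_rng(1)
        n_obs, n_miss = 2 * 10**5, 10**5
        col = np.concatenate([rng.normal(20, 2, n_obs), np.full(n_miss, np.nan)])
        table = make_protein_table(col[:, None])
        # second sample with no missing values to satisfy the table contract
        table.intensities["S02"] = 20.0
        table.intensities.loc[table.intensities.index[0], "S02"] = 21.0
        out = impute_downshift(table, ImputationConfig(width_factor=0.3,
                                                       downshift_factor=2.5),
                               cycle_seed=7)
        imputed = out["S01"].to_numpy()[n_obs:]
        obs = col[:n_obs]
        mu, sigma = obs.mean(), obs.std(ddof=1)
        exp_mean, exp_sd = mu - 2.5 * sigma, 0.3 * sigma
        se_mean = exp_sd / np.sqrt(n_miss)
        se_sd = exp_sd / np.sqrt(2 * n_miss)
        assert abs(imputed.mean() - exp_mean) < 3 * se_mean
        assert abs(imputed.std(ddof=1) - exp_sd) < 3 * se_sd

    def test_cycles_differ_only_at_masked_cells(self, default_proteome):
        table, ann, _ = default_proteome
        filtered, _ = filter_protein_groups(table, ann)
        mask = filtered.missing_mask.to_numpy()
        a = impute_downshift(filtered, cycle_seed=1).to_numpy()
        b = impute_downshift(filtered, cycle_seed=2).to_numpy()
        assert np.array_equal(a[~mask], b[~mask])
        assert not np.array_equal(a[mask], b[mask])

    def test_sample_with_too_few_observed_errors(self):
        vals = np.array([[20.0, np.nan], [np.nan, np.nan], [21.0, np.nan]])
        table = make_protein_table(vals)
        with pytest.raises(ValueError, match="fewer than 2"):
            impute_downshift(table)


class TestModeratedT:
    def test_no_moderation_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        ann = make_annotation(6, 6)
        X = pd.DataFrame(rng.normal(20, 1, (40, 12)),
                         index=[f"PG{i}" for i in range(40)],
                         columns=ann.sample_ids)
        res = fit_moderated_t(X, ann, d0_override=0.0)
        pat = list(ann.samples_in(group="patient"))
        ctl = list(ann.samples_in(group="control"))
        t_ref = sps.ttest_ind(X[pat], X[ctl], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_mod"], t_ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.table["p_raw"], t_ref.pvalue, rtol=1e-10)

    def test_posterior_variance_hand_formula(self):
        """d0=4, s0^2=1, d=2, s^2=2: posterior variance 8/6."""
        ann = make_annotation(2, 2)
        # craft one protein with residual variance exactly 2 (d = 2)
        X = pd.DataFrame([[19.0, 21.0, 20.0, 22.0]], index=["PG1"],
                         columns=ann.sample_ids)
        res = fit_moderated_t(X, ann, d0_override=4.0, s0sq_override=1.0)
        s2 = res.table["s2"].iloc[0]
        assert s2 == pytest.approx(2.0)
        lfc = res.table["log2fc"].iloc[0]
        s2_post = 8.0 / 6.0
        t_expected = lfc / np.sqrt(s2_post * (1 / 2 + 1 / 2))
        assert res.table["t_mod"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert res.table["df_total"].iloc[0] == pytest.approx(6.0)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: R limma's eBayes on the same matrix."""
        cfg = ProteomeSimConfig(n_proteins=80, frac_differential=0.2,
                                censor_midpoint=-1e6, censor_slope=1.0, seed=5)
        table, ann, _ = simulate_proteome(cfg)
        xpath = tmp_path / "X.tsv"
        gpath = tmp_path / "groups.txt"
        opath = tmp_path / "out.tsv"
        table.intensities.to_csv(xpath, sep="\t")
        gpath.write_text("\n".join(ann.table.loc[table.sample_ids, "group"]))
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{xpath}", sep="\\t", header=TRUE, row.names=1))
            groups <- scan("{gpath}", what=character(), quiet=TRUE)
            design <- model.matrix(~ 0 + factor(groups, levels=c("control","patient")))
            colnames(design) <- c("control","patient")
            fit <- eBayes(contrasts.fit(lmFit(x, design),
                          makeContrasts(patient - control, levels=design)))
            out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],
                              d0=fit$df.prior, s0sq=fit$s2.prior)
            write.table(out, "{opath}", sep="\\t", quote=FALSE)
        """)
        rfile = tmp_path / "check.R"
        rfile.write_text(script)
        subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
        ref = pd.read_csv(opath, sep="\t")
        res = fit_moderated_t(table.intensities, ann)
        assert res.d0_hat == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
        assert res.s0sq_hat == pytest.approx(ref["s0sq"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(res.table["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res.table["p_raw"], ref["p"], rtol=1e-8)

    def test_incomplete_matrix_rejected(self):
        ann = make_annotation(2, 2)
        X = pd.DataFrame(np.array([[1.0, 2.0, np.nan, 3.0]]), index=["PG1"],
                         columns=ann.sample_ids)
        with pytest.raises(ValueError, match="complete"):
            fit_moderated_t(X, ann)


class TestSignificanceCurve:
    def test_threshold_closed_form(self):
        cfg = SignificanceCurveConfig(p_max=0.05, lfc_asymptote=1.0, curve_factor=1.0)
        # c = curve_factor * sigma; pass sigma = 0.2 so c = 0.2, l = 1.2
        tau = significance_threshold([1.2], cfg, sigma=0.2)
        assert tau[0] == pytest.approx(0.05 * np.exp(-1.0), rel=1e-12)

    def test_never_significant_at_asymptote(self):
        tbl = pd.DataFrame({"log2fc": [1.0, -1.0, 0.5], "s2": 1.0, "t_mod": 0.0,
                            "df_total": 10.0, "p_raw": [0.0, 0.0, 0.0],
                            "p_adj": [0.0, 0.0, 0.0]},
                           index=["a", "b", "c"])
        from tearomics.datatypes import ModeratedTestResult
        res = ModeratedTestResult(tbl, d0_hat=1.0, s0sq_hat=1.0, n1=4, n2=4)
        sig = significance_call(res)
        assert not sig.any()

    def test_supremum_is_pmax(self):
        cfg = SignificanceCurveConfig()
        tau = significance_threshold([1e9], cfg, sigma=1.0)
        assert tau[0] == pytest.approx(cfg.p_max, rel=1e-6)
        tau_seq = significance_threshold(np.linspace(1.001, 50, 500), cfg, sigma=1.0)
        assert (np.diff(tau_seq) > 0).all()
        assert (tau_seq < cfg.p_max).all()

    def test_monotone_in_p_and_lfc(self):
        """Lower p_adj or larger |log2FC| never flips significant -> not."""
        from tearomics.datatypes import ModeratedTestResult

        rng = np.random.default_rng(0)
        lfc = rng.normal(0, 1.2, 300)
        p_adj = rng.random(300)
        tbl = pd.DataFrame({"log2fc": lfc, "s2": 1.0, "t_mod": 0.0,
                            "df_total": 10.0, "p_raw": p_adj, "p_adj": p_adj})
        res = ModeratedTestResult(tbl, 1.0, 1.0, 4, 4)
        sig1 = significance_call(res)
        tbl2 = tbl.copy()
        tbl2["p_adj"] = tbl2["p_adj"] * 0.5
        tbl2["log2fc"] = tbl2["log2fc"] * 1.5
        # same sigma reference must be used for a fair monotonicity check
        sigma = float(np.std(lfc, ddof=1))
        cfg = SignificanceCurveConfig()
        tau1 = significance_threshold(np.abs(lfc), cfg, sigma)
        tau2 = significance_threshold(np.abs(lfc * 1.5), cfg, sigma)
        mono = (p_adj * 0.5 <= tau2) | ~((p_adj <= tau1) & (np.abs(lfc) > 1))
        assert mono.all()


@pytest.fixture(scope="module")
def small_run():
    cfg = ProteomeSimConfig(n_proteins=400, seed=3)
    table, ann, truth = simulate_proteome(cfg)
    icfg = ImputationConfig(n_cycles=5, seed=3)
    de, report = run_proteome_pipeline(table, ann, imputation_cfg=icfg)
    return table, ann, truth, icfg, de, report


class TestStabilityAndPipeline:

    def test_stable_subset_of_significant(self, small_run):
        _, _, _, _, de, _ = small_run
        assert (de.table.loc[de.table["stable"], "significant"]).all()

    def test_single_cycle_stable_equals_significant(self):
        table, ann, _ = simulate_proteome(ProteomeSimConfig(n_proteins=300, seed=4))
        filtered, _ = filter_protein_groups(table, ann)
        de = stability_flags(filtered, ann, ImputationConfig(n_cycles=1, seed=4))
        pd.testing.assert_series_equal(de.table["stable"], de.table["significant"],
                                       check_names=False)

    def test_cycle_calls_match_manual_rerun(self, small_run):
        """Per-cycle oracle: recompute each cycle independently and compare."""
        table, ann, _, icfg, de, _ = small_run
        filtered, _ = filter_protein_groups(table, ann)
        for cycle in (1, 3, 5):
            seed_c = child_seed(icfg.seed, "impute-cycle", cycle)
            Xc = impute_downshift(filtered, icfg, cycle_seed=seed_c)
            res = fit_moderated_t(Xc, ann)
            calls = significance_call(res, intensities=Xc)
            pd.testing.assert_series_equal(de.cycle_calls[cycle], calls,
                                           check_names=False)

    def test_fully_observed_strong_protein_is_stable(self, small_run):
        _, _, _, _, de, _ = small_run
        table, ann, truth, icfg, de, _ = small_run
        filtered, _ = filter_protein_groups(table, ann)
        observed = ~filtered.missing_mask.any(axis=1)
        strong = de.table["significant"] & observed & (de.table["p_adj"] < 1e-6) \
            & (de.table["log2fc"].abs() > 2.5)
        if strong.any():
            assert de.table.loc[strong, "stable"].all()

    def test_pipeline_deterministic(self):
        cfg = ProteomeSimConfig(n_proteins=300, seed=6)
        icfg = ImputationConfig(n_cycles=3, seed=6)
        t1, a1, _ = simulate_proteome(cfg)
        de1, _ = run_proteome_pipeline(t1, a1, imputation_cfg=icfg)
        t2, a2, _ = simulate_proteome(cfg)
        de2, _ = run_proteome_pipeline(t2, a2, imputation_cfg=icfg)
        pd.testing.assert_frame_equal(de1.table, de2.table)

    def test_report_contents(self, small_run):
        _, _, _, _, de, report = small_run
        assert report["filter"]["input"] == 400
        assert "cycle_seeds" in report["imputation"]
        assert len(report["imputation"]["cycle_seeds"]) == 5
        assert report["n_stable"] == de.n_stable
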