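"""eQTL scan: OLS oracle equivalence, MAF/cis boundaries, BH FDR, hotspots."""

import numpy as np
import pandas as pd
import pytest

from popdiff.data_model import PopulationPanel
from popdiff.eqtl import (
    ExpressionMatrix,
    classify_cis_trans,
    filter_maf,
    fit_eqtl,
    hotspot_counts,
    population_design,
    scan,
    threshold_and_fdr,
    transcription_ratios,
)

from conftest import make_matrix


def ols_oracle(y, X):
    """Closed-form normal-equations OLS, independent of the package path."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    from scipy import stats

    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, t, p


class TestFitEqtl:
    def test_noiseless_signal_recovered_exactly(self):
        dosage = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=float)
        expr = 2.0 * dosage
        cov = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        beta, t, p = fit_eqtl(dosage, expr, np.column_stack([np.ones(10), cov]))
        assert beta == pytest.approx(2.0)
        assert p < 1e-12

    def test_six_sample_fixture_matches_closed_form_ols(self):
        dosage = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        expr = np.array([1.0, 1.2, 2.1, 1.9, 3.0, 3.2])
        X = np.column_stack([np.ones(6), dosage])
        b_exp, t_exp, p_exp = ols_oracle(expr, X)
        beta, t, p = fit_eqtl(dosage, expr, covariates=None)
        assert beta == pytest.approx(b_exp[1])
        assert t == pytest.approx(t_exp[1])
        assert p == pytest.approx(p_exp[1])

    def test_with_population_covariate_matches_full_ols(self):
        rng = np.random.default_rng(5)
        n = 40
        dosage = rng.integers(0, 3, size=n).astype(float)
        pop = (np.arange(n) >= n // 2).astype(float)
        expr = 0.7 * dosage + 1.5 * pop + rng.normal(size=n)
        C = np.column_stack([np.ones(n), pop])
        X = np.column_stack([C, dosage])
        b_exp, t_exp, p_exp = ols_oracle(expr, X)
        beta, t, p = fit_eqtl(dosage, expr, C)
        assert beta == pytest.approx(b_exp[-1])
        assert t == pytest.approx(t_exp[-1])
        assert p == pytest.approx(p_exp[-1])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, reps = 30, 2000
        hits = 0
        for _ in range(reps):
            dosage = rng.integers(0, 3, size=n).astype(float)
            expr = rng.normal(size=n)
            _, _, p = fit_eqtl(dosage, expr)
            hits += p < 0.05
        frac = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(frac - 0.05) < 4 * se

    def test_collinear_dosage_rejected(self):
        pop = np.array([0.0] * 5 + [1.0] * 5)
        dosage = 2 * pop  # constant within strata
        with pytest.raises(ValueError, match="collinear"):
            fit_eqtl(dosage, np.random.default_rng(0).normal(size=10),
                     np.column_stack([np.ones(10), pop]))


class TestMafFilter:
    @pytest.mark.parametrize(
        "freq,kept",
        [(0.04, False), (0.05, False), (0.06, True), (0.5, True), (0.96, False)],
    )
    def test_strict_boundary(self, freq, kept):
        n_hap = 100
        row = np.zeros(n_hap, dtype=np.int8)
        row[: int(round(freq * n_hap))] = 1
        matrix, _ = make_matrix([row], ["X"] * (n_hap // 2))
        out = filter_maf(matrix, 0.05)
        assert (out.n_variants == 1) is kept


class TestCisTrans:
    @pytest.mark.parametrize(
        "vc,vp,fc,fp,expected",
        [
            ("chr1", 5_000_000, "chr1", 4_000_000, "cis"),   # exactly 1 Mb
            ("chr1", 5_000_001, "chr1", 4_000_000, "trans"),  # 1 Mb + 1
            ("chr1", 100, "chr2", 100, "trans"),
        ],
    )
    def test_distance_rule(self, vc, vp, fc, fp, expected):
        assert classify_cis_trans(vc, vp, fc, fp) == expected


class TestThresholdAndFdr:
    @staticmethod
    def bh_oracle(pvals):
        """Brute-force BH: largest k with p_(k) <= k*alpha/m defines the
        rejection set; adjusted value is min over j>=k of m*p_(j)/j."""
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, m * pvals[order[rank - 1]] / rank)
            adj[order[rank - 1]] = running
        return np.minimum(adj, 1.0)

    def make_records(self, pvals, kind):
        return pd.DataFrame(
            {
                "variant_key": [f"v{i}" for i in range(len(pvals))],
                "feature": [f"f{i}" for i in range(len(pvals))],
                "beta": 0.0,
                "tstat": 0.0,
                "p": pvals,
                "kind": kind,
            }
        )

    def test_cis_family_cutoff_then_bh(self):
        """(0.001, 0.02, 0.04, 0.8) as cis tests: 0.8 falls to the p<0.05
        cutoff, BH runs on the retained three with m=3."""
        out = threshold_and_fdr(self.make_records([0.001, 0.02, 0.04, 0.8], "cis"))
        got = out.set_index("variant_key")["fdr"]
        assert got["v0"] == pytest.approx(0.003)
        assert got["v1"] == pytest.approx(0.03)
        assert got["v2"] == pytest.approx(0.04)
        assert "v3" not in got.index

    def test_bh_matches_oracle_on_random_families(self):
        rng = np.random.default_rng(21)
        pvals = rng.uniform(0.0001, 0.0099, size=25)  # all pass the trans cutoff
        out = threshold_and_fdr(self.make_records(pvals, "trans"))
        expect = self.bh_oracle(pvals)
        got = out.set_index("variant_key")["fdr"]
        for i, p in enumerate(pvals):
            assert got[f"v{i}"] == pytest.approx(expect[i])

    def test_bh_adjusted_values_on_full_four_element_family(self):
        # the classical worked example: (0.001, 0.02, 0.04, 0.8) with m=4
        adj = self.bh_oracle(np.array([0.001, 0.02, 0.04, 0.8]))
        assert np.allclose(adj, [0.004, 0.04, 0.8 / 15, 0.8])

    def test_single_cis_test_keeps_its_p_as_fdr(self):
        out = threshold_and_fdr(self.make_records([0.04], "cis"))
        assert out["fdr"].iloc[0] == pytest.approx(0.04)
        assert bool(out["significant"].iloc[0])

    def test_trans_above_cutoff_discarded_before_fdr(self):
        out = threshold_and_fdr(self.make_records([0.02, 0.005], "trans"))
        assert len(out) == 1
        assert out["p"].iloc[0] == pytest.approx(0.005)
        # and m reflects the retained family only
        assert out["fdr"].iloc[0] == pytest.approx(0.005)

    def test_cis_and_trans_adjusted_separately(self):
        recs = pd.concat(
            [self.make_records([0.04, 0.045], "cis"), self.make_records([0.004], "trans")],
            ignore_index=True,
        )
        out = threshold_and_fdr(recs)
        cis = out[out["kind"] == "cis"]["fdr"].to_numpy()
        assert np.allclose(np.sort(cis), [0.045, 0.045])
        assert out[out["kind"] == "trans"]["fdr"].iloc[0] == pytest.approx(0.004)

    def test_empty_family_yields_empty_output(self):
        out = threshold_and_fdr(self.make_records([], "cis"))
        assert out.empty


class TestScan:
    def test_scan_matches_per_pair_fit(self, tiny_dataset):
        """The vectorised all-pairs scan equals looping fit_eqtl per pair."""
        ds = tiny_dataset
        analyzed = filter_maf(ds.matrix)
        rec = scan(analyzed, ds.expression, ds.panel)
        samples = [s for s in ds.expression.samples if s in set(analyzed.sample_ids)]
        C = population_design(ds.panel, samples)
        cols = [analyzed.sample_ids.index(s) for s in samples]
        dos = analyzed.dosages()[:, cols]
        rng = np.random.default_rng(0)
        take = rng.choice(len(rec), size=25, replace=False)
        key_row = {v.key: i for i, v in enumerate(analyzed.variants)}
        for _, r in rec.iloc[take].iterrows():
            d = dos[key_row[r["variant_key"]]]
            y = ds.expression.values.loc[r["feature"], samples].to_numpy()
            beta, t, p = fit_eqtl(d, y, C)
            assert r["beta"] == pytest.approx(beta, rel=1e-8)
            assert r["tstat"] == pytest.approx(t, rel=1e-8)
            assert r["p"] == pytest.approx(p, rel=1e-6, abs=1e-300)

    def test_population_shift_without_covariate_inflates_p(self):
        """Population-shifted null: with the covariate p-values are uniform;
        omitting it inflates small p-values (why the covariate exists)."""
        rng = np.random.default_rng(33)
        n_var, n_feat = 60, 40
        n_a = n_b = 60
        sample_pops = ["A"] * n_a + ["B"] * n_b
        # population-differentiated genotypes
        freqs = np.column_stack(
            [rng.uniform(0.1, 0.5, n_var), rng.uniform(0.5, 0.9, n_var)]
        )
        rows = np.zeros((n_var, 2 * (n_a + n_b)), dtype=np.int8)
        for i in range(n_var):
            f = np.repeat(freqs[i], (2 * n_a, 2 * n_b))
            rows[i] = rng.uniform(size=2 * (n_a + n_b)) < f
        matrix, panel = make_matrix(rows, sample_pops)
        # expression: population shift only, independent of genotype
        shift = rng.normal(0, 1.0, size=n_feat)
        pop_of = np.array([0] * n_a + [1] * n_b)
        Y = shift[:, None] * pop_of[None, :] + rng.normal(size=(n_feat, n_a + n_b))
        anchors = {f"f{j}": ("chrX", 1) for j in range(n_feat)}  # all trans
        expr = ExpressionMatrix(
            values=pd.DataFrame(Y, index=list(anchors), columns=matrix.sample_ids),
            anchors=anchors,
        )
        with_cov = scan(matrix, expr, panel, use_covariate=True)
        without = scan(matrix, expr, panel, use_covariate=False)
        from scipy import stats

        ks = stats.kstest(with_cov["p"], "uniform")
        assert ks.pvalue > 0.01  # uniformity not rejected
        frac_small_with = (with_cov["p"] < 0.01).mean()
        frac_small_without = (without["p"] < 0.01).mean()
        assert frac_small_without > 5 * frac_small_with


class TestHotspots:
    def test_planted_hub_tops_the_table(self, small_dataset):
        ds = small_dataset
        rec = threshold_and_fdr(scan(filter_maf(ds.matrix), ds.expression, ds.panel))
        hot = hotspot_counts(rec)
        hub = ds.truth.attrs["hub"]
        driver_rank = hot.index[hot["variant_key"] == hub["driver"]]
        assert len(driver_rank) == 1
        # the driver (or a perfect-LD block mate) dominates; the driver's
        # trans count must be near the planted target count and within the
        # top of the table
        n_trans = int(hot.loc[hot["variant_key"] == hub["driver"], "n_trans"].iloc[0])
        assert n_trans >= hub["n_targets"] * 0.6
        assert driver_rank[0] < 10

    def test_empty_records_give_empty_table(self):
        empty = pd.DataFrame(
            columns=["variant_key", "feature", "beta", "tstat", "p", "kind",
                     "fdr", "significant"]
        )
        assert hotspot_counts(empty).empty


class TestTranscriptionRatios:
    def test_ratios_sum_to_one_per_gene_and_zero_total_guarded(self):
        vals = pd.DataFrame(
            {"s1": [2.0, 2.0, 0.0], "s2": [1.0, 3.0, 0.0]},
            index=["e1", "e2", "e3"],
        )
        fg = {"e1": "g1", "e2": "g1", "e3": "g2"}
        ratios = transcription_ratios(vals, fg)
        assert ratios.loc["e1", "s1"] == pytest.approx(0.5)
        assert ratios.loc[["e1", "e2"], "s2"].sum() == pytest.approx(1.0)
        assert ratios.loc["e3"].isna().all()  # zero denominator dropped
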