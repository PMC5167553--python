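"""Hudson estimator components, ratio-of-averages, windowing."""

import numpy as np
import pytest

from popdiff.data_model import population_frequencies
from popdiff.fst import (
    FstComponents,
    fst_region,
    fst_structural,
    hudson_components,
    hudson_components_arrays,
    per_variant_fst,
    window_fst_from_components,
    windowed_fst,
)

from conftest import make_matrix


def brute_force_fst(count_table, corrected):
    """Independent ratio-of-averages oracle from raw allele-count tables.

    count_table rows: (alt1, n1, alt2, n2).  Written directly from the
    estimator definition, without the package's vectorised helpers.
    """
    snum = sden = 0.0
    for alt1, n1, alt2, n2 in count_table:
        p1, p2 = alt1 / n1, alt2 / n2
        num = (p1 - p2) ** 2
        if corrected:
            num -= p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        snum += num
        sden += den
    return snum / sden if sden > 0 else float("nan")


class TestHudsonComponents:
    def test_fixed_difference_gives_one(self):
        c = hudson_components(1.0, 100, 0.0, 100, corrected=True)
        assert c.num == pytest.approx(1.0)
        assert c.den == pytest.approx(1.0)
        assert c.ratio == pytest.approx(1.0)

    def test_equal_intermediate_frequencies_corrected_value(self):
        # p1=p2=0.5, n=100 each: num = -0.25/99 - 0.25/99, den = 0.5
        c = hudson_components(0.5, 100, 0.5, 100, corrected=True)
        assert c.num == pytest.approx(-2 * 0.25 / 99)
        assert c.den == pytest.approx(0.5)
        assert c.ratio == pytest.approx(-0.0101010101)

    def test_equal_frequencies_uncorrected_is_zero(self):
        c = hudson_components(0.37, 50, 0.37, 80, corrected=False)
        assert c.num == 0.0

    def test_corrected_requires_two_called_haplotypes(self):
        with pytest.raises(ValueError):
            hudson_components(0.5, 1, 0.5, 100, corrected=True)

    def test_uncorrected_single_variant_in_unit_interval(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(size=200)
        p2 = rng.uniform(size=200)
        num, den = hudson_components_arrays(p1, None, p2, None, corrected=False)
        ratio = num[den > 0] / den[den > 0]
        assert (ratio >= 0).all() and (ratio <= 1).all()

    def test_corrected_never_exceeds_one(self):
        rng = np.random.default_rng(2)
        p1, p2 = rng.uniform(size=500), rng.uniform(size=500)
        num, den = hudson_components_arrays(
            p1, np.full(500, 30), p2, np.full(500, 40), corrected=True
        )
        ratio = num[den > 0] / den[den > 0]
        assert (ratio <= 1 + 1e-12).all()


class TestFstRegion:
    def test_ratio_of_averages_arithmetic(self):
        comps = [
            FstComponents(0.1, 0.4, False),
            FstComponents(0.3, 0.6, False),
        ]
        est = fst_region(comps)
        assert est.value == pytest.approx(0.4 / 1.0)
        # NOT the mean of per-variant ratios
        mean_of_ratios = np.mean([0.1 / 0.4, 0.3 / 0.6])
        assert est.value != pytest.approx(mean_of_ratios)

    def test_single_component_equals_its_ratio(self):
        est = fst_region([FstComponents(0.12, 0.3, False)])
        assert est.value == pytest.approx(0.4)

    def test_all_zero_denominators_undefined(self):
        est = fst_region([FstComponents(0.0, 0.0, False)] * 3)
        assert not est.defined

    def test_nan_components_are_dropped_from_sums(self):
        num = np.array([0.1, np.nan, 0.3])
        den = np.array([0.4, np.nan, 0.6])
        est = fst_region((num, den))
        assert est.value == pytest.approx(0.4)
        assert est.n_variants == 2

    def test_matches_brute_force_oracle_on_count_tables(self):
        rng = np.random.default_rng(42)
        for corrected in (False, True):
            table = []
            for _ in range(20):
                n1, n2 = 2 * rng.integers(5, 30), 2 * rng.integers(5, 30)
                table.append((int(rng.integers(0, n1 + 1)), n1, int(rng.integers(0, n2 + 1)), n2))
            p1 = np.array([a / n for a, n, _, _ in table])
            n1 = np.array([n for _, n, _, _ in table])
            p2 = np.array([a / n for _, _, a, n in table])
            n2 = np.array([n for _, _, _, n in table])
            num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=corrected)
            assert fst_region((num, den)).value == pytest.approx(
                brute_force_fst(table, corrected)
            )


class TestWindowedFst:
    def test_trailing_remnant_excluded(self):
        # chrom 25,000 bp, 10 kb windows: exactly 2, variants >= 20 kb ignored
        pos = np.array([500.0, 10_500.0, 24_000.0])
        num = np.array([0.5, 0.2, 0.9])
        den = np.array([1.0, 1.0, 1.0])
        fst, nvar = window_fst_from_components(pos, num, den, 10_000, 25_000)
        assert fst.shape == (2,)
        assert nvar.tolist() == [1, 1]
        assert fst[0] == pytest.approx(0.5)

    def test_identical_frequencies_give_zero_windows(self):
        rows = [[0, 1, 0, 1]] * 4  # same haplotypes in both populations
        matrix, panel = make_matrix(rows, ["X", "Y"], start_pos=100)
        ests = windowed_fst(matrix, panel, "X", "Y", 1_000, 2_000, corrected=False)
        assert len(ests) == 2
        assert ests[0].value == pytest.approx(0.0)
        assert not ests[1].defined  # no variants there

    def test_windows_with_no_usable_variants_reported_undefined(self):
        fst, nvar = window_fst_from_components(
            np.array([100.0]), np.array([0.1]), np.array([0.2]), 1_000, 5_000
        )
        assert fst.shape == (5,)
        assert np.isnan(fst[1:]).all()

    def test_monomorphic_in_both_contributes_nothing(self):
        pos = np.array([10.0, 20.0])
        num, den = hudson_components_arrays(
            np.array([0.0, 0.5]), None, np.array([0.0, 0.1]), None, corrected=False
        )
        fst, nvar = window_fst_from_components(pos, num, den, 1_000, 1_000)
        only = hudson_components(0.5, None, 0.1, None, corrected=False)
        assert fst[0] == pytest.approx(only.num / only.den)


class TestUnbiasedness:
    def test_corrected_mean_near_zero_on_panmictic_resampling(self):
        """Two same-sized samples from one panmictic pool: corrected
        genome-wide estimate ~ 0, uncorrected strictly positive."""
        rng = np.random.default_rng(7)
        n_reps, n_var, n_hap = 40, 300, 60
        corrected_vals, uncorrected_vals = [], []
        for _ in range(n_reps):
            p = rng.uniform(0.05, 0.95, size=n_var)
            pool = (rng.uniform(size=(n_var, 2 * n_hap)) < p[:, None]).astype(float)
            a, b = pool[:, :n_hap], pool[:, n_hap:]
            p1, p2 = a.mean(axis=1), b.mean(axis=1)
            n_arr = np.full(n_var, n_hap)
            for corrected, sink in ((True, corrected_vals), (False, uncorrected_vals)):
                num, den = hudson_components_arrays(
                    p1, n_arr, p2, n_arr, corrected=corrected
                )
                sink.append(num.sum() / den.sum())
        corrected_vals = np.array(corrected_vals)
        se = corrected_vals.std(ddof=1) / np.sqrt(n_reps)
        assert abs(corrected_vals.mean()) < 3 * se
        assert np.mean(uncorrected_vals) > 0


class TestStructural:
    def test_fixed_sv_allele_gives_one(self):
        rows = [[1, 1, 1, 1, 0, 0, 0, 0]]
        matrix, panel = make_matrix(rows, ["A", "A", "B", "B"])
        per_allele, pooled = fst_structural(matrix, panel, "A", "B")
        assert per_allele[0].value == pytest.approx(1.0)
        assert pooled.value == pytest.approx(1.0)

    def test_rare_in_both_gives_small_negative_corrected(self):
        n = 504
        row = np.zeros(4 * n, dtype=np.int8)
        row[0] = 1  # one alt haplotype in each population
        row[2 * n] = 1
        matrix, panel = make_matrix([row], ["A"] * n + ["B"] * n)
        per_allele, _ = fst_structural(matrix, panel, "A", "B")
        assert per_allele[0].value < 0
        assert per_allele[0].value == pytest.approx(0, abs=0.01)

    def test_pooled_is_ratio_of_averages_not_mean(self, tiny_dataset):
        ds = tiny_dataset
        per_allele, pooled = fst_structural(ds.matrix, ds.panel, "AFR", "EUR")
        p1, n1 = population_frequencies(ds.matrix, ds.panel, "AFR")
        p2, n2 = population_frequencies(ds.matrix, ds.panel, "EUR")
        num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=True)
        assert pooled.value == pytest.approx(np.nansum(num) / np.nansum(den))


def test_per_variant_fst_matches_component_ratio(tiny_dataset):
    ds = tiny_dataset
    vals = per_variant_fst(ds.matrix, ds.panel, "AFR", "EAS")
    p1, n1 = population_frequencies(ds.matrix, ds.panel, "AFR")
    p2, n2 = population_frequencies(ds.matrix, ds.panel, "EAS")
    num, den = hudson_components_arrays(p1, n1, p2, n2)
    ok = den > 0
    assert np.allclose(vals[ok], num[ok] / den[ok], equal_nan=True)
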