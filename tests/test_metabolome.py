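"""FI-MS processing, modified z-scores, pathway counting and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from tscreen.metabolome import (
    MetaboliteMatrix,
    PathwayMap,
    Spectrum,
    annotate_peaks,
    compare_pcc_groups,
    correlation_matrix,
    enrichment_test,
    mod_z,
    pathway_response,
    pick_peaks,
    resolve_annotations,
    sum_top_spectra,
)


def _gaussian_spectrum(centers, heights, sigma=0.01, mz=None):
    mz = np.arange(100.0, 200.0, 0.002) if mz is None else mz
    inten = np.zeros_like(mz)
    for c, h in zip(centers, heights):
        inten += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return Spectrum(mz, inten)


class TestSumTopSpectra:
    def test_identical_spectra_scale(self):
        s = _gaussian_spectrum([150.0], [2000.0])
        out = sum_top_spectra([Spectrum(s.mz, s.intensity) for _ in range(10)], 10)
        assert np.allclose(out.intensity, 10 * s.intensity)

    def test_low_tic_spectra_excluded(self):
        big = [_gaussian_spectrum([150.0], [2000.0]) for _ in range(10)]
        small = [_gaussian_spectrum([150.0], [1.0]) for _ in range(2)]
        out = sum_top_spectra(big + small, 10)
        assert np.allclose(out.intensity, sum_top_spectra(big, 10).intensity)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        spectra = [
            _gaussian_spectrum([120.0 + i], [float(rng.uniform(1e3, 1e4))])
            for i in range(12)
        ]
        a = sum_top_spectra(spectra, 10)
        b = sum_top_spectra(spectra[::-1], 10)
        assert np.allclose(a.intensity, b.intensity)

    def test_fewer_than_n_warns(self):
        with pytest.warns(UserWarning, match="summing all"):
            sum_top_spectra([_gaussian_spectrum([150.0], [2000.0])], 10)


def oracle_prominence(y, i):
    """Brute-force topographic prominence of the local maximum at i."""
    peak = y[i]
    left_min = peak
    j = i - 1
    best_left = None
    while j >= 0:
        left_min = min(left_min, y[j])
        if y[j] > peak:
            best_left = left_min
            break
        j -= 1
    if best_left is None:
        best_left = left_min
    right_min = peak
    j = i + 1
    best_right = None
    while j < len(y):
        right_min = min(right_min, y[j])
        if y[j] > peak:
            best_right = right_min
            break
        j += 1
    if best_right is None:
        best_right = right_min
    return peak - max(best_left, best_right)


def oracle_peaks(spec, min_height, min_prom):
    y = spec.intensity
    out = []
    for i in range(1, len(y) - 1):
        if y[i - 1] < y[i] and y[i] > y[i + 1]:
            if y[i] >= min_height and oracle_prominence(y, i) >= min_prom:
                out.append(i)
    return out


class TestPickPeaks:
    def test_flat_spectrum_no_peaks(self):
        s = Spectrum(np.arange(100.0, 110.0, 0.01), np.full(1000, 10.0))
        assert pick_peaks(s).empty

    def test_single_gaussian_single_apex(self):
        s = _gaussian_spectrum([150.0], [5000.0])
        peaks = pick_peaks(s)
        assert len(peaks) == 1
        assert peaks["mz"].iloc[0] == pytest.approx(150.0, abs=0.002)

    def test_low_prominence_shoulder_suppressed(self):
        # a 400-prominence shoulder on a large peak is not reported
        s = _gaussian_spectrum([150.0, 150.03], [5000.0, 400.0], sigma=0.01)
        peaks = pick_peaks(s)
        oracle = oracle_peaks(s, 1000, 500)
        assert len(peaks) == len(oracle)

    def test_matches_bruteforce_oracle_on_random_spectra(self):
        rng = np.random.default_rng(77)
        mz = np.arange(0.0, 60.0, 0.05)
        for _ in range(100):
            n_pk = int(rng.integers(1, 8))
            y = rng.uniform(0, 600, mz.size)
            for c, h in zip(rng.uniform(5, 55, n_pk), rng.uniform(500, 6000, n_pk)):
                y += h * np.exp(-0.5 * ((mz - c) / 0.3) ** 2)
            s = Spectrum(mz, y)
            got = pick_peaks(s)
            want = oracle_peaks(s, 1000, 500)
            assert np.allclose(np.sort(got["mz"]), np.sort(mz[want]))


class TestAnnotatePeaks:
    GLUCOSE = {"glucose": 180.06339}

    def test_within_tolerance_annotated(self):
        peaks = pd.DataFrame({"mz": [179.0570], "height": [5000.0]})
        ann = annotate_peaks(peaks, self.GLUCOSE, "negative")
        assert list(ann["metabolite"]) == ["glucose"]
        assert ann["delta_mda"].iloc[0] == pytest.approx(0.886, abs=0.05)

    def test_beyond_tolerance_unannotated(self):
        peaks = pd.DataFrame({"mz": [179.0600], "height": [5000.0]})
        assert annotate_peaks(peaks, self.GLUCOSE, "negative").empty

    def test_dual_polarity_resolved_to_higher_peak(self):
        neg = annotate_peaks(
            pd.DataFrame({"mz": [179.0561], "height": [10000.0]}),
            self.GLUCOSE, "negative",
        )
        pos = annotate_peaks(
            pd.DataFrame({"mz": [181.0706], "height": [4000.0]}),
            self.GLUCOSE, "positive",
        )
        res = resolve_annotations(neg, pos)
        assert len(res) == 1
        assert res["polarity"].iloc[0] == "negative"
        assert res["height"].iloc[0] == 10000.0

    def test_isobars_flagged_ambiguous(self):
        masses = {"threonine": 119.05824, "homoserine": 119.05824}
        peaks = pd.DataFrame({"mz": [118.0510], "height": [3000.0]})
        ann = annotate_peaks(peaks, masses, "negative")
        assert len(ann) == 2 and ann["ambiguous"].all()

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaks(
                pd.DataFrame({"mz": [], "height": []}),
                [("x", 100.0), ("x", 101.0)], "negative",
            )


class TestModZ:
    @staticmethod
    def _matrix(x_norm_row, sigma=1e-9):
        # control is the first strain (x_norm = 0 by construction)
        x = pd.DataFrame(
            [2.0 ** np.asarray(x_norm_row)],
            index=["m1"],
            columns=[f"s{i}" for i in range(len(x_norm_row))],
        )
        return MetaboliteMatrix(x, x * 0 + sigma, "s0")

    def test_worked_example(self):
        z = mod_z(self._matrix([0.0, 1.0, 2.0, 3.0, 10.0]))
        expected = [-1.349, -0.6745, 0.0, 0.6745, 5.396]
        assert np.allclose(z.modz.loc["m1"], expected, atol=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(4)
        row = rng.normal(0, 2, 9)
        z1 = mod_z(self._matrix(row))
        z2 = mod_z(self._matrix(row + 7.0))
        # adding a constant in log space multiplies x; the control shifts
        # with it, so x_norm and hence modz are unchanged
        m = self._matrix(row)
        m2 = MetaboliteMatrix(m.x * 2**7, m.sigma_x, "s0")
        assert np.allclose(mod_z(m2).modz, z1.modz)

    def test_median_strain_scores_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            row = rng.normal(0, 1, 7)
            z = mod_z(self._matrix(row)).modz.loc["m1"]
            assert z.min() <= 0 <= z.max()
            assert (z == 0).any() or np.isclose(z, 0).any() or len(row) % 2 == 0

    def test_mad_zero_flagged(self):
        z = mod_z(self._matrix([0.0, 0.0, 0.0, 0.0, 5.0]))
        assert z.undefined_metabolites == ["m1"]
        assert z.modz.loc["m1"].isna().all()

    def test_error_propagation_formula(self):
        x = pd.DataFrame(
            [[1.0, 2.0, 4.0, 8.0, 3.0]], index=["m1"],
            columns=[f"s{i}" for i in range(5)],
        )
        sx = x * 0.1
        z = mod_z(MetaboliteMatrix(x, sx, "s0"))
        mad = (np.log2(x.iloc[0] / 1.0) - np.log2(x.iloc[0] / 1.0).median()).abs().median()
        expected = 0.6745 * (np.sqrt(0.1**2 + 0.1**2) / np.log(2)) / mad
        assert z.sigma_modz.loc["m1", "s1"] == pytest.approx(expected)

    def test_missing_control_raises(self):
        m = self._matrix([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            mod_z(MetaboliteMatrix(m.x, m.sigma_x, "nope"))


class TestPathwayResponse:
    def _toy(self):
        modz = pd.DataFrame(
            {"str1": [5.0, 0.0, 0.0], "str2": [0.0, 0.0, 0.0]},
            index=["metA", "metB", "metC"],
        )
        pmap = PathwayMap(
            {"metA": {"pw1"}, "metB": {"pw2"}, "metC": {"pw1", "pw2"}},
            gene_target_pathway={"geneX": "pw1"},
            gene_substrate={"geneX": "metA"},
        )
        return modz, pmap

    def test_no_increases_all_zero(self):
        modz, pmap = self._toy()
        resp = pathway_response(modz * 0.0, pmap)
        assert (resp["counts"].to_numpy() == 0).all()

    def test_single_planted_increase(self):
        modz, pmap = self._toy()
        resp = pathway_response(modz, pmap, strain_genes={"str1": "geneX"})
        assert resp["counts"].loc["str1", "pw1"] == 1
        assert resp["counts"].drop(index="str1").to_numpy().sum() == 0
        assert resp["pathways_per_strain"]["str1"] == 1
        assert resp["strains_per_pathway"]["pw1"] == 1
        assert bool(resp["target_response"]["str1"])
        assert bool(resp["substrate_increase"]["str1"])

    def test_multi_membership_counts_both(self):
        modz, pmap = self._toy()
        modz.loc["metC", "str2"] = 4.0
        resp = pathway_response(modz, pmap)
        assert resp["counts"].loc["str2", "pw1"] == 1
        assert resp["counts"].loc["str2", "pw2"] == 1

    def test_unmapped_metabolite_warned(self):
        modz, pmap = self._toy()
        modz.loc["metX"] = [4.0, 0.0]
        with pytest.warns(UserWarning, match="unmapped"):
            resp = pathway_response(modz, pmap)
        assert resp["counts"].loc["str1", "unmapped"] == 1


class TestCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        z = pd.DataFrame({"a": a, "b": -a})
        pcc = correlation_matrix(z)
        assert pcc.loc["a", "a"] == pytest.approx(1.0)
        assert pcc.loc["a", "b"] == pytest.approx(-1.0)

    def test_planted_correlated_pair_above_median(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(0, 2, 50)
        z = pd.DataFrame(
            {f"s{i}": rng.normal(0, 1, 50) for i in range(8)}
        )
        z["p1"] = shared + rng.normal(0, 0.5, 50)
        z["p2"] = shared + rng.normal(0, 0.5, 50)
        pcc = correlation_matrix(z)
        off = pcc.where(~np.eye(len(pcc), dtype=bool)).stack()
        assert pcc.loc["p1", "p2"] > off.median()

    def test_group_comparison_detects_planted_structure(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(0, 2, 60)
        cols = {f"s{i}": rng.normal(0, 1, 60) for i in range(10)}
        for name in ("p1", "p2", "p3"):
            cols[name] = shared + rng.normal(0, 0.7, 60)
        pcc = correlation_matrix(pd.DataFrame(cols))
        pairs = {frozenset(p) for p in (("p1", "p2"), ("p1", "p3"), ("p2", "p3"))}
        res = compare_pcc_groups(pcc, pathway_pairs=pairs)
        row = res[(res.group1 == "all") & (res.group2 == "pathway")].iloc[0]
        assert row["median2"] > row["median1"]
        assert row["p_value"] < 0.05


def oracle_fisher_upper(a, b, c, d):
    """Exact hypergeometric upper tail by direct combinatorial sum."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    total = 0
    for x in range(a, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


class TestEnrichment:
    def test_worked_example(self):
        assert enrichment_test(3, 1, 1, 3) == pytest.approx(17 / 70, abs=1e-12)

    def test_a_zero_gives_one(self):
        assert enrichment_test(0, 4, 4, 4) == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        assert enrichment_test(3, 2, 1, 5) == pytest.approx(enrichment_test(3, 1, 2, 5))

    def test_empty_margin_convention(self):
        with pytest.warns(UserWarning, match="empty margin"):
            assert enrichment_test(0, 0, 3, 5) == 1.0

    def test_matches_exhaustive_hypergeometric_tail(self):
        """Every 2x2 table with N <= 30 agrees with the brute-force sum."""
        for N in range(1, 31):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for a in range(max(0, K + n - N), min(K, n) + 1):
                        b, c = K - a, n - a
                        d = N - a - b - c
                        if min(b, c, d) < 0 or 0 in (K, n, N - K, N - n):
                            continue
                        assert enrichment_test(a, b, c, d) == pytest.approx(
                            oracle_fisher_upper(a, b, c, d), abs=1e-10
                        )
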