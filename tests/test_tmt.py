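"""Reporter-ion pipeline: QC filtering, PMM imputation, normalization,
roll-up, loading correction, reference bridging and coverage filtering."""

import numpy as np
import pandas as pd
import pytest

import myoaging as ma
from myoaging import tmt
from myoaging.synthetic import CHANNEL_COLUMNS
from oracles import column_median_polish, median_center_log2

CH = list(CHANNEL_COLUMNS)


def _spectrum(sid, protein="P1", batch=1, intensities=None, decoy=False,
              contaminant=False, shared=False):
    row = {"spectrum_id": sid, "peptide": f"{protein}_pep", "protein": protein,
           "batch": batch, "decoy": decoy, "contaminant": contaminant,
           "shared": shared}
    vals = intensities if intensities is not None else [100.0] * 6
    row.update(dict(zip(CH, vals)))
    return row


class TestFilterSpectra:
    def test_flag_removal(self):
        df = pd.DataFrame([
            _spectrum("s1"),
            _spectrum("s2", decoy=True),
            _spectrum("s3", contaminant=True),
            _spectrum("s4", shared=True),
        ])
        kept, counts = tmt.filter_spectra(df)
        assert list(kept["spectrum_id"]) == ["s1"]
        assert counts == {"decoy": 1, "contaminant": 1, "shared": 1,
                          "too_many_missing": 0}

    def test_missing_channel_rule(self):
        three = [np.nan, np.nan, np.nan, 100, 100, 100]
        two = [np.nan, np.nan, 100, 100, 100, 100]
        none_obs = [np.nan] * 6
        df = pd.DataFrame([
            _spectrum("s1", intensities=three),
            _spectrum("s2", intensities=two),
            _spectrum("s3", intensities=none_obs),
        ])
        kept, counts = tmt.filter_spectra(df)
        assert list(kept["spectrum_id"]) == ["s2"]
        assert counts["too_many_missing"] == 2

    def test_counts_match_brute_force(self, cohort4):
        truth = ma.simulate_protein_truth(60, seed=21)
        sp = ma.simulate_tmt_spectra(cohort4, truth, missing_rate=0.08, seed=22,
                                     decoy_frac=0.05, contaminant_frac=0.03,
                                     shared_frac=0.02)
        kept, counts = tmt.filter_spectra(sp)
        # independent tally, applying reasons in the same precedence
        clean = sp[~(sp["decoy"] | sp["contaminant"] | sp["shared"])]
        assert counts["decoy"] == int(sp["decoy"].sum())
        assert counts["contaminant"] == int(sp["contaminant"].sum())
        assert counts["shared"] == int(sp["shared"].sum())
        assert counts["too_many_missing"] == int(
            (clean[CH].isna().sum(axis=1) > 2).sum()
        )
        assert len(kept) + sum(counts.values()) == len(sp)


class TestImputation:
    def test_identity_when_complete(self, clean_spectra):
        sp, _ = clean_spectra
        out = tmt.impute_reporters(sp, seed=1)
        pd.testing.assert_frame_equal(out, sp)

    def test_imputed_values_are_observed_members(self, cohort4):
        truth = ma.simulate_protein_truth(120, seed=23)
        sp = ma.simulate_tmt_spectra(cohort4, truth, missing_rate=0.02, seed=24,
                                     decoy_frac=0, contaminant_frac=0,
                                     shared_frac=0)
        kept, _ = tmt.filter_spectra(sp)
        out = tmt.impute_reporters(kept, seed=25)
        assert not out[CH].isna().any().any()
        for batch, sub in kept.groupby("batch"):
            filled = out.loc[sub.index]
            for c in CH:
                miss = sub[c].isna()
                if miss.any():
                    observed = set(sub.loc[~miss, c])
                    assert set(filled.loc[miss, c]) <= observed

    def test_rejects_overly_missing_spectra(self):
        df = pd.DataFrame([_spectrum("s1", intensities=[np.nan] * 4 + [10, 10])])
        with pytest.raises(ValueError, match="more than two"):
            tmt.impute_reporters(df)

    def test_channel_without_observations_raises(self):
        rows = [_spectrum(f"s{i}", intensities=[np.nan, 10, 10, 10, 10, 10])
                for i in range(3)]
        with pytest.raises(ValueError, match="no observed values"):
            tmt.impute_reporters(pd.DataFrame(rows))


class TestNormalizeWithinProtein:
    def test_constant_spectrum_centers_to_zero(self):
        df = pd.DataFrame([_spectrum("s1", intensities=[2.0] * 6)])
        out = tmt.normalize_within_protein(df)
        assert np.allclose(out[CH].to_numpy(), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(7, 1, size=(4, 6))
        df1 = pd.DataFrame([_spectrum(f"s{i}", intensities=vals[i]) for i in range(4)])
        df2 = pd.DataFrame([_spectrum(f"s{i}", intensities=vals[i] * 10) for i in range(4)])
        out1 = tmt.normalize_within_protein(df1)
        out2 = tmt.normalize_within_protein(df2)
        assert np.allclose(out1[CH].to_numpy(), out2[CH].to_numpy())

    def test_matches_two_step_oracle(self):
        rng = np.random.default_rng(1)
        rows, oracle = [], {}
        for prot in ["A", "B", "C"]:
            n_spec = rng.integers(1, 5)
            vals = rng.lognormal(7, 1, size=(n_spec, 6))
            oracle[prot] = median_center_log2(vals)
            rows += [_spectrum(f"{prot}{i}", protein=prot, intensities=vals[i])
                     for i in range(n_spec)]
        out = tmt.normalize_within_protein(pd.DataFrame(rows))
        for prot in ["A", "B", "C"]:
            got = out[out["protein"] == prot][CH].to_numpy()
            assert np.allclose(got, oracle[prot])

    def test_post_median_zero_per_protein(self, clean_spectra):
        sp, _ = clean_spectra
        out = tmt.normalize_within_protein(sp)
        med = (
            out.melt(id_vars=["batch", "protein"], value_vars=CH)["value"]
            .groupby([out.melt(id_vars=["batch", "protein"], value_vars=CH)["batch"],
                      out.melt(id_vars=["batch", "protein"], value_vars=CH)["protein"]])
            .median()
        )
        assert np.allclose(med.to_numpy(), 0.0, atol=1e-9)

    def test_nonpositive_raises_with_id(self):
        df = pd.DataFrame([_spectrum("bad1", intensities=[0, 1, 1, 1, 1, 1])])
        with pytest.raises(ValueError, match="bad1"):
            tmt.normalize_within_protein(df)


class TestRollup:
    def test_odd_count_median(self):
        rows = [_spectrum(f"s{i}", intensities=[v] * 6) for i, v in
                enumerate([2.0, 4.0, 8.0])]
        df = tmt.normalize_within_protein(pd.DataFrame(rows))
        # bypass normalization effects: feed known log2 values directly
        df[CH] = np.array([[1.0] * 6, [2.0] * 6, [3.0] * 6])
        mats = tmt.rollup_proteins(df)
        assert np.allclose(mats[1].loc["P1"], 2.0)

    def test_single_spectrum_passthrough(self):
        df = pd.DataFrame([_spectrum("s1")])
        df[CH] = [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]]
        mats = tmt.rollup_proteins(df)
        assert np.allclose(mats[1].loc["P1"], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_matches_numpy_median_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        vals = {}
        for prot in "ABCD":
            n = int(rng.integers(1, 7))
            v = rng.normal(0, 1, size=(n, 6))
            vals[prot] = v
            for i in range(n):
                rows.append(_spectrum(f"{prot}{i}", protein=prot))
        df = pd.DataFrame(rows)
        df[CH] = np.vstack(list(vals.values()))
        mats = tmt.rollup_proteins(df)
        for prot, v in vals.items():
            assert np.allclose(mats[1].loc[prot], np.median(v, axis=0))


class TestCorrectLoading:
    def test_channel_medians_zero(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(0, 1, (15, 6)), columns=CH)
        out = tmt.correct_loading(mat)
        assert np.allclose(out.median(axis=0), 0.0, atol=1e-12)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(0, 1, (15, 6)), columns=CH)
        shifted = mat.copy()
        shifted[CH[2]] += 3.7
        pd.testing.assert_frame_equal(tmt.correct_loading(mat),
                                      tmt.correct_loading(shifted))

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(0, 1, (10, 6))
        arr[rng.random((10, 6)) < 0.2] = np.nan
        mat = pd.DataFrame(arr, columns=CH)
        out = tmt.correct_loading(mat)
        assert np.allclose(out.to_numpy(), column_median_polish(arr),
                           equal_nan=True)

    def test_empty_channel_raises(self):
        mat = pd.DataFrame(np.ones((3, 6)), columns=CH)
        mat[CH[0]] = np.nan
        with pytest.raises(ValueError, match="without observed"):
            tmt.correct_loading(mat)


class TestBridgeBatches:
    @staticmethod
    def _donors_two_batches():
        rows = []
        strata = ["20-34", "35-49", "50-64", "65-79", "80+"]
        for b in (1, 2):
            for c in range(1, 6):
                rows.append({"donor_id": f"D{b}{c}", "tmt_batch": b,
                             "tmt_channel": c, "stratum": strata[c - 1]})
        return pd.DataFrame(rows).set_index("donor_id")

    def test_identical_reference_equals_concatenation(self):
        donors = self._donors_two_batches()
        rng = np.random.default_rng(6)
        m1 = pd.DataFrame(rng.normal(0, 1, (8, 6)), columns=CH,
                          index=[f"P{i}" for i in range(8)])
        m1[CH[5]] = 0.0
        m2 = pd.DataFrame(rng.normal(0, 1, (8, 6)), columns=CH, index=m1.index)
        m2[CH[5]] = 0.0
        bridged, counts = tmt.bridge_batches({1: m1, 2: m2}, donors)
        assert counts["missing_reference"] == 0
        expected = pd.concat(
            [m1[CH[:5]].set_axis([f"D1{c}" for c in range(1, 6)], axis=1),
             m2[CH[:5]].set_axis([f"D2{c}" for c in range(1, 6)], axis=1)], axis=1
        )
        assert np.allclose(bridged[expected.columns], expected)

    def test_batch_offset_invariance(self):
        donors = self._donors_two_batches()
        rng = np.random.default_rng(7)
        m1 = pd.DataFrame(rng.normal(0, 1, (8, 6)), columns=CH,
                          index=[f"P{i}" for i in range(8)])
        m2 = pd.DataFrame(rng.normal(0, 1, (8, 6)), columns=CH, index=m1.index)
        b0, _ = tmt.bridge_batches({1: m1, 2: m2}, donors)
        b1, _ = tmt.bridge_batches({1: m1, 2: m2 + 5.0}, donors)
        pd.testing.assert_frame_equal(b0, b1)

    def test_missing_reference_sets_batch_missing(self):
        donors = self._donors_two_batches()
        rng = np.random.default_rng(8)
        m1 = pd.DataFrame(rng.normal(0, 1, (4, 6)), columns=CH,
                          index=[f"P{i}" for i in range(4)])
        m1.loc["P0", CH[5]] = np.nan
        m2 = pd.DataFrame(rng.normal(0, 1, (4, 6)), columns=CH, index=m1.index)
        bridged, counts = tmt.bridge_batches({1: m1, 2: m2}, donors)
        assert counts["missing_reference"] == 1
        assert bridged.loc["P0", [f"D1{c}" for c in range(1, 6)]].isna().all()
        assert bridged.loc["P0", [f"D2{c}" for c in range(1, 6)]].notna().all()

    def test_bridging_improves_cross_batch_agreement(self, cohort12):
        """Rank correlation of per-stratum relative abundances between two
        batches is higher after per-batch reference anchoring than for a
        globally centered alternative that leaves batch effects in —
        mirroring the rationale for carrying a reference channel in
        every multiplexed set."""
        from scipy.stats import spearmanr

        truth = ma.simulate_protein_truth(200, seed=31, frac_age_assoc=0.5,
                                          batch_sd=0.6, resid_sd=0.05)
        sp = ma.simulate_tmt_spectra(cohort12, truth, missing_rate=0.0, seed=32,
                                     loading_sd=0.0, decoy_frac=0,
                                     contaminant_frac=0, shared_frac=0)
        # full pipeline (per-batch centering + reference bridging)
        centered = tmt.normalize_within_protein(sp)
        mats = {b: tmt.correct_loading(m) for b, m in
                tmt.rollup_proteins(centered).items()}
        bridged, _ = tmt.bridge_batches(mats, cohort12)

        # alternative: one global per-protein median, no reference anchoring,
        # so per-batch offsets survive
        raw = sp.copy()
        raw[CH] = np.log2(raw[CH].to_numpy())
        global_med = raw.groupby("protein")[CH].median().median(axis=1)
        raw[CH] = raw[CH].to_numpy() - global_med.loc[raw["protein"]].to_numpy()[:, None]
        unbridged = {}
        for b, m in tmt.rollup_proteins(raw).items():
            sub = cohort12[cohort12["tmt_batch"] == b]
            for donor_id, ch in zip(sub.index, sub["tmt_channel"]):
                unbridged[donor_id] = m[CH[ch - 1]]
        unbridged = pd.DataFrame(unbridged).loc[bridged.index]

        def cross_batch_corr(mat):
            d1 = cohort12[cohort12["tmt_batch"] == 1].sort_values("stratum")
            d2 = cohort12[cohort12["tmt_batch"] == 2].sort_values("stratum")
            a = mat[d1.index].to_numpy().ravel()
            b = mat[d2.index].to_numpy().ravel()
            return spearmanr(a, b).statistic

        assert cross_batch_corr(bridged) > cross_batch_corr(unbridged)


class TestCoverageFilter:
    def test_sparse_stratum_excluded_full_retained(self, cohort4):
        donors = cohort4
        proteins = ["full", "sparse"]
        mat = pd.DataFrame(1.0, index=proteins, columns=donors.index)
        # knock protein "sparse" down to 2 observed donors in one stratum
        victims = donors.index[donors["stratum"] == "80+"][2:]
        mat.loc["sparse", donors.index[donors["stratum"] == "80+"]] = np.nan
        mat.loc["sparse", victims[:0]] = 1.0  # keep none back
        mat.loc["sparse", donors.index[donors["stratum"] == "80+"][:2]] = 1.0
        filtered, retained, excluded = tmt.filter_by_stratum_coverage(mat, donors)
        assert retained == ["full"]
        assert excluded == ["sparse"]

    def test_half_rule_admits_widely_observed(self, cohort4):
        donors = cohort4
        mat = pd.DataFrame(1.0, index=["p"], columns=donors.index)
        # missing entirely in one stratum but present in 80% of donors
        mat.loc["p", donors.index[donors["stratum"] == "80+"]] = np.nan
        _, retained_strict, _ = tmt.filter_by_stratum_coverage(mat, donors)
        _, retained_half, _ = tmt.filter_by_stratum_coverage(
            mat, donors, rule="half_or_per_stratum"
        )
        assert retained_strict == []
        assert retained_half == ["p"]

    def test_empty_matrix_warns(self, cohort4):
        mat = pd.DataFrame(columns=cohort4.index)
        with pytest.warns(UserWarning):
            filtered, retained, excluded = tmt.filter_by_stratum_coverage(mat, cohort4)
        assert retained == [] and excluded == []


def test_end_to_end_noiseless_identity(cohort12):
    """Full pipeline on noiseless data reproduces the generating line
    baseline + beta*age per protein up to a constant (perfect correlation,
    exact slope)."""
    truth = ma.simulate_protein_truth(60, seed=41, batch_sd=0, bias_sd=0,
                                      resid_sd=0)
    sp = ma.simulate_tmt_spectra(cohort12, truth, noise_sd=0, missing_rate=0,
                                 loading_sd=0, seed=42, decoy_frac=0,
                                 contaminant_frac=0, shared_frac=0)
    mat, qc = tmt.process_batches(sp, cohort12, seed=0)
    ages = cohort12["age"].to_numpy()
    A = np.vstack([np.ones_like(ages), ages]).T
    for prot in mat.index:
        y = mat.loc[prot].to_numpy()
        slope = np.linalg.lstsq(A, y, rcond=None)[0][1]
        assert np.isclose(slope, truth.proteins.loc[prot, "beta_age"], atol=1e-9)
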