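"""E-score computation: normalization, alignment, calls and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escapeseq import escore as es
from escapeseq.readproc import BINS


def long_counts(rows):
    """rows: (peptide, allele, rep, bg, low, med, high) -> long count table."""
    recs = []
    for pep, allele, rep, *counts in rows:
        for b, c in zip(BINS, counts):
            recs.append((pep, allele, b, rep, c))
    return pd.DataFrame(recs, columns=["peptide", "allele", "bin",
                                       "replicate", "count"])


class TestNormalization:
    def test_depth_step_divides_by_bin_mean(self):
        df = long_counts([("p1", "A", "R1", 10, 0, 0, 0),
                          ("p2", "A", "R1", 30, 0, 0, 0)])
        wide = df.pivot_table(index=["peptide", "allele", "replicate"],
                              columns="bin", values="count")
        # bg mean is 20 -> depth-normalized bg counts 0.5 and 1.5; after the
        # per-trimer step both rows collapse to all-bg fractions
        fr = es.normalize_bins(df)
        assert fr.loc[("p1", "A", "R1"), "bg"] == 1.0
        assert fr.loc[("p2", "A", "R1"), "bg"] == 1.0
        assert wide.loc[("p1", "A", "R1"), "bg"] == 10  # sanity on input

    def test_uniform_vector_gives_quarter_fractions(self):
        df = long_counts([("p1", "A", "R1", 1, 1, 1, 1)])
        fr = es.normalize_bins(df)
        assert np.allclose(fr.loc[("p1", "A", "R1"), list(BINS)], 0.25)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [(f"p{i}", "A", "R1", *rng.integers(1, 100, size=4))
                for i in range(30)]
        fr = es.normalize_bins(long_counts(rows))
        assert np.allclose(fr[list(BINS)].sum(axis=1), 1.0)

    def test_all_zero_trimer_is_missing_not_zero(self):
        df = long_counts([("p1", "A", "R1", 5, 5, 5, 5),
                          ("p2", "A", "R1", 0, 0, 0, 0)])
        fr = es.normalize_bins(df)
        assert bool(fr.loc[("p2", "A", "R1"), "missing"])
        assert fr.loc[("p2", "A", "R1"), list(BINS)].isna().all()
        tab = es.escore_table(df)
        assert np.isnan(tab.set_index("peptide").loc["p2", "escore"])


class TestEScore:
    @pytest.mark.parametrize("fractions,expected", [
        ((1, 0, 0, 0), 0.0),
        ((0, 0, 0, 1), 8.0),
        ((0.25, 0.25, 0.25, 0.25), 3.5),
    ])
    def test_identities(self, fractions, expected):
        assert es.compute_escore(np.array(fractions)) == pytest.approx(expected)

    def test_weights_must_increase(self):
        with pytest.raises(ValueError):
            es.EScoreWeights(0, 4, 2, 8)

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        rows = [(f"p{i}", "A", "R1", *rng.integers(1, 200, size=4))
                for i in range(25)]
        df = long_counts(rows)
        scaled = df.copy()
        scaled.loc[scaled["bin"] == "med", "count"] *= 7
        a = es.escore_table(df)["escore"].to_numpy()
        b = es.escore_table(scaled)["escore"].to_numpy()
        assert np.allclose(a, b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_under_mass_shift(self, seed):
        """Moving probability mass to a higher bin never lowers the score."""
        rng = np.random.default_rng(seed)
        frac = rng.dirichlet(np.ones(4))
        lo = rng.integers(0, 3)
        hi = rng.integers(lo + 1, 4)
        delta = frac[lo] * rng.random()
        shifted = frac.copy()
        shifted[lo] -= delta
        shifted[hi] += delta
        assert es.compute_escore(shifted) >= es.compute_escore(frac) - 1e-12

    def test_bounds(self):
        rng = np.random.default_rng(2)
        fracs = rng.dirichlet(np.ones(4), size=200)
        scores = es.compute_escore(fracs)
        assert np.all(scores >= 0) and np.all(scores <= 8)


def bimodal_scores(n, neg_mode, pos_mode=6.0, pos_frac=0.1, seed=0):
    rng = np.random.default_rng(seed)
    n_pos = int(n * pos_frac)
    neg = rng.normal(neg_mode, 0.3, size=n - n_pos)
    pos = rng.normal(pos_mode, 0.5, size=n_pos)
    return np.clip(np.concatenate([neg, pos]), 0, 8)


class TestAlignment:
    @staticmethod
    def frame(allele_modes, n=400, seed=0):
        rows = []
        for i, (allele, mode) in enumerate(allele_modes.items()):
            scores = bimodal_scores(n, mode, seed=seed + i)
            for j, s in enumerate(scores):
                rows.append({"peptide": f"p{j}", "allele": allele,
                             "replicate": "R1", "escore": s})
        return pd.DataFrame(rows)

    def test_two_allele_modes_converge(self):
        df = self.frame({"A": 1.0, "B": 1.4})
        aligned, shifts = es.align_alleles(df)
        got = shifts.set_index("allele")
        # shifts move both modes onto the median of the two
        assert got.loc["A", "shift"] == pytest.approx(0.2, abs=0.05)
        assert got.loc["B", "shift"] == pytest.approx(-0.2, abs=0.05)
        re_modes = {}
        for allele, sub in aligned.groupby("allele"):
            re_modes[allele] = es._lower_mode(
                sub["aligned"].to_numpy(), 4.0, "silverman", 512)
        assert re_modes["A"] == pytest.approx(re_modes["B"], abs=0.05)

    def test_single_allele_zero_shift(self):
        df = self.frame({"A": 1.2})
        _, shifts = es.align_alleles(df)
        assert shifts["shift"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_equal_modes_identity(self):
        df = self.frame({"A": 1.2, "B": 1.2, "C": 1.2})
        aligned, shifts = es.align_alleles(df)
        # mode estimates carry KDE sampling noise; shifts stay near zero
        assert np.allclose(shifts["shift"], 0.0, atol=0.1)

    def test_alignment_idempotent(self):
        df = self.frame({"A": 0.8, "B": 1.6})
        once, _ = es.align_alleles(df)
        again, shifts2 = es.align_alleles(
            once.drop(columns="escore").rename(columns={"aligned": "escore"}))
        assert np.allclose(shifts2["shift"], 0.0, atol=0.05)

    def test_sparse_allele_warns_and_skips(self):
        df = self.frame({"A": 1.0}).head(10)
        with pytest.warns(UserWarning, match="trimers"):
            _, shifts = es.align_alleles(df)
        assert shifts["shift"].iloc[0] == 0.0


class TestCallsAndQC:
    def test_mode_thresholds(self):
        assert bool(es.call_binders(pd.Series([3.3]), mode="single")[0])
        assert not bool(es.call_binders(pd.Series([3.3]),
                                        mode="combinatorial")[0])

    def test_threshold_is_strict(self):
        assert not bool(es.call_binders(pd.Series([3.2]), mode="single")[0])
        assert not bool(es.call_binders(pd.Series([3.8]),
                                        mode="combinatorial")[0])

    def test_out_of_band_override_warns(self):
        with pytest.warns(UserWarning, match="guidance band"):
            es.call_binders(pd.Series([3.0]), threshold=3.0)

    def test_identical_replicates_r1(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 8, size=60)
        df = pd.DataFrame({
            "peptide": [f"p{i}" for i in range(60)] * 2,
            "allele": "A",
            "replicate": ["R1"] * 60 + ["R2"] * 60,
            "escore": np.concatenate([base, base])})
        qc = es.replicate_qc(df)
        assert qc["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert bool(qc["pass"].iloc[0])

    def test_independent_noise_fails(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "peptide": [f"p{i}" for i in range(200)] * 2,
            "allele": "A",
            "replicate": ["R1"] * 200 + ["R2"] * 200,
            "escore": rng.uniform(0, 8, size=400)})
        qc = es.replicate_qc(df)
        assert abs(qc["pearson_r"].iloc[0]) < 0.3
        assert not bool(qc["pass"].iloc[0])

    def test_constant_vector_undefined(self):
        df = pd.DataFrame({
            "peptide": ["p1", "p2"] * 2, "allele": "A",
            "replicate": ["R1", "R1", "R2", "R2"],
            "escore": [1.0, 1.0, 2.0, 3.0]})
        qc = es.replicate_qc(df)
        assert np.isnan(qc["pearson_r"].iloc[0])
        assert not bool(qc["pass"].iloc[0])


class TestSummaries:
    def test_motif_single_residue_column(self):
        pfm = es.build_motif(["AAA", "AAA"])
        assert pfm.loc[1, "A"] == 1.0
        assert np.allclose(pfm.sum(axis=1), 1.0)

    def test_motif_uniform(self):
        peptides = ["".join(p) for p in zip(*[list(es.AA_ALPHABET)] * 3)]
        pfm = es.build_motif(peptides)
        assert np.allclose(pfm.to_numpy(), 0.05)

    def test_motif_matches_tally_oracle(self):
        rng = np.random.default_rng(5)
        peptides = ["".join(rng.choice(list(es.AA_ALPHABET), size=9))
                    for _ in range(50)]
        pfm = es.build_motif(peptides)
        for pos in (1, 5, 9):
            for aa in "AKY":
                tally = sum(p[pos - 1] == aa for p in peptides) / 50
                assert pfm.loc[pos, aa] == pytest.approx(tally)

    def test_motif_mixed_lengths_error(self):
        with pytest.raises(ValueError):
            es.build_motif(["AAAA", "AAA"])

    def test_capture_percentage(self):
        ms = [(f"p{i}", "A") for i in range(10)]
        binders = [(f"p{i}", "A") for i in range(8)] + [("x", "A")]
        cap = es.capture_percentage(ms, binders)
        assert cap.loc[cap["allele"] == "A", "capture"].iloc[0] == 0.8
        full = es.capture_percentage(ms, ms)
        assert full["capture"].iloc[0] == 1.0
        with pytest.raises(ValueError):
            es.capture_percentage([], binders)

    def test_quadrants_examples_and_oracle(self):
        df = pd.DataFrame({"mut_escore": [5.0, 5.0, 1.0, 1.0],
                           "wt_escore": [1.0, 5.0, 5.0, 1.0]})
        got = es.quadrant_classify(df, threshold=3.8)["quadrant"].tolist()
        assert got == ["Mut+only", "WT+Mut+", "WT+only", "WT-Mut-"]
        rng = np.random.default_rng(6)
        rand = pd.DataFrame({"mut_escore": rng.uniform(0, 8, 200),
                             "wt_escore": rng.uniform(0, 8, 200)})
        cls = es.quadrant_classify(rand, threshold=3.8)
        for _, row in cls.iterrows():
            m, w = row["mut_escore"] > 3.8, row["wt_escore"] > 3.8
            expect = {(False, False): "WT-Mut-", (True, True): "WT+Mut+",
                      (False, True): "WT+only", (True, False): "Mut+only"}[(m, w)]
            assert row["quadrant"] == expect

    def test_quadrant_unpaired_excluded_with_warning(self):
        df = pd.DataFrame({"mut_escore": [5.0, np.nan],
                           "wt_escore": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="excluded"):
            out = es.quadrant_classify(df)
        assert len(out) == 1

    def test_sharing_profile_tallies(self):
        calls = pd.DataFrame({
            "peptide": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "allele": ["A", "B"] * 3,
            "call": [True, True, True, False, False, False]})
        per_pep, per_mut = es.sharing_profile(
            calls, mutation_of={"p1": "m1", "p2": "m1", "p3": "m2"})
        assert per_pep.to_dict() == {"p1": 2, "p2": 1, "p3": 0}
        cell = per_mut.set_index(["mutation", "allele"])["n_presented"]
        assert cell.loc[("m1", "A")] == 2
        assert cell.loc[("m1", "B")] == 1
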