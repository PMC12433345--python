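"""Entropy scoring, classification boundaries, and QC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from atacspec.consensus import ConsensusRegion
from atacspec.formats import TranscriptModel
from atacspec.specificity import (
    classify,
    entropy,
    genomic_context,
    qc_frip,
    relative_accessibility,
    sample_correlation,
    score_specificity,
    tissue_profile,
    tss_peak_fraction,
)

TISSUES = ["Amy", "Hip", "HT", "Tal", "AG", "PG"]


class TestTissueProfile:
    def _rpm(self):
        return pd.DataFrame(
            {"a1": [100.0, 10.0], "a2": [300.0, 20.0], "b1": [50.0, 70.0]},
            index=["r1", "r2"],
        )

    def test_mean_over_replicates(self):
        E = tissue_profile(self._rpm(), {"a1": "A", "a2": "A", "b1": "B"})
        assert E.loc["r1", "A"] == 200.0
        assert E.loc["r1", "B"] == 50.0

    def test_single_sample_tissue_passthrough(self):
        E = tissue_profile(self._rpm(), {"a1": "A", "a2": "A", "b1": "B"})
        assert E.loc["r2", "B"] == 70.0

    def test_replicate_order_irrelevant(self):
        rpm = self._rpm()
        shuffled = rpm[["a2", "b1", "a1"]]
        E1 = tissue_profile(rpm, {"a1": "A", "a2": "A", "b1": "B"})
        E2 = tissue_profile(shuffled, {"a1": "A", "a2": "A", "b1": "B"})
        assert E1.equals(E2[E1.columns])

    def test_unlabeled_sample_rejected(self):
        with pytest.raises(ValueError, match="without tissue"):
            tissue_profile(self._rpm(), {"a1": "A", "a2": "A"})


class TestRelativeAccessibility:
    def test_one_hot(self):
        assert relative_accessibility(np.array([10.0, 0, 0, 0, 0, 0])).tolist() == [
            1, 0, 0, 0, 0, 0
        ]

    def test_uniform(self):
        assert np.allclose(relative_accessibility(np.full(6, 3.0)), 1 / 6)

    def test_arithmetic(self):
        R = relative_accessibility(np.array([6.0, 2.0, 2.0, 0, 0, 0]))
        assert np.allclose(R, [0.6, 0.2, 0.2, 0, 0, 0])

    def test_zero_row_stays_zero(self):
        assert relative_accessibility(np.zeros(6)).tolist() == [0] * 6

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_accessibility(np.array([1.0, -1.0]))


class TestEntropy:
    def test_one_hot_is_zero(self):
        assert entropy(np.array([1.0, 0, 0, 0, 0, 0])) == 0.0

    def test_uniform_attains_log2_n(self):
        assert entropy(np.full(6, 1 / 6)) == pytest.approx(np.log2(6), abs=1e-12)

    def test_two_equal_masses_give_one_bit(self):
        assert entropy(np.array([0.5, 0.5, 0, 0, 0, 0])) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_simplex(self):
        rng = np.random.default_rng(5)
        R = rng.dirichlet(np.ones(6), size=1000)
        H = entropy(R)
        brute = np.array(
            [-sum(r * np.log2(r) for r in row if r > 0) for row in R]
        )
        assert np.abs(H - brute).max() < 1e-12

    def test_all_zero_row_unclassifiable(self):
        assert np.isnan(entropy(np.zeros(6)))

    def test_sum_violation_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            entropy(np.array([0.5, 0.4]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8))
    def test_entropy_bounds_hold(self, values):
        R = np.array(values) / np.sum(values)
        R = R / R.sum()  # exact renormalization
        H = entropy(R)
        assert -1e-9 <= H <= np.log2(len(R)) + 1e-9


class TestClassify:
    def _E(self, rows):
        return pd.DataFrame(rows, columns=TISSUES)

    def test_one_hot_labeled_with_its_tissue(self):
        out = classify(self._E([[0, 0, 0, 0, 10.0, 0]]))
        assert out["label"].iloc[0] == "AG"
        assert out["H"].iloc[0] == 0.0

    def test_uniform_unlabeled(self):
        out = classify(self._E([[5.0] * 6]))
        assert out["label"].iloc[0] == "none"

    def test_entropy_exactly_two_excluded(self):
        # four equal masses give H = 2 exactly; threshold is strict
        out = classify(self._E([[1.0, 1.0, 1.0, 1.0, 0, 0]]))
        assert out["H"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert out["label"].iloc[0] == "none"

    def test_r_min_boundary_inclusive_and_tie_breaks_first(self):
        out = classify(self._E([[5.0, 5.0, 0, 0, 0, 0]]), r_min=0.5)
        assert out["label"].iloc[0] == "Amy"

    def test_r_min_below_threshold_excluded(self):
        E = self._E([[4.0, 3.0, 3.0, 0, 0, 0]])  # max R = 0.4, H ~ 1.57
        out = classify(E, r_min=0.5)
        assert out["label"].iloc[0] == "none"

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(6)
        E = self._E(rng.gamma(2.0, 50.0, size=(200, 6)))
        assert classify(E)["label"].equals(classify(E * 37.5)["label"])

    def test_zero_profile_unclassifiable(self):
        out = classify(self._E([[0.0] * 6]))
        assert out["label"].iloc[0] == "none"
        assert np.isnan(out["H"].iloc[0])

    def test_labels_equal_argmax_of_r(self, small_result):
        st_ = small_result.spec_table
        labeled = st_[st_["label"] != "none"]
        rcols = [c for c in st_.columns if c.startswith("R_")]
        argmax = labeled[rcols].idxmax(axis=1).str.removeprefix("R_")
        assert (argmax == labeled["label"]).all()


class TestQc:
    def test_frip_values(self):
        frip = qc_frip(
            pd.Series({"s1": 100, "s2": 10, "s3": 8}),
            pd.Series({"s1": 35, "s2": 0, "s3": 8}),
        )
        assert frip.tolist() == [0.35, 0.0, 1.0]

    def test_frip_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            qc_frip(pd.Series({"s1": 10}), pd.Series({"s1": 11}))

    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(7)
        col = rng.gamma(2, 100, size=500)
        rpm = pd.DataFrame({"s1": col, "s2": col, "s3": rng.gamma(2, 100, 500)})
        corr = sample_correlation(rpm)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.equals(corr.T)

    def test_depth_scaling_invisible_after_rpm(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(50, size=300).astype(float)
        rpm = pd.DataFrame({
            "s1": counts / counts.sum() * 1e6,
            "s2": (2 * counts) / (2 * counts).sum() * 1e6,
        })
        assert sample_correlation(rpm).loc["s1", "s2"] == pytest.approx(1.0)

    def test_independent_samples_nearly_uncorrelated(self):
        rng = np.random.default_rng(9)
        rpm = pd.DataFrame(rng.gamma(2, 100, size=(10_000, 2)), columns=["a", "b"])
        assert abs(sample_correlation(rpm).loc["a", "b"]) < 0.05

    def test_zero_variance_sample_reported_missing(self):
        rpm = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [5.0, 5.0, 5.0]})
        assert np.isnan(sample_correlation(rpm).loc["s1", "s2"])


def _region(summit, rid="r1", chrom="chr1"):
    return ConsensusRegion(rid, chrom, summit - 75, summit + 76, summit, 2)


def _tx(tss, strand="+", chrom="chr1", tid="t1", span=2000):
    if strand == "+":
        start, end = tss, tss + span
    else:
        start, end = tss - span + 1, tss + 1
    return TranscriptModel(
        transcript_id=tid, gene_id=tid, chrom=chrom, strand=strand,
        start=start, end=end, exons=((start, end),),
    )


class TestTssPeakFraction:
    def test_summit_at_tss_counted(self):
        assert tss_peak_fraction([_region(5000)], [_tx(5000)]) == 100.0

    def test_window_boundaries_plus_strand(self):
        transcripts = [_tx(5000)]
        assert tss_peak_fraction([_region(5100)], transcripts) == 100.0  # +100
        assert tss_peak_fraction([_region(5101)], transcripts) == 0.0   # +101
        assert tss_peak_fraction([_region(4000)], transcripts) == 100.0  # -1000
        assert tss_peak_fraction([_region(3999)], transcripts) == 0.0

    def test_window_mirrored_on_minus_strand(self):
        transcripts = [_tx(5000, strand="-")]
        assert tss_peak_fraction([_region(4900)], transcripts) == 100.0  # +100 downstream
        assert tss_peak_fraction([_region(6000)], transcripts) == 100.0  # -1000 upstream
        assert tss_peak_fraction([_region(6001)], transcripts) == 0.0

    def test_no_transcripts_gives_zero(self):
        assert tss_peak_fraction([_region(5000)], []) == 0.0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tss_peak_fraction([], [_tx(5000)])


class TestGenomicContext:
    def test_upstream_midpoint_is_promoter(self):
        ctx = genomic_context([_region(4500)], [_tx(5000)])
        assert ctx.iloc[0] == "promoter"

    def test_exon_midpoint(self):
        tx = TranscriptModel(
            transcript_id="t1", gene_id="t1", chrom="chr1", strand="+",
            start=1000, end=3000, exons=((1000, 1200), (2800, 3000)),
        )
        assert genomic_context([_region(2900, rid="rx")], [tx]).iloc[0] == "exon"
        assert genomic_context([_region(2000, rid="ri")], [tx]).iloc[0] == "intron"

    def test_gene_free_chromosome_is_other(self):
        ctx = genomic_context([_region(5000, chrom="chrU")], [_tx(5000)])
        assert ctx.iloc[0] == "other"

    def test_promoter_takes_precedence_over_exon(self):
        # first-exon midpoint that also sits in a neighbor's promoter window
        tx1 = _tx(5000)
        tx2 = _tx(6000, tid="t2")
        ctx = genomic_context([_region(5500)], [tx1, tx2])
        assert ctx.iloc[0] == "promoter"


class TestScoreSpecificity:
    def test_end_to_end_on_known_profile(self):
        rpm = pd.DataFrame(
            {
                "A_r1": [900.0, 100.0],
                "A_r2": [1100.0, 100.0],
                "B_r1": [100.0, 100.0],
                "B_r2": [100.0, 100.0],
            },
            index=["spec", "flat"],
        )
        tissues = {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
        out = score_specificity(rpm, tissues, h_max=0.8, r_min=0.6)
        assert out.loc["spec", "label"] == "A"
        assert out.loc["flat", "label"] == "none"
        assert out.loc["flat", "H"] == pytest.approx(1.0)
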