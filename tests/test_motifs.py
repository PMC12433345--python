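"""PWM scanning, background sampling, and hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_scan
from atacspec.formats import Pwm
from atacspec.motifs import (
    enrich_tissue,
    enrichment_matrix,
    gc_content,
    hypergeom_tail,
    log_odds,
    rank_by_cv,
    sample_background,
    scan,
    unique_motifs,
)


def sharp_pwm(consensus: str, threshold: float, name: str = "m") -> Pwm:
    probs = np.full((4, len(consensus)), 0.01)
    for j, b in enumerate(consensus):
        probs["ACGT".index(b), j] = 0.97
    return Pwm(name=name, tf_name=name, probs=probs, log_odds_threshold=threshold)


def random_pwm(rng, length):
    probs = rng.dirichlet(np.full(4, 0.5), size=length).T
    return Pwm(name="rand", tf_name="rand", probs=probs,
               log_odds_threshold=float(rng.uniform(-2, 6)))


class TestLogOdds:
    def test_probability_twice_background_is_one_bit(self):
        probs = np.full((4, 4), 0.25)
        probs[:, 0] = [0.5, 0.0, 0.25, 0.25]
        pwm = Pwm("m", "m", probs, 0.0)
        sm = log_odds(pwm)
        assert sm[0, 0] == pytest.approx(1.0)

    def test_background_equal_probs_scores_zero(self):
        pwm = Pwm("m", "m", np.full((4, 5), 0.25), 0.0)
        assert np.allclose(log_odds(pwm)[:4], 0.0)

    def test_floor_applied_before_ratio(self):
        probs = np.full((4, 4), 0.001)
        probs[0] = 0.997
        pwm = Pwm("m", "m", probs, 0.0)
        sm = log_odds(pwm)
        assert sm[1, 0] == pytest.approx(np.log2(0.001 / 0.25), abs=1e-9)
        assert sm[1, 0] == pytest.approx(-7.9658, abs=1e-3)

    def test_n_base_penalty_row(self):
        pwm = Pwm("m", "m", np.full((4, 4), 0.25), 0.0)
        assert (log_odds(pwm)[4] == -10.0).all()

    def test_zero_background_rejected(self):
        pwm = Pwm("m", "m", np.full((4, 4), 0.25), 0.0)
        with pytest.raises(ValueError, match="positive"):
            log_odds(pwm, np.array([0.5, 0.5, 0.0, 0.0]))


class TestScan:
    def test_tata_found_on_forward_strand(self):
        pwm = sharp_pwm("TATA", threshold=4.0)
        hits = scan("GGTATAGG", pwm)
        assert {(h.position, h.strand) for h in hits} == {(2, "+"), (2, "-")}
        # TATA is its own reverse complement, hence the paired strand call

    def test_non_palindromic_motif_strand_assignment(self):
        pwm = sharp_pwm("TGACGT", threshold=8.0)
        assert [(h.position, h.strand) for h in scan("CCTGACGTAA", pwm)] == [(2, "+")]
        # revcomp(TGACGT) = ACGTCA: present means a minus-strand site
        assert [(h.position, h.strand) for h in scan("GGACGTCAGG", pwm)] == [(2, "-")]

    def test_no_hits_in_unrelated_sequence(self):
        assert scan("GGGGGGGG", sharp_pwm("TATA", 4.0)) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        assert scan("GG", sharp_pwm("TATA", 4.0)) == []

    def test_n_bases_blocked_by_penalty(self):
        assert scan("GGTANAGG", sharp_pwm("TATA", 4.0)) == []

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(10)
        for i in range(100):
            length = int(rng.integers(4, 12))
            pwm = random_pwm(rng, length)
            seq = "".join(rng.choice(list("ACGTN"), size=60, p=[0.23] * 4 + [0.08]))
            got = {(h.position, h.strand, round(h.score, 9)) for h in scan(seq, pwm)}
            assert got == brute_force_scan(seq, pwm)


class TestBackgroundSampling:
    def _genome(self, seed=0, gc=0.4, n=200_000):
        rng = np.random.default_rng(seed)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return {"chr1": "".join(rng.choice(list("ACGT"), size=n, p=p))}

    def _targets(self, genome, k=10, width=151):
        return [("chr1", 1000 + 5000 * i, 1000 + 5000 * i + width) for i in range(k)]

    def test_ratio_and_no_target_overlap(self):
        genome = self._genome()
        targets = self._targets(genome)
        bg = sample_background(genome, targets, ratio=2, seed=1)
        assert len(bg) == 20
        for r in bg.itertuples():
            assert all(
                r.end <= s or r.start >= e for _, s, e in targets
            )
            assert len(r.seq) == 151

    def test_gc_histogram_matches_targets_within_one_per_bin(self):
        genome = self._genome(seed=3)
        rng = np.random.default_rng(4)
        targets = [
            ("chr1", int(p), int(p) + 151)
            for p in rng.choice(np.arange(0, 199_000, 200), size=50, replace=False)
        ]
        bg = sample_background(genome, targets, ratio=2, seed=5)
        tgt_bins = np.floor(
            [gc_content(genome["chr1"][s:e]) / 0.05 for _, s, e in targets]
        )
        bg_bins = np.floor(bg["seq"].map(gc_content) / 0.05)
        t_hist = pd.Series(tgt_bins).value_counts() * 2
        b_hist = pd.Series(bg_bins).value_counts()
        for b in set(t_hist.index) | set(b_hist.index):
            assert abs(t_hist.get(b, 0) - b_hist.get(b, 0)) <= 1

    def test_deterministic_given_seed(self):
        genome = self._genome()
        targets = self._targets(genome)
        a = sample_background(genome, targets, seed=42)
        b = sample_background(genome, targets, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_backgrounds_do_not_overlap_each_other(self):
        genome = self._genome()
        bg = sample_background(genome, self._targets(genome), ratio=4, seed=2)
        ivs = sorted(zip(bg["start"], bg["end"]))
        assert all(b0 >= a1 for (_, a1), (b0, _) in zip(ivs, ivs[1:]))


def exact_tail(k, K, n, M):
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(M - K, n - i), comb(M, n))
    return total


class TestHypergeomTail:
    def test_worked_example_is_exact_fraction(self):
        expected = Fraction(13013, 184756)
        assert hypergeom_tail(5, 6, 10, 20) == pytest.approx(float(expected), abs=1e-12)
        assert exact_tail(5, 6, 10, 20) == expected

    def test_zero_successes_gives_one(self):
        assert hypergeom_tail(0, 6, 10, 20) == 1.0

    def test_degenerate_full_draw_forced(self):
        assert hypergeom_tail(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_tail(7, 6, 10, 20)

    def test_spot_enumeration_small_populations(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            M = int(rng.integers(1, 26))
            K = int(rng.integers(0, M + 1))
            n = int(rng.integers(0, M + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(k, K, n, M) == pytest.approx(
                float(exact_tail(k, K, n, M)), abs=1e-12
            )


class TestEnrichment:
    def _seqs(self, rng, n, length=60, motif=None, rate=0.0):
        out = []
        for _ in range(n):
            s = list(rng.choice(list("ACGT"), size=length))
            if motif is not None and rng.random() < rate:
                pos = int(rng.integers(0, length - len(motif)))
                s[pos:pos + len(motif)] = list(motif)
            out.append("".join(s))
        return out

    def test_planted_motif_strongly_significant(self):
        rng = np.random.default_rng(12)
        pwm = sharp_pwm("TGACGTCATC", threshold=15.0)
        targets = self._seqs(rng, 200, motif="TGACGTCATC", rate=0.8)
        background = self._seqs(rng, 400, motif="TGACGTCATC", rate=0.05)
        rec = enrich_tissue(targets, background, [pwm], tissue="AG").iloc[0]
        assert rec["significant"]
        assert rec["p"] < 1e-10
        assert rec["fold"] > 5

    def test_target_equals_background_not_significant(self):
        rng = np.random.default_rng(13)
        seqs = self._seqs(rng, 100, motif="TGACGTCATC", rate=0.5)
        rec = enrich_tissue(seqs, seqs, [sharp_pwm("TGACGTCATC", 15.0)]).iloc[0]
        assert rec["fold"] == pytest.approx(1.0)
        assert not rec["significant"]
        assert rec["p"] >= 0.5

    def test_absent_motif_gives_p_one(self):
        rng = np.random.default_rng(14)
        seqs = self._seqs(rng, 50)
        rec = enrich_tissue(seqs, seqs, [sharp_pwm("TTTTTTTTTTTT", 20.0)]).iloc[0]
        assert rec["k_target"] == 0
        assert rec["p"] == 1.0
        assert rec["fold"] == 0.0


class TestReportingLayers:
    def _pmat(self):
        return pd.DataFrame(
            {
                "AG": [1e-9, 1e-9, 0.5, 1.0],
                "PG": [1.0, 1e-9, 0.5, 1.0],
                "HT": [1.0, 1.0, 0.5, 1.0],
            },
            index=["onlyAG", "AGandPG", "weak", "nothing"],
        )

    def test_unique_and_intersection_sets(self):
        unique, upset = unique_motifs(self._pmat(), alpha=0.001)
        assert unique == {"AG": ["onlyAG"], "PG": [], "HT": []}
        assert len(upset) == 2 ** 3 - 1
        both = upset[(upset["AG"]) & (upset["PG"]) & (~upset["HT"])]
        assert both["count"].iloc[0] == 1
        assert upset["count"].sum() == 2

    def test_no_significant_motifs_all_empty(self):
        unique, upset = unique_motifs(self._pmat(), alpha=1e-12)
        assert all(len(v) == 0 for v in unique.values())
        assert upset["count"].sum() == 0

    def test_cv_ranking_prefers_concentrated_scores(self):
        scores = pd.DataFrame(
            {
                "t1": [126.0, 63.0, 21.0, 10.0],
                "t2": [0.0, 63.0, 21.0, 10.0],
                "t3": [0.0, 0.0, 21.0, 10.0],
                "t4": [0.0, 0.0, 21.0, 10.0],
                "t5": [0.0, 0.0, 21.0, 10.0],
                "t6": [0.0, 0.0, 21.0, 10.0],
            },
            index=["spiky", "paired", "flat", "lowmean"],
        )
        with pytest.warns(UserWarning, match="returning all"):
            ranked = rank_by_cv(scores, mean_min=20, top_k=50)
        assert "lowmean" not in ranked.index  # mean 10 < 20
        assert list(ranked.index) == ["spiky", "paired", "flat"]
        assert ranked.loc["flat", "cv"] == pytest.approx(0.0)

    def test_matrix_pivot_roundtrip(self):
        records = pd.DataFrame(
            {
                "motif": ["m1", "m1", "m2", "m2"],
                "tissue": ["AG", "PG", "AG", "PG"],
                "p": [0.1, 0.2, 0.3, 0.4],
            }
        )
        pmat = enrichment_matrix(records)
        assert pmat.loc["m2", "PG"] == 0.4
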