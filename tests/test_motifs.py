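"""PWM scoring, lognormal tile null, top-motif percentage, TF peak overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from imprintscan.io import PFM
from imprintscan.motifs import (affinity_score, affinity_scores,
                                base_frequencies, encode_sequences,
                                extract_windows, fisher_exact_2x2,
                                fit_lognormal_background, group_pvalue,
                                pfm_to_pwm, remap_binding_enrichment,
                                run_motif_enrichment, sequence_pvalues,
                                top_motif_percentage)

UNIFORM = np.array([0.25] * 4)


class TestExtractWindows:
    def genome(self, n=2_000, seed=0):
        rng = np.random.default_rng(seed)
        return {"chr1": "".join(rng.choice(list("ACGT"), n))}

    def test_window_length_and_center(self):
        genome = self.genome()
        cpgs = pd.DataFrame({"chrom": ["chr1"], "pos": [500]}, index=["c"])
        ids, seqs = extract_windows(cpgs, genome, flank=50)
        assert len(seqs[0]) == 101
        assert seqs[0] == genome["chr1"][450:551]

    def test_contig_edge_dropped(self, caplog):
        genome = self.genome()
        cpgs = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 500]},
                            index=["edge", "ok"])
        with caplog.at_level("WARNING"):
            ids, seqs = extract_windows(cpgs, genome, flank=50)
        assert list(ids) == ["ok"]

    def test_unknown_contig_raises(self):
        cpgs = pd.DataFrame({"chrom": ["chrX"], "pos": [500]}, index=["c"])
        with pytest.raises(KeyError):
            extract_windows(cpgs, self.genome(), flank=50)


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pwm = pfm_to_pwm(np.array([[1.0], [1.0], [1.0], [1.0]]), UNIFORM)
        np.testing.assert_allclose(pwm, 0.0, atol=1e-12)

    def test_documented_pseudocount_value(self):
        pwm = pfm_to_pwm(np.array([[10.0], [0.0], [0.0], [0.0]]), UNIFORM)
        assert pwm[0, 0] == pytest.approx(math.log2((10.25 / 11) / 0.25), rel=1e-12)
        assert pwm[0, 0] == pytest.approx(1.898, abs=5e-4)

    def test_pseudocount_dilution_monotone(self):
        col = np.array([[6.0], [2.0], [1.0], [1.0]])
        small = pfm_to_pwm(col, UNIFORM)
        large = pfm_to_pwm(col * 10, UNIFORM)
        ml = math.log2((6 / 10) / 0.25)
        assert abs(large[0, 0] - ml) < abs(small[0, 0] - ml)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.zeros((4, 2)), UNIFORM)


class TestAffinity:
    def pwm(self):
        counts = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8], [1, 1, 1]], dtype=float)
        return pfm_to_pwm(counts, UNIFORM)

    def test_single_window_definition(self):
        pwm = self.pwm()
        seq = "ACG"
        fwd = sum(pwm["ACGT".index(b), j] for j, b in enumerate(seq))
        rc = "CGT"  # reverse complement of ACG
        rev = sum(pwm["ACGT".index(b), j] for j, b in enumerate(rc))
        expected = (2 ** fwd + 2 ** rev) / 2
        assert affinity_score(seq, pwm) == pytest.approx(expected, rel=1e-12)

    def test_palindrome_strand_symmetry(self):
        # palindromic PWM: reverse-complement equals itself
        counts = np.array([[8, 1, 1, 1], [1, 8, 8, 1], [1, 8, 8, 1], [1, 1, 1, 8]],
                          dtype=float)
        pwm = pfm_to_pwm(counts, UNIFORM)
        np.testing.assert_allclose(pwm, pwm[::-1, ::-1], atol=1e-12)
        seq = "ACGTA"
        codes = encode_sequences([seq])
        from imprintscan.motifs import _window_log2_scores
        fwd = _window_log2_scores(codes, pwm)
        rev = _window_log2_scores(codes, pwm[::-1, ::-1])
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_consensus_base_increases_score(self):
        pwm = self.pwm()
        low = affinity_score("TTT", pwm)
        high = affinity_score("ATT", pwm)  # first base to column-1 consensus
        assert high > low

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            affinity_score("AC", self.pwm())

    def test_non_acgt_windows_skipped(self):
        pwm = self.pwm()
        s_clean = affinity_score("ACGT", pwm)
        s_masked = affinity_score("ACGTNN", pwm)
        # the N-containing windows are excluded, clean windows remain
        assert s_masked > 0
        with pytest.raises(ValueError):
            affinity_score("NNN", pwm)


class TestLognormalNull:
    def test_monte_carlo_recovery(self, rng):
        scores = rng.lognormal(mean=-2.0, sigma=0.5, size=10_000)
        mu, sigma = fit_lognormal_background(scores)
        assert mu == pytest.approx(-2.0, abs=3 * 0.5 / math.sqrt(10_000))
        assert sigma == pytest.approx(0.5, abs=0.02)

    def test_degenerate_tiles_floor_sigma(self, caplog):
        with caplog.at_level("WARNING"):
            mu, sigma = fit_lognormal_background(np.full(50, 0.25))
        assert sigma == 1e-6

    def test_order_invariance(self, rng):
        scores = rng.lognormal(size=200)
        a = fit_lognormal_background(scores)
        b = fit_lognormal_background(scores[::-1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_background(np.ones(10))


class TestGroupPvalue:
    def test_single_sequence_reduces_to_lognormal_tail(self):
        mu, sigma = -1.0, 0.7
        s = 0.9
        expected = sps.norm.sf((math.log(s) - mu) / sigma)
        assert group_pvalue([s], mu, sigma) == pytest.approx(expected, rel=1e-12)
        assert group_pvalue([s], mu, sigma, statistic="arith_mean") == pytest.approx(
            expected, rel=1e-9)

    def test_half_at_null_center(self):
        # a target statistic sitting at the null center gives p ~ 0.5
        mu, sigma = -2.0, 0.5
        n = 10_000
        geo_center = np.full(n, math.exp(mu))
        assert group_pvalue(geo_center, mu, sigma) == pytest.approx(0.5)
        arith_center = np.full(n, math.exp(mu + sigma**2 / 2))
        p = group_pvalue(arith_center, mu, sigma, statistic="arith_mean")
        assert 0.45 < p < 0.55

    def test_monotone_decreasing_in_statistic(self):
        mu, sigma = 0.0, 1.0
        ps = [group_pvalue([s], mu, sigma) for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            group_pvalue([0.0], 0.0, 1.0)


class TestTopMotifPercentage:
    def test_cutoff_is_ceil(self):
        # 40 motifs -> ceil(2.0) = 2 top ranks
        rng = np.random.default_rng(0)
        pvals = rng.random((40, 10))
        pct = top_motif_percentage(pvals)
        ranks = sps.rankdata(pvals, method="min", axis=0)
        np.testing.assert_allclose(pct, 100 * (ranks <= 2).mean(axis=1))

    def test_two_of_three_sequences(self):
        pvals = np.array([
            [0.01, 0.02, 0.9],
            [0.5, 0.5, 0.5],
            [0.6, 0.1, 0.1],
        ] + [[0.7, 0.8, 0.9]] * 17)
        pct = top_motif_percentage(pvals)  # 20 motifs -> cutoff 1
        assert pct[0] == pytest.approx(100 * 2 / 3)

    def test_ties_share_minimal_rank(self):
        pvals = np.full((5, 4), 0.5)
        pct = top_motif_percentage(pvals)
        np.testing.assert_allclose(pct, 100.0)


class TestEndToEnd:
    def build(self, rng, n_target=60, n_bg=400, plant_rate=0.5):
        motif = PFM("M1", "PLANT", np.array(
            [[90, 2, 2, 90, 2, 2, 2, 90],
             [2, 90, 2, 2, 2, 2, 90, 2],
             [2, 2, 90, 2, 90, 2, 2, 2],
             [2, 2, 2, 2, 2, 90, 2, 2]], dtype=float))
        decoys = [PFM(f"D{i}", f"DEC{i}", rng.integers(1, 40, (4, 8)).astype(float))
                  for i in range(9)]
        L = 3_000 * 110
        genome = {"chr1": "".join(rng.choice(list("ACGT"), L))}
        pos = np.arange(100, 110 * (n_target + n_bg), 110)[: n_target + n_bg]
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": pos},
                            index=[f"c{i}" for i in range(len(pos))])
        target = cpgs.iloc[:n_target]
        background = cpgs.iloc[n_target:]
        seq = list(genome["chr1"])
        consensus = motif.consensus()
        planted = rng.random(n_target) < plant_rate
        for p, use in zip(target["pos"], planted):
            if use:
                start = p + 5
                seq[start : start + len(consensus)] = consensus
        genome["chr1"] = "".join(seq)
        return motif, decoys, genome, target, background

    def test_planted_motif_selected(self, rng):
        motif, decoys, genome, target, background = self.build(rng)
        res = run_motif_enrichment(target, background, [motif] + decoys, genome)
        row = res.set_index("motif").loc["M1"]
        assert row["p"] < 0.05 and row["top_pct"] >= 10
        assert bool(row["selected"])

    def test_null_targets_not_selected(self, rng):
        motif, decoys, genome, target, background = self.build(rng, plant_rate=0.0)
        res = run_motif_enrichment(target, background, [motif] + decoys, genome)
        row = res.set_index("motif").loc["M1"]
        assert row["p"] > 0.01  # no planted signal

    def test_overlapping_cpgs_removed_from_background(self, rng, caplog):
        motif, decoys, genome, target, background = self.build(rng, plant_rate=0.0)
        bg_plus = pd.concat([background, target.iloc[:5]])
        with caplog.at_level("WARNING"):
            run_motif_enrichment(target, bg_plus, [motif] + decoys, genome)
        assert "removing 5 CpGs" in caplog.text


class TestRemapEnrichment:
    def toy(self):
        target = pd.DataFrame({"chrom": "chr1",
                               "pos": np.arange(1_000, 1_000 + 100 * 200, 200)},
                              index=[f"t{i}" for i in range(100)])
        background = pd.DataFrame({"chrom": "chr1",
                                   "pos": np.arange(50_000, 50_000 + 900 * 200, 200)},
                                  index=[f"b{i}" for i in range(900)])
        return target, background

    def test_reduces_to_fisher(self):
        target, background = self.toy()
        peaks = []
        for p in target["pos"][:10]:
            peaks.append(("chr1", p - 5, p + 5, "TFX"))
        for p in background["pos"][:4]:
            peaks.append(("chr1", p - 5, p + 5, "TFX"))
        tf_peaks = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
        res = remap_binding_enrichment(target, background, tf_peaks).set_index("tf")
        odds, p = fisher_exact_2x2(10, 90, 4, 896)
        assert res.loc["TFX", "n_target_bound"] == 10
        assert res.loc["TFX", "n_bg_bound"] == 4
        assert res.loc["TFX", "p"] == pytest.approx(p, rel=1e-12)
        assert res.loc["TFX", "odds_ratio"] == pytest.approx(odds, rel=1e-9)
        assert res.loc["TFX", "low_background"]  # only 4 bound background CpGs

    def test_empty_peaks_not_assessable(self):
        target, background = self.toy()
        tf_peaks = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10],
                                 "name": ["TFY"]})
        res = remap_binding_enrichment(target, background, tf_peaks).set_index("tf")
        assert not res.loc["TFY", "assessable"]

    def test_window_is_inclusive_of_flank(self):
        target = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000]}, index=["t"])
        background = pd.DataFrame({"chrom": ["chr1"] * 3,
                                   "pos": [5_000, 6_000, 7_000]},
                                  index=list("abc"))
        # peak touching the right edge of the +/-50 window
        tf_peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1_050],
                                 "end": [1_060], "name": ["TFZ"]})
        res = remap_binding_enrichment(target, background, tf_peaks).set_index("tf")
        assert res.loc["TFZ", "n_target_bound"] == 1
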