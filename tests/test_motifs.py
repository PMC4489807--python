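import numpy as np
import pytest

from dellaseq import motifs
from dellaseq.motifs import (
    PWM, DegenerateMotifError, ScanParams, aggregate_by_family,
    binomial_enrichment_test, bonferroni_threshold, count_hit_sequences,
    estimate_expected_frequency, extract_central_windows, format_threshold,
    generate_background_sequences, pwm_log_odds_scan, run_enrichment,
)

from conftest import make_site
from oracles import binom_upper_tail_exact



def sharp_pwm(consensus, family="FAM", information=0.91, motif_id="M1"):
    idx = {b: i for i, b in enumerate("ACGT")}
    freqs = np.full((len(consensus), 4), (1 - information) / 3)
    for j, b in enumerate(consensus):
        freqs[j, idx[b]] = information
    return PWM(motif_id, family, freqs)


REVCOMP = str.maketrans("ACGT", "TGCA")
PARAMS = ScanParams()


class TestWindows:
    def test_window_equals_site_when_widths_match(self):
        genome = {"chr1": "A" * 300 + "CGT" * 300}
        site = make_site("s", "chr1", 500)
        (w,) = extract_central_windows([site], genome, PARAMS)
        assert w == genome["chr1"][400:600]

    def test_central_sub_window(self):
        genome = {"chr1": "ACGT" * 300}
        site = make_site("s", "chr1", 500)
        (w,) = extract_central_windows([site], genome, ScanParams(window_width=100))
        assert w == genome["chr1"][450:550]

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            extract_central_windows([make_site("s", "chrZ", 500)], {"chr1": "A" * 1000}, PARAMS)


class TestScanner:
    def test_consensus_is_a_hit_at_its_offset(self):
        pwm = sharp_pwm("ACGTACGTAC")
        seq = "T" * 20 + pwm.consensus + "G" * 20
        hits = pwm_log_odds_scan(seq, pwm, PARAMS)
        assert (20, "+") in {(off, strand) for off, strand, _ in hits}

    def test_minus_strand_hit_needs_both_strands(self):
        pwm = sharp_pwm("AACCGGTTAA")
        planted = pwm.consensus.translate(REVCOMP)[::-1]
        seq = "T" * 20 + planted + "G" * 20
        both = pwm_log_odds_scan(seq, pwm, PARAMS)
        assert {s for _, s, _ in both} == {"-"}
        fwd_only = pwm_log_odds_scan(seq, pwm, ScanParams(both_strands=False))
        assert fwd_only == []

    def test_n_scores_as_background_neutral(self):
        pwm = sharp_pwm("ACGTACGTAC")
        with_n = "T" * 20 + "NCGTACGTAC" + "G" * 20
        hits = pwm_log_odds_scan(with_n, pwm, PARAMS)
        # one mismatching N costs only that column's positive contribution
        assert any(off == 20 for off, _, _ in hits)

    def test_background_equal_pwm_is_degenerate(self):
        flat = PWM("FLAT", "FAM", np.full((6, 4), 0.25))
        with pytest.raises(DegenerateMotifError):
            pwm_log_odds_scan("ACGTACGTAC", flat, PARAMS)

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            pwm_log_odds_scan("ACGTXCGTACGT", sharp_pwm("ACGTAC"), PARAMS)


class TestHitCounting:
    def test_at_least_one_semantics(self):
        pwm = sharp_pwm("ACGTACGTAC")
        window = ("T" * 5 + pwm.consensus) * 3 + "G" * 20
        assert count_hit_sequences([window], pwm, PARAMS) == 1
        assert count_hit_sequences([], pwm, PARAMS) == 0

    def test_all_planted_windows_count(self):
        pwm = sharp_pwm("ACGTACGTAC")
        windows = ["T" * 30 + pwm.consensus + "A" * 30 for _ in range(7)]
        assert count_hit_sequences(windows, pwm, PARAMS) == 7

    def test_reverse_complementing_windows_preserves_counts(self, rng):
        pwm = sharp_pwm("AGGTCANTGA".replace("N", "C"))
        windows = generate_background_sequences(80, PARAMS, rng)
        windows += ["T" * 95 + pwm.consensus + "A" * 95 for _ in range(5)]
        rc = [w.translate(REVCOMP)[::-1] for w in windows]
        assert count_hit_sequences(windows, pwm, PARAMS) == count_hit_sequences(
            rc, pwm, PARAMS
        )

    def test_batched_and_looped_paths_agree(self, rng):
        pwm = sharp_pwm("ACGGTTCA")
        windows = generate_background_sequences(50, ScanParams(window_width=60), rng)
        encoded = motifs.encode_windows(windows)
        assert count_hit_sequences(windows, pwm, PARAMS) == count_hit_sequences(
            encoded, pwm, PARAMS
        )


class TestExpectedFrequency:
    def test_matches_first_order_occurrence_bound(self, rng):
        # high-information 12-mer: the chance of >=1 hit in a 200-mer is
        # approximately 2 * (200 - 12 + 1) * prod(background at consensus)
        pwm = sharp_pwm("ACGTAGCTAGCT", information=0.97)
        n = 10_000
        seqs = generate_background_sequences(n, PARAMS, rng)
        p_hat = estimate_expected_frequency(pwm, PARAMS, seqs)
        p_analytic = 2 * (200 - 12 + 1) * 0.25 ** 12
        se = np.sqrt(p_analytic * (1 - p_analytic) / n)
        assert abs(p_hat - p_analytic) <= max(3 * se, 1.0 / n)

    def test_monotone_in_threshold(self, rng):
        pwm = sharp_pwm("ACGTACGT")
        seqs = generate_background_sequences(500, PARAMS, rng)
        strict = estimate_expected_frequency(pwm, ScanParams(score_threshold_fraction=1.0), seqs)
        loose = estimate_expected_frequency(pwm, ScanParams(score_threshold_fraction=0.8), seqs)
        assert strict <= loose

    def test_floor_avoids_zero(self, rng):
        pwm = sharp_pwm("ACGTAGCTAGCTACGTAGCT", information=0.97)
        seqs = generate_background_sequences(200, PARAMS, rng)
        assert estimate_expected_frequency(pwm, PARAMS, seqs) >= 1 / 400

    def test_requires_enough_background(self):
        with pytest.raises(ValueError, match="100"):
            estimate_expected_frequency(sharp_pwm("ACGTAC"), PARAMS, ["ACGT" * 50] * 10)


class TestBinomialTest:
    def test_k_zero_gives_one(self):
        assert binomial_enrichment_test(0, 10, 0.1) == 1.0

    def test_small_example_against_exact_tail(self):
        # frozen from the rational-arithmetic oracle
        p = binomial_enrichment_test(5, 10, 0.1)
        assert p == pytest.approx(1.6349374e-3, rel=1e-6)
        assert p == pytest.approx(binom_upper_tail_exact(5, 10, 0.1), rel=1e-12)

    def test_k_equals_n_closed_form(self):
        assert binomial_enrichment_test(20, 20, 0.5) == pytest.approx(0.5 ** 20, rel=1e-12)

    def test_invalid_p_expected(self):
        with pytest.raises(ValueError):
            binomial_enrichment_test(1, 10, 0.0)


class TestBonferroni:
    def test_study_library_size_prints_as_published(self):
        thr = bonferroni_threshold(0.05, 254)
        assert thr == pytest.approx(1.9685e-4, rel=1e-4)
        assert format_threshold(thr) == "1.9E-4"

    def test_single_motif_keeps_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_fifty_motifs(self):
        assert bonferroni_threshold(0.05, 50) == pytest.approx(1e-3)


class TestFamilyAggregation:
    def _results(self, windows, pwms):
        return run_enrichment(
            windows, pwms, PARAMS, alpha=0.05, n_background=200,
            rng=np.random.default_rng(7),
        )

    def test_family_reported_with_best_member_p(self, rng):
        sig = sharp_pwm("ACGTTGCAAC", motif_id="SIG", family="F1")
        dull = sharp_pwm("TTGACGTCAA", motif_id="DULL", family="F1")
        other = sharp_pwm("GGGTTTAAAC", motif_id="OTH", family="F2")
        windows = generate_background_sequences(40, PARAMS, rng)
        windows = [w[:95] + sig.consensus + w[105:] for w in windows]
        results = self._results(windows, [sig, dull, other])
        table = aggregate_by_family(results, windows, [sig, dull, other], PARAMS)
        assert list(table["family"]) == ["F1"]
        row = table.iloc[0]
        by_id = {r.motif_id: r for r in results}
        assert row["best_p_value"] == min(by_id["SIG"].p_value, by_id["DULL"].p_value)

    def test_union_counts_window_once(self, rng):
        a = sharp_pwm("ACGTTGCAAC", motif_id="A", family="F1")
        b = sharp_pwm("GCATGCATGC", motif_id="B", family="F1")
        windows = [
            "T" * 60 + a.consensus + "T" * 30 + b.consensus + "T" * 100,
        ] * 30
        results = self._results(windows, [a, b])
        table = aggregate_by_family(results, windows, [a, b], PARAMS)
        assert int(table.iloc[0]["n_windows_hit"]) == 30

    def test_no_significant_member_no_row(self, rng):
        pwm = sharp_pwm("ACGTTGCAAC", motif_id="A", family="F1")
        windows = generate_background_sequences(30, PARAMS, rng)
        results = self._results(windows, [pwm])
        if not any(r.significant for r in results):
            assert aggregate_by_family(results).empty
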