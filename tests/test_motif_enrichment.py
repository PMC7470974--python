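import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from promoterome.io_formats import PWMModel, PromoterWindow
from promoterome.motif_enrichment import (
    W_PENTAMERS, best_match, fisher_enrichment, log2_odds_ratio,
    motif_group_enrichment, motif_hit_table, polyw_pentamer_enrichment,
    pwm_match_percent, tata_match_distribution, ww_dinucleotide_profile,
)
from promoterome.synthetic_data import synthetic_pwms


def pwm_from_consensus(name, consensus, dominant=0.85):
    counts = np.full((len(consensus), 4), (1 - dominant) / 3 * 100)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = dominant * 100
    return PWMModel.from_counts(name, counts, pseudocount=0.0)


def window(seq, offset_start=-120):
    return PromoterWindow(seq=seq, offset_start=offset_start, chrom="chr1",
                          dominant_pos=1000, strand="+")


TATA = next(m for m in synthetic_pwms() if m.name == "TATA")


class TestScanner:
    def test_forced_consensus_scores_100(self):
        pwm = pwm_from_consensus("M", "TA")
        offsets, pct = pwm_match_percent(pwm, window("GGTAGG", offset_start=-3))
        assert pct.max() == pytest.approx(100.0)
        assert offsets[int(pct.argmax())] == -1  # "TA" starts at index 2

    def test_all_c_window_matches_formula(self):
        pwm = pwm_from_consensus("TATAish", "TATAA")
        w = window("C" * 30, offset_start=-10)
        _, pct = pwm_match_percent(pwm, w)
        assert np.allclose(pct, oracles.pwm_scan(pwm.matrix, w.seq))

    def test_equals_bruteforce_rescoring_on_random_inputs(self, rng):
        """The vectorized scanner reproduces naive per-offset rescoring for
        random PWMs and windows."""
        for _ in range(100):
            L = int(rng.integers(2, 9))
            counts = rng.uniform(0.5, 50, size=(L, 4))
            pwm = PWMModel.from_counts("R", counts, pseudocount=0.1)
            seq = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(L, 40))))
            w = window(seq, offset_start=int(rng.integers(-60, 0)))
            offsets, pct = pwm_match_percent(pwm, w)
            np.testing.assert_allclose(pct, oracles.pwm_scan(pwm.matrix, seq),
                                       atol=1e-9)
            assert offsets[0] == w.offset_start

    def test_degenerate_pwm_is_error(self):
        flat = PWMModel("flat", np.full((3, 4), 0.25))
        with pytest.raises(ValueError, match="degenerate"):
            pwm_match_percent(flat, window("ACGTACGT", -4))

    def test_region_restriction_property(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=171))
            w = window(seq, offset_start=-120)
            hits = motif_hit_table([TATA], {"x": w}, hit_percent=0.0,
                                   region=(-40, -20))
            offs = hits["hit_offsets"].iloc[0]
            if offs:
                assert all(-40 <= int(o) <= -20 for o in offs.split(","))


class TestFisher:
    def test_worked_table(self):
        p, l2or = fisher_enrichment(10, 90, 5, 195)
        assert 2.0 ** l2or == pytest.approx(13 / 3, rel=1e-12)  # OR 4.333...
        assert p == pytest.approx(oracles.fisher_exact_p(10, 90, 5, 195),
                                  abs=1e-9)

    def test_matches_enumeration_on_random_small_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            p, _ = fisher_enrichment(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(
                oracles.fisher_exact_p(int(a), int(b), int(c), int(d)),
                abs=1e-9)

    def test_identical_rates_are_null(self):
        p, l2or = fisher_enrichment(10, 90, 20, 180)
        assert abs(l2or) < 1e-9
        assert p == pytest.approx(1.0, abs=0.05)

    def test_haldane_correction_on_zero_cell(self):
        assert np.isfinite(log2_odds_ratio(0, 10, 5, 5))


class TestGroupEnrichment:
    def test_planted_tata_enrichment(self, rng):
        """TATA planted in 60% of the signal group vs 10% background gives a
        positive log2 OR at p < 0.01."""
        windows, labels = {}, {}
        for i in range(400):
            group = "signal" if i < 200 else "background"
            p_tata = 0.6 if group == "signal" else 0.1
            seq = "".join(rng.choice(list("CG"), size=171))
            if rng.random() < p_tata:
                k = 120 - 30  # motif start at offset -30
                seq = seq[:k] + TATA.consensus + seq[k + len(TATA):]
            windows[f"cc{i}"] = window(seq)
            labels[f"cc{i}"] = group
        hits = motif_hit_table([TATA], windows)
        enr = motif_group_enrichment(pd.Series(labels), hits, "background")
        row = enr[(enr["motif"] == "TATA") & (enr["group"] == "signal")].iloc[0]
        assert row["log2_odds_ratio"] > 0
        assert row["p_value"] < 0.01 and row["significant"]

    def test_empty_background_is_error(self):
        hits = pd.DataFrame({"cc_id": ["a"], "motif": ["M"], "is_hit": [True]})
        with pytest.raises(ValueError, match="background"):
            motif_group_enrichment(pd.Series({"a": "g1"}), hits, "nope")


class TestTataDistribution:
    def test_canonical_tata_in_top_bin(self):
        seq = "G" * (120 - 30) + TATA.consensus + "G" * (171 - 120 + 30 - len(TATA))
        per, dist = tata_match_distribution(TATA, {"x": window(seq)})
        assert per["best_percent"].iloc[0] == pytest.approx(100.0)
        assert dist.set_index("match_bin").loc[">90", "n_promoters"] == 1

    def test_no_at_in_region_lowest_bin(self):
        per, dist = tata_match_distribution(TATA, {"x": window("C" * 171)})
        assert dist.set_index("match_bin").loc["<75", "n_promoters"] == 1

    def test_single_mismatch_lands_in_tata_like_bin(self, rng):
        """One-mismatch (TATA-like) sequences fall in the 75-90% band."""
        n_mid = 0
        for i in range(20):
            cons = list(TATA.consensus)
            j = int(rng.integers(len(cons)))
            cons[j] = {"A": "C", "T": "G", "G": "T", "C": "A"}[cons[j]]
            seq = "G" * 90 + "".join(cons) + "G" * (171 - 90 - len(cons))
            per, _ = tata_match_distribution(
                TATA, {"x": window(seq)}, region=(-120, 50))
            if 75 <= per["best_percent"].iloc[0] <= 90:
                n_mid += 1
        assert n_mid >= 18

    def test_offsets_restricted_to_region(self):
        seq = "G" * 50 + TATA.consensus + "G" * (171 - 50 - len(TATA))
        per, _ = tata_match_distribution(TATA, {"x": window(seq)})
        off = per["best_offset"].iloc[0]
        assert -40 <= off <= -20


class TestWWProfile:
    def test_extremes_and_uniform(self, rng):
        at = [window("AT" * 50, -50) for _ in range(5)]
        assert (ww_dinucleotide_profile(at)["ww_frequency"] == 1.0).all()
        gc = [window("GC" * 50, -50) for _ in range(5)]
        assert (ww_dinucleotide_profile(gc)["ww_frequency"] == 0.0).all()
        rand = [window("".join(rng.choice(list("ACGT"), size=100)), -50)
                for _ in range(400)]
        prof = ww_dinucleotide_profile(rand)
        assert prof["ww_frequency"].mean() == pytest.approx(0.25, abs=0.02)


class TestPentamers:
    def test_universe_is_32(self):
        assert len(W_PENTAMERS) == 32
        assert len(set(W_PENTAMERS)) == 32

    def test_tataaa_contains_flagged_pentamer(self):
        seq = "G" * 90 + TATA.consensus + "G" * (171 - 90 - len(TATA))
        groups = pd.Series({"x": "sig", "y": "bg"})
        windows = {"x": window(seq), "y": window("G" * 171)}
        out = polyw_pentamer_enrichment(groups, windows, "bg", tata_pwm=TATA)
        row = out[(out["pentamer"] == "TATAA") & (out["group"] == "sig")].iloc[0]
        assert row["n_group_hit"] == 1
        assert row["n_tata_overlap"] == 1

    def test_planted_pentamer_enrichment(self, rng):
        """TTAAA planted in 40% of the signal group vs 5% of the background
        is significantly enriched (Fisher p < 0.01)."""
        windows, labels = {}, {}
        for i in range(400):
            group = "sig" if i < 200 else "bg"
            seq = list("".join(rng.choice(list("CG"), size=171)))
            if rng.random() < (0.4 if group == "sig" else 0.05):
                k = 120 - 30
                seq[k:k + 5] = "TTAAA"
            windows[f"c{i}"] = window("".join(seq))
            labels[f"c{i}"] = group
        out = polyw_pentamer_enrichment(pd.Series(labels), windows, "bg")
        row = out[(out["pentamer"] == "TTAAA") & (out["group"] == "sig")].iloc[0]
        assert row["p_value"] < 0.01 and row["log2_odds_ratio"] > 0


def test_best_match_region_none_when_window_too_short():
    pct, off = best_match(TATA, window("ACG", -1))
    assert np.isnan(pct) and off is None
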