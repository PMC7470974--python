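import numpy as np
import pandas as pd
import pytest

from promoterome.io_formats import extract_promoter_window, read_ctss, \
    read_pwm_jaspar
from promoterome.motif_enrichment import pwm_match_percent
from promoterome.synthetic_data import (
    SimConfig, shape_profile, simulate_dataset, simulate_genome, synthetic_pwms,
    write_dataset,
)
from conftest import small_config


def tiny_config(**kw):
    base = dict(seed=5, n_genes=60, genes_per_chrom=30, n_up_a=6, n_up_b=6,
                alt_recipe={"not_selected": 2}, n_temporal_gained=2,
                n_temporal_lost=2, n_temporal_none=2)
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_deterministic_given_seed(self, tmp_path):
        ds1 = simulate_dataset(tiny_config())
        ds2 = simulate_dataset(tiny_config())
        assert ds1.genome == ds2.genome
        pd.testing.assert_frame_equal(ds1.truth, ds2.truth)
        for s in ds1.ctss:
            pd.testing.assert_frame_equal(ds1.ctss[s], ds2.ctss[s])
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_dataset(ds1, p1)
        write_dataset(ds2, p2)
        assert (p1 / "genome.fa").read_bytes() == (p2 / "genome.fa").read_bytes()

    def test_zero_gc_background_is_all_at(self):
        cfg = tiny_config(gc_fraction=0.0, motif_prob_background=0.0,
                          baseline_motif_probs={"SP1": 0.0, "INR": 0.0,
                                                "YY1": 0.0},
                          motif_prob_matched=0.0, tatalike_prob_matched=0.0,
                          tatalike_prob_background=0.0)
        genome, _, _ = simulate_genome(cfg)
        assert set("".join(genome.values())) <= {"A", "T"}

    def test_certain_tata_planting_yields_canonical_hits(self):
        """With TATA probability 1 every promoter window carries a >=90%
        TATA match starting in the -40..-20 region."""
        cfg = tiny_config(motif_prob_matched=1.0, motif_prob_background=1.0,
                          n_up_a=0, n_up_b=0)
        genome, ann, truth = simulate_genome(cfg)
        tata = next(m for m in synthetic_pwms() if m.name == "TATA")
        for _, g in truth.iterrows():
            w = extract_promoter_window(genome, g["chrom"], g["tss"],
                                        g["strand"])
            offs, pct = pwm_match_percent(tata, w)
            keep = (offs >= -40) & (offs <= -20)
            assert pct[keep].max() >= 90.0

    def test_truth_motif_flags_match_planted_sequence(self, small_dataset):
        ds = small_dataset
        tata = next(m for m in ds.pwms if m.name == "TATA")
        with_tata = ds.truth[ds.truth["has_TATA"]]
        for _, g in with_tata.head(30).iterrows():
            w = extract_promoter_window(ds.genome, g["chrom"], g["tss"],
                                        g["strand"])
            _, pct = pwm_match_percent(tata, w)
            assert pct.max() >= 90.0

    def test_annotation_tss_matches_truth(self, small_dataset):
        merged = small_dataset.annotation.merge(small_dataset.truth,
                                                on="gene_id")
        assert (merged["tss_x"] == merged["tss_y"]).all()


class TestProfiles:
    def test_sharp_profile_concentrates_within_ten_bases(self):
        """A sharp promoter with many tags yields an interquantile width
        below 10 bp essentially always."""
        cfg = tiny_config()
        probs = shape_profile(cfg, "sharp")
        rng = np.random.default_rng(0)
        offsets = np.arange(-cfg.profile_halfwidth, cfg.profile_halfwidth + 1)
        narrow = 0
        for _ in range(100):
            tags = rng.multinomial(10_000, probs)
            cum = np.cumsum(tags) / tags.sum()
            lo = offsets[np.searchsorted(cum, 0.1)]
            hi = offsets[np.searchsorted(cum, 0.9)]
            narrow += (hi - lo + 1) < 10
        assert narrow >= 99

    def test_peaked_profile_mass_and_extent(self):
        cfg = tiny_config()
        rng = np.random.default_rng(1)
        for _ in range(20):
            probs = shape_profile(cfg, "peaked_broad", rng)
            assert probs[cfg.profile_halfwidth] == pytest.approx(
                cfg.peaked_dominant_mass)
            assert probs.sum() == pytest.approx(1.0)
            support = np.flatnonzero(probs) - cfg.profile_halfwidth
            assert support.min() <= -6 and support.max() >= 6


class TestCounts:
    def test_replicate_correlation_high(self, small_dataset):
        """Within-condition replicates correlate strongly (r > 0.9) on
        per-promoter log tpm at the default dispersion."""
        from promoterome.normalization import normalize_sample

        ds = small_dataset
        truth = ds.truth
        totals = {}
        for s in ("G1_rep1", "G1_rep2"):
            t, _ = normalize_sample(ds.ctss[s])
            sums = []
            for _, g in truth.iterrows():
                sub = t[(t["chrom"] == g["chrom"])
                        & (t["pos"].between(g["tss"] - 150, g["tss"] + 150))]
                sums.append(sub["tpm"].sum())
            totals[s] = np.log10(np.array(sums) + 0.1)
        r = np.corrcoef(totals["G1_rep1"], totals["G1_rep2"])[0, 1]
        assert r > 0.9

    def test_planted_fold_change_visible_in_raw_totals(self, small_dataset):
        ds = small_dataset
        truth = ds.truth
        up_a = truth[truth["de_group"] == "up_G1"].head(10)
        for _, g in up_a.iterrows():
            tot = {}
            for cond in ("G1", "SG2M"):
                t = ds.ctss[f"{cond}_rep1"]
                sub = t[(t["chrom"] == g["chrom"])
                        & (t["pos"].between(g["tss"] - 150, g["tss"] + 150))]
                tot[cond] = sub["count"].sum()
            assert tot["G1"] > tot["SG2M"]


class TestWrittenFormats:
    def test_outputs_are_pipeline_readable(self, tmp_path):
        ds = simulate_dataset(tiny_config())
        paths = write_dataset(ds, tmp_path / "out")
        table = read_ctss(paths["ctss_G1_rep1"])
        assert len(table) == len(ds.ctss["G1_rep1"])
        pwms = read_pwm_jaspar(paths["pwms"])
        assert {m.name for m in pwms} == {"TATA", "CCAAT", "SP1", "INR", "YY1"}
        import pyfaidx
        fa = pyfaidx.Fasta(str(paths["genome"]))
        assert set(fa.keys()) == set(ds.genome)


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimConfig()  # no seed
    with pytest.raises(ValueError):
        SimConfig(seed=None)


def test_shape_proportions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(seed=1, shape_proportions={"sharp": 0.5,
                                             "peaked_broad": 0.2,
                                             "broad": 0.2})


def test_small_config_importable():
    cfg = small_config()
    assert cfg.n_genes == 400
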