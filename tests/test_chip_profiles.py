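import numpy as np
import pandas as pd
import pytest

from xdosage import chip_profiles as cp
from xdosage.io_core import CoverageTrack, ValidationError


def track(values: dict, bin_size=10, kind="raw"):
    return CoverageTrack(bin_size, {c: np.asarray(v, dtype=float)
                                    for c, v in values.items()}, kind)


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestNormalizeEnrichment:
    def test_identical_constant_tracks_give_zero(self):
        chip = track({"I": np.full(10, 5.0)})
        inp = track({"I": np.full(10, 5.0)})
        out = cp.normalize_enrichment(chip, inp)
        np.testing.assert_allclose(out.values["I"], 0.0)
        assert out.value_kind == "normalized"

    def test_twofold_region_over_flat_input_gives_one(self):
        chip_vals = np.full(100, 4.0)
        chip_vals[10:20] = 8.0  # 2x the chip median
        chip = track({"I": chip_vals})
        inp = track({"I": np.full(100, 7.0)})  # flat at its own median
        out = cp.normalize_enrichment(chip, inp)
        np.testing.assert_allclose(out.values["I"][10:20], 1.0)
        np.testing.assert_allclose(out.values["I"][:10], 0.0)

    def test_mtdna_excluded_from_median_but_carried_through(self):
        base = {"I": np.arange(1, 101, dtype=float), "MtDNA": np.full(10, 3.0)}
        inflated = {"I": base["I"].copy(), "MtDNA": base["MtDNA"] * 100}
        inp = {"I": np.full(100, 2.0), "MtDNA": np.full(10, 2.0)}
        out1 = cp.normalize_enrichment(track(base), track(inp))
        out2 = cp.normalize_enrichment(track(inflated), track(inp))
        np.testing.assert_allclose(out1.values["I"], out2.values["I"])
        assert "MtDNA" in out1.values

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        c, i = rng.poisson(20, 200).astype(float) + 1, rng.poisson(20, 200).astype(float) + 1
        out1 = cp.normalize_enrichment(track({"I": c}), track({"I": i}))
        out2 = cp.normalize_enrichment(track({"I": c * 13}), track({"I": i * 0.4}))
        np.testing.assert_allclose(out1.values["I"], out2.values["I"], atol=1e-9)

    def test_zero_median_rejected(self):
        with pytest.raises(ValidationError, match="median"):
            cp.normalize_enrichment(track({"I": np.zeros(10)}),
                                    track({"I": np.ones(10)}))


class TestMergeReplicates:
    def test_mean_of_zero_and_two_track(self):
        out = cp.merge_replicates([track({"I": np.zeros(5)}),
                                   track({"I": np.full(5, 2.0)})])
        np.testing.assert_allclose(out.values["I"], 1.0)

    def test_single_track_is_itself(self):
        t = track({"I": np.arange(5, dtype=float)})
        np.testing.assert_allclose(cp.merge_replicates([t]).values["I"],
                                   t.values["I"])

    def test_identical_tracks_unchanged(self):
        t = track({"I": np.arange(5, dtype=float)})
        out = cp.merge_replicates([t, t, t])
        np.testing.assert_allclose(out.values["I"], t.values["I"])

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValidationError):
            cp.merge_replicates([track({"I": np.zeros(5)}),
                                 track({"I": np.zeros(6)})])


class TestStandardizeZscore:
    def test_background_moments_after_transform(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 2, 100_000)
        vals[:1000] = 50.0  # peak region
        t = track({"I": vals}, kind="normalized")
        peaks = bed([("I", 0, 1000 * 10)])
        out = cp.standardize_zscore(t, peaks)
        background = out.values["I"][1000:]
        assert background.mean() == pytest.approx(0.0, abs=0.05)
        assert background.std() == pytest.approx(1.0, abs=0.05)

    def test_bin_at_background_mean_maps_to_zero(self):
        vals = np.array([1.0, 3.0, 100.0])
        t = track({"I": vals}, kind="normalized")
        peaks = bed([("I", 20, 30)])
        out = cp.standardize_zscore(t, peaks)
        # background {1, 3}: mean 2, sd 1 -> values (-1, 1, 98)
        np.testing.assert_allclose(out.values["I"], [-1.0, 1.0, 98.0])

    def test_no_peaks_means_genome_wide_zscore(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(3, 1, 1000)
        out = cp.standardize_zscore(track({"I": vals}, kind="normalized"))
        np.testing.assert_allclose(out.values["I"],
                                   (vals - vals.mean()) / vals.std(), atol=1e-12)

    def test_zero_background_sd_rejected(self):
        with pytest.raises(ValidationError, match="deviation"):
            cp.standardize_zscore(track({"I": np.full(10, 2.0)},
                                        kind="normalized"))


class TestConsensusPeaks:
    def test_majority_of_three_retained(self):
        combined = bed([("I", 100, 200), ("I", 500, 600)])
        reps = [bed([("I", 150, 180)]), bed([("I", 190, 250)]),
                bed([("I", 800, 900)])]
        out = cp.consensus_peaks(combined, reps)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100

    def test_one_of_three_dropped(self):
        combined = bed([("I", 100, 200)])
        reps = [bed([("I", 150, 180)]), bed([("II", 150, 180)]),
                bed([("I", 300, 400)])]
        assert len(cp.consensus_peaks(combined, reps)) == 0

    def test_two_replicates_require_both(self):
        combined = bed([("I", 100, 200)])
        reps = [bed([("I", 150, 180)]), bed([("I", 300, 400)])]
        assert len(cp.consensus_peaks(combined, reps)) == 0
        reps2 = [bed([("I", 150, 180)]), bed([("I", 199, 300)])]
        assert len(cp.consensus_peaks(combined, reps2)) == 1

    def test_output_subset_and_monotone_in_support(self):
        rng = np.random.default_rng(3)
        combined = bed([("I", int(s), int(s) + 50)
                        for s in rng.integers(0, 10_000, 20)])
        reps = [bed([("I", int(s), int(s) + 50)
                     for s in rng.integers(0, 10_000, 30)]) for _ in range(3)]
        out = cp.consensus_peaks(combined, reps)
        merged = pd.merge(out, combined, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        # adding a replicate set that overlaps everything only grows support
        everything = bed([("I", 0, 10_000 + 100)])
        out2 = cp.consensus_peaks(combined, reps + [everything, everything])
        assert set(map(tuple, out.to_numpy())) <= set(map(tuple, out2.to_numpy()))


class TestMetageneProfile:
    def catalog(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start",
                                         "end", "strand"])
        return df.set_index("gene_id")

    def test_impulse_at_plus_strand_tss(self):
        vals = np.zeros(100)
        vals[50] = 7.0
        t = track({"I": vals}, kind="normalized")
        cat = self.catalog([("g", "I", 501, 700, "+")])  # TSS in bin 50
        prof = cp.metagene_profile(t, cat, anchor="TSS", flank=100)
        at0 = prof.loc[prof["position"] == 0, "mean"].iloc[0]
        assert at0 == pytest.approx(7.0)
        assert prof.loc[prof["position"] != 0, "mean"].abs().max() == 0.0

    def test_minus_strand_impulse_flips_orientation(self):
        vals = np.zeros(200)
        vals[110] = 5.0  # 100 bp 3'-of-TSS in genome coords (TSS bin 100)
        t = track({"I": vals}, kind="normalized")
        cat = self.catalog([("g", "I", 501, 1010, "-")])  # TSS = end = 1010
        prof = cp.metagene_profile(t, cat, anchor="TSS", flank=200)
        # genomic position +100 relative to a minus-strand TSS is upstream (-100)
        at = prof.loc[prof["position"] == -100, "mean"].iloc[0]
        assert at == pytest.approx(5.0)

    def test_constant_track_gives_flat_profile(self):
        t = track({"I": np.full(100, 2.5), "X": np.full(100, 2.5)},
                  kind="normalized")
        cat = self.catalog([("a", "I", 301, 400, "+"), ("b", "X", 301, 400, "-")])
        prof = cp.metagene_profile(t, cat, anchor="TES", flank=100)
        np.testing.assert_allclose(prof["mean"], 2.5)

    def test_quintile_groups_are_exact_fifths(self):
        rng = np.random.default_rng(4)
        cat = self.catalog([(f"g{i}", "I", 1 + 100 * i, 100 * i + 50, "+")
                            for i in range(100)])
        t = track({"I": np.zeros(2000)}, kind="normalized")
        expr = pd.Series(rng.lognormal(1, 1, 100), index=cat.index)
        prof = cp.metagene_profile(t, cat, anchor="TSS", flank=50,
                                   groups="expression_quintiles",
                                   expression=expr)
        n_per_group = prof.groupby("group")["n"].max()
        assert (n_per_group == 20).all()

    def test_intergenic_midpoints_respect_min_distance(self):
        cat = self.catalog([("a", "I", 1001, 2000, "+"),
                            ("b", "I", 20_001, 21_000, "+")])
        mids = cp.intergenic_midpoints(cat, {"I": 40_000}, min_distance=5000)
        # gap between genes: 2000..20000 (18 kb > 10 kb) and tail 21000..40000
        assert len(mids) == 2
        assert mids.iloc[0]["position"] == (2000 + 20_000) // 2

    def test_edge_genes_contribute_only_in_bounds_positions(self):
        vals = np.arange(10, dtype=float)
        t = track({"I": vals}, kind="normalized")
        cat = self.catalog([("g", "I", 11, 60, "+")])  # TSS bin 1; flank 3 bins
        prof = cp.metagene_profile(t, cat, anchor="TSS", flank=30)
        n_by_pos = prof.set_index("position")["n"]
        assert n_by_pos.loc[-30] == 0  # off-chromosome
        assert n_by_pos.loc[0] == 1
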