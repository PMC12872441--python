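"""Codon occupancy, pause calling, short-footprint ratios and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oracles import brute_force_pause_scan

from codonscape.landscape import (
    calibrate_offsets,
    codon_occupancy,
    detect_pauses,
    occupancy_by_class,
    periodicity_qc,
    short_footprint_ratio,
)


def make_track(genes):
    """genes: {gene_id: [(codon, short, long), ...]} in codon order."""
    rows = []
    for gene_id, entries in genes.items():
        for idx, (codon, short, long_) in enumerate(entries):
            rows.append(
                {
                    "gene_id": gene_id,
                    "codon_index": idx,
                    "codon": codon,
                    "short_count": short,
                    "long_count": long_,
                }
            )
    return pd.DataFrame(rows)


def uniform_gene(n, codon="AAA", per_codon=2, stop=True):
    entries = [("ATG", 0, per_codon)] + [(codon, 0, per_codon)] * (n - 1)
    if stop:
        entries.append(("TAA", 0, 0))
    return entries


class TestOccupancy:
    def test_relative_density(self):
        # 10 codons, 20 footprints total, one position with 4
        entries = [("AAA", 0, 2)] * 10
        entries[6] = ("AAA", 0, 4)
        entries[3] = ("AAA", 0, 0)
        track = make_track({"g": entries})
        occ = codon_occupancy(track)
        pos = occ.positions.set_index("codon_index")
        assert pos.loc[6, "e"] == pytest.approx(4 / 2.0)
        assert pos.loc[3, "e"] == 0.0

    def test_mean_density_is_one_without_exclusions(self, rng):
        entries = [("AAA", 0, int(c)) for c in rng.integers(1, 30, 50)]
        occ = codon_occupancy(make_track({"g": entries}), exclude_first=0)
        assert occ.positions["e"].mean() == pytest.approx(1.0)

    def test_mean_rpf_rule_is_strict(self):
        track = make_track({"g": [("AAA", 0, 1)] * 10})  # mean exactly 1
        occ = codon_occupancy(track)
        assert not occ.gene_stats.loc["g", "included"]
        track2 = make_track({"g": [("AAA", 0, 2)] * 10})
        assert codon_occupancy(track2).gene_stats.loc["g", "included"]

    def test_first_four_and_stop_excluded_from_type_mean(self):
        entries = [("GGG", 0, 2)] * 4 + [("AAA", 0, 2)] * 8 + [("TAA", 0, 5)]
        occ = codon_occupancy(make_track({"g": entries}))
        assert "GGG" not in occ.per_codon_type.index
        assert "TAA" not in occ.per_codon_type.index

    def test_codon_type_mean(self):
        # two AAA positions with e = 0.5 and 1.5 -> occupancy 1.0
        entries = (
            [("GGG", 0, 2)] * 4
            + [("AAA", 0, 1), ("AAA", 0, 3), ("GGC", 0, 2), ("GGC", 0, 2)]
        )
        occ = codon_occupancy(make_track({"g": entries}))
        assert occ.gene_stats.loc["g", "mean_rpf"] == pytest.approx(2.0)
        assert occ.per_codon_type["AAA"] == pytest.approx(1.0)


class TestPauseCalling:
    @staticmethod
    def _occupancy_from_e(e_values):
        """Hand-built relative-density profile for one gene."""
        from codonscape.landscape import OccupancyTable

        positions = pd.DataFrame(
            {
                "gene_id": "g",
                "codon_index": np.arange(len(e_values)) + 4,
                "codon": "AAA",
                "count": np.asarray(e_values, dtype=float),
                "e": np.asarray(e_values, dtype=float),
                "in_type_mean": True,
            }
        )
        stats = pd.DataFrame(
            {"rpf": [np.sum(e_values)], "length": [len(e_values)],
             "mean_rpf": [np.mean(e_values)], "included": [True]},
            index=pd.Index(["g"], name="gene_id"),
        )
        return OccupancyTable(positions, pd.Series(dtype=float), stats)

    def test_nine_ones_one_eleven_profile(self):
        # ē = 2, population sd = 3, threshold at k=2 is 8 -> one call
        occ = self._occupancy_from_e([1.0] * 9 + [11.0])
        calls = detect_pauses(occ, k=2)
        assert int(calls.calls["is_pause"].sum()) == 1
        flagged = calls.calls[calls.calls["is_pause"]]
        assert flagged.iloc[0]["e"] == pytest.approx(11.0)
        assert flagged.iloc[0]["threshold"] == pytest.approx(8.0)

    def test_k3_threshold_strict_inequality(self):
        # threshold = 2 + 3*3 = 11 and e = 11 is not strictly above
        occ = self._occupancy_from_e([1.0] * 9 + [11.0])
        calls = detect_pauses(occ, k=3)
        assert int(calls.calls["is_pause"].sum()) == 0

    def test_constant_profile_no_calls(self):
        track = make_track({"g": [("AAA", 0, 5)] * 20})
        calls = detect_pauses(codon_occupancy(track), k=2)
        assert int(calls.calls["is_pause"].sum()) == 0

    def test_sample_sd_mode(self):
        occ = self._occupancy_from_e([1.0] * 9 + [11.0])
        pop = detect_pauses(occ, k=2, sd_mode="population")
        samp = detect_pauses(occ, k=2, sd_mode="sample")
        assert samp.calls["threshold"].iloc[0] > pop.calls["threshold"].iloc[0]

    def test_gene_fraction(self):
        occ = self._occupancy_from_e([1.0] * 9 + [11.0])
        calls = detect_pauses(occ, k=2)
        assert calls.gene_fraction["g"] == pytest.approx(0.1)

    def test_matches_brute_force_scan(self, small_dataset):
        track = small_dataset.footprints["t4"]["rep1"]
        occ = codon_occupancy(track)
        for k in (1.5, 2.0, 3.0):
            calls = detect_pauses(occ, k=k)
            flagged = {
                (r.gene_id, r.codon_index)
                for r in calls.calls[calls.calls["is_pause"]].itertuples()
            }
            pool = occ.positions[occ.positions["in_type_mean"]]
            e_by_gene = {
                g: list(zip(sub["codon_index"], sub["e"]))
                for g, sub in pool.groupby("gene_id")
            }
            assert flagged == brute_force_pause_scan(e_by_gene, k)

    def test_raising_k_never_adds_calls(self, small_dataset):
        occ = codon_occupancy(small_dataset.footprints["t0"]["rep2"])
        counts = [
            int(detect_pauses(occ, k=k).calls["is_pause"].sum())
            for k in (1.0, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestShortFootprintRatio:
    def test_basic_ratio(self):
        track = make_track({"g": [("ATG", 0, 1)] + [("AAA", 3, 7)]})
        sfr = short_footprint_ratio(track)
        assert sfr["AAA"] == pytest.approx(0.3)

    def test_all_short(self):
        track = make_track({"g": [("ATG", 0, 1), ("AAA", 5, 0)]})
        assert short_footprint_ratio(track)["AAA"] == 1.0

    def test_short_over_long_variant(self):
        track = make_track({"g": [("ATG", 0, 1), ("AAA", 3, 7)]})
        assert short_footprint_ratio(track, mode="long")["AAA"] == pytest.approx(3 / 7)

    def test_start_and_stop_excluded(self):
        track = make_track(
            {"g": [("AAA", 9, 9), ("AAA", 1, 3), ("TAA", 9, 9)]}
        )
        assert short_footprint_ratio(track)["AAA"] == pytest.approx(0.25)

    def test_unobserved_codon_unscored(self):
        track = make_track({"g": [("ATG", 0, 1), ("AAA", 0, 0), ("GGG", 1, 1)]})
        sfr = short_footprint_ratio(track)
        assert np.isnan(sfr["AAA"]) and sfr["GGG"] == 0.5

    def test_complement_with_long_ratio(self, small_dataset):
        track = small_dataset.footprints["t0"]["rep1"]
        sfr = short_footprint_ratio(track).dropna()
        long_ratio = 1.0 - sfr
        agg = track[(track["codon_index"] > 0) & (track["codon"] != "TAA")]
        direct = agg.groupby("codon")[["short_count", "long_count"]].sum()
        direct = (direct["long_count"] / direct.sum(axis=1)).dropna()
        assert np.allclose(long_ratio, direct.reindex(long_ratio.index))
        assert ((sfr >= 0) & (sfr <= 1)).all()


class TestClassContrasts:
    def test_identical_distributions_not_significant(self):
        values = pd.Series(
            {"AAA": 0.3, "AAT": 0.3, "GCA": 0.3, "AAG": 0.3, "GCG": 0.3, "CGC": 0.3}
        )
        out = occupancy_by_class(values)
        assert np.isnan(out["test"]["p_value"])

    def test_au3_shift_detected(self, small_dataset):
        """Host AU3 codons carry more short footprints (lower tRNA
        accessibility) than GC3 codons in the generator's study design."""
        host = {g.gene_id for g in small_dataset.genes if g.organism == "host"}
        track = small_dataset.footprints["t0"]["rep1"]
        occ = codon_occupancy(track[track["gene_id"].isin(host)])
        sfr = short_footprint_ratio(
            track[track["gene_id"].isin(host)], occ.included_genes
        )
        out = occupancy_by_class(sfr, alternative="greater")
        assert out["AU3"]["median"] > out["GC3"]["median"]
        assert out["test"]["p_value"] < 0.01


class TestOffsetCalibration:
    def _reads(self, offset, lengths=(30,), n_genes=5, gene_len_nt=300):
        rows = []
        starts = {}
        for g in range(n_genes):
            gid = f"g{g}"
            starts[gid] = 60  # CDS starts at nt 60 of the transcript
            for length in lengths:
                # elongating ribosomes across the ORF plus the strong
                # initiation peak on the start codon
                occupancy = [(0, 8)] + [
                    (cs, 1) for cs in range(3, gene_len_nt, 3)
                ]
                for codon_start, n in occupancy:
                    for _ in range(n):
                        rows.append(
                            {
                                "gene_id": gid,
                                "length": length,
                                "five_prime_pos": 60 + codon_start - offset,
                            }
                        )
        return pd.DataFrame(rows), pd.Series(starts)

    def test_recovers_known_offset(self):
        reads, starts = self._reads(offset=15)
        profile = calibrate_offsets(reads, starts)
        assert profile.offsets[30] == 15

    def test_short_class_offset(self):
        reads, starts = self._reads(offset=8, lengths=(21,))
        profile = calibrate_offsets(reads, starts)
        assert profile.offsets[21] == 8

    def test_no_reads_leaves_uncalibrated(self):
        reads = pd.DataFrame(
            {"gene_id": ["g0"], "length": [28], "five_prime_pos": [10_000]}
        )
        with pytest.warns(UserWarning, match="uncalibrated"):
            profile = calibrate_offsets(reads, pd.Series({"g0": 60}))
        assert profile.uncalibrated == [28]

    def test_override_echoed(self):
        reads, starts = self._reads(offset=15)
        profile = calibrate_offsets(reads, starts, overrides={30: 12, 22: 9})
        assert profile.offsets[30] == 12 and profile.offsets[22] == 9


class TestPeriodicity:
    def test_perfect_three_periodicity(self):
        profile = periodicity_qc([3, 0, 0] * 50)
        assert profile.frame_fractions[0] == 1.0
        assert profile.dominant_period == pytest.approx(3.0)

    def test_uniform_track_no_dominant_frame(self):
        profile = periodicity_qc([2] * 150)
        assert max(profile.frame_fractions) <= 0.34

    def test_partial_phasing(self, rng):
        counts = np.tile([8.0, 1.0, 1.0], 120) + rng.poisson(0.5, 360)
        profile = periodicity_qc(counts)
        assert profile.frame_fractions[0] > 0.6
        period3_power = profile.periodogram.loc[
            np.isclose(profile.periodogram.index, 1 / 3)
        ]
        assert period3_power.iloc[0] == profile.periodogram.max()

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            periodicity_qc([0, 0, 0])


class TestSupplyOccupancyCoupling:
    def test_occupancy_anticorrelates_with_w(self, small_dataset):
        """Dwell ∝ 1/w must surface as slower decoding (higher occupancy)
        of low-supply codons."""
        from codonscape.adaptation import compute_w_scores
        from codonscape.codon_core import WobbleConstraintSet

        W = compute_w_scores(
            small_dataset.true_pool,
            WobbleConstraintSet.from_vector(small_dataset.config.true_s),
        )
        occ = codon_occupancy(small_dataset.footprints["t0"]["rep1"])
        common = occ.per_codon_type.index
        rho = spearmanr(W[common], occ.per_codon_type).statistic
        assert rho < -0.5
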