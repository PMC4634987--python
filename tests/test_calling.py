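import math

import numpy as np
import pandas as pd
import pytest

from helpers import make_profile, segmented_cohort
from oralcna import calling
from oralcna.calling import (
    ConsistencyError,
    call_segments,
    classify_events,
    expected_log2,
    recurrent_cnas,
)
from oralcna.segment import SegmentProfile, segment_pcf


def _seg(sample, rows, gamma=40.0):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "mean"])
    return SegmentProfile(sample, df, gamma)


class TestExpectedLog2:
    def test_hemizygous_deletion_at_half_clonality(self):
        v = expected_log2(0.5, 1, 2)
        assert v == pytest.approx(math.log2(0.75))
        assert math.trunc(v * 100) / 100 == -0.41  # printed convention

    def test_single_copy_gain_at_half_clonality(self):
        assert round(expected_log2(0.5, 3, 2), 2) == 0.32

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
    def test_copy_neutral_is_zero(self, alpha):
        assert expected_log2(alpha, 2, 2) == 0.0

    def test_homozygous_deletion_sentinel(self):
        assert expected_log2(1.0, 0, 2) == float("-inf")

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_log2(1.2, 2, 2)
        with pytest.raises(ValueError):
            expected_log2(0.5, 2, 0)


class TestCallSegments:
    def test_threshold_states_inclusive(self):
        sp = _seg("S", [("chr1", 0, 10, 5, 0.32), ("chr1", 10, 20, 5, 0.0),
                        ("chr1", 20, 30, 5, 0.3), ("chr1", 30, 40, 5, -0.3)])
        states = [r.state for r in call_segments(sp)]
        assert states[0] == "gain"
        assert states[1] == "neutral"
        assert states[2] == "gain"  # boundary inclusive
        assert states[3] == "loss"

    def test_adjacent_same_state_merged_probe_weighted(self):
        sp = _seg("S", [("chr1", 0, 10, 10, 0.4), ("chr1", 10, 20, 30, 0.8)])
        called = call_segments(sp)
        assert len(called) == 1
        assert called[0].mean == pytest.approx((0.4 * 10 + 0.8 * 30) / 40)
        assert called[0].n_probes == 40

    def test_bad_thresholds_rejected(self):
        sp = _seg("S", [("chr1", 0, 10, 5, 0.0)])
        with pytest.raises(ValueError):
            call_segments(sp, gain_thr=-0.1)


class TestClassifyEvents:
    def test_sixty_percent_of_arm_is_broad(self, toy_genome):
        # chr1: 2Mb per arm, centromere at 2e6
        sp = [calling.CalledRegion("S", "chr1", 0, 1_200_000, 12, 0.5, "gain")]
        evs = classify_events(sp, toy_genome)
        assert len(evs) == 1
        assert evs[0].klass == "broad" and evs[0].arm == "p"
        assert evs[0].label == "1p gain"

    def test_single_band_is_focal(self, toy_genome):
        sp = [calling.CalledRegion("S", "chr1", 0, 900_000, 9, 0.5, "gain")]
        (ev,) = classify_events(sp, toy_genome)
        assert ev.klass == "focal"
        assert ev.bands == ("1p2",)

    def test_whole_chromosome_gives_two_broad_events(self, toy_genome):
        length = toy_genome.chromosome("chr1").length
        sp = [calling.CalledRegion("S", "chr1", 0, length, 40, -0.6, "loss")]
        evs = classify_events(sp, toy_genome)
        assert [(e.klass, e.arm) for e in evs] == [("broad", "p"), ("broad", "q")]
        assert {e.label for e in evs} == {"1p loss", "1q loss"}

    def test_region_outside_genome_raises(self, toy_genome):
        sp = [calling.CalledRegion("S", "chr1", 0, 10**9, 10, 0.5, "gain")]
        with pytest.raises(ConsistencyError):
            classify_events(sp, toy_genome)

    def test_neutral_regions_ignored(self, toy_genome):
        sp = [calling.CalledRegion("S", "chr1", 0, 1_000_000, 10, 0.0, "neutral")]
        assert classify_events(sp, toy_genome) == []

    def test_call_then_classify_idempotent_under_remerge(self, toy_genome, rng):
        x = np.concatenate([rng.normal(0.5, 0.05, 30), rng.normal(0.0, 0.05, 50)])
        prof = make_profile(x, spacing=50_000)
        sp = segment_pcf(prof, gamma=40.0)
        called = call_segments(sp)
        # re-threshold the already-merged regions: nothing changes
        again = call_segments(
            SegmentProfile(
                "S1",
                pd.DataFrame(
                    [(r.chrom, r.start, r.end, r.n_probes, r.mean) for r in called],
                    columns=["chrom", "start", "end", "n_probes", "mean"],
                ),
            )
        )
        assert [(r.start, r.end, r.state) for r in again] == [
            (r.start, r.end, r.state) for r in called
        ]


class TestRecurrence:
    def _noise_profiles(self, rng, n=10, sigma=0.1, planted=None, n_probes=240):
        profs = []
        for i in range(n):
            x = rng.normal(0, sigma, n_probes)
            if planted and i < planted["carriers"]:
                x[planted["slice"]] += planted["level"]
            profs.append(segment_pcf(make_profile(x, sample_id=f"S{i}",
                                                  spacing=50_000), gamma=40.0))
        return profs

    def test_planted_band_retained(self, toy_genome, rng):
        # toy genome chr1 band 1q1 covers [2e6, 3e6): probes 40..59
        planted = {"carriers": 8, "slice": slice(40, 60), "level": 0.6}
        profs = self._noise_profiles(rng, planted=planted, n_probes=80)
        rec = recurrent_cnas(profs, toy_genome, n_perm=1000, seed=1)
        focal_gains = rec[(rec["class"] == "focal") & (rec["direction"] == "gain")]
        assert "1q1 gain" in set(focal_gains["label"])
        assert (focal_gains.set_index("label").loc["1q1 gain", "q"] < 0.25)

    def test_planted_arm_loss_retained_as_broad(self, toy_genome, rng):
        planted = {"carriers": 6, "slice": slice(40, 80), "level": -0.6}  # all of 1q
        profs = self._noise_profiles(rng, planted=planted, n_probes=80)
        rec = recurrent_cnas(profs, toy_genome, n_perm=1000, seed=1)
        broad_losses = rec[(rec["class"] == "broad") & (rec["direction"] == "loss")]
        assert "1q loss" in set(broad_losses["label"])

    def test_pure_noise_rarely_retains(self, toy_genome, rng):
        counts = []
        for seed in range(3):
            profs = self._noise_profiles(rng, n_probes=80)
            counts.append(len(recurrent_cnas(profs, toy_genome, n_perm=200, seed=seed)))
        assert np.median(counts) == 0

    def test_g_score_monotone_in_carriers_and_amplitude(self, toy_genome):
        def g_for(level, carriers):
            profs = []
            for i in range(6):
                x = np.zeros(80)
                if i < carriers:
                    x[40:60] = level
                profs.append(segment_pcf(make_profile(x, sample_id=f"S{i}",
                                                      spacing=50_000),
                                         gamma=40.0, normalize=False))
            mats = calling.amplitude_matrices(profs, toy_genome)
            return mats["focal_gain"]["1q1"].sum()

        assert g_for(0.6, 4) >= g_for(0.6, 2) >= g_for(0.6, 1)
        assert g_for(0.9, 3) >= g_for(0.6, 3) >= g_for(0.4, 3)

    def test_presence_consistent_with_events(self):
        genome, _, profs = segmented_cohort(3, n_samples=20)
        rec = recurrent_cnas(profs, genome, n_perm=200, seed=3)
        assert len(rec) > 0
        for r in rec.itertuples():
            for sid, present in r.presence.items():
                sp = next(p for p in profs if p.sample_id == sid)
                evs = calling.classify_events(calling.call_segments(sp), genome)
                target, _, direction = r.label.rpartition(" ")
                klass = r._2  # "class" column
                carries = any(
                    e.direction == direction
                    and e.klass == klass
                    and (
                        (e.klass == "broad" and _arm_label(e) == target)
                        or (e.klass == "focal" and target in e.bands)
                    )
                    for e in evs
                )
                assert carries == bool(present)


def _arm_label(e):
    chrom_num = e.chrom[3:] if e.chrom.startswith("chr") else e.chrom
    return f"{chrom_num}{e.arm}"
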