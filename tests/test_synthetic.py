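"""Phantom generator, simulated raters, cohort assembly, benchmark recipe."""
import numpy as np
import pytest

from m3sl.metrics import confusion_counts, f_measure, nwmh, recall
from m3sl.staple import binarize_consensus, staple
from m3sl.synthetic import (
    STAGE_NWMH_RANGES,
    Cohort,
    PhantomSpec,
    RaterSpec,
    generate_cohort,
    generate_phantom,
    load_cohort,
    reference_benchmark,
    simulate_rater,
)
from m3sl.types import BinaryMask


class TestGeneratePhantom:
    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(cube_edge=48, stage="MCI", scanner_label="B", seed=11)
        v1, g1, i1 = generate_phantom(spec)
        v2, g2, i2 = generate_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(g1.data, g2.data)
        np.testing.assert_array_equal(i1.data, i2.data)

    def test_stage_ordering_cn_below_ad(self):
        for seed in (0, 1, 2):
            _, g_cn, i_cn = generate_phantom(PhantomSpec(cube_edge=48, stage="CN", seed=seed))
            _, g_ad, i_ad = generate_phantom(PhantomSpec(cube_edge=48, stage="AD", seed=seed))
            assert nwmh(g_ad, i_ad) > nwmh(g_cn, i_cn)

    @pytest.mark.parametrize("stage", ["CN", "MCI", "AD"])
    def test_realized_nwmh_inside_target_range(self, stage):
        lo, hi = STAGE_NWMH_RANGES[stage]
        for seed in range(20):
            _, gold, icv = generate_phantom(
                PhantomSpec(cube_edge=48, stage=stage, seed=seed)
            )
            assert lo <= nwmh(gold, icv) <= hi

    def test_brain_occupies_forty_to_sixty_percent(self):
        for seed in range(5):
            _, _, icv = generate_phantom(PhantomSpec(cube_edge=48, seed=seed))
            assert 0.35 <= icv.data.mean() <= 0.62

    def test_lesions_hyperintense_inside_brain(self, small_phantom):
        vol, gold, icv = small_phantom
        bg = icv.data & ~gold.data
        p98 = np.percentile(vol.data[bg], 98)
        assert np.median(vol.data[gold.data]) > p98

    def test_gold_is_exact_lesion_support_within_icv(self, small_phantom):
        _, gold, icv = small_phantom
        assert not (gold.data & ~icv.data).any()


class TestSimulateRater:
    def _gold(self, edge=40, lo=8, hi=32):
        g = np.zeros((edge,) * 3, bool)
        g[lo:hi, lo:hi, lo:hi] = True
        return BinaryMask(data=g, role="gold")

    def test_noiseless_rater_reproduces_gold(self):
        gold = self._gold()
        spec = RaterSpec(sensitivity=1 - 1e-12, specificity=1 - 1e-12, boundary_jitter=0, seed=0)
        out = simulate_rater(gold, spec)
        np.testing.assert_array_equal(out.data, gold.data)
        assert out.role == "bronze"

    def test_empirical_recall_tracks_sensitivity(self):
        gold = self._gold()  # 24^3 = 13824 true voxels
        out = simulate_rater(
            gold, RaterSpec(sensitivity=0.8, specificity=0.999, boundary_jitter=0, seed=3)
        )
        r = recall(confusion_counts(out, gold))
        assert 0.77 <= r <= 0.83

    def test_flip_rates_converge_at_large_masks(self):
        """Law of large numbers: realized per-voxel rates within +-0.01 of
        the spec at ~10^5 foreground voxels."""
        g = np.zeros((64, 64, 64), bool)
        g[5:52, 5:52, 5:52] = True  # ~10^5 True voxels
        gold = BinaryMask(data=g, role="gold")
        spec = RaterSpec(sensitivity=0.85, specificity=0.99, boundary_jitter=0, seed=1)
        out = simulate_rater(gold, spec)
        c = confusion_counts(out, gold)
        assert abs(c.tp / (c.tp + c.fn) - 0.85) < 0.01
        assert abs(c.tn / (c.tn + c.fp) - 0.99) < 0.01

    def test_jitter_keeps_rates_near_spec(self):
        g = np.zeros((64, 64, 64), bool)
        g[5:52, 5:52, 5:52] = True
        gold = BinaryMask(data=g, role="gold")
        out = simulate_rater(
            gold, RaterSpec(sensitivity=0.85, specificity=0.99, boundary_jitter=2, seed=2)
        )
        c = confusion_counts(out, gold)
        assert abs(c.tp / (c.tp + c.fn) - 0.85) < 0.03
        assert abs(c.tn / (c.tn + c.fp) - 0.99) < 0.03

    def test_fp_confined_to_icv(self):
        gold = self._gold(edge=30, lo=12, hi=18)
        icv = np.zeros((30,) * 3, bool)
        icv[5:25, 5:25, 5:25] = True
        out = simulate_rater(
            gold,
            RaterSpec(sensitivity=0.9, specificity=0.9, boundary_jitter=0, seed=0),
            icv=BinaryMask(data=icv, role="icv"),
        )
        assert not (out.data & ~icv).any()

    def test_empty_gold_rejected(self):
        from m3sl.errors import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            simulate_rater(
                BinaryMask(data=np.zeros((5, 5, 5), bool)), RaterSpec(seed=0)
            )

    def test_staple_fusion_beats_each_distinct_rater(self):
        gold = self._gold()
        specs = [
            RaterSpec(0.90, 0.995, 1, seed=10),
            RaterSpec(0.75, 0.999, 2, seed=11),
            RaterSpec(0.85, 0.990, 1, seed=12),
        ]
        masks = [simulate_rater(gold, s) for s in specs]
        assert len({m.data.tobytes() for m in masks}) == 3
        silver = binarize_consensus(staple(masks))
        f_silver = f_measure(confusion_counts(silver, gold))
        for m in masks:
            assert f_silver > f_measure(confusion_counts(m, gold))


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(n=40, master_seed=7, cube_edge=48)

    def test_every_subject_fully_equipped(self, cohort):
        assert len(cohort) == 40
        for s in cohort.subjects:
            assert s.volume is not None and s.gold is not None and s.icv is not None
            assert len(s.bronze) == 3
            assert s.stage in ("CN", "MCI", "AD")
            assert s.sex in ("M", "F") and s.age > 0

    def test_default_unannotated_share(self, cohort):
        # round(0.53 * 40) = 21 subjects carry no training annotation
        assert len(cohort.unannotated()) == 21
        assert len(cohort.annotated()) == 19

    def test_stage_mix_within_one_subject_of_request(self):
        cohort = generate_cohort(
            n=20, stage_mix={"CN": 0.5, "MCI": 0.3, "AD": 0.2}, master_seed=1,
            cube_edge=48,
        )
        counts = {
            st: sum(s.stage == st for s in cohort.subjects) for st in ("CN", "MCI", "AD")
        }
        for st, frac in (("CN", 0.5), ("MCI", 0.3), ("AD", 0.2)):
            assert abs(counts[st] - frac * 20) <= 1

    def test_reproducible_from_master_seed(self):
        a = generate_cohort(n=10, master_seed=5, cube_edge=48)
        b = generate_cohort(n=10, master_seed=5, cube_edge=48)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.volume.data, sb.volume.data)
            np.testing.assert_array_equal(sa.gold.data, sb.gold.data)
            assert sa.age == sb.age and sa.stage == sb.stage

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            generate_cohort(n=5)

    def test_save_load_round_trip(self, tmp_path):
        cohort = generate_cohort(n=10, master_seed=3, cube_edge=32)
        manifest = cohort.save(tmp_path / "cohort")
        loaded = load_cohort(manifest)
        assert len(loaded) == 10
        for sa, sb in zip(cohort.subjects, loaded.subjects):
            np.testing.assert_allclose(sa.volume.data, sb.volume.data, atol=1e-6)
            np.testing.assert_array_equal(sa.gold.data, sb.gold.data)
            np.testing.assert_array_equal(sa.bronze[2].data, sb.bronze[2].data)
            assert sa.annotated == sb.annotated


class TestReferenceBenchmark:
    def test_canonical_regeneration_is_bit_identical(self):
        c1, cfg1 = reference_benchmark(seed=7)
        c2, cfg2 = reference_benchmark(seed=7)
        assert len(c1) == 40 and c1.cube_edge == 64
        assert cfg1 == cfg2
        np.testing.assert_array_equal(
            c1.subjects[0].volume.data, c2.subjects[0].volume.data
        )
        np.testing.assert_array_equal(
            c1.subjects[-1].gold.data, c2.subjects[-1].gold.data
        )

    def test_silver_beats_mean_single_rater_on_gold_subjects(self):
        cohort, _ = reference_benchmark(seed=7)
        f_single, f_silver = [], []
        for s in cohort.annotated()[:6]:
            fs = [f_measure(confusion_counts(b, s.gold)) for b in s.bronze]
            silver = binarize_consensus(staple(s.bronze))
            f_single.append(np.mean(fs))
            f_silver.append(f_measure(confusion_counts(silver, s.gold)))
        assert np.mean(f_silver) > np.mean(f_single)
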