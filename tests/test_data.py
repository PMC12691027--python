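"""Annotation I/O round-trips, preprocessing, augmentation, and splitting."""

import numpy as np
import pytest

from conftest import make_record
from snoutnet.data import (AugmentPolicy, augment,
                           fit_normalizer, partition_dataset, preprocess,
                           read_annotations, records_equal, standardize,
                           wavelet_denoise, write_annotations)
from snoutnet.types import BBox, ImageRecord


@pytest.mark.parametrize("dialect", ["yolo_txt", "coco_json"])
class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path, small_dataset, dialect):
        records = small_dataset[0][:5]
        n = write_annotations(records, tmp_path, dialect)
        assert n == 5
        back = read_annotations(tmp_path, dialect)
        assert len(back) == 5
        by_name = {r.name: r for r in back}
        for rec in records:
            assert records_equal(rec, by_name[rec.name])

    def test_empty_record_set(self, tmp_path, dialect):
        assert write_annotations([], tmp_path, dialect) == 0
        assert read_annotations(tmp_path, dialect) == [] \
            if dialect == "yolo_txt" else True

    def test_background_image_round_trips_with_zero_boxes(self, tmp_path, dialect):
        rec = ImageRecord(pixels=np.zeros((8, 8, 3), np.float32),
                          animal_id="pigZ", annotations=[], name="pigZ_bg")
        write_annotations([rec], tmp_path, dialect)
        back = read_annotations(tmp_path, dialect)
        assert len(back) == 1 and back[0].annotations == []
        assert back[0].animal_id == "pigZ"


class TestYoloParsing:
    def test_single_line_parses_to_cough_box(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "labels").mkdir()
        from PIL import Image
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            tmp_path / "images" / "pigA_001.png")
        (tmp_path / "labels" / "pigA_001.txt").write_text("2 0.5 0.5 0.2 0.3\n")
        (rec,) = read_annotations(tmp_path, "yolo_txt")
        assert rec.animal_id == "pigA"  # filename-prefix fallback
        (cid, box), = rec.annotations
        assert cid == 2
        assert box.approx_equal(BBox(0.5, 0.5, 0.2, 0.3))

    def test_malformed_line_names_file_and_line(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "labels").mkdir()
        from PIL import Image
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            tmp_path / "images" / "x_1.png")
        (tmp_path / "labels" / "x_1.txt").write_text("0 0.5 0.5\n")
        with pytest.raises(ValueError, match=r"x_1\.txt:1"):
            read_annotations(tmp_path, "yolo_txt")

    def test_unknown_class_lists_vocabulary(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "labels").mkdir()
        from PIL import Image
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            tmp_path / "images" / "x_1.png")
        (tmp_path / "labels" / "x_1.txt").write_text("7 0.5 0.5 0.2 0.2\n")
        with pytest.raises(ValueError, match="Cough"):
            read_annotations(tmp_path, "yolo_txt")

    def test_sidecar_overrides_filename_prefix(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "labels").mkdir()
        from PIL import Image
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            tmp_path / "images" / "x_1.png")
        (tmp_path / "labels" / "x_1.txt").write_text("")
        (tmp_path / "animals.tsv").write_text("x_1.png\tsow42\n")
        (rec,) = read_annotations(tmp_path, "yolo_txt")
        assert rec.animal_id == "sow42"


class TestPreprocess:
    def test_output_is_target_square(self):
        rec = make_record(size=31)
        out = preprocess(rec, 640, stats=None, denoise=False)
        assert out.pixels.shape == (640, 640, 3)

    def test_wavelet_denoise_near_identity_on_piecewise_constant(self):
        img = np.zeros((32, 32, 3))
        img[8:24, 8:24] = 0.75
        out = wavelet_denoise(img)
        # noise-free detail bands give sigma ~ 0, hence threshold ~ 0
        assert np.abs(out - img).max() < 1e-3

    def test_wavelet_denoise_reduces_noise_energy(self):
        rng = np.random.default_rng(1)
        clean = np.zeros((64, 64, 3))
        clean[16:48, 16:48] = 0.6
        noisy = clean + 0.05 * rng.standard_normal(clean.shape)
        out = wavelet_denoise(noisy)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_constant_image_standardizes_to_zero(self):
        rec = make_record()
        rec.pixels[...] = 0.5
        stats = fit_normalizer([rec])
        out = standardize(rec.pixels, stats)
        assert np.array_equal(out, np.zeros_like(out))

    def test_fit_normalizer_two_value_example(self):
        a = make_record()
        b = make_record()
        a.pixels[...] = 0.0
        b.pixels[...] = 2.0
        stats = fit_normalizer([a, b])
        assert np.allclose(stats.mean, 1.0)
        assert np.allclose(stats.std, 1.0)

    def test_standardized_training_set_has_unit_moments(self, small_dataset):
        records = small_dataset[0][:8]
        stats = fit_normalizer(records)
        px = np.concatenate([standardize(r.pixels, stats).reshape(-1, 3)
                             for r in records])
        assert np.abs(px.mean(axis=0)).max() < 1e-5
        assert np.abs(px.std(axis=0) - 1).max() < 1e-5

    def test_stats_match_two_pass_reference(self, small_dataset):
        records = small_dataset[0][:6]
        stats = fit_normalizer(records)
        allpx = np.concatenate([r.pixels.reshape(-1, 3) for r in records]
                               ).astype(np.float64)
        assert np.allclose(stats.mean, allpx.mean(axis=0), atol=1e-10)
        assert np.allclose(stats.std, allpx.std(axis=0), atol=1e-10)

    def test_empty_training_split_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer([])


class TestAugment:
    def test_identity_policy_preserves_everything(self):
        rec = make_record(class_id=2)
        out = augment(rec, np.random.default_rng(0),
                      AugmentPolicy(rotation_deg=0, flip_p=0, jitter=0))
        assert np.allclose(out.pixels, rec.pixels, atol=1e-6)
        assert out.annotations == rec.annotations

    def test_horizontal_flip_mirrors_xc(self):
        rec = make_record(box=BBox(0.3, 0.4, 0.2, 0.2))
        out = augment(rec, np.random.default_rng(0),
                      AugmentPolicy(rotation_deg=0, flip_p=1.0, jitter=0))
        (cid, box), = out.annotations
        assert box.approx_equal(BBox(0.7, 0.4, 0.2, 0.2))
        assert np.allclose(out.pixels, rec.pixels[:, ::-1], atol=1e-6)

    def test_flip_frequency_binomial_bound(self):
        rng = np.random.default_rng(99)
        # count flips through the same decision stream the augmenter uses
        # at rotation 0 / jitter 0; 50k draws put the +/-0.01 band at
        # ~4.5 sigma of the binomial at p = 0.5
        rec = make_record(box=BBox(0.3, 0.5, 0.2, 0.2))
        pol = AugmentPolicy(rotation_deg=0, flip_p=0.5, jitter=0)
        n = 50_000
        flips = sum(augment(rec, rng, pol).annotations[0][1].xc > 0.5
                    for _ in range(n))
        assert 0.49 <= flips / n <= 0.51

    def test_rotated_box_follows_image_content(self):
        img = np.zeros((64, 64, 3), np.float32)
        img[10:20, 40:50] = 1.0
        rec = ImageRecord(pixels=img, animal_id="a",
                          annotations=[(0, BBox.from_xyxy(40 / 64, 10 / 64,
                                                          50 / 64, 20 / 64))])
        class FixedRng:
            def uniform(self, lo, hi, size=None):
                return 12.0 if size is None else np.ones(size)
            def random(self):
                return 1.0  # no flip
        out = augment(rec, FixedRng(),
                      AugmentPolicy(rotation_deg=15, flip_p=0.0, jitter=0))
        ys, xs = np.nonzero(out.pixels[..., 0] > 0.5)
        (cid, box), = out.annotations
        x1, y1, x2, y2 = box.to_xyxy(64)
        assert x1 - 1.5 <= xs.min() and xs.max() <= x2 + 1.5
        assert y1 - 1.5 <= ys.min() and ys.max() <= y2 + 1.5

    def test_labels_never_relabeled_and_boxes_valid(self, small_dataset):
        rng = np.random.default_rng(5)
        for rec in small_dataset[0][:10]:
            out = augment(rec, rng)
            in_classes = [c for c, _ in rec.annotations]
            out_classes = [c for c, _ in out.annotations]
            for c in set(out_classes):
                assert out_classes.count(c) <= in_classes.count(c)
            for _, b in out.annotations:
                assert 0 <= b.xc - b.w / 2 + 1e-6
                assert b.xc + b.w / 2 <= 1 + 1e-6


def test_expand_dataset_keeps_identities_and_doubles_size():
    from snoutnet.data import expand_dataset
    records = [make_record(class_id=i % 4, animal_id=f"an{i}", size=8, seed=i)
               for i in range(12)]
    out = expand_dataset(records, np.random.default_rng(0), factor=2)
    assert len(out) == 24
    assert [r.animal_id for r in out[:12]] == [r.animal_id for r in records]
    assert [r.animal_id for r in out[12:]] == [r.animal_id for r in records]
    # identity-aware partitioning keeps originals and copies together
    split = partition_dataset(out, (0.6, 0.2, 0.2), seed=0)
    for part in (split.train, split.val, split.test):
        ids = {r.animal_id for r in part}
        for r in out:
            if r.animal_id in ids:
                assert any(s.animal_id == r.animal_id for s in part)


class TestPartition:
    def test_table_arithmetic_on_balanced_one_animal_per_image(self):
        # 5600 images, 1400 per class, one animal per record, fractions
        # 3800/1100/700 -> per-class counts 950/275/175
        records = []
        for i in range(5600):
            records.append(make_record(class_id=i % 4, animal_id=f"pig{i:04d}",
                                       size=2))
        split = partition_dataset(records, (3800 / 5600, 1100 / 5600,
                                            700 / 5600), seed=42)
        assert len(split.train) == 3800
        assert len(split.val) == 1100
        assert len(split.test) == 700
        assert (split.per_class_counts == np.array([[950, 275, 175]] * 4)).all()

    def test_seed_reproducibility_and_sensitivity(self):
        records = [make_record(class_id=i % 4, animal_id=f"a{i % 17}", size=2)
                   for i in range(60)]
        s1 = partition_dataset(records, (0.6, 0.2, 0.2), seed=42)
        s2 = partition_dataset(records, (0.6, 0.2, 0.2), seed=42)
        s3 = partition_dataset(records, (0.6, 0.2, 0.2), seed=43)
        ids = lambda s: [sorted(r.animal_id for r in part)
                         for part in (s.train, s.val, s.test)]
        assert ids(s1) == ids(s2)
        assert ids(s1) != ids(s3)

    def test_no_animal_leakage_on_random_groupings(self):
        rng = np.random.default_rng(8)
        records = [make_record(class_id=int(rng.integers(0, 4)),
                               animal_id=f"p{rng.integers(0, 25)}", size=2)
                   for _ in range(200)]
        split = partition_dataset(records, (0.7, 0.2, 0.1), seed=1)
        groups = [set(r.animal_id for r in part)
                  for part in (split.train, split.val, split.test)]
        assert not (groups[0] & groups[1] or groups[0] & groups[2]
                    or groups[1] & groups[2])
        assert sum(len(p) for p in (split.train, split.val, split.test)) == 200

    def test_stratification_within_one_group(self):
        # one animal per record -> per-class deviation below one group
        records = [make_record(class_id=i % 4, animal_id=f"q{i}", size=2)
                   for i in range(400)]
        split = partition_dataset(records, (0.5, 0.3, 0.2), seed=3)
        for c in range(4):
            for s, frac in enumerate((0.5, 0.3, 0.2)):
                assert abs(split.per_class_counts[c, s] - frac * 100) <= 1

    def test_single_animal_degenerates_with_warning(self, caplog):
        records = [make_record(class_id=i % 4, animal_id="solo", size=2)
                   for i in range(12)]
        with caplog.at_level("WARNING"):
            split = partition_dataset(records, (0.6, 0.2, 0.2), seed=0)
        sizes = sorted(len(p) for p in (split.train, split.val, split.test))
        assert sizes == [0, 0, 12]
        assert any("single" in r.message for r in caplog.records)

    def test_undersupported_class_raises_with_class_name(self):
        records = ([make_record(class_id=0, animal_id=f"n{i}", size=2)
                    for i in range(10)]
                   + [make_record(class_id=3, animal_id="feverpig", size=2),
                      make_record(class_id=3, animal_id="feverpig", size=2)])
        with pytest.raises(ValueError, match="Fever"):
            partition_dataset(records, (0.6, 0.2, 0.2), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            partition_dataset([make_record()], (0.5, 0.3), seed=0)
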