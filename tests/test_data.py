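"""Label/bbox CSV dialects, preprocessing, augmentation, splits, statistics."""

import numpy as np
import pytest

from lmeran.data import (
    CHESTXRAY14_LABELS, BoxRecord, LabelRecord, NO_FINDING, augment,
    from_target, label_statistics, load_split, preprocess, read_bbox_csv,
    read_label_csv, scale_box, to_target, write_bbox_csv, write_label_csv,
)

VOCAB = ["Effusion", "Infiltration", "Nodule"]


def test_label_csv_parsing(tmp_path):
    path = tmp_path / "labels.csv"
    path.write_text("Image Index,Finding Labels\n"
                    "img1.png,Effusion|Infiltration\n"
                    "img2.png,No Finding\n")
    records = read_label_csv(path, vocabulary=VOCAB)
    assert records[0].findings == {"Effusion", "Infiltration"}
    assert records[1].findings == frozenset()
    assert to_target(records[1], VOCAB).tolist() == [0, 0, 0]
    assert to_target(records[0], VOCAB).tolist() == [1, 1, 0]


def test_label_csv_unknown_name_strictness(tmp_path):
    path = tmp_path / "labels.csv"
    path.write_text("Image Index,Finding Labels\nimg.png,Gremlin\n")
    with pytest.raises(ValueError):
        read_label_csv(path, vocabulary=VOCAB)
    with pytest.warns(UserWarning):
        records = read_label_csv(path, vocabulary=VOCAB, strict=False)
    assert records[0].findings == frozenset()


def test_no_finding_cannot_cooccur():
    with pytest.raises(ValueError):
        LabelRecord("x.png", frozenset({NO_FINDING, "Effusion"}))


def test_label_roundtrip_lossless(tmp_path, rng):
    records = []
    for i in range(50):
        k = int(rng.integers(0, 4))
        names = frozenset(rng.choice(VOCAB, size=k, replace=False))
        records.append(LabelRecord(f"img{i:03d}.png", names))
    path = tmp_path / "rt.csv"
    write_label_csv(records, path)
    back = read_label_csv(path, vocabulary=VOCAB)
    assert back == records


def test_target_roundtrip(rng):
    y = rng.integers(0, 2, size=len(VOCAB))
    rec = from_target("a.png", y, VOCAB)
    assert np.array_equal(to_target(rec, VOCAB), y)


def test_label_statistics_published_distribution():
    # the 15 printed (label, quantity) pairs of the ChestX-ray14 release
    counts = {
        "No Finding": 60361, "Infiltration": 19894, "Effusion": 13317,
        "Atelectasis": 11559, "Nodule": 6331, "Mass": 5782,
        "Pneumothorax": 5302, "Consolidation": 4667,
        "Pleural Thickening": 3385, "Cardiomegaly": 2776,
        "Emphysema": 2516, "Edema": 2303, "Fibrosis": 1686,
        "Pneumonia": 1431, "Hernia": 227,
    }
    expected = {
        "No Finding": 42.65, "Infiltration": 14.06, "Effusion": 9.41,
        "Atelectasis": 8.17, "Nodule": 4.47, "Mass": 4.09,
        "Pneumothorax": 3.75, "Consolidation": 3.30,
        "Pleural Thickening": 2.39, "Cardiomegaly": 1.96,
        "Emphysema": 1.78, "Edema": 1.63, "Fibrosis": 1.19,
        "Pneumonia": 1.01, "Hernia": 0.16,
    }
    df = label_statistics(counts=counts).set_index("Labels")
    for name, freq in expected.items():
        assert round(float(df.loc[name, "Frequency"]), 2) == freq


def test_label_statistics_from_records_sums_to_100(rng):
    records = [from_target(f"i{i}.png",
                           rng.integers(0, 2, size=len(VOCAB)), VOCAB)
               for i in range(200)]
    df = label_statistics(records, vocabulary=VOCAB)
    assert np.isclose(df["Frequency"].sum(), 100.0, atol=0.05)
    single = label_statistics([LabelRecord("a.png", frozenset({"Nodule"}))])
    assert float(single["Frequency"].iloc[0]) == 100.0


def test_preprocess_sizes_and_constants(rng):
    big = rng.random((1024, 1024))
    out = preprocess(big, size=448)
    assert out.shape == (448, 448)
    const = preprocess(np.full((100, 100), 0.37), size=64)
    assert np.allclose(const, 0.37, atol=1e-6)


def test_preprocess_near_inverse(rng):
    # band-limited image: down(up(x)) should approximately recover x
    yy, xx = np.mgrid[0:56, 0:56] / 56.0
    small = 0.5 + 0.2 * np.sin(2 * np.pi * xx) * np.cos(2 * np.pi * yy)
    up = preprocess(small, size=112)
    down = preprocess(up, size=56)
    assert np.abs(down - small).mean() < 1e-2


def test_augment_deterministic_and_flip_frequency(rng):
    img = rng.random((64, 64))
    a1 = augment(img, np.random.default_rng(7))
    a2 = augment(img, np.random.default_rng(7))
    assert np.array_equal(a1, a2)
    assert a1.shape == img.shape
    # flip-only configuration is an involution and hits p = 0.5
    flips = 0
    check = np.random.default_rng(3)
    for _ in range(1000):
        out = augment(img, check, scale_range=(1.0, 1.0))
        flipped = np.allclose(out, img[:, ::-1], atol=1e-6)
        identity = np.allclose(out, img, atol=1e-6)
        assert flipped or identity
        flips += flipped
    assert 450 <= flips <= 550


def test_split_ratio_and_disjoint(rng):
    ids = [f"p{i:03d}_{j}.png" for i in range(25) for j in range(4)]
    split = load_split(ids, rng=rng)
    assert (len(split.train), len(split.validation), len(split.test)) == (70, 10, 20)
    all_ids = set(split.train) | set(split.validation) | set(split.test)
    assert len(all_ids) == 100


def test_split_patient_disjoint(rng):
    ids = [f"p{i:03d}_{j}.png" for i in range(30) for j in range(3)]
    split = load_split(ids, rng=rng, patient_disjoint=True)
    groups = [set(i.split("_")[0] for i in part)
              for part in (split.train, split.validation, split.test)]
    assert not (groups[0] & groups[1] or groups[0] & groups[2]
                or groups[1] & groups[2])


def test_split_explicit_lists_verbatim():
    split = load_split(lists=(["a.png"], ["b.png"], ["c.png"]))
    assert split.train == ("a.png",) and split.test == ("c.png",)
    with pytest.raises(ValueError):
        load_split(lists=(["a.png"], ["a.png"], []))


def test_bbox_scaling_and_roundtrip(tmp_path):
    box = BoxRecord("img.png", "Nodule", 100, 100, 200, 200)
    scaled = scale_box(box, 1024, 448)
    assert np.allclose((scaled.x, scaled.y, scaled.w, scaled.h),
                       (43.75, 43.75, 87.5, 87.5))
    with pytest.raises(ValueError):
        BoxRecord("img.png", "Nodule", 5, 5, 0, 10)
    path = tmp_path / "bbox.csv"
    boxes = [box, BoxRecord("other.png", "Mass", 1.5, 2.5, 10, 20)]
    write_bbox_csv(boxes, path)
    assert read_bbox_csv(path) == boxes
    scaled_back = read_bbox_csv(path, original_size=1024, target_size=448)
    assert np.allclose((scaled_back[0].x, scaled_back[0].w), (43.75, 87.5))


def test_vocabulary_has_14_diseases():
    assert len(CHESTXRAY14_LABELS) == 14
    assert len(set(CHESTXRAY14_LABELS)) == 14
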