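import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hlrr.datamodel import (MultimodalDataset, partition_groups, read_dataset,
                            write_dataset, FeatureScaler)
from conftest import make_dataset

MODS = ("MRI", "PET", "CSF")


def write_toy_table(tmp_path, rows, dims=(2, 2, 1)):
    """rows: list of (subject_id, {modality: values-or-None}, label)."""
    cols = [f"{m}_{d}" for m, dm in zip(MODS, dims) for d in range(dm)]
    table = []
    for sid, blocks, _ in rows:
        vals = []
        for m, dm in zip(MODS, dims):
            b = blocks.get(m)
            vals += ([np.nan] * dm if b is None else list(b))
        table.append([sid] + vals)
    pd.DataFrame(table, columns=["subject_id"] + cols).to_csv(
        tmp_path / "feat.csv", index=False)
    pd.DataFrame([(c, m) for m, dm in zip(MODS, dims)
                  for c in [f"{m}_{d}" for d in range(dm)]],
                 columns=["feature_column", "modality"]).to_csv(
        tmp_path / "map.csv", index=False)
    pd.DataFrame([(sid, lab) for sid, _, lab in rows],
                 columns=["subject_id", "label"]).to_csv(
        tmp_path / "lab.csv", index=False)
    return tmp_path / "feat.csv", tmp_path / "map.csv", tmp_path / "lab.csv"


class TestReadDataset:
    def test_missing_block_sets_availability(self, tmp_path):
        rows = [("s1", {"MRI": [1, 2], "PET": [3, 4], "CSF": [5]}, "AD"),
                ("s2", {"MRI": [1, 1], "PET": None, "CSF": [2]}, "NC"),
                ("s3", {"MRI": [0, 1], "PET": [1, 0], "CSF": [1]}, "AD")]
        ds = read_dataset(*write_toy_table(tmp_path, rows))
        assert ds.availability.tolist() == [[True, True, True],
                                            [True, False, True],
                                            [True, True, True]]
        assert ds.dims == {"MRI": 2, "PET": 2, "CSF": 1}

    def test_cohort_dims(self, tmp_path, rng):
        # 90 + 90 + 3 feature columns give per-modality dims (90, 90, 3)
        dims = (90, 90, 3)
        rows = [(f"s{i}", {m: list(rng.standard_normal(d))
                           for m, d in zip(MODS, dims)}, "NC")
                for i in range(3)]
        ds = read_dataset(*write_toy_table(tmp_path, rows, dims=dims))
        assert tuple(ds.dims[m] for m in MODS) == (90, 90, 3)

    def test_all_blocks_missing_is_error(self, tmp_path):
        rows = [("s1", {"MRI": [1, 2], "PET": [3, 4], "CSF": [5]}, "AD"),
                ("s2", {}, "NC")]
        with pytest.raises(ValueError, match="no available modality"):
            read_dataset(*write_toy_table(tmp_path, rows))

    def test_partial_block_rejected(self, tmp_path):
        f, m, l = write_toy_table(
            tmp_path, [("s1", {"MRI": [1, 2], "PET": [3, 4], "CSF": [5]}, "AD")])
        t = pd.read_csv(f)
        t.loc[0, "PET_0"] = np.nan   # half-missing PET block
        t.to_csv(f, index=False)
        with pytest.raises(ValueError, match="partially-missing"):
            read_dataset(f, m, l)

    def test_duplicate_ids_rejected(self, tmp_path):
        rows = [("s1", {"MRI": [1, 2], "PET": [3, 4], "CSF": [5]}, "AD"),
                ("s1", {"MRI": [0, 0], "PET": [1, 1], "CSF": [2]}, "NC")]
        with pytest.raises(ValueError, match="duplicate"):
            read_dataset(*write_toy_table(tmp_path, rows))

    def test_missing_label_rejected(self, tmp_path):
        f, m, l = write_toy_table(
            tmp_path, [("s1", {"MRI": [1, 2], "PET": [3, 4], "CSF": [5]}, "AD"),
                       ("s2", {"MRI": [1, 1], "PET": [0, 0], "CSF": [1]}, "NC")])
        pd.read_csv(l).iloc[:1].to_csv(l, index=False)
        with pytest.raises(ValueError, match="label missing"):
            read_dataset(f, m, l)


class TestPartition:
    def test_group_sizes(self, rng):
        pats = [MODS, ("MRI", "PET"), MODS, ("MRI",)]
        groups = partition_groups(make_dataset(rng, pats))
        assert sorted(g.n_samples for g in groups) == [1, 1, 2]

    def test_complete_subjects_form_single_group(self, rng):
        ds = make_dataset(rng, [MODS] * 5, dims=(90, 90, 3))
        groups = partition_groups(ds)
        assert len(groups) == 1
        assert groups[0].pattern == MODS
        assert groups[0].X.shape == (183, 5)   # 90 + 90 + 3 concatenated

    def test_seven_singleton_groups(self, rng):
        # one subject per non-empty subset of three modalities
        from itertools import combinations
        pats = [c for size in (3, 2, 1) for c in combinations(MODS, size)]
        groups = partition_groups(make_dataset(rng, pats))
        assert len(groups) == 7
        assert all(g.n_samples == 1 for g in groups)

    def test_concatenation_follows_canonical_order(self, rng):
        ds = make_dataset(rng, [("MRI", "CSF")], dims=(2, 2, 1))
        g = partition_groups(ds)[0]
        expect = np.concatenate([ds.features["MRI"][0], ds.features["CSF"][0]])
        np.testing.assert_allclose(g.X[:, 0], expect)

    @given(mask=st.lists(st.integers(min_value=1, max_value=7), min_size=1,
                         max_size=25))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, mask):
        # groups are disjoint and exhaustive for any availability pattern mix
        rng = np.random.default_rng(42)
        pats = [tuple(m for b, m in zip((4, 2, 1), MODS) if v & b)
                for v in mask]
        ds = make_dataset(rng, pats)
        groups = partition_groups(ds)
        seen = np.concatenate([g.member_indices for g in groups])
        assert sorted(seen.tolist()) == list(range(len(mask)))
        assert sum(g.n_samples for g in groups) == len(mask)


def test_write_read_round_trip(tmp_path, rng):
    pats = [MODS, ("MRI", "PET"), ("PET", "CSF"), ("CSF",)]
    ds = make_dataset(rng, pats, labels=["a", "b", "a", "b"])
    f, m, l = tmp_path / "f.csv", tmp_path / "m.csv", tmp_path / "l.csv"
    write_dataset(ds, f, m, l)
    back = read_dataset(f, m, l)
    assert back.subject_ids == ds.subject_ids
    np.testing.assert_array_equal(back.availability, ds.availability)
    np.testing.assert_array_equal(back.labels.astype(str), ds.labels)
    for mod in ds.modalities:
        av = ds.availability[:, ds.modalities.index(mod)]
        np.testing.assert_allclose(back.features[mod][av],
                                   ds.features[mod][av])


def test_scaler_uses_training_statistics_only(rng):
    ds = make_dataset(rng, [("MRI",)] * 6, dims=(3, 2, 1))
    scaler = FeatureScaler().fit(ds)
    other = make_dataset(rng, [("MRI",)] * 4, dims=(3, 2, 1))
    out = scaler.transform(other)
    expect = (other.features["MRI"] - scaler.mean_["MRI"]) / scaler.std_["MRI"]
    np.testing.assert_allclose(out.features["MRI"], expect)
    scaled = scaler.transform(ds)
    np.testing.assert_allclose(scaled.features["MRI"].mean(axis=0), 0,
                               atol=1e-12)
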