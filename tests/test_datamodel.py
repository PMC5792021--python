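"""Dataset representation, manifest I/O, filtering, summaries, splitting."""

import csv

import numpy as np
import pytest

from antsemble.datamodel import (
    VIEWS,
    EmptyDatasetError,
    ImageSample,
    ManifestError,
    MultiViewDataset,
    View,
    cardinality_summary,
    filter_labels_by_support,
    flatten_to_samples,
    largest_remainder_quotas,
    read_manifest,
    split_dataset,
    write_manifest,
)

from conftest import make_specimen


class TestView:
    def test_canonical_order(self):
        assert VIEWS == (View.HEAD, View.DORSUM, View.PROFILE)

    @pytest.mark.parametrize("token,view", [
        ("head", View.HEAD), ("H", View.HEAD), ("dorsal", View.DORSUM),
        ("d", View.DORSUM), ("Profile", View.PROFILE), ("lateral", View.PROFILE),
    ])
    def test_parse_aliases(self, token, view):
        assert View.parse(token) is view

    def test_parse_rejects_unknown(self):
        with pytest.raises(ValueError, match="side"):
            View.parse("side")


class TestImageSample:
    def test_rejects_out_of_range_intensities(self):
        with pytest.raises(ValueError):
            ImageSample("s", View.HEAD, np.full((4, 4), 2.0))

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            ImageSample("s", View.HEAD, np.zeros((4, 4, 3)))


class TestManifest:
    def test_round_trip_preserves_structure(self, tmp_path, small_synth):
        _, ds, _ = small_synth
        write_manifest(ds, tmp_path)
        again = read_manifest(tmp_path / "manifest.csv")
        assert len(again) == len(ds)
        assert again.n_labels == ds.n_labels
        assert again.labels == list(range(1, ds.n_labels + 1))
        by_id = {s.specimen_id: s for s in again.specimens}
        for spec in ds.specimens:
            back = by_id[spec.specimen_id]
            for v in VIEWS:
                assert back.n_pictures(v) == spec.n_pictures(v)
            # PNG round trip quantizes to 8 bits
            a = spec.pictures(View.HEAD)[0].pixels
            b = back.pictures(View.HEAD)[0].pixels
            assert np.abs(a - b).max() <= 1 / 255 + 1e-6

    def test_duplicated_specimen_view_row_gives_length_two(self, tmp_path, small_synth):
        _, ds, _ = small_synth
        manifest = write_manifest(ds, tmp_path)
        rows = list(csv.reader(open(manifest)))
        rows.append(rows[1])  # duplicate the first data row
        with open(manifest, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        again = read_manifest(manifest)
        sid, _, view, _ = rows[1]
        dup = next(s for s in again.specimens if s.specimen_id == sid)
        assert dup.n_pictures(View.parse(view)) == 2

    def test_unknown_view_token_names_row(self, tmp_path, small_synth):
        _, ds, _ = small_synth
        manifest = write_manifest(ds, tmp_path)
        rows = list(csv.reader(open(manifest)))
        rows[3][2] = "side"
        with open(manifest, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        with pytest.raises(ManifestError, match="row 4"):
            read_manifest(manifest)

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_manifest(tmp_path / "nope.csv")

    def test_missing_image_names_row(self, tmp_path, small_synth):
        _, ds, _ = small_synth
        manifest = write_manifest(ds, tmp_path)
        rows = list(csv.reader(open(manifest)))
        rows[2][3] = "images/absent.png"
        with open(manifest, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        with pytest.raises(ManifestError, match="row 3"):
            read_manifest(manifest)


class TestFilterBySupport:
    def _toy(self):
        return MultiViewDataset(
            [make_specimen(f"a{i}", 1) for i in range(3)]
            + [make_specimen("b0", 2)]
        )

    def test_min_one_is_identity(self, toy_dataset):
        filtered, mapping = filter_labels_by_support(toy_dataset, 1)
        assert len(filtered) == len(toy_dataset)
        assert mapping == {1: 1, 2: 2}

    def test_drops_low_support_and_relabels(self):
        filtered, mapping = filter_labels_by_support(self._toy(), 2)
        assert {s.genus for s in filtered.specimens} == {1}
        assert len(filtered) == 3
        assert mapping == {1: 1}

    def test_empty_result_signals(self):
        with pytest.raises(EmptyDatasetError):
            filter_labels_by_support(self._toy(), 5)

    def test_idempotent_at_same_threshold(self):
        once, _ = filter_labels_by_support(self._toy(), 2)
        twice, _ = filter_labels_by_support(once, 2)
        assert [s.specimen_id for s in twice.specimens] == \
            [s.specimen_id for s in once.specimens]
        assert [s.genus for s in twice.specimens] == \
            [s.genus for s in once.specimens]


class TestCardinalitySummary:
    def test_uniform_one_per_view(self):
        ds = MultiViewDataset([make_specimen("s1", 1), make_specimen("s2", 1)])
        summary = cardinality_summary(ds).as_dict()
        assert summary["N_h = N_p = N_d = 1"] == {"count": 2, "rate": 1.0}

    def test_missing_dorsal_changes_all_views_row(self, toy_dataset):
        summary = cardinality_summary(toy_dataset).as_dict()
        row = summary["N_h >= 1 and N_p >= 1 and N_d >= 1"]
        assert row["count"] == 2
        assert row["rate"] == pytest.approx(2 / 3)
        assert summary["N_d >= 1"]["count"] == 2

    def test_empty_dataset_rates_zero(self):
        summary = cardinality_summary(MultiViewDataset([]))
        assert all(c == 0 and r == 0.0 for _, c, r in summary.rows)

    def test_rates_equal_count_over_total(self, small_synth):
        _, ds, _ = small_synth
        summary = cardinality_summary(ds)
        for _, count, rate in summary.rows:
            assert rate == count / len(ds)


class TestSplit:
    def test_degenerate_fractions_all_train(self, small_synth):
        _, ds, _ = small_synth
        split = split_dataset(ds, (1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == len(ds)
        assert len(split.validation) == len(split.test) == 0

    def test_single_genus_quotas(self):
        ds = MultiViewDataset([make_specimen(f"s{i}", 1) for i in range(10)])
        split = split_dataset(ds, (0.7, 0.2, 0.1), seed=3)
        assert (len(split.train), len(split.validation), len(split.test)) == (7, 2, 1)

    def test_deterministic_for_fixed_seed(self, small_synth):
        _, ds, _ = small_synth
        a = split_dataset(ds, (0.7, 0.2, 0.1), seed=5)
        b = split_dataset(ds, (0.7, 0.2, 0.1), seed=5)
        for pa, pb in zip(a.parts, b.parts):
            assert [s.specimen_id for s in pa.specimens] == \
                [s.specimen_id for s in pb.specimens]

    def test_partition_is_disjoint_and_covers(self, small_synth):
        _, ds, _ = small_synth
        split = split_dataset(ds, (0.7, 0.2, 0.1), seed=1)
        ids = [s.specimen_id for part in split.parts for s in part.specimens]
        assert len(ids) == len(set(ids)) == len(ds)

    def test_val_test_have_exactly_one_per_view(self, small_synth):
        _, ds, _ = small_synth
        split = split_dataset(ds, (0.6, 0.2, 0.2), seed=9)
        for part in (split.validation, split.test):
            assert all(s.has_exactly_one_per_view() for s in part.specimens)

    def test_short_eligible_pool_warns(self):
        # every specimen has an extra profile picture: nothing is eligible
        ds = MultiViewDataset([
            make_specimen(f"s{i}", 1, {v: (2 if v is View.PROFILE else 1)
                                       for v in VIEWS})
            for i in range(10)
        ])
        with pytest.warns(UserWarning, match="quota"):
            split = split_dataset(ds, (0.7, 0.2, 0.1), seed=0)
        assert len(split.train) == 10

    def test_invalid_fractions(self, small_synth):
        _, ds, _ = small_synth
        with pytest.raises(ValueError):
            split_dataset(ds, (0.5, 0.2, 0.1), seed=0)
        with pytest.raises(EmptyDatasetError):
            split_dataset(MultiViewDataset([]), (0.7, 0.2, 0.1), seed=0)


class TestFlatten:
    def test_count_is_sum_of_list_lengths(self, toy_dataset):
        samples = flatten_to_samples(toy_dataset)
        assert len(samples) == sum(
            s.n_pictures(v) for s in toy_dataset.specimens for v in VIEWS
        ) == 9  # s1: 3, s2: 4 (two profile), s3: 2 (no dorsal)

    def test_view_filter(self, toy_dataset):
        assert len(flatten_to_samples(toy_dataset, views=(View.HEAD,))) == 3
        # s2 has two profile pictures: profile contributes 4 in total
        assert len(flatten_to_samples(toy_dataset, views=(View.PROFILE,))) == 4

    def test_labels_attached(self, toy_dataset):
        labels = [g for _, g in flatten_to_samples(toy_dataset, views=(View.HEAD,))]
        assert labels == [1, 1, 2]

    def test_shuffle_deterministic(self, toy_dataset):
        a = flatten_to_samples(toy_dataset, shuffle_seed=4)
        b = flatten_to_samples(toy_dataset, shuffle_seed=4)
        assert [(s.specimen_id, s.view) for s, _ in a] == \
            [(s.specimen_id, s.view) for s, _ in b]


def test_largest_remainder_is_exact_and_deterministic():
    assert largest_remainder_quotas(10, (0.7, 0.2, 0.1)) == [7, 2, 1]
    assert largest_remainder_quotas(3, (0.7, 0.2, 0.1)) == [2, 1, 0]
    assert largest_remainder_quotas(1, (0.7, 0.2, 0.1)) == [1, 0, 0]
    for total in range(0, 30):
        assert sum(largest_remainder_quotas(total, (0.7, 0.2, 0.1))) == total
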