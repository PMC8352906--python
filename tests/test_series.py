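"""Series construction: binning, concatenation, relative transform, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taphoseries.series import (
    ELEMENTS,
    AssemblageSeries,
    BoneTemplate,
    CutMarkRecord,
    LabeledDataset,
    bin_marks,
    build_series,
    default_templates,
    read_series_csv,
    to_relative,
    write_series_csv,
)


def rec(element, position, sid="s1"):
    return CutMarkRecord(sid, element, position)


class TestBinMarks:
    def test_empty_input_gives_zero_vector(self):
        out = bin_marks([], BoneTemplate("humerus", 30))
        assert out.shape == (30,) and not out.any()

    @pytest.mark.parametrize(
        "position, orientation, expected_index",
        [
            (0.5, "proximal_first", 15),   # floor(0.5 * 30)
            (0.0, "distal_first", 29),     # reversal maps index 0 -> 29
            (0.0, "proximal_first", 0),
            (1.0, "proximal_first", 29),   # position 1.0 joins the last bin
            (1.0, "distal_first", 0),
        ],
    )
    def test_bin_rule_and_orientation(self, position, orientation, expected_index):
        t = BoneTemplate("tibia", 30, orientation)
        out = bin_marks([rec("tibia", position)], t)
        assert out[expected_index] == 1 and out.sum() == 1

    def test_element_mismatch_identifies_offender(self):
        with pytest.raises(ValueError, match="bad_sample"):
            bin_marks([rec("femur", 0.5, sid="bad_sample")], BoneTemplate("humerus"))

    @given(
        positions=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=0, max_size=50
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_count_conservation_and_reversal_involution(self, positions):
        records = [rec("radius", p) for p in positions]
        prox = bin_marks(records, BoneTemplate("radius", 17, "proximal_first"))
        dist = bin_marks(records, BoneTemplate("radius", 17, "distal_first"))
        assert prox.sum() == len(positions)
        assert np.array_equal(dist, prox[::-1])


class TestBuildSeries:
    def test_single_humerus_mark_lands_in_first_block(self):
        s = build_series([rec("humerus", 0.1)])
        assert len(s.values) == 120
        assert s.values[:30].sum() == 1 and s.values[30:].sum() == 0
        assert s.total_marks == 1

    def test_missing_elements_are_zero_blocks(self):
        s = build_series([rec("femur", 0.2), rec("femur", 0.9)])
        blocks = s.values.reshape(4, 30)
        assert blocks[ELEMENTS.index("femur")].sum() == 2
        assert blocks[[0, 1, 3]].sum() == 0

    def test_empty_sample_is_zero_series(self):
        s = build_series([], sample_id="void")
        assert s.total_marks == 0 and not s.values.any()

    @given(st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=20)
    def test_record_order_irrelevant(self, random):
        records = [
            rec(el, pos)
            for el in ELEMENTS
            for pos in (0.0, 0.25, 0.26, 0.8, 1.0)
        ]
        shuffled = records[:]
        random.shuffle(shuffled)
        assert np.array_equal(
            build_series(records).values, build_series(shuffled).values
        )

    def test_templates_must_share_n_bins(self):
        templates = default_templates(30)
        templates["femur"] = BoneTemplate("femur", 20)
        with pytest.raises(ValueError, match="n_bins"):
            build_series([rec("femur", 0.5)], templates)


class TestToRelative:
    def test_uniform_counts(self):
        s = AssemblageSeries("a", [1, 1, 1, 1], total_marks=4)
        assert np.allclose(to_relative(s).values, [25, 25, 25, 25])

    def test_direct_percentages(self):
        s = AssemblageSeries("a", [3, 1, 0, 0], total_marks=4)
        out = to_relative(s)
        assert np.allclose(out.values, [75, 25, 0, 0])
        assert out.mode == "relative"

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError, match="no marks"):
            to_relative(AssemblageSeries("z", np.zeros(8)))

    def test_relative_input_rejected(self):
        s = AssemblageSeries("a", [50.0, 50.0], mode="relative")
        with pytest.raises(ValueError):
            to_relative(s)

    @given(
        counts=st.lists(st.integers(0, 20), min_size=4, max_size=40).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_percentages_sum_to_100(self, counts):
        s = AssemblageSeries("a", counts, total_marks=sum(counts))
        assert to_relative(s).values.sum() == pytest.approx(100.0, abs=1e-9)


def test_series_csv_round_trip(tmp_path, separable_dataset):
    path = tmp_path / "series.csv"
    write_series_csv(separable_dataset, path)
    back = read_series_csv(path)
    assert back.labels == separable_dataset.labels
    assert np.allclose(back.X, separable_dataset.X)
    assert back.sample_ids == separable_dataset.sample_ids


def test_dataset_matrix_shape(separable_dataset):
    ds = separable_dataset
    assert ds.X.shape == (80, 120)
    assert set(ds.y) == {"P", "S"}
    sub = ds.subset([0, 1, 79])
    assert len(sub) == 3 and sub.labels[-1] == "S"
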