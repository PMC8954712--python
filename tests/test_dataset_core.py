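"""Activity conversion, potency labeling, fingerprint IO, stratified splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragminer.dataset_core import (
    ActivityRecord,
    FingerprintMatrix,
    assign_class,
    label_records,
    load_activity_table,
    load_fingerprint_table,
    parse_ratio,
    pic50_from_ic50,
    stratified_split,
    write_fingerprint_table,
)


class TestPic50Conversion:
    @pytest.mark.parametrize(
        "ic50, expected",
        [
            (1.0, 6.0),       # the 1 uM potency cutoff
            (1000.0, 3.0),
            (0.056, 6 - math.log10(0.056)),  # ~7.252, a highly potent compound
        ],
    )
    def test_known_conversions(self, ic50, expected):
        assert pic50_from_ic50(ic50) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_nonpositive_and_nonfinite(self, bad):
        with pytest.raises(ValueError):
            pic50_from_ic50(bad)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert pic50_from_ic50(lo) > pic50_from_ic50(hi)


class TestAssignClass:
    def test_boundary_and_sides(self):
        assert assign_class(7.0) == "P"
        assert assign_class(6.0) == "P"  # boundary counts potent (IC50 = 1 uM)
        assert assign_class(pic50_from_ic50(28.1)) == "N"  # ~4.55

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assign_class(float("nan"))

    def test_labeling_study_sized_set_is_idempotent(self, study_dataset):
        _, records = study_dataset
        labeled = label_records(records)
        counts = {"P": 0, "N": 0}
        for r in labeled:
            counts[r.potency_class] += 1
        assert counts == {"P": 89, "N": 28}
        assert label_records(labeled) == labeled


class TestActivityRecord:
    def test_pic50_derived_from_ic50(self):
        r = ActivityRecord("c1", ic50_uM=1.0)
        assert r.pic50 == pytest.approx(6.0)

    def test_requires_some_activity(self):
        with pytest.raises(ValueError):
            ActivityRecord("c1")

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError):
            ActivityRecord("c1", ic50_uM=1.0, pic50=5.0)


class TestFingerprintIO:
    def test_toy_round_trip(self, tmp_path):
        p = tmp_path / "fp.csv"
        p.write_text("Name,b1,b2,b3,b4\nc1,0,1,0,1\nc2,1,1,0,0\nc3,0,0,0,1\n")
        fm = load_fingerprint_table(p)
        assert fm.shape == (3, 4)
        assert fm.compound_ids == ["c1", "c2", "c3"]
        assert fm.values[1].tolist() == [1, 1, 0, 0]

    def test_non_binary_cell_named_in_error(self, tmp_path):
        p = tmp_path / "fp.csv"
        p.write_text("Name,b1,b2\nc1,0,1\nc2,2,0\n")
        with pytest.raises(ValueError, match=r"c2.*b1|b1.*c2"):
            load_fingerprint_table(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "fp.csv"
        p.write_text("Name,b1\nc1,0\nc1,1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_fingerprint_table(p)

    def test_study_scale_write_read_identity(self, tmp_path, study_dataset):
        fm, _ = study_dataset
        p = tmp_path / "big.csv"
        write_fingerprint_table(fm, p)
        back = load_fingerprint_table(p)
        assert back.compound_ids == fm.compound_ids
        assert back.bit_names == fm.bit_names
        assert np.array_equal(back.values, fm.values)

    def test_semicolon_dialect(self, tmp_path):
        p = tmp_path / "fp.csv"
        p.write_text("Name;b1;b2\nc1;0;1\n c2;1;0\n".replace(" ", ""))
        fm = load_fingerprint_table(p, sep=";")
        assert fm.shape == (2, 2)

    def test_activity_table_loading(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("compound_id,smiles,ic50_uM\nc1,CCO,0.5\nc2,,2.0\n")
        recs = load_activity_table(p)
        assert recs[0].pic50 == pytest.approx(6 - math.log10(0.5))
        assert recs[1].smiles is None


class TestFingerprintMatrixInvariants:
    def test_non_binary_values_rejected(self):
        with pytest.raises(ValueError):
            FingerprintMatrix(["a"], ["b1"], np.array([[2]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FingerprintMatrix(["a", "b"], ["b1"], np.zeros((1, 1)))

    def test_duplicate_bit_names_rejected(self):
        with pytest.raises(ValueError):
            FingerprintMatrix(["a"], ["b1", "b1"], np.zeros((1, 2)))

    def test_subset_preserves_order(self, study_dataset):
        fm, _ = study_dataset
        sub = fm.subset(["MOL005", "MOL001"])
        assert sub.compound_ids == ["MOL005", "MOL001"]
        assert np.array_equal(sub.values[0], fm.values[4])


def _records(n_p, n_n):
    recs = [ActivityRecord(f"p{i}", pic50=7.0) for i in range(n_p)]
    recs += [ActivityRecord(f"n{i}", pic50=5.0) for i in range(n_n)]
    return label_records(recs)


class TestStratifiedSplit:
    def test_three_to_one_totals_on_study_sized_set(self):
        recs = _records(89, 28)
        sp = stratified_split(recs, ratio="3:1", seed=3)
        assert len(sp.train_ids) == 88
        assert len(sp.test_ids) == 29
        assert set(sp.train_ids) | set(sp.test_ids) == {r.compound_id for r in recs}
        assert not set(sp.train_ids) & set(sp.test_ids)

    def test_proportional_class_allocation(self):
        sp = stratified_split(_records(89, 28), ratio=3.0, seed=0)
        test_p = sum(i.startswith("p") for i in sp.test_ids)
        # 89 * 29 / 117 = 22.06 -> 22 potent in test under proportional quota
        assert test_p == 22

    def test_published_per_class_layout_via_explicit_counts(self):
        sp = stratified_split(
            _records(89, 28), ratio="3:1", seed=0, test_counts={"P": 20, "N": 9}
        )
        train_p = sum(i.startswith("p") for i in sp.train_ids)
        train_n = sum(i.startswith("n") for i in sp.train_ids)
        test_p = sum(i.startswith("p") for i in sp.test_ids)
        test_n = sum(i.startswith("n") for i in sp.test_ids)
        assert (train_p, train_n) == (69, 19)
        assert (test_p, test_n) == (20, 9)

    def test_all_train_ratio(self):
        sp = stratified_split(_records(5, 5), ratio="1:0", seed=0)
        assert len(sp.train_ids) == 10 and sp.test_ids == []

    def test_determinism_and_seed_sensitivity(self):
        recs = _records(30, 10)
        a = stratified_split(recs, 3.0, seed=5)
        b = stratified_split(recs, 3.0, seed=5)
        c = stratified_split(recs, 3.0, seed=6)
        assert a.test_ids == b.test_ids
        assert a.test_ids != c.test_ids

    def test_tiny_class_refused(self):
        with pytest.raises(ValueError, match="cannot stratify"):
            stratified_split(_records(10, 1), 3.0, seed=0)

    def test_parse_ratio_forms(self):
        assert parse_ratio("3:1") == 3.0
        assert parse_ratio(3.0) == 3.0
        assert math.isinf(parse_ratio("1:0"))
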