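import itertools

import numpy as np
import pandas as pd
import pytest

from lobemap.barcode import (
    BarcodeParams,
    apply_corrections,
    assign_object_barcodes,
    build_records,
    classify_size,
    encode_barcodes,
    encode_channels,
    filter_small_objects,
    label_objects,
    object_volumes,
    union_mask,
)
from lobemap.core import MetastasisRecord, VoxelGrid

from _oracles import flood_fill_labels, same_partition
from conftest import ANISO


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=np.uint8), spacing, "binary")


class TestEncode:
    def test_all_eight_combinations(self):
        # one voxel per (S,V,T) combination: code is the binary interpretation
        combos = list(itertools.product([0, 1], repeat=3))
        s = _mask(np.array([[ [c[0] for c in combos] ]]))
        v = _mask(np.array([[ [c[1] for c in combos] ]]))
        t = _mask(np.array([[ [c[2] for c in combos] ]]))
        codes = encode_barcodes(s, v, t).data[0, 0]
        assert codes.tolist() == [c[0] * 1 + c[1] * 2 + c[2] * 4 for c in combos]
        assert sorted(codes.tolist()) == list(range(8))

    def test_single_channel_bit_values(self):
        one = _mask(np.ones((1, 1, 1)))
        zero = _mask(np.zeros((1, 1, 1)))
        assert encode_barcodes(one, zero, zero).data.item() == 1  # S → 001
        assert encode_barcodes(zero, one, zero).data.item() == 2  # V → 010
        assert encode_barcodes(zero, zero, one).data.item() == 4  # T → 100

    @pytest.mark.parametrize("k,expected", [(3, 7), (5, 31)])
    def test_generalised_encoder_code_count(self, k, expected, rng):
        masks = [_mask(rng.integers(0, 2, size=(4, 6, 6))) for _ in range(k)]
        codes = encode_channels(masks).data
        assert codes.max() <= 2**k - 1
        # enumerate all combinations explicitly: 2^k − 1 nonzero codes
        full = [_mask(np.array([c]).reshape(1, 1, -1))
                for c in zip(*itertools.product([0, 1], repeat=k))]
        all_codes = encode_channels(full).data.ravel()
        assert len(set(all_codes.tolist()) - {0}) == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            encode_barcodes(_mask(np.zeros((1, 2, 2))), _mask(np.zeros((1, 2, 3))),
                            _mask(np.zeros((1, 2, 2))))

    def test_union_equals_positive_codes(self, rng):
        masks = [_mask(rng.integers(0, 2, size=(5, 5, 5))) for _ in range(3)]
        u = union_mask(*masks).data
        codes = encode_barcodes(*masks).data
        assert np.array_equal(u, (codes > 0).astype(np.uint8))

    def test_code_conservation(self, rng):
        # per-code voxel counts over codes 1–7 sum to the union voxel count
        masks = [_mask(rng.integers(0, 2, size=(6, 6, 6))) for _ in range(3)]
        codes = encode_barcodes(*masks).data
        counts = np.bincount(codes.ravel(), minlength=8)
        assert counts[1:].sum() == union_mask(*masks).data.sum()


class TestLabelObjects:
    def test_empty_mask(self):
        _, n = label_objects(_mask(np.zeros((3, 3, 3))))
        assert n == 0

    def test_two_separated_cubes(self):
        data = np.zeros((2, 2, 7), dtype=np.uint8)
        data[:, :, :2] = 1
        data[:, :, 5:] = 1
        _, n = label_objects(_mask(data), 26)
        assert n == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((10, 10, 10)) < 0.3
        labels, n = label_objects(_mask(mask), connectivity)
        oracle = flood_fill_labels(mask, connectivity)
        assert n == oracle.max()
        assert same_partition(labels.data, oracle)

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_objects(_mask(np.zeros((2, 2, 2))), 4)


class TestObjectVolumes:
    def test_single_voxel_unit_spacing(self):
        lab = VoxelGrid(np.eye(1, 8, dtype=np.int32).reshape(1, 2, 4), (1, 1, 1), "label")
        vols = object_volumes(lab)
        assert vols[1][0] == 1 and vols[1][1] == pytest.approx(1.0)

    def test_acquisition_spacing_arithmetic(self):
        data = np.zeros((2, 3, 3), dtype=np.int32)
        data.ravel()[:10] = 1
        lab = VoxelGrid(data, (2.90, 1.22, 1.22), "label")
        assert object_volumes(lab)[1][1] == pytest.approx(10 * 2.90 * 1.22**2)  # 43.164

    def test_translation_equivariance(self):
        a = np.zeros((6, 6, 6), dtype=np.int32)
        a[1:3, 1:3, 1:3] = 1
        b = np.roll(a, (2, 1, 3), axis=(0, 1, 2))
        va = object_volumes(VoxelGrid(a, ANISO, "label"))[1]
        vb = object_volumes(VoxelGrid(b, ANISO, "label"))[1]
        assert va[0] == vb[0] and va[1] == pytest.approx(vb[1])
        shift = np.subtract(vb[2], va[2])
        assert shift == pytest.approx((2 * 2.9, 1 * 1.22, 3 * 1.22))


def _rec(i, vol):
    return MetastasisRecord(object_id=i, voxel_count=1, volume_um3=vol, centroid=(0, 0, 0))


class TestVolumeFilter:
    def test_boundary_inclusive_at_9000(self):
        recs = [_rec(1, 8999.9), _rec(2, 9000.0), _rec(3, 9001.0)]
        kept, removed = filter_small_objects(recs, 9000.0)
        assert [r.object_id for r in kept] == [2, 3]
        assert removed == [1]

    def test_zero_threshold_keeps_all_and_empty_input(self):
        recs = [_rec(1, 0.0), _rec(2, 5.0)]
        kept, removed = filter_small_objects(recs, 0.0)
        assert len(kept) == 2 and removed == []
        assert filter_small_objects([], 9000.0) == ([], [])

    def test_survivors_unchanged(self):
        rec = _rec(5, 10000.0)
        kept, _ = filter_small_objects([rec], 9000.0)
        assert kept[0] is rec

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_small_objects([], -1.0)


class TestAssignBarcodes:
    def _setup(self, code_values):
        codes = np.asarray(code_values, dtype=np.int8).reshape(1, 1, -1)
        labels = (codes > 0).astype(np.int32)
        n = codes.size
        rec = MetastasisRecord(object_id=1, voxel_count=int((codes > 0).sum()),
                               volume_um3=float(n), centroid=(0, 0, 0))
        return ([rec], VoxelGrid(labels, (1, 1, 1), "label"),
                VoxelGrid(codes, (1, 1, 1), "code"))

    def test_pure_object_monochromatic(self):
        recs, labels, codes = self._setup([5] * 10)
        out = assign_object_barcodes(recs, labels, codes)[0]
        assert out.barcode_set == {5} and out.chromatic_class == "monochromatic"
        assert out.barcode_fractions[5] == pytest.approx(1.0)

    def test_even_split_polychromatic(self):
        recs, labels, codes = self._setup([1] * 5 + [2] * 5)
        out = assign_object_barcodes(recs, labels, codes, 0.05)[0]
        assert out.barcode_set == {1, 2} and out.chromatic_class == "polychromatic"

    def test_small_fraction_vetoed(self):
        recs, labels, codes = self._setup([1] * 97 + [3] * 3)
        out = assign_object_barcodes(recs, labels, codes, 0.05)[0]
        assert out.barcode_set == {1} and out.chromatic_class == "monochromatic"
        assert out.barcode_fractions[3] == pytest.approx(0.03)

    def test_no_code_reaching_cutoff_keeps_largest(self):
        recs, labels, codes = self._setup([1] * 3 + [2] * 3 + [4] * 2 + [5] * 2)
        out = assign_object_barcodes(recs, labels, codes, presence_fraction=0.5)[0]
        assert out.barcode_set == {1}  # ties broken toward the smaller code

    def test_fractions_sum_to_one(self, rng):
        vals = rng.integers(1, 8, size=40)
        recs, labels, codes = self._setup(vals)
        out = assign_object_barcodes(recs, labels, codes)[0]
        assert sum(out.barcode_fractions.values()) == pytest.approx(1.0)

    def test_zero_code_inside_object_is_error(self):
        codes = np.array([[[1, 0, 1]]], dtype=np.int8)
        labels = np.array([[[1, 1, 1]]], dtype=np.int32)
        rec = MetastasisRecord(object_id=1, voxel_count=3, volume_um3=3.0, centroid=(0, 0, 0))
        with pytest.raises(ValueError, match="code-0"):
            assign_object_barcodes([rec], VoxelGrid(labels, (1, 1, 1), "label"),
                                   VoxelGrid(codes, (1, 1, 1), "code"))


class TestCorrections:
    def _recs(self):
        return [
            MetastasisRecord(object_id=i, voxel_count=1, volume_um3=1.0, centroid=(0, 0, 0),
                             barcode_set=frozenset({1}), chromatic_class="monochromatic")
            for i in (3, 5)
        ]

    def test_single_code_replacement_is_monochromatic(self):
        out = apply_corrections(self._recs(), {3: frozenset({7})})
        assert out[0].barcode_set == {7}
        assert out[0].chromatic_class == "monochromatic"
        assert out[0].corrected and not out[1].corrected

    def test_multi_code_replacement_is_polychromatic(self):
        out = apply_corrections(self._recs(), {5: frozenset({1, 2})})
        assert out[1].chromatic_class == "polychromatic"

    def test_empty_table_identity(self):
        recs = self._recs()
        out = apply_corrections(recs, {})
        assert [r.barcode_set for r in out] == [r.barcode_set for r in recs]
        assert not any(r.corrected for r in out)

    def test_dataframe_input_with_names(self):
        df = pd.DataFrame({"object_id": [3], "new_barcode_set": ["S;VT"]})
        out = apply_corrections(self._recs(), df)
        assert out[0].barcode_set == {1, 6}

    def test_unknown_id_and_empty_set_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_corrections(self._recs(), {99: frozenset({1})})
        with pytest.raises(ValueError, match="empty"):
            apply_corrections(self._recs(), {3: frozenset()})


class TestSizeClasses:
    @pytest.mark.parametrize(
        "volume,preset,expected",
        [
            (5e4, "fig3", "below_small"),
            (5e5, "fig3", "small"),
            (1e6, "fig3", "medium"),   # half-open boundary
            (5e6, "fig3", "medium"),
            (2e7, "fig3", "large"),
            (5e7, "fig3", "very_large"),
            (6e7, "fig3", "very_large"),
            (2e7, "fig5", "large"),
            (6e7, "fig5", "large"),    # no very_large bin in the 3-bin preset
            (5e5, "fig5", "small"),
        ],
    )
    def test_bin_assignment(self, volume, preset, expected):
        assert classify_size(volume, preset) == expected

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            classify_size(1e6, "fig9")


class TestParams:
    @pytest.mark.parametrize(
        "kw", [dict(min_volume_um3=-1), dict(presence_fraction=1.0), dict(connectivity=13)]
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            BarcodeParams(**kw)
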