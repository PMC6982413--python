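import numpy as np
import pandas as pd
import pytest

from chorodig.classify import ClassifiedMap, class_raster_from_objects
from chorodig.cleanup import (CleanupParams, OverrideEntry, OverrideList,
                              absorb_black_objects, apply_overrides,
                              detect_black_objects, fill_missing_from)
from chorodig.geo import Affine
from chorodig.legend import BLACK, NODATA
from chorodig.segmentation import SegmentMap, compute_object_stats


def make_cmap(classes, labels, legend, transform=None):
    ids = np.unique(labels[labels > 0])
    oc = {}
    for oid in ids:
        vals = classes[labels == oid]
        oc[int(oid)] = int(vals[0])
    oc = pd.Series(oc, dtype=int)
    return ClassifiedMap(classes, labels, oc,
                         pd.Series("model", index=oc.index, dtype=object),
                         transform or Affine.identity(), "", legend.nodata_id)


def scene_with_black_blob(legend):
    """8x8 class-1 field with a 3-pixel black blob."""
    pixels = np.tile(np.asarray(legend[1].color, np.uint8), (8, 8, 1))
    labels = np.ones((8, 8), np.int32)
    classes = np.full((8, 8), 1, np.int16)
    pixels[4, 2:5] = 0
    labels[4, 2:5] = 2
    classes[4, 2:5] = BLACK
    objects, adjacency = compute_object_stats(pixels, labels)
    seg = SegmentMap(labels, objects, adjacency)
    return make_cmap(classes, labels, legend), seg


class TestDetect:
    def test_black_and_colored_means(self, legend):
        objects = pd.DataFrame({
            "n": [3, 5],
            "mean_R": [0.0, 200.0], "mean_G": [0.0, 30.0], "mean_B": [0.0, 30.0],
            "sd_R": 0.0, "sd_G": 0.0, "sd_B": 0.0,
        }, index=pd.Index([1, 2], name="id"))
        found = detect_black_objects(objects, CleanupParams())
        assert found == {1}

    def test_detects_rendered_ink_exactly(self, clean_scene):
        img, gt, _ = clean_scene
        from chorodig.segmentation import SegmentationParams, multiresolution_segment

        seg = multiresolution_segment(img, SegmentationParams(scale=10.0))
        found = detect_black_objects(seg.objects, CleanupParams(black_max_channel=60))
        ink = gt.ink_mask
        flagged = np.isin(seg.labels, sorted(found))
        np.testing.assert_array_equal(flagged, ink)


class TestAbsorb:
    def test_small_blob_takes_surrounding_class(self, legend):
        cmap, seg = scene_with_black_blob(legend)
        out = absorb_black_objects(cmap, seg, CleanupParams(), legend)
        assert (out.classes == 1).all()
        assert out.provenance.loc[2] == "rule"

    def test_border_line_absorbed_and_area_conserved(self, legend):
        # 1-pixel black border between classes 1 and 2
        pixels = np.zeros((6, 9, 3), np.uint8)
        pixels[:, :4] = legend[1].color
        pixels[:, 5:] = legend[2].color
        labels = np.zeros((6, 9), np.int32)
        labels[:, :4] = 1
        labels[:, 4] = 2
        labels[:, 5:] = 3
        classes = np.zeros((6, 9), np.int16)
        classes[:, :4] = 1
        classes[:, 4] = BLACK
        classes[:, 5:] = 2
        objects, adjacency = compute_object_stats(pixels, labels)
        seg = SegmentMap(labels, objects, adjacency)
        cmap = make_cmap(classes, labels, legend)
        out = absorb_black_objects(cmap, seg, CleanupParams(), legend)
        assert not (out.classes == BLACK).any()
        assert (out.classes != legend.nodata_id).all()  # area conserved
        assert set(np.unique(out.classes)) == {1, 2}
        # former border pixels split between the adjacent sides
        assert set(np.unique(out.classes[:, 4])) <= {1, 2}

    def test_no_black_identity(self, legend):
        pixels = np.tile(np.asarray(legend[1].color, np.uint8), (5, 5, 1))
        labels = np.ones((5, 5), np.int32)
        classes = np.full((5, 5), 1, np.int16)
        objects, adjacency = compute_object_stats(pixels, labels)
        seg = SegmentMap(labels, objects, adjacency)
        cmap = make_cmap(classes, labels, legend)
        out = absorb_black_objects(cmap, seg, CleanupParams(), legend)
        np.testing.assert_array_equal(out.classes, cmap.classes)
        np.testing.assert_array_equal(out.labels, cmap.labels)

    def test_idempotent(self, legend):
        cmap, seg = scene_with_black_blob(legend)
        once = absorb_black_objects(cmap, seg, CleanupParams(), legend)
        twice = absorb_black_objects(once, seg, CleanupParams(), legend)
        np.testing.assert_array_equal(once.classes, twice.classes)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_black_surrounded_by_nodata_becomes_nodata(self, legend):
        classes = np.full((5, 5), NODATA, np.int16)
        labels = np.zeros((5, 5), np.int32)
        classes[2, 2] = BLACK
        labels[2, 2] = 1
        cmap = make_cmap(classes, labels, legend)
        with pytest.warns(UserWarning, match="absorbed"):
            out = absorb_black_objects(cmap, None,
                                       CleanupParams(max_absorption_passes=3),
                                       legend)
        assert out.classes[2, 2] == NODATA


class TestOverrides:
    def test_empty_list_identity(self, legend):
        cmap, _ = scene_with_black_blob(legend)
        out = apply_overrides(cmap, OverrideList(), legend)
        np.testing.assert_array_equal(out.classes, cmap.classes)

    def test_object_override_changes_exactly_its_pixels(self, legend):
        cmap, _ = scene_with_black_blob(legend)
        out = apply_overrides(
            cmap, OverrideList([OverrideEntry("object", 2, 3, "fix")]), legend)
        changed = out.classes != cmap.classes
        np.testing.assert_array_equal(changed, cmap.labels == 2)
        assert (out.classes[cmap.labels == 2] == 3).all()
        assert out.provenance.loc[2] == "override"

    def test_unknown_object_id(self, legend):
        cmap, _ = scene_with_black_blob(legend)
        with pytest.raises(KeyError, match="42"):
            apply_overrides(
                cmap, OverrideList([OverrideEntry("object", 42, 1)]), legend)

    def test_box_overrides_later_entry_wins(self, legend):
        cmap, _ = scene_with_black_blob(legend)
        ov = OverrideList([
            OverrideEntry("box", (0, 0, 4, 4), 2, "first"),
            OverrideEntry("box", (2, 2, 6, 6), 3, "second"),
        ])
        out = apply_overrides(cmap, ov, legend)
        assert (out.classes[2:6, 2:6] == 3).all()   # overlap: later wins
        assert (out.classes[0:2, 0:4] == 2).all()

    def test_override_csv_round_trip(self, tmp_path, legend):
        p = tmp_path / "overrides.csv"
        p.write_text("target_type,target,class_id,reason\n"
                     "object,2,3,border fix\n"
                     "box,1;1;3;3,4,smudge\n")
        ov = OverrideList.from_csv(p)
        assert ov.entries[0] == OverrideEntry("object", 2, 3, "border fix")
        assert ov.entries[1].target == (1, 1, 3, 3)


class TestFillMissing:
    def _pair(self, legend, clean_scene):
        img, gt, zones = clean_scene
        classes = gt.classes.astype(np.int16)
        labels = gt.unit_raster.astype(np.int32) + 1
        truth = make_cmap(classes, labels, legend, gt.transform)
        # primary: one unit blanked out
        primary = truth.copy()
        hole_unit = 3
        m = gt.unit_raster == hole_unit
        primary.classes[m] = legend.nodata_id
        primary.labels[m] = 0
        primary.object_classes = primary.object_classes.drop(
            index=[hole_unit + 1], errors="ignore")
        return truth, primary, zones, zones.unit_ids[hole_unit]

    def test_no_units_identity(self, legend, clean_scene):
        truth, primary, zones, _ = self._pair(legend, clean_scene)
        out = fill_missing_from(primary, truth, zones, [], legend)
        np.testing.assert_array_equal(out.classes, primary.classes)

    def test_masked_unit_restored(self, legend, clean_scene):
        truth, primary, zones, uid = self._pair(legend, clean_scene)
        out = fill_missing_from(primary, truth, zones, [uid], legend)
        np.testing.assert_array_equal(out.classes, truth.classes)
        filled = out.labels != primary.labels
        assert (out.provenance.loc[np.unique(out.labels[filled])] ==
                "fallback-map").all()

    def test_untouched_outside_listed_units(self, legend, clean_scene):
        truth, primary, zones, uid = self._pair(legend, clean_scene)
        other = [u for u in zones.unit_ids if u != uid][0]
        out = fill_missing_from(primary, truth, zones, [other], legend)
        np.testing.assert_array_equal(out.classes, primary.classes)

    def test_grid_mismatch(self, legend, clean_scene):
        truth, primary, zones, uid = self._pair(legend, clean_scene)
        shrunk = ClassifiedMap(truth.classes[:-1], truth.labels[:-1],
                               truth.object_classes, truth.provenance,
                               truth.transform, "", legend.nodata_id)
        with pytest.raises(ValueError, match="grid"):
            fill_missing_from(primary, shrunk, zones, [uid], legend)

    def test_unknown_unit(self, legend, clean_scene):
        truth, primary, zones, _ = self._pair(legend, clean_scene)
        with pytest.raises(KeyError, match="nope"):
            fill_missing_from(primary, truth, zones, ["nope"], legend)
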