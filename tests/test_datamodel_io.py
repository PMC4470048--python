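"""Data model invariants and on-disk round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioflow4d.datamodel import (
    PlanarROI,
    SegmentationSet,
    ValvePlane,
    VelocityField4D,
    plane_basis,
)
from cardioflow4d.flow_io import (
    import_nifti_series,
    read_dataset,
    write_dataset,
    write_results,
)


def _small_field(nt=4, shape=(3, 4, 5), spacing=(3.0, 3.0, 3.0), venc=100.0):
    rng = np.random.default_rng(7)
    vel = rng.normal(0, 30, size=(nt, *shape, 3))
    return VelocityField4D(vel, spacing, 25.0, venc, origin=(-6.0, -4.5, -3.0))


class TestVelocityField:
    def test_voxel_volume_is_product_of_spacings(self):
        f = _small_field(spacing=(3.0, 2.0, 1.5))
        assert f.voxel_volume == pytest.approx(9.0, rel=1e-12)
        f3 = _small_field(spacing=(3.0, 3.0, 3.0))
        assert f3.voxel_volume == pytest.approx(27.0, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(nt=1),
            dict(spacing=(0.0, 3.0, 3.0)),
            dict(venc=-5.0),
        ],
    )
    def test_invalid_construction_rejected(self, kwargs):
        with pytest.raises(ValueError):
            _small_field(**kwargs)

    def test_cycle_length_and_frame_times(self):
        f = _small_field(nt=4)
        assert f.cycle_length == 100.0
        assert np.array_equal(f.frame_times(), [0.0, 25.0, 50.0, 75.0])


class TestSegmentation:
    def test_ed_es_derived_from_volume_curve(self):
        masks = np.zeros((3, 2, 2, 2), dtype=bool)
        masks[0, 0] = True  # 4 voxels
        masks[1, 0, 0, 0] = True  # 1 voxel
        masks[2, 0, 0] = True  # 2 voxels
        seg = SegmentationSet.from_masks(masks)
        assert (seg.ed_index, seg.es_index) == (0, 1)
        assert np.allclose(seg.volumes_ml(1000.0), [4.0, 1.0, 2.0])

    def test_ed_smaller_than_es_rejected(self):
        masks = np.zeros((2, 2, 2, 2), dtype=bool)
        masks[1, 0] = True
        with pytest.raises(ValueError):
            SegmentationSet(masks, ed_index=0, es_index=1)


class TestPlanes:
    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            ValvePlane(np.zeros(3), np.array([0.0, 0.0, 2.0]), "mitral")

    def test_signed_distance_sign_is_basal(self):
        vp = ValvePlane(np.array([0.0, 0.0, 10.0]), np.array([0.0, 0.0, 1.0]),
                        "aortic")
        d = vp.signed_distance(np.array([[0, 0, 15.0], [0, 0, 5.0]]))
        assert d[0] > 0 > d[1]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_plane_basis_orthonormal(self, n):
        if np.linalg.norm(n) < 1e-3:
            return
        e1, e2 = plane_basis(n)
        nn = np.asarray(n) / np.linalg.norm(n)
        for a, b in [(e1, e1), (e2, e2)]:
            assert np.dot(a, b) == pytest.approx(1.0, abs=1e-12)
        for a, b in [(e1, e2), (e1, nn), (e2, nn)]:
            assert np.dot(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            PlanarROI(np.zeros(3), np.array([0, 0, 1.0]), [bowtie])


class TestContainerRoundTrip:
    def test_write_read_identity(self, tmp_path):
        f = _small_field()
        masks = np.zeros((4, 3, 4, 5), dtype=bool)
        masks[:, 1, 1:3, 1:3] = True
        seg = SegmentationSet(masks, 0, 2)
        path = tmp_path / "ds.h5"
        write_dataset(path, f, seg)
        f2, seg2 = read_dataset(path)
        assert np.array_equal(f2.velocities, f.velocities)  # bit-identical
        assert f2.spacing == f.spacing
        assert f2.venc == f.venc
        assert f2.origin == f.origin
        assert f2.timeframe_duration == f.timeframe_duration
        assert np.array_equal(seg2.lv_masks, seg.lv_masks)
        assert (seg2.ed_index, seg2.es_index) == (0, 2)

    def test_missing_metadata_names_field(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        f = _small_field()
        write_dataset(path, f)
        with h5py.File(path, "a") as h:
            del h["meta"].attrs["venc"]
        with pytest.raises(KeyError, match="venc"):
            read_dataset(path)

    def test_no_silent_overwrite(self, tmp_path):
        f = _small_field()
        path = tmp_path / "ds.h5"
        write_dataset(path, f)
        with pytest.raises(FileExistsError):
            write_dataset(path, f)


class TestNiftiImport:
    def _write_series(self, tmp_path, nt=3, shape=(5, 4, 3), drop=None):
        import nibabel as nib

        rng = np.random.default_rng(1)
        paths = {}
        for comp in ("vx", "vy", "vz"):
            files = []
            for t in range(nt):
                p = tmp_path / f"{comp}_{t:02d}.nii"
                if drop != (comp, t):
                    img = nib.Nifti1Image(
                        rng.normal(size=shape), np.diag([3.0, 3.0, 3.0, 1.0])
                    )
                    nib.save(img, p)
                files.append(p)
            paths[comp] = files
        return paths

    def test_import_shapes_and_spacing(self, tmp_path):
        paths = self._write_series(tmp_path)
        f = import_nifti_series(paths, timeframe_duration=25.0, venc=100.0)
        assert f.nt == 3
        assert f.grid_shape == (3, 4, 5)  # (z, y, x) from (x, y, z) files
        assert f.spacing == (3.0, 3.0, 3.0)

    def test_missing_timeframe_reported_by_index(self, tmp_path):
        paths = self._write_series(tmp_path, drop=("vy", 1))
        with pytest.raises(FileNotFoundError, match=r"\[1\]"):
            import_nifti_series(paths, timeframe_duration=25.0, venc=100.0)


class TestResultsWriter:
    RECORDS = [
        {"subject": f"S{s}", "condition": "RespPlus", "metric": m,
         "value": 1.0 * s, "units": "ml"}
        for s in (1, 2)
        for m in ("sv", "pt_inflow", "ke_mean")
    ]

    def test_row_count(self, tmp_path):
        csv_path, _ = write_results(tmp_path, self.RECORDS)
        import pandas as pd

        assert len(pd.read_csv(csv_path)) == 6

    def test_empty_records_header_only(self, tmp_path):
        csv_path, _ = write_results(tmp_path, [])
        lines = csv_path.read_text().strip().splitlines()
        assert lines == ["subject,condition,metric,value,units"]

    def test_rerun_identical_apart_from_timestamp(self, tmp_path):
        import json

        c1, j1 = write_results(tmp_path / "a", self.RECORDS, config={"x": 1}, seed=3)
        c2, j2 = write_results(tmp_path / "b", self.RECORDS, config={"x": 1}, seed=3)
        assert c1.read_bytes() == c2.read_bytes()
        m1, m2 = json.loads(j1.read_text()), json.loads(j2.read_text())
        m1.pop("timestamp"), m2.pop("timestamp")
        assert m1 == m2
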