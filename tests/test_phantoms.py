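"""Synthetic phantom generation, Rician noise, DICOM ingestion, AIF extraction."""

import os

import numpy as np
import pytest

from conftest import small_phantom_spec
from dcemri import (
    STANDARD_TOFTS,
    InvalidParameterError,
    NoiseSpec,
    PhantomSpec,
    add_rician_noise,
    extract_aif,
    fit_voxels_parallel,
    generate_phantom,
    load_qiba_dicom,
    population_aif,
    qiba_v4_layout,
    qiba_v6_layout,
)


class TestLayout:
    def test_standard_region_count_and_shape(self):
        spec = qiba_v6_layout()
        assert spec.n_regions == 30
        ph = generate_phantom(spec)
        n_rows = ph.tissue_rows.stop
        assert (n_rows, ph.series.data.shape[2]) == (60, 50)
        assert ph.series.data.shape[1] == 60 + spec.strip_rows
        assert len(np.unique(ph.region_ids)) == 30

    def test_extended_region_counts(self):
        spec = qiba_v4_layout()
        assert spec.n_regions == 108
        kt = np.array([kt for kt in spec.ktrans_values])
        n_nonzero = np.count_nonzero(kt) * len(spec.ve_values) * len(spec.vp_values)
        assert n_nonzero == 90

    def test_patches_are_uniform(self):
        ph = generate_phantom(small_phantom_spec())
        pr, pc = ph.spec.patch_shape
        patch = ph.series.data[:, :pr, :pc]
        assert np.all(patch == patch[:, :1, :1])

    def test_zero_kinetics_gives_flat_baseline(self):
        spec = small_phantom_spec(ktrans_values=(0.0,), ve_values=(0.1,))
        ph = generate_phantom(spec)
        tissue = ph.series.data[:, ph.tissue_rows, :]
        assert np.all(tissue == tissue[0])

    def test_empty_value_lists_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhantomSpec(ktrans_values=(), ve_values=(0.1,))

    def test_truth_maps_match_layout(self):
        spec = small_phantom_spec()
        ph = generate_phantom(spec)
        pr, pc = spec.patch_shape
        assert ph.truth["ktrans"][0, 0] == spec.ktrans_values[0]
        assert ph.truth["ve"][0, pc] == spec.ve_values[1]
        assert ph.truth["ktrans"][pr, 0] == spec.ktrans_values[1]


class TestAif:
    def test_population_aif_shape(self):
        t = np.arange(0.0, 6.0, 0.01)
        cp = population_aif(t, bolus_arrival_min=0.5)
        assert np.all(cp[t <= 0.5] == 0.0)
        assert 3.0 < cp.max() < 8.0  # realistic first-pass peak, mM
        assert cp[-1] < cp.max() / 4  # washout

    def test_extract_aif_round_trip(self):
        ph = generate_phantom(small_phantom_spec())
        aif = extract_aif(ph.series, ph.maps, ph.spec.acq, ph.vessel_rows,
                          ph.spec.relaxivity)
        rel_err = np.max(np.abs(aif.cp - ph.aif.cp)) / ph.aif.cp.max()
        assert rel_err < 1e-6

    def test_constant_strip_gives_zero_cp(self):
        ph = generate_phantom(small_phantom_spec())
        data = ph.series.data.copy()
        data[:, ph.vessel_rows, :] = data[0, ph.vessel_rows, :]
        series = type(ph.series)(t=ph.series.t, data=data)
        aif = extract_aif(series, ph.maps, ph.spec.acq, ph.vessel_rows,
                          ph.spec.relaxivity)
        assert np.allclose(aif.cp, 0.0, atol=1e-12)

    def test_out_of_image_strip_rejected(self):
        ph = generate_phantom(small_phantom_spec())
        n_rows = ph.series.data.shape[1]
        with pytest.raises(ValueError):
            extract_aif(ph.series, ph.maps, ph.spec.acq,
                        slice(n_rows + 5, n_rows + 10), ph.spec.relaxivity)


class TestRicianNoise:
    def _flat_series(self):
        data = np.zeros((100, 42, 40))
        data[:, :2, :] = 100.0  # bright tissue rows define the baseline
        from dcemri import DynamicSeries

        return DynamicSeries(t=np.arange(100.0), data=data)

    def test_zero_sigma_is_identity(self):
        s = self._flat_series()
        out = add_rician_noise(s, NoiseSpec(sigma_rel=0.0, seed=1))
        assert np.array_equal(out.data, s.data)

    def test_seed_reproducibility(self):
        s = self._flat_series()
        a = add_rician_noise(s, NoiseSpec(sigma_rel=0.2, seed=7))
        b = add_rician_noise(s, NoiseSpec(sigma_rel=0.2, seed=7))
        c = add_rician_noise(s, NoiseSpec(sigma_rel=0.2, seed=8))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_signal_voxels_follow_rayleigh_mean(self):
        s = self._flat_series()
        baseline = s.data[:3].mean()
        sigma0 = 0.2 * baseline
        out = add_rician_noise(s, NoiseSpec(sigma_rel=0.2, seed=0))
        zero_samples = out.data[:, 2:, :]  # >1e5 draws from |N + iN|
        expected = sigma0 * np.sqrt(np.pi / 2.0)
        assert zero_samples.mean() == pytest.approx(expected, rel=0.01)

    def test_high_snr_sd_approaches_gaussian(self):
        s = self._flat_series()
        s.data[:, 2:, :] = 2000.0  # SNR >> 10 against the tissue baseline
        baseline = s.data[:3].mean()
        sigma0 = 0.05 * baseline
        out = add_rician_noise(s, NoiseSpec(sigma_rel=0.05, seed=0))
        sd = (out.data[:, 2:, :] - 2000.0).std()
        assert abs(sd - sigma0) / sigma0 < 0.05

    def test_vessel_strip_untouched_by_default(self):
        ph = generate_phantom(small_phantom_spec())
        out = add_rician_noise(ph.series, NoiseSpec(sigma_rel=0.2, seed=3),
                               vessel_rows=ph.vessel_rows)
        assert np.array_equal(out.data[:, ph.vessel_rows],
                              ph.series.data[:, ph.vessel_rows])
        assert not np.array_equal(out.data[:, ph.tissue_rows],
                                  ph.series.data[:, ph.tissue_rows])


class TestNoiseFreeSubsampling:
    def test_one_voxel_per_region_equals_all_voxels(self):
        spec = small_phantom_spec()
        ph = generate_phantom(spec)
        from dcemri import invert_spgr, r1_to_concentration

        rel = invert_spgr(ph.series, ph.maps, spec.acq)
        conc = r1_to_concentration(rel, ph.maps, ph.series.t, spec.relaxivity)
        ct = conc.ct[:, ph.tissue_rows, :]
        t_min = ph.series.t / 60.0
        cp = ph.aif.cp
        pr, pc = spec.patch_shape
        all_curves = ct.reshape(ct.shape[0], -1).T
        res_all = fit_voxels_parallel(all_curves, STANDARD_TOFTS, t_min, cp)
        corners = ct[:, ::pr, ::pc].reshape(ct.shape[0], -1).T
        res_sub = fit_voxels_parallel(corners, STANDARD_TOFTS, t_min, cp)
        region_ids = ph.region_ids.ravel()
        sub_ids = ph.region_ids[::pr, ::pc].ravel()
        for rid in np.unique(region_ids):
            full = [r.params for i, r in enumerate(res_all)
                    if region_ids[i] == rid]
            sub = res_sub[list(sub_ids).index(rid)].params
            for p in full:
                assert np.array_equal(p, sub)


class TestDicomLoader:
    @staticmethod
    def _write_frame(path, inst, value, trig=None, shape=(2, 2)):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.InstanceNumber = inst
        ds.Rows, ds.Columns = shape
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RepetitionTime = "5.0"
        ds.FlipAngle = "30.0"
        if trig is not None:
            ds.TriggerTime = str(trig)
        ds.PixelData = np.full(shape, value, dtype=np.uint16).tobytes()
        ds.save_as(path, enforce_file_format=True)

    def test_frames_reordered_by_instance_number(self, tmp_path):
        for i, (inst, val) in enumerate([(2, 20), (1, 10), (3, 30)]):
            self._write_frame(tmp_path / f"f{i}.dcm", inst, val,
                              trig=inst * 500.0)
        series, acq = load_qiba_dicom(tmp_path)
        assert list(series.data[:, 0, 0]) == [10.0, 20.0, 30.0]
        assert acq.tr == pytest.approx(5e-3)
        assert acq.flip_deg == pytest.approx(30.0)

    def test_single_frame(self, tmp_path):
        self._write_frame(tmp_path / "f0.dcm", 1, 7)
        series, _ = load_qiba_dicom(tmp_path)
        assert series.n_time == 1

    def test_duplicate_instance_number_rejected(self, tmp_path):
        self._write_frame(tmp_path / "a.dcm", 1, 1)
        self._write_frame(tmp_path / "b.dcm", 1, 2)
        with pytest.raises(ValueError, match="duplicate"):
            load_qiba_dicom(tmp_path)

    def test_gap_in_instance_numbers_rejected(self, tmp_path):
        self._write_frame(tmp_path / "a.dcm", 1, 1)
        self._write_frame(tmp_path / "b.dcm", 3, 2)
        with pytest.raises(ValueError, match="missing"):
            load_qiba_dicom(tmp_path)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_qiba_dicom(tmp_path)
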