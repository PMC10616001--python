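"""Isocontour lesion segmentation and burden metrics on exact phantoms."""

import numpy as np
import pytest
from scipy import ndimage

from covpet import burden
from covpet.image import Mask, Scan
from covpet.synthetic import LesionPhantomSpec, Solid, simulate_body_phantom


def box_phantom():
    """10x10x10-voxel box lesion at SUV 10 on background 0.5, 4 mm spacing."""
    spec = LesionPhantomSpec(
        grid_shape=(24, 24, 24), spacing_mm=(4, 4, 4), background_suv=0.5,
        lesions=[Solid((48, 48, 48), (20, 20, 20), 10.0, shape="box")],
    )
    return simulate_body_phantom(spec)


def three_lesion_phantom():
    spec = LesionPhantomSpec(
        grid_shape=(40, 40, 40), spacing_mm=(4, 4, 4), background_suv=0.5,
        lesions=[
            Solid((40, 40, 40), (14, 12, 10), 12.0),
            Solid((120, 120, 120), (10, 10, 10), 8.0),
            Solid((40, 120, 80), (8, 8, 12), 6.0),
        ],
    )
    return simulate_body_phantom(spec)


class TestDetectPeaks:
    def test_uniform_volume_no_peaks(self):
        scan = Scan(values=np.full((16, 16, 16), 0.5), spacing_mm=(4, 4, 4), id="u")
        assert burden.detect_peaks(scan) == []

    def test_two_lesions_two_peaks_at_centers(self):
        spec = LesionPhantomSpec(
            grid_shape=(32, 32, 32), spacing_mm=(4, 4, 4),
            lesions=[Solid((30, 30, 30), (10, 10, 10), 10.0),
                     Solid((94, 94, 94), (10, 10, 10), 10.0)],
        )
        scan, truth = simulate_body_phantom(spec)
        peaks = burden.detect_peaks(scan)
        assert len(peaks) == 2
        for peak in peaks:
            assert truth[peak] > 0
        # plateau representative is the voxel nearest the lesion centroid
        centers = {tuple(np.argwhere(truth == k).mean(axis=0).round().astype(int))
                   for k in (1, 2)}
        assert set(peaks) == centers

    def test_peak_inside_exclusion_not_reported(self):
        scan, truth = box_phantom()
        assert burden.detect_peaks(scan, exclusion_mask=truth == 1) == []

    def test_min_suv_gates(self):
        scan, _ = box_phantom()
        assert burden.detect_peaks(scan, min_suv=11.0) == []


class TestSegmentLesion:
    def test_isocontour_threshold_arithmetic(self):
        # a peak of SUV 20 at 41% includes voxels at 8.2 and above
        values = np.full((9, 9, 9), 0.5)
        values[4, 4, 4] = 20.0
        values[4, 4, 5] = 8.2
        values[4, 4, 3] = 8.1
        scan = Scan(values=values, spacing_mm=(4, 4, 4), id="t")
        region = burden.segment_lesion(scan, (4, 4, 4), fraction=0.41)
        assert region[4, 4, 5] and not region[4, 4, 3]

    def test_box_lesion_exact_1000_voxels(self):
        scan, truth = box_phantom()
        peaks = burden.detect_peaks(scan)
        region = burden.segment_lesion(scan, peaks[0])
        assert region.sum() == 1000
        np.testing.assert_array_equal(region, truth == 1)

    def test_isolated_hot_voxel(self):
        values = np.full((9, 9, 9), 0.5)
        values[2, 3, 4] = 10.0
        scan = Scan(values=values, spacing_mm=(4, 4, 4), id="h")
        region = burden.segment_lesion(scan, (2, 3, 4))
        assert region.sum() == 1 and region[2, 3, 4]


class TestSegmentAll:
    def test_three_disjoint_lesions_match_truth_exactly(self):
        scan, truth = three_lesion_phantom()
        seg = burden.segment_all(scan)
        assert seg.n_lesions == 3
        # labels are ordered by peak SUV desc = spec order here
        for k in (1, 2, 3):
            np.testing.assert_array_equal(seg.labels == k, truth == k)
        for rec in seg.lesions:
            region = seg.labels == rec.label
            assert region[rec.peak_index]
            assert np.all(scan.values[region] >= 0.41 * rec.peak_suv)

    def test_touching_isocontours_merge(self):
        values = np.full((20, 9, 9), 0.5)
        values[5, 4, 4] = 10.0
        values[6:9, 4, 4] = 5.0  # bridge above both 41% thresholds
        values[9, 4, 4] = 9.0
        scan = Scan(values=values, spacing_mm=(4, 4, 4), id="m")
        seg = burden.segment_all(scan)
        assert seg.n_lesions == 1
        assert seg.lesions[0].peak_suv == 10.0

    def test_all_lesions_excluded_gives_empty(self):
        scan, truth = three_lesion_phantom()
        seg = burden.segment_all(scan, exclusion_mask=truth > 0)
        assert seg.n_lesions == 0
        assert np.all(seg.labels == 0)

    def test_explicit_seeds_mimic_semiautomatic(self):
        scan, truth = box_phantom()
        peak = tuple(np.argwhere(truth == 1)[0])
        seg = burden.segment_all(scan, seeds=[peak])
        assert seg.n_lesions == 1
        assert seg.lesions[0].n_voxels == 1000


class TestBurdenMetrics:
    def test_box_phantom_exact_tmtv_tlg(self):
        scan, _ = box_phantom()
        seg = burden.segment_all(scan)
        metrics = burden.burden_metrics(seg, scan)
        assert metrics.tmtv_ml == pytest.approx(64.0, abs=0)  # 1000 * 0.064 mL
        assert metrics.suv_mean == pytest.approx(10.0)
        assert metrics.tlg == pytest.approx(640.0)
        assert metrics.lg_tmtv == pytest.approx(np.log10(64.0), abs=1e-12)

    def test_tlg_identity(self):
        scan, _ = three_lesion_phantom()
        metrics = burden.burden_metrics(burden.segment_all(scan), scan)
        assert metrics.tlg == pytest.approx(metrics.tmtv_ml * metrics.suv_mean,
                                            rel=1e-9)
        assert metrics.suv_max >= metrics.suv_mean >= 0

    def test_empty_segmentation_missing_logs(self):
        scan = Scan(values=np.full((8, 8, 8), 0.5), spacing_mm=(4, 4, 4), id="e")
        metrics = burden.burden_metrics(burden.segment_all(scan), scan)
        assert metrics.tmtv_ml == 0 and metrics.tlg == 0
        assert metrics.lg_tmtv is None and metrics.lg_tlg is None

    def test_tmtv_monotone_in_fraction(self):
        scan, _ = three_lesion_phantom()
        # add a radial falloff so the isocontour actually varies with fraction
        smoothed = Scan(values=ndimage.gaussian_filter(scan.values, 1.5),
                        spacing_mm=scan.spacing_mm, id="s")
        tmtvs = []
        for fraction in (0.2, 0.41, 0.6, 0.8):
            seg = burden.segment_all(smoothed, fraction=fraction)
            tmtvs.append(burden.burden_metrics(seg, smoothed).tmtv_ml)
        assert all(a >= b for a, b in zip(tmtvs, tmtvs[1:]))


class TestBrainGlycolysis:
    def test_uniform_suv_identity(self):
        # 1300 voxels of 1 mL each -> a 1300 mL "brain"
        mask = Mask(np.ones((10, 10, 13), bool), (10, 10, 10))
        scan = Scan(values=np.ones((10, 10, 13)), spacing_mm=(10, 10, 10),
                    id="b", units="SUV")
        out = burden.brain_glycolysis(scan, mask)
        assert out.volume_ml == pytest.approx(1300.0)
        assert out.tbg == pytest.approx(1300.0)

    def test_linearity_in_suv(self, template):
        values = np.where(template.brain_mask, np.exp(template.mu), 0.0)
        scan = Scan(values=values, spacing_mm=template.spacing_mm, id="b", units="SUV")
        double = Scan(values=2 * values, spacing_mm=template.spacing_mm, id="b2",
                      units="SUV")
        mask = template.mask
        assert burden.brain_glycolysis(double, mask).tbg == pytest.approx(
            2 * burden.brain_glycolysis(scan, mask).tbg, rel=1e-12)

    def test_product_identity_against_closed_form(self):
        # uniform SUV ellipsoid: TBG = volume * SUV exactly, and the
        # voxelized volume approaches the analytic ellipsoid volume
        spec = LesionPhantomSpec(
            grid_shape=(40, 40, 40), spacing_mm=(2, 2, 2), background_suv=0.0,
        )
        scan, _ = simulate_body_phantom(spec)
        values = scan.values.copy()
        xs, ys, zs = np.meshgrid(*[(np.arange(40) + 0.5) * 2] * 3, indexing="ij")
        member = (((xs - 40) / 30) ** 2 + ((ys - 40) / 25) ** 2
                  + ((zs - 40) / 20) ** 2) <= 1
        values[member] = 3.0
        scan = Scan(values=values, spacing_mm=(2, 2, 2), id="el", units="SUV")
        mask = Mask(member, (2, 2, 2))
        out = burden.brain_glycolysis(scan, mask)
        analytic_ml = 4 / 3 * np.pi * 30 * 25 * 20 / 1000
        assert out.tbg == pytest.approx(out.volume_ml * 3.0, rel=1e-12)
        assert out.volume_ml == pytest.approx(analytic_ml, rel=0.05)
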