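import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import habitatmap as hm
from habitatmap.core import GeometryError, HabitatError


def rot_z(deg):
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def landmarks_from(ct, us, names=None):
    names = names or tuple(f"p{i}" for i in range(len(ct)))
    return hm.LandmarkSet(names=names, ct=np.asarray(ct, float),
                          us=np.asarray(us, float))


class TestFitRigid:
    def test_identical_points_give_identity(self):
        pts = [[0, 0, 0], [10, 0, 5], [0, 10, -5]]
        T = hm.fit_rigid(landmarks_from(pts, pts))
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_three_points_recover_known_transform(self):
        ct = np.array([[0, 0, 0], [50, 0, 0], [0, 40, 20.0]])
        R = rot_z(30)
        t = np.array([10.0, -5.0, 2.0])
        us = ct @ R.T + t
        T = hm.fit_rigid(landmarks_from(ct, us))
        np.testing.assert_allclose(T.apply(ct), us, atol=1e-9)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)

    def test_single_pair_is_pure_translation(self):
        T = hm.fit_rigid(landmarks_from([[0, 0, 0]], [[5, 5, 0]]))
        np.testing.assert_allclose(T.rotation, np.eye(3))
        np.testing.assert_allclose(T.translation, [5, 5, 0])

    def test_two_pairs_recover_z_rotation(self):
        ct = np.array([[0, 0, 0], [30, 0, 10.0]])
        R = rot_z(-25)
        us = ct @ R.T + np.array([3.0, 4.0, -6.0])
        T = hm.fit_rigid(landmarks_from(ct, us))
        np.testing.assert_allclose(T.apply(ct), us, atol=1e-9)

    def test_collinear_triplet_falls_back_with_warning(self):
        ct = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0.0]])
        us = ct + np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="collinear"):
            T = hm.fit_rigid(landmarks_from(ct, us))
        np.testing.assert_allclose(T.apply(ct), us, atol=1e-9)

    def test_matches_independent_kabsch_oracle(self, rng):
        for _ in range(20):
            ct = rng.uniform(-100, 100, size=(3, 3))
            if np.linalg.norm(np.cross(ct[1] - ct[0], ct[2] - ct[0])) < 1.0:
                continue
            R_true = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            us = ct @ R_true.T + rng.uniform(-20, 20, 3) + 0.5 * rng.standard_normal((3, 3))
            T = hm.fit_rigid(landmarks_from(ct, us))
            # independent implementation: scipy orthogonal Procrustes
            cct, cus = ct.mean(axis=0), us.mean(axis=0)
            R_ref, _ = Rotation.align_vectors(us - cus, ct - cct)
            np.testing.assert_allclose(T.rotation, R_ref.as_matrix(), atol=1e-6)

    def test_landmark_validation(self):
        with pytest.raises(HabitatError):
            landmarks_from(np.zeros((4, 3)), np.zeros((4, 3)))
        with pytest.raises(HabitatError, match="duplicate"):
            hm.LandmarkSet(names=("a", "a"), ct=np.zeros((2, 3)),
                           us=np.zeros((2, 3)))


class TestFRE:
    def test_exact_correspondence_is_zero(self):
        pts = [[0, 0, 0], [10, 0, 0], [0, 10, 0]]
        lm = landmarks_from(pts, pts)
        assert hm.fre(lm, hm.RigidTransform.identity()) == 0.0

    def test_single_offset_rms_identity(self):
        ct = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]])
        us = ct.copy()
        us[0, 0] += 3.0  # one landmark off by 3 mm under the identity
        lm = landmarks_from(ct, us)
        assert hm.fre(lm, hm.RigidTransform.identity()) == pytest.approx(
            np.sqrt(9.0 / 3.0)
        )

    def test_invariant_under_joint_rigid_motion(self, rng):
        ct = rng.uniform(-50, 50, (3, 3))
        us = ct + rng.standard_normal((3, 3))
        lm = landmarks_from(ct, us)
        base = hm.fre(lm, hm.RigidTransform.identity())
        M = hm.RigidTransform(rot_z(40), np.array([7.0, -2.0, 1.0]))
        moved = landmarks_from(M.apply(ct), M.apply(us))
        # identity residuals transform rigidly too
        assert hm.fre(moved, hm.RigidTransform.identity()) == pytest.approx(base)


class TestResliceAndDice:
    def test_identity_frame_on_axial_slice_reproduces_voi_slice(
        self, small_phantom
    ):
        ph = small_phantom
        iz = hm.select_largest_slice(ph.mask)
        vol = ph.volume
        frame = hm.USFrame(
            pixels=np.zeros(vol.shape[1:]),
            spacing=vol.spacing[:2],
            origin=vol.index_to_patient(np.array([0.0, 0.0, float(iz)])),
            dir_col=vol.orientation[:, 0],
            dir_row=vol.orientation[:, 1],
        )
        out = hm.reslice_mask(ph.mask, vol, frame, hm.RigidTransform.identity())
        assert np.array_equal(out, ph.mask.voxels[iz])
        assert hm.dice(out, ph.mask.voxels[iz]) == 1.0

    def test_frame_outside_volume_rejected(self, small_phantom):
        vol = small_phantom.volume
        frame = hm.USFrame(
            pixels=np.zeros((8, 8)), spacing=(1.0, 1.0),
            origin=np.array([5000.0, 5000.0, 5000.0]),
            dir_col=np.array([1.0, 0, 0]), dir_row=np.array([0, 1.0, 0]),
        )
        with pytest.raises(GeometryError, match="no overlap"):
            hm.reslice_mask(small_phantom.mask, vol, frame,
                            hm.RigidTransform.identity())

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (np.ones((4, 4)), np.ones((4, 4)), 1.0),
            (np.eye(4), 1 - np.eye(4), 0.0),
        ],
    )
    def test_dice_known_values(self, a, b, expected):
        assert hm.dice(a, b) == expected

    def test_dice_half_overlap(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:10] = True
        b[5:15] = True
        assert hm.dice(a, b) == 0.5
        assert hm.dice(b, a) == 0.5

    def test_dice_undefined_for_two_empty_masks(self):
        assert hm.dice(np.zeros((3, 3)), np.zeros((3, 3))) is None

    def test_dice_shape_mismatch(self):
        with pytest.raises(GeometryError):
            hm.dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSelectLargestSlice:
    def test_sphere_equatorial_slice(self):
        z, y, x = np.mgrid[:11, :11, :11]
        sphere = (z - 5) ** 2 + (y - 5) ** 2 + (x - 5) ** 2 <= 16
        assert hm.select_largest_slice(sphere) == 5

    def test_tie_broken_toward_first_slice(self):
        # per-slice areas (3, 10, 10, 2): the first maximal slice wins
        m = np.zeros((4, 5, 5), bool)
        m[0].flat[:3] = True
        m[1].flat[:10] = True
        m[2].flat[:10] = True
        m[3].flat[:2] = True
        assert hm.select_largest_slice(m) == 1

    def test_matches_brute_force_argmax(self, rng):
        m = rng.random((6, 9, 9)) > 0.6
        m[0, 0, 0] = True  # ensure non-empty
        best, best_count = 0, -1
        for iz in range(m.shape[0]):
            c = int(m[iz].sum())
            if c > best_count:
                best, best_count = iz, c
        assert hm.select_largest_slice(m) == best


class TestSummarize:
    def test_reported_per_patient_dsc_summary(self):
        # the five per-lesion overlap values from the clinical evaluation
        dsc = [0.76, 0.79, 0.37, 0.43, 0.53]
        median, lo, hi = hm.summarize(dsc)
        assert median == pytest.approx(0.53)
        assert (lo, hi) == (0.37, 0.79)

    def test_days_between_scan_and_biopsy_summary(self):
        days = [30, 10, 29, 16, 7, 26]
        median, lo, hi = hm.summarize(days)
        assert median == pytest.approx(21.0)
        assert (lo, hi) == (7, 30)

    def test_site_wise_volume_summaries(self):
        omental = [15.7, 295.2, 19.4, 187.4]
        pelvic = [591.7, 448.3]
        assert hm.summarize(omental)[0] == pytest.approx(103.4)
        assert hm.summarize(pelvic)[0] == pytest.approx(520.0)

    def test_undefined_entries_excluded(self):
        median, lo, hi = hm.summarize([None, 0.5, np.nan, 0.7])
        assert median == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(HabitatError):
            hm.summarize([None])


class TestDSCReport:
    def test_summary_and_serialisation(self):
        rep = hm.DSCReport(per_lesion=(
            ("p1", "omentum", None),
            ("p2", "pelvis", 0.76),
            ("p5", "pelvis", 0.79),
        ))
        d = rep.to_dict()
        assert d["median_dsc"] == pytest.approx(0.775)
        assert d["per_lesion"][0]["dsc"] is None

    def test_out_of_range_dsc_rejected(self):
        with pytest.raises(HabitatError):
            hm.DSCReport(per_lesion=(("x", "pelvis", 1.2),))
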