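"""Phantom generators: geometry, determinism, encode round trips."""

import numpy as np
import pytest

from texphan import phantom_forge as pf
from texphan import qrcodec


class TestHilbertCurve:
    @pytest.mark.parametrize("level,ncells", [(1, 8), (2, 64)])
    def test_single_self_avoiding_chain_of_unit_steps(self, level, ncells):
        path = pf.hilbert_curve_3d(level)
        assert len(path) == ncells
        assert len(np.unique(path, axis=0)) == ncells  # self-avoiding
        steps = np.abs(np.diff(path, axis=0)).sum(axis=1)
        assert np.all(steps == 1)  # face-adjacent chain
        assert path.min() >= 0 and path.max() < 2 ** level

    def test_pipe_is_one_connected_component(self):
        from scipy.ndimage import label

        ph = pf.make_hilbert_phantom(pitch_mm=0.5)
        w = int(round(pf.WALL_MM / ph.pitch_mm))
        interior = ph.labels[w:-w, w:-w, w:-w] == pf.LABEL_PLASTIC
        _, ncomp = label(interior, structure=np.ones((3, 3, 3)))
        assert ncomp == 1

    def test_pipe_width_exceeding_cell_raises(self):
        with pytest.raises(pf.PhantomGeometryError):
            pf.make_hilbert_phantom(pipe_width_mm=15.0, pitch_mm=0.5)

    def test_face_pattern_carves_air(self):
        ph = pf.make_hilbert_phantom(pitch_mm=0.5)
        assert pf.LABEL_AIR in set(np.unique(ph.labels[0]))


class TestQRPhantom:
    def test_large_phantom_dims_and_metadata(self):
        ph = pf.large_qr_phantom(pitch_mm=0.5)
        assert ph.dims_mm == (50.0, 40.0, 50.0)  # (x, y=extrusion, z)
        assert ph.meta["modules"] == 29
        assert ph.payload == "UNIDEB MRI Texture Analysis Phantom"
        assert ph.label_set() <= {pf.LABEL_PLASTIC, pf.LABEL_SOLUTION}

    def test_small_phantom_dims(self):
        ph = pf.small_qr_phantom(pitch_mm=0.5)
        assert ph.dims_mm == (40.0, 30.0, 40.0)

    def test_module_matrix_roundtrip_bit_for_bit(self):
        """Collapsing the code region along the extrusion axis and
        thresholding reproduces the encoded module matrix exactly."""
        ph = pf.large_qr_phantom()  # full 0.25 mm pitch
        mods = qrcodec.encode_text(ph.payload)
        n = mods.shape[0]
        mm = ph.meta["module_mm"]
        w = int(round(pf.WALL_MM / ph.pitch_mm))
        code = ph.labels[:, w:w + int(round(30.0 / ph.pitch_mm)), :]
        plastic_frac = (code == pf.LABEL_PLASTIC).mean(axis=1)  # (x, z)
        x0 = (ph.labels.shape[0] * ph.pitch_mm - n * mm) / 2.0
        recovered = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                x = int((x0 + (j + 0.5) * mm) / ph.pitch_mm)
                z = int((ph.labels.shape[2] * ph.pitch_mm
                         - (x0 + (i + 0.5) * mm)) / ph.pitch_mm)
                recovered[i, j] = plastic_frac[x, z] > 0.5
        assert np.array_equal(recovered, mods)

    def test_code_height_restricted_to_declared_extent(self):
        ph = pf.large_qr_phantom(pitch_mm=0.5)
        w = int(round(pf.WALL_MM / ph.pitch_mm))
        y_end = w + int(round(30.0 / ph.pitch_mm))
        above = ph.labels[w:-w, y_end:-w, w:-w]
        assert np.all(above == pf.LABEL_SOLUTION)

    def test_empty_payload_rejected(self):
        with pytest.raises(ValueError):
            pf.make_qr_phantom("", (50, 50, 40), 30)

    def test_coarse_pitch_rejected(self):
        with pytest.raises(pf.PhantomResolutionError):
            pf.make_qr_phantom("abc", (50, 50, 40), 30, pitch_mm=1.0)

    def test_overlong_payload_raises_capacity_error(self):
        with pytest.raises(qrcodec.QRCapacityError):
            pf.make_qr_phantom("x" * 500, (50, 50, 40), 30, pitch_mm=0.5)


class TestBioPhantoms:
    def test_deterministic_under_seed(self):
        a = pf.make_bio_phantom("kiwi", (45, 45, 40), 1)
        b = pf.make_bio_phantom("kiwi", (45, 45, 40), 1)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.modulation, b.modulation)

    @pytest.mark.parametrize("kind", ["kiwi", "tomato", "onion"])
    def test_at_least_three_tissue_classes(self, kind):
        ph = pf.make_bio_phantom(kind, (40, 40, 40), 7)
        tissue = {l for l in ph.label_set() if l >= 3}
        assert len(tissue) >= 3

    def test_onion_shells_alternate(self):
        ph = pf.make_bio_phantom("onion", (40, 40, 40), 7)
        # radial profile through the center must alternate between the two
        # shell classes several times
        c = tuple(s // 2 for s in ph.labels.shape)
        ray = ph.labels[c[0]:, c[1], c[2]]
        ray = ray[ray >= 3]
        changes = (np.diff(ray) != 0).sum()
        assert changes >= 4

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            pf.make_bio_phantom("mango", (40, 40, 40), 0)

    def test_oversized_rejected(self):
        with pytest.raises(pf.PhantomGeometryError):
            pf.make_bio_phantom("kiwi", (60, 40, 40), 0)

    def test_kinds_texturally_distinguishable(self):
        """GLCM contrast separates kiwi from onion beyond within-kind spread."""
        from texphan import texturex
        from texphan.voiprep import DiscreteVOI, DiscretizationSpec

        def contrast(kind, seed):
            ph = pf.make_bio_phantom(kind, (30, 30, 30), seed, pitch_mm=1.0)
            lv = ph.labels.astype(np.int64).copy()
            lv[lv > 0] -= 2  # tissue classes -> levels 1..
            d = DiscreteVOI(levels=lv, mask=lv > 0, n_levels=int(lv.max()),
                            spec=DiscretizationSpec("FBS"))
            return texturex.glcm_features(texturex.compute_glcm(d))["Contrast"]

        kiwi = [contrast("kiwi", s) for s in (1, 2, 3)]
        onion = [contrast("onion", s) for s in (1, 2, 3)]
        spread = max(np.ptp(kiwi), np.ptp(onion))
        assert abs(np.mean(kiwi) - np.mean(onion)) > spread


class TestRotation:
    def test_four_quarter_turns_are_identity(self):
        ph = pf.make_bio_phantom("tomato", (30, 30, 24), 3, pitch_mm=1.0)
        out = ph
        for _ in range(4):
            out = pf.rotate_phantom(out, "z", 90)
        assert np.array_equal(out.labels, ph.labels)

    def test_orientation_variability_exceeds_repetition_noise(self):
        """Rotating a kiwi between scans perturbs direction-sensitive
        features more than repetition noise alone does."""
        from texphan import repstats as rs, texturex as tx, virtual_mr as vm, voiprep

        kiwi = pf.make_bio_phantom("kiwi", (40, 40, 36), 5, pitch_mm=1.0)
        orients = [kiwi, pf.rotate_phantom(kiwi, "x", 90),
                   pf.rotate_phantom(kiwi, "y", 90)]
        setup = vm.parse_setup_label("1.5T_T1_6ch_2mm_FBS")

        def feats(phantom, seed):
            truth = vm.assign_contrast(phantom, None, "T1")
            vol = vm.acquire(truth, 1.0, setup, seed, pad_mm=4.0)
            mask = voiprep.centered_cubic_voi(vol, 20.0)
            return tx.extract_all(vol, mask, "FBS", normalize=True)

        f_orient = [feats(ph, 1234) for ph in orients]
        f_rep = [feats(kiwi, s) for s in (1234, 77, 991)]
        for name in ("Contrast", "Correlation"):
            cv_orient = rs.cv([f[name] for f in f_orient])
            cv_rep = rs.cv([f[name] for f in f_rep])
            assert abs(cv_orient) > abs(cv_rep)

    def test_quarter_turn_is_index_permutation(self):
        ph = pf.make_bio_phantom("onion", (30, 30, 24), 3, pitch_mm=1.0)
        rot = pf.rotate_phantom(ph, "z", 90)
        assert np.array_equal(rot.labels, np.rot90(ph.labels, axes=(0, 1)))
        assert rot.dims_mm == (ph.dims_mm[1], ph.dims_mm[0], ph.dims_mm[2])


class TestIO:
    def test_nifti_sidecar_roundtrip(self, tmp_path):
        ph = pf.make_bio_phantom("onion", (24, 24, 24), 5, pitch_mm=1.0)
        path = tmp_path / "onion.nii.gz"
        pf.save_phantom(ph, path)
        back = pf.load_phantom(path)
        assert np.array_equal(back.labels, ph.labels)
        assert back.pitch_mm == ph.pitch_mm
        assert np.allclose(back.modulation, ph.modulation, atol=1e-6)
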