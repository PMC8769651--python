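import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from lamellakit.exceptions import ParamError, TruncatedStackWarning, ZeroConfidence
from lamellakit.frames import PixelGrid
from lamellakit.milling_protocols import (
    LamellaTarget,
    MillingStep,
    PatternCommand,
    PatternSequence,
    PatternShape,
    Protocol,
)
from lamellakit.simulator import (
    Correction,
    InstrumentState,
    SessionPosition,
    SimulatedDriver,
    VirtualSpecimen,
    apply_correction,
    measure_lamella,
    realign,
    realign_on_current_change,
    run_lamella_session,
    run_volume_session,
    synth_bead_image,
    synth_charge,
    synth_curtain,
    synth_drift_stack,
    synth_flm_volume,
)

from conftest import make_driver, textured_specimen

GRID50 = PixelGrid(50.0, 50.0)

ROUGH = Protocol("rough", (
    MillingStep(1000, 150, pattern_distance=3.0, pattern_height=3.0),
    MillingStep(500, 200, pattern_distance=2.0, pattern_height=1.0),
    MillingStep(300, 300, pattern_distance=1.0, pattern_height=1.0)), "rough")
FINE = Protocol("fine", (
    MillingStep(100, 500, pattern_distance=0.5, pattern_height=0.5),
    MillingStep(50, 800, pattern_distance=0.3, pattern_height=0.35)), "fine")
TARGET = LamellaTarget(position=(0.0, 0.0), width=8.0, extremes=(-4.0, 4.0))


class TestImaging:
    def test_unchanged_state_reproduces_raster(self):
        drv = make_driver()
        a = drv.acquire_image("SEM")
        b = drv.acquire_image("SEM")
        assert np.array_equal(a, b)

    def test_beam_shift_translates_image(self):
        drv = make_driver()
        a = drv.acquire_image("SEM")
        drv.apply_beam_shift((1.0, 0.0))
        b = drv.acquire_image("SEM")
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=10,
                                              normalization=None)
        assert np.allclose(shift, (0.0, 20.0), atol=0.3)  # 1 um / 50 nm px

    def test_fib_view_compresses_height_by_sin_angle(self):
        drv = make_driver(noise_scale=0.0)
        sem = drv.acquire_image("SEM")
        fib = drv.acquire_image("FIB")
        ratio = (np.nonzero(fib.sum(axis=1))[0].max()
                 / np.nonzero(sem.sum(axis=1))[0].max())
        assert ratio == pytest.approx(np.sin(np.deg2rad(52)), abs=0.01)


class TestMilling:
    def _flat(self, shape=(20, 100, 100)):
        return VirtualSpecimen.uniform_block(shape, 50.0)

    def test_through_hole_footprint(self):
        spec = self._flat()
        drv = SimulatedDriver(spec, InstrumentState(seed=0), noise_scale=0.0)
        # 2x1 um rectangle, budget far beyond the column volume
        cmd = PatternCommand(PatternShape.RECTANGLE, (2.5, 2.5), 2.0, 1.0,
                             10000.0, 1000.0)
        drv.mill(PatternSequence("", (cmd,)))
        hole = spec.labels[:, 40:60, 30:70]
        assert hole.sum() == 0
        assert spec.labels[:, :39, :].all() and spec.labels[:, 61:, :].all()

    def test_zero_time_is_noop(self):
        spec = self._flat()
        before = spec.material_voxels()
        drv = SimulatedDriver(spec, InstrumentState(seed=0))
        cmd = PatternCommand(PatternShape.RECTANGLE, (2.5, 2.5), 2.0, 1.0,
                             0.0, 1000.0)
        drv.mill(PatternSequence("", (cmd,)))
        assert spec.material_voxels() == before

    def test_mass_balance_and_additivity(self):
        def removed(commands):
            spec = self._flat()
            drv = SimulatedDriver(spec, InstrumentState(seed=0))
            before = spec.material_voxels()
            drv.mill(PatternSequence("", commands))
            return before - spec.material_voxels()

        # budgets below the 1 um^3 column volume so milling stops mid-column
        c1 = PatternCommand(PatternShape.RECTANGLE, (1.0, 1.0), 1.0, 1.0,
                            0.8, 1000.0)
        c2 = PatternCommand(PatternShape.RECTANGLE, (4.0, 4.0), 1.0, 1.0,
                            0.6, 1000.0)
        assert removed((c1, c2)) == removed((c1,)) + removed((c2,))
        # budget bookkeeping: 1 nA * 0.8 s * 0.5 um^3/(nA s) = 0.4 um^3
        assert removed((c1,)) == pytest.approx(0.4 / (0.05 ** 3), rel=0.01)

    def test_outside_pattern_warns_noop(self):
        spec = self._flat()
        drv = SimulatedDriver(spec, InstrumentState(seed=0))
        cmd = PatternCommand(PatternShape.RECTANGLE, (50.0, 50.0), 1.0, 1.0,
                             10.0, 1000.0)
        with pytest.warns(UserWarning, match="outside"):
            drv.mill(PatternSequence("", (cmd,)))
        assert spec.material_voxels() == 20 * 100 * 100


class TestRealign:
    def test_small_offset_uses_beam_shift(self):
        drv = make_driver()
        ref = drv.acquire_image("FIB")
        drv.state.drift_nm_per_min = np.array([50.0, 0.0])
        drv.state.clock_min = 10.0  # 0.5 um planted offset
        live = drv.acquire_image("FIB")
        corr = realign(ref, live, GRID50)
        assert corr.mode == "beam_shift"
        assert abs(corr.offset_um[0] - 0.5) <= 0.05
        apply_correction(drv, corr)
        residual = realign(ref, drv.acquire_image("FIB"), GRID50)
        assert residual.magnitude_um < 0.1

    def test_large_offset_uses_stage(self):
        drv = make_driver()
        ref = drv.acquire_image("FIB")
        drv.stage_error_um = np.array([0.0, 12.0])  # planted 12 um
        live = drv.acquire_image("FIB")
        corr = realign(ref, live, GRID50)
        assert corr.mode == "stage"
        assert abs(corr.offset_um[1] - 12.0) < 0.5

    def test_identical_images_zero_offset(self):
        drv = make_driver()
        img = drv.acquire_image("SEM")
        corr = realign(img, img, GRID50)
        assert corr.magnitude_um == 0.0

    def test_zero_signal_raises(self):
        with pytest.raises(ZeroConfidence):
            realign(np.zeros((32, 32)), np.zeros((32, 32)), GRID50)

    def test_current_change_correction_is_beam_shift_only(self):
        offsets = {100.0: (0.3, 0.0), 10.0: (0.0, 0.0)}
        drv = make_driver(current_offsets=offsets)
        corr = realign_on_current_change(drv, 10.0, 100.0, GRID50)
        assert corr.mode == "beam_shift"
        assert abs(corr.offset_um[0] - 0.3) <= 0.05
        apply_correction(drv, corr)
        assert abs(drv.misalignment_um()[0]) <= 0.05


class TestLamellaSession:
    def test_final_thickness_and_ordering(self):
        drv = make_driver(drift=(0.0, 0.0),
                          current_offsets={10.0: (0.05, -0.1),
                                           1000.0: (0.2, 0.1),
                                           500.0: (-0.15, 0.2),
                                           300.0: (0.1, -0.2),
                                           100.0: (0.0, 0.15),
                                           50.0: (-0.1, 0.0)})
        pos = [SessionPosition("p1", (10.0, 10.0), TARGET)]
        stats, outcomes, spec = run_lamella_session(pos, ROUGH, FINE, drv)
        o = outcomes["p1"]
        assert o.fine_done and not o.failed
        # fine protocol targets 300 nm; one voxel is 50 nm
        assert abs(o.thickness_nm - 300.0) <= 50.0

    def test_rough_all_then_fine_all_ordering(self):
        spec = textured_specimen(shape=(30, 500, 500))
        drv = make_driver(spec, noise_scale=0.0)
        positions = [SessionPosition(f"p{i}", (6.0 + 6.0 * i, 12.0), TARGET)
                     for i in range(3)]
        run_lamella_session(positions, ROUGH, FINE, drv, realign_enabled=False)
        recalls = [tuple(e["position_um"]) for e in drv.log
                   if e["op"] == "move_stage"]
        expected = [p.location_um for p in positions]
        # setup pass, rough pass, fine pass -- each visits p1, p2, p3 in order
        assert recalls == expected * 3

    def test_drift_closed_loop(self):
        # 60 nm/min drift: realignment keeps placement error < 2 px
        drv = make_driver(drift=(0.0, 60.0))
        pos = [SessionPosition("p1", (10.0, 10.0), TARGET)]
        _, outcomes, _ = run_lamella_session(pos, ROUGH, FINE, drv)
        o = outcomes["p1"]
        assert abs(o.placement_error_nm) < 2 * 50.0
        assert abs(o.thickness_nm - 300.0) <= 50.0


class TestVolumeSession:
    def test_buried_sphere_cross_sections(self):
        labs = np.ones((100, 64, 64), np.uint8)
        zz, yy, xx = np.mgrid[:100, :64, :64]
        labs[((zz - 50) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2) < 15 ** 2] = 2
        spec = VirtualSpecimen(labs, 50.0, {1: 0.5, 2: 0.5},
                               {1: 50.0, 2: 250.0})
        drv = SimulatedDriver(spec, InstrumentState(seed=1), noise_scale=0.0)
        stack = run_volume_session((3.2, 3.2), 100.0, 40, drv)
        areas = np.array([(s > 100).sum() for s in stack.slices])
        equator = int(np.argmax(areas))
        assert abs(equator - 50 * 50 / 100) <= 2
        first, last = np.nonzero(areas)[0][[0, -1]]
        assert np.all(np.diff(areas[first:equator + 1]) >= 0)
        assert np.all(np.diff(areas[equator:last + 1]) <= 0)

    def test_front_bookkeeping(self):
        drv = make_driver(textured_specimen(shape=(40, 64, 64)), noise_scale=0.0)
        stack = run_volume_session((3.2, 3.2), 100.0, 10, drv)
        assert len(stack) == 10
        assert drv.front_nm == pytest.approx(1000.0)
        assert stack.grid.slice_thickness == 100.0

    def test_zero_slices(self):
        drv = make_driver(textured_specimen(shape=(20, 32, 32)))
        stack = run_volume_session((1.6, 1.6), 100.0, 0, drv)
        assert len(stack) == 0

    def test_truncation_warns(self):
        drv = make_driver(textured_specimen(shape=(10, 32, 32)), noise_scale=0.0)
        with pytest.warns(TruncatedStackWarning):
            stack = run_volume_session((1.6, 1.6), 100.0, 20, drv)
        assert len(stack) < 20


class TestGenerators:
    def test_bead_field_contract(self):
        img, truth = synth_bead_image(5, 6, 10, seed=7)
        assert truth.shape == (5, 2)
        from scipy.spatial.distance import pdist
        assert pdist(truth).min() >= 4 * 6

    def test_anisotropic_psf_width_ordering(self):
        vol, centers = synth_flm_volume(1, (2.0, 2.0, 4.0), seed=1,
                                        shape=(48, 64, 64))
        cx, cy, cz = centers[0]
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))

        def fwhm(profile):
            half = profile.max() / 2
            return (profile >= half).sum()

        z_width = fwhm(vol[:, iy, ix])
        x_width = fwhm(vol[iz, iy, :])
        assert z_width > x_width

    def test_determinism(self):
        a, _ = synth_bead_image(4, 5, 8, seed=3)
        b, _ = synth_bead_image(4, 5, 8, seed=3)
        assert np.array_equal(a, b)
        s1, _ = synth_drift_stack(a, (1, 1), 3, seed=4)
        s2, _ = synth_drift_stack(a, (1, 1), 3, seed=4)
        assert np.array_equal(s1, s2)

    def test_seed_mandatory_and_param_validation(self):
        with pytest.raises(ParamError):
            synth_bead_image(3, 5, 10, seed=None)
        with pytest.raises(ParamError):
            synth_curtain(np.zeros((8, 8)), -1, 0.1, seed=0)
        with pytest.raises(ParamError):
            synth_charge(np.zeros((8, 8)), -5, 0.1)
        with pytest.raises(ParamError):
            synth_drift_stack(np.zeros((8, 8)), (1, 1), 0, seed=0)
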