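"""PIV displacement recovery, drift correction, filtering, averaged maps."""

import numpy as np
import pytest
from scipy import ndimage

from matrixplast.displacement import (DisplacementField,
                                      average_displacement_map, correct_drift,
                                      filter_vectors, max_matrix_displacement,
                                      piv_displacement_field)
from matrixplast.synth import FieldSpec, generate_bead_image_pair

PX = 0.5  # um per px used throughout


def make_pair(kind="uniform_translation", amplitude=1.5, seed=0, **kw):
    spec = FieldSpec(kind=kind, amplitude=amplitude,
                     center=kw.pop("center", (64.0, 64.0)),
                     decay_length=kw.pop("decay_length", 15.0))
    return generate_bead_image_pair(spec, image_size=256, pixel_size=PX,
                                    seed=seed, **kw)


def synthetic_grid_field(u, v, spacing=16.0, valid=None):
    ny, nx = u.shape
    gx, gy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    if valid is None:
        valid = np.ones(u.shape, dtype=bool)
    return DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v, valid_mask=valid)


class TestDriftCorrection:
    def test_identical_frames_zero_shift(self):
        pair = make_pair(amplitude=0.0, seed=4)
        stack = np.stack([pair.reference, pair.reference])
        _, shifts = correct_drift(stack)
        assert np.allclose(shifts, 0.0, atol=1e-3)

    @pytest.mark.parametrize("dy, dx", [(5.0, -3.0), (5.5, -2.25)])
    def test_translation_recovered_subpixel(self, dy, dx):
        pair = make_pair(amplitude=0.0, seed=4, noise_sd=0.0)
        base = pair.reference
        moved = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(base),
                                                   (dy, dx))).real
        reg, shifts = correct_drift(np.stack([base, moved]))
        # registration shift is the negative of the applied drift
        assert np.allclose(shifts[1], (-dy, -dx), atol=0.1)
        assert np.allclose(reg[1], base, atol=0.02)

    def test_featureless_frame_warns(self):
        base = np.zeros((64, 64))
        with pytest.warns(UserWarning, match="featureless"):
            correct_drift(np.stack([base, base]))


class TestPIV:
    def test_identical_frames_zero_field(self):
        pair = make_pair(amplitude=0.0, seed=1, noise_sd=0.0)
        pair.deformed = pair.reference.copy()
        field = piv_displacement_field(pair)
        assert field.valid_mask.all()
        assert np.allclose(field.u, 0.0, atol=1e-9)
        assert np.allclose(field.v, 0.0, atol=1e-9)

    def test_uniform_translation_vectors(self):
        """3 px translation -> every valid vector (3, 0) px within 0.1 px."""
        pair = make_pair(amplitude=3.0 * PX, seed=0, bead_density=80.0,
                         psf_sigma=0.8)
        field = piv_displacement_field(pair)
        assert field.valid_mask.sum() >= 40
        err = np.hypot(field.u / PX - 3.0, field.v / PX)[field.valid_mask]
        assert err.max() < 0.1

    def test_dipole_rmse_below_fifth_of_pixel(self):
        """Contractile dipole around an excluded cell body: RMSE < 0.2 px."""
        pair = make_pair(kind="contractile_dipole", amplitude=1.0, seed=0,
                         exclusion_radius=14.0)
        field = piv_displacement_field(pair)
        m = field.valid_mask
        rmse = np.sqrt(np.mean(
            ((field.u - pair.truth_u)[m] / PX) ** 2
            + ((field.v - pair.truth_v)[m] / PX) ** 2))
        assert rmse < 0.2

    def test_translation_equivariance(self):
        """Shifting both frames by the same integer offset leaves the
        recovered vectors unchanged on the common mesh."""
        pair = make_pair(kind="contractile_dipole", amplitude=1.0, seed=3,
                         exclusion_radius=14.0)
        f0 = piv_displacement_field(pair)
        rolled = type(pair)(
            reference=np.roll(pair.reference, (32, 32), axis=(0, 1)),
            deformed=np.roll(pair.deformed, (32, 32), axis=(0, 1)),
            pixel_size=pair.pixel_size)
        f1 = piv_displacement_field(rolled)
        # node (iy, ix) of f0 corresponds to (iy+1, ix+1) of f1 (32 px = 1 step)
        sel = f0.valid_mask[:-1, :-1] & f1.valid_mask[1:, 1:]
        assert sel.sum() > 20
        assert np.allclose(f0.u[:-1, :-1][sel], f1.u[1:, 1:][sel], atol=0.05)
        assert np.allclose(f0.v[:-1, :-1][sel], f1.v[1:, 1:][sel], atol=0.05)

    def test_empty_windows_flagged_invalid(self):
        pair = make_pair(amplitude=0.0, seed=2, noise_sd=0.0)
        pair.reference[:, :128] = 0.0
        pair.deformed = pair.reference.copy()
        field = piv_displacement_field(pair)
        assert not field.valid_mask[:, 0].any()
        assert field.valid_mask[:, -1].all()

    def test_oversized_window_rejected(self):
        pair = make_pair(seed=1)
        with pytest.raises(ValueError):
            piv_displacement_field(pair, window=200)


class TestFilterVectors:
    def test_spike_invalidated_smooth_field_untouched(self):
        u = np.ones((5, 5))
        u[2, 2] = 10.0
        field = synthetic_grid_field(u, np.zeros((5, 5)))
        out = filter_vectors(field)
        assert not out.valid_mask[2, 2]
        assert out.valid_mask.sum() == 24
        smooth = synthetic_grid_field(np.ones((5, 5)), np.zeros((5, 5)))
        assert filter_vectors(smooth).valid_mask.all()

    def test_isolated_node_left_as_is_with_warning(self):
        valid = np.zeros((3, 3), dtype=bool)
        valid[1, 1] = True
        field = synthetic_grid_field(np.ones((3, 3)), np.zeros((3, 3)),
                                     valid=valid)
        with pytest.warns(UserWarning, match="no valid neighbours"):
            out = filter_vectors(field)
        assert out.valid_mask[1, 1]


class TestMaxDisplacement:
    def test_uniform_and_zero_fields(self):
        zero = synthetic_grid_field(np.zeros((5, 5)), np.zeros((5, 5)))
        assert max_matrix_displacement(zero, (32.0, 32.0), 40.0) == 0.0
        two = synthetic_grid_field(np.full((5, 5), 2.0), np.zeros((5, 5)))
        assert max_matrix_displacement(two, (32.0, 32.0), 40.0) == pytest.approx(2.0)

    def test_dipole_closed_form_maximum(self):
        spec = FieldSpec(kind="contractile_dipole", amplitude=2.0,
                         center=(40.0, 40.0), decay_length=10.0)
        xs = np.arange(0.0, 81.0, 8.0)
        gx, gy = np.meshgrid(xs, xs)
        u, v = spec.evaluate(gx, gy)
        valid = np.ones(gx.shape, dtype=bool)
        valid[5, 5] = False  # knock out the r=0 node
        field = DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v,
                                  valid_mask=valid)
        got = max_matrix_displacement(field, (40.0, 40.0), 20.0)
        assert got == pytest.approx(2.0 * np.exp(-8.0 / 10.0))

    def test_no_valid_nodes_in_range(self):
        field = synthetic_grid_field(np.zeros((3, 3)), np.zeros((3, 3)),
                                     valid=np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError):
            max_matrix_displacement(field, (16.0, 16.0), 10.0)


def dipole_grid_field(center=(40.0, 40.0), rot_deg=0.0):
    spec = FieldSpec(kind="contractile_dipole", amplitude=2.0, center=center,
                     decay_length=10.0)
    # half-pixel offset keeps nodes off the 10-um bin edges, so rotating and
    # un-rotating cannot flip a node across an edge through float round-off
    xs = np.arange(0.0, 81.0, 4.0) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    u, v = spec.evaluate(gx, gy)
    if rot_deg:
        th = np.deg2rad(rot_deg)
        c, s = np.cos(th), np.sin(th)
        # rotate node positions and vectors about the centre
        px, py = gx - center[0], gy - center[1]
        gx = c * px - s * py + center[0]
        gy = s * px + c * py + center[1]
        u, v = c * u - s * v, s * u + c * v
    return DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v,
                             valid_mask=np.ones(gx.shape, dtype=bool))


class TestAveragedMap:
    def test_single_aligned_entry_equals_binned_field(self):
        field = dipole_grid_field()
        amap = average_displacement_map([(field, (40.0, 40.0), (1.0, 0.0))])
        assert amap.n_cells == 1
        # manual binning oracle
        sel = np.hypot(field.grid_x - 40, field.grid_y - 40) <= 20.0
        hu, _, _ = np.histogram2d((field.grid_x - 40)[sel],
                                  (field.grid_y - 40)[sel],
                                  bins=(amap.bin_edges, amap.bin_edges),
                                  weights=field.u[sel])
        assert np.allclose(amap.mean_u, hu)

    def test_n_identical_entries_equal_single(self):
        field = dipole_grid_field()
        one = average_displacement_map([(field, (40.0, 40.0), (1.0, 0.0))])
        many = average_displacement_map([(field, (40.0, 40.0), (1.0, 0.0))] * 4)
        assert np.allclose(one.mean_u, many.mean_u)
        assert np.allclose(one.mean_v, many.mean_v)

    @pytest.mark.parametrize("angle", [90.0, 37.0])
    def test_rotation_equivariance(self, angle):
        """Rotating field, centroid, and migration vector together leaves
        the averaged map unchanged (the dipole itself is isotropic, so any
        angle must give bin-identical maps)."""
        base = average_displacement_map(
            [(dipole_grid_field(), (40.0, 40.0), (1.0, 0.0))])
        th = np.deg2rad(angle)
        mig = (np.cos(th), np.sin(th))
        rotated = average_displacement_map(
            [(dipole_grid_field(rot_deg=angle), (40.0, 40.0), mig)])
        assert np.allclose(base.mean_u, rotated.mean_u, atol=1e-9)
        assert np.allclose(base.mean_v, rotated.mean_v, atol=1e-9)

    def test_zero_migration_vector_rejected(self):
        field = dipole_grid_field()
        with pytest.raises(ValueError, match="zero migration"):
            average_displacement_map([(field, (40.0, 40.0), (0.0, 0.0))])

    def test_random_fields_average_to_zero(self):
        """Zero-mean random entries: the averaged map shrinks like 1/sqrt(N)."""
        rng = np.random.default_rng(0)
        xs = np.arange(0.0, 81.0, 4.0)
        gx, gy = np.meshgrid(xs, xs)
        valid = np.ones(gx.shape, dtype=bool)

        def entry():
            u = rng.normal(0, 1.0, gx.shape)
            v = rng.normal(0, 1.0, gx.shape)
            return (DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v,
                                      valid_mask=valid),
                    (40.0, 40.0), (1.0, 0.0))

        small = average_displacement_map([entry() for _ in range(4)])
        large = average_displacement_map([entry() for _ in range(64)])
        mag = lambda m: float(np.mean(np.hypot(m.mean_u, m.mean_v)))
        assert mag(large) < 0.5 * mag(small)
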