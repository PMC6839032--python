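import numpy as np
import pytest

from rhizotrace.core import point_to_polyline_distance
from rhizotrace.synthetic import (
    MIN_TIP_SEPARATION,
    fibrous_params,
    generate_architecture,
    render_image,
    taproot_params,
)


class TestGenerateArchitecture:
    def test_counts_forced_by_params(self):
        params = fibrous_params(
            n_first_order=(3, 3), laterals_per_root=(0, 0), rng_seed=4
        )
        rs = generate_architecture(params)
        assert rs.n_plants == 1
        assert rs.count_roots(1) == 3
        assert rs.count_roots(2) == 0

    def test_deterministic_for_fixed_seed(self, small_fibrous_params):
        a = generate_architecture(small_fibrous_params)
        b = generate_architecture(small_fibrous_params)
        assert a.n_plants == b.n_plants
        for (_, ra), (_, rb) in zip(a.all_roots(), b.all_roots()):
            np.testing.assert_array_equal(ra.points, rb.points)

    def test_taproot_multiplant_attachments_on_parent(self):
        params = taproot_params(n_plants=5, laterals_per_root=(2, 4), rng_seed=9)
        rs = generate_architecture(params)
        assert rs.n_plants == 5
        for plant in rs.plants:
            assert len(plant.roots_of_order(1)) == 1
            laterals = plant.roots_of_order(2)
            assert 2 <= len(laterals) <= 4
            for lat in laterals:
                # independent geometric oracle: exact point-to-polyline distance
                d = point_to_polyline_distance(lat.attachment, lat.parent.points)
                assert d <= 1.0

    def test_roots_grow_predominantly_downward(self, small_fibrous_system):
        for _, root in small_fibrous_system.all_roots():
            dy = np.diff(np.asarray(root.points)[:, 1])
            # allow brief excursions but require overall downward growth
            assert dy.sum() > 0
            assert (dy > -4.0).all()

    def test_same_class_tips_respect_minimum_separation(self):
        params = taproot_params(n_plants=4, rng_seed=2)
        rs = generate_architecture(params)
        for order in (1, 2):
            tips = np.array([r.tip for _, r in rs.all_roots(order)])
            if len(tips) < 2:
                continue
            d = np.linalg.norm(tips[:, None] - tips[None, :], axis=-1)
            iu = np.triu_indices(len(tips), k=1)
            assert d[iu].min() >= MIN_TIP_SEPARATION

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            generate_architecture(fibrous_params(n_plants=2))


class TestRenderImage:
    def test_empty_system_is_pure_background(self):
        from rhizotrace.core import RootSystem

        params = fibrous_params(image_size=(96, 96), rng_seed=0)
        img = render_image(RootSystem(), params)
        assert img.shape == (96, 96, 3)
        # blue paper: blue channel dominates, no bright root pixels
        assert img[..., 2].mean() > img[..., 0].mean()
        assert img.max() < 0.9

    def test_vertical_root_stroke_width(self, straight_root_system):
        params = fibrous_params(image_size=(128, 128), root_width=8.0, rng_seed=0)
        img = render_image(straight_root_system, params)
        # roots are bright on blue paper; count bright pixels per row
        bright = (img[..., 0] > 0.55) & (img[..., 1] > 0.55)
        rows = bright[30:90]  # well inside the stroke
        widths = rows.sum(axis=1)
        assert np.all(widths >= 6) and np.all(widths <= 11)
        cols = np.argwhere(bright[60])[:, 0]
        assert abs(cols.mean() - 50) < 1.5

    def test_rendering_is_deterministic(self, small_fibrous_system, small_fibrous_params):
        a = render_image(small_fibrous_system, small_fibrous_params)
        b = render_image(small_fibrous_system, small_fibrous_params)
        np.testing.assert_array_equal(a, b)

    def test_out_of_bounds_points_clip_with_warning(self, small_fibrous_params):
        from rhizotrace.core import Plant, Root, RootSystem

        root = Root(order=1, points=np.array([[50.0, -40.0], [50.0, 500.0]]))
        rs = RootSystem(plants=[Plant(seed=np.array([50.0, -40.0]), roots=[root])])
        params = fibrous_params(image_size=(128, 128), rng_seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            render_image(rs, params)

    def test_taproot_style_renders_dark_plate(self):
        params = taproot_params(n_plants=2, image_size=(256, 256), rng_seed=3)
        rs = generate_architecture(params)
        img = render_image(rs, params)
        assert np.median(img) < 0.25  # dark background dominates
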