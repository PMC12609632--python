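"""Noise model, normalization, dataset assembly and container round-trips."""

import numpy as np
import pytest

from cceit import band, dataset, forward, phantom


@pytest.fixture(scope="module")
def sensor():
    layout = band.equidistant_layout()
    S = forward.sensitivity_for_layout(layout)
    C_low, C_high = dataset.reference_vectors(S)
    return S, C_low, C_high


@pytest.fixture(scope="module")
def thorax_measurement(sensor):
    S, C_low, C_high = sensor
    _, eps = phantom.rasterize(phantom.template_scene())
    C = forward.simulate_capacitance(S, eps.ravel())
    return dataset.normalize(C, C_low, C_high)


class TestAddNoise:
    def test_disabled_noise_is_identity(self, thorax_measurement):
        C = thorax_measurement
        np.testing.assert_array_equal(dataset.add_noise(C, None, 0), C)
        np.testing.assert_array_equal(dataset.add_noise(C, np.inf, 0), C)

    def test_opposite_channel_snr_is_30db(self, thorax_measurement):
        """Empirical SNR on the opposite-pair channels over many draws is
        30 dB within 0.1 dB; the added noise has one sigma for the vector."""
        C = thorax_measurement
        rng = np.random.default_rng(0)
        draws = np.stack([dataset.add_noise(C, 30.0, rng)
                          for _ in range(10_000)])
        noise = draws - C
        opp = forward.ORDERING.opposite_channels()
        c_opp = np.mean(np.abs(C[opp]))
        snr = 20 * np.log10(c_opp / noise[:, opp].std())
        assert snr == pytest.approx(30.0, abs=0.1)

    def test_opposite_channels_smallest_others_higher_snr(self, sensor):
        """Diametrically opposite pairs carry the smallest raw capacitances,
        so with one noise sigma for the whole vector every other channel sees
        a higher SNR on average (>= the 30 dB opposite-pair reference)."""
        S, _, _ = sensor
        _, eps = phantom.rasterize(phantom.template_scene())
        C = np.abs(forward.simulate_capacitance(S, eps.ravel()))
        opp = forward.ORDERING.opposite_channels()
        non_opp = np.setdiff1d(np.arange(len(C)), opp)
        assert C.min() == pytest.approx(C[opp].min())
        c_opp = C[opp].mean()
        sigma = c_opp / 10 ** 1.5  # the 30 dB noise level
        snr = 20 * np.log10(C / sigma)
        assert snr[non_opp].mean() >= 30.0
        assert snr[non_opp].mean() > snr[opp].mean()

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            dataset.add_noise(np.zeros(992), 30.0, 0)


class TestNormalize:
    def test_reference_scenes_map_to_zero_and_one(self, sensor):
        S, C_low, C_high = sensor
        np.testing.assert_allclose(dataset.normalize(C_low, C_low, C_high),
                                   0.0, atol=1e-14)
        np.testing.assert_allclose(dataset.normalize(C_high, C_low, C_high),
                                   1.0, atol=1e-12)

    def test_midpoint_scene_maps_to_half(self, sensor):
        """Linearity of the forward model through the affine normalization:
        a scene halfway between the references lands on 0.5 everywhere."""
        S, C_low, C_high = sensor
        lo = phantom.TISSUES["air"].complex_permittivity
        hi = phantom.TISSUES["background"].complex_permittivity
        _, eps_lo = phantom.rasterize(phantom.uniform_scene(phantom.TISSUES["air"]))
        _, eps_hi = phantom.rasterize(phantom.uniform_scene(phantom.TISSUES["background"]))
        C_mid = forward.simulate_capacitance(S, (eps_lo.ravel() + eps_hi.ravel()) / 2)
        np.testing.assert_allclose(
            dataset.normalize(C_mid, C_low, C_high), 0.5, atol=1e-10)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            dataset.normalize(np.ones(4), np.ones(4), np.ones(4))


@pytest.fixture(scope="module")
def small():
    spec = dataset.DatasetSpec(content="thorax", target_size=12,
                               level="small", seed=42)
    return dataset.build_dataset(spec)


class TestBuildDataset:
    def test_shapes_and_labels(self, small):
        assert small.images.shape[1:] == (64, 64)
        assert small.measurements.shape[1:] == (992,)
        assert len(small.layouts) == len(small)
        valid = {b"healthy", b"pneumothorax", b"effusion", b"hydropneumothorax"}
        assert set(small.labels.ravel()) <= valid

    def test_determinism_bit_identical(self, tmp_path):
        spec = dataset.DatasetSpec(content="thorax", target_size=6,
                                   level="none", seed=3)
        a = dataset.build_dataset(spec)
        b = dataset.build_dataset(spec)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.measurements, b.measurements)
        a.save(tmp_path / "a.h5")
        b.save(tmp_path / "b.h5")
        assert (tmp_path / "a.h5").read_bytes() == (tmp_path / "b.h5").read_bytes()

    def test_achieved_size_never_exceeds_target(self, small):
        assert len(small) + small.n_rejected == small.spec.target_size
        assert len(small) <= small.spec.target_size

    def test_level_large_stored_shifts_bounded(self):
        spec = dataset.DatasetSpec(content="thorax", target_size=5,
                                   level="large", seed=9)
        ds = dataset.build_dataset(spec)
        import json
        for meta in ds.layouts:
            rec = json.loads(meta)
            assert abs(rec["global_shift"]) <= 50.0
            assert all(abs(v) <= 10.0 for v in rec["local_shifts"])

    def test_noise_touches_measurements_not_images(self):
        base = dataset.DatasetSpec(content="thorax", target_size=4,
                                   level="none", seed=5, noise_snr_db=None)
        noisy = dataset.DatasetSpec(content="thorax", target_size=4,
                                    level="none", seed=5, noise_snr_db=30.0)
        a = dataset.build_dataset(base)
        b = dataset.build_dataset(noisy)
        np.testing.assert_array_equal(a.images, b.images)
        assert not np.array_equal(a.measurements, b.measurements)

    def test_container_roundtrip(self, small, tmp_path):
        p = tmp_path / "ds.h5"
        small.save(p)
        back = dataset.Dataset.load(p)
        np.testing.assert_array_equal(back.images, small.images)
        np.testing.assert_array_equal(back.measurements, small.measurements)
        np.testing.assert_array_equal(back.labels, small.labels)
        assert back.layouts == small.layouts
        assert back.spec == small.spec
        # idempotence: write -> read -> write gives identical bytes
        p2 = tmp_path / "ds2.h5"
        back.save(p2)
        assert p.read_bytes() == p2.read_bytes()


class TestTrainTestSplit:
    def _tiny(self, n=20):
        return dataset.Dataset(
            images=np.arange(n * 4, dtype=np.float32).reshape(n, 2, 2),
            measurements=np.arange(n * 3, dtype=np.float32).reshape(n, 3),
            labels=np.array([("healthy", "healthy")] * n, dtype="S20"),
            layouts=["{}"] * n,
            seeds=np.arange(n, dtype=np.uint32))

    def test_sizes_disjoint_exhaustive(self):
        ds = self._tiny(1000 // 50)
        tr, va = dataset.train_test_split(ds, 0.9, 0)
        assert len(tr) == 18 and len(va) == 2
        ids = np.concatenate([tr.seeds, va.seeds])
        assert sorted(ids) == list(range(20))

    def test_seed_determinism(self):
        ds = self._tiny()
        t1, v1 = dataset.train_test_split(ds, 0.7, 5)
        t2, v2 = dataset.train_test_split(ds, 0.7, 5)
        np.testing.assert_array_equal(t1.seeds, t2.seeds)
        np.testing.assert_array_equal(v1.seeds, v2.seeds)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            dataset.train_test_split(self._tiny(), 1.0, 0)
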