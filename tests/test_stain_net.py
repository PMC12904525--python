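"""Stage-II staining network: block identities, loss arithmetic, training."""

import numpy as np
import pytest

from ptystain import autodiff as ad
from ptystain import nn
from ptystain.report import LossReport
from ptystain.stain_net import (
    STAIN_CHANNELS,
    CrossTaskWeights,
    FSFF,
    GeneratorConfig,
    MultiStainGenerator,
    PatchDiscriminator,
    StainObjectiveWeights,
    StainTrainer,
    adversarial_losses,
    cross_task_losses,
    lambda_s_schedule,
    stain_objective,
)
from ptystain.tissue import TissuePhantomSpec, generate_bundle

RNG = np.random.default_rng(0)


class TestWTConvBlock:
    def test_identity_initialization_is_perfect_reconstruction(self):
        block = nn.WTConvBlock(3, np.random.default_rng(0), identity_init=True)
        x = ad.Tensor(RNG.normal(size=(2, 3, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(block(x).numpy(), x.numpy(), atol=1e-6)

    def test_constant_input_subband_structure(self):
        c = 0.6
        x = ad.Tensor(np.full((1, 2, 8, 8), c, dtype=np.float64))
        ll, lh, hl, hh = ad.haar_dwt2(x)
        np.testing.assert_allclose(ll.numpy(), 2 * c, atol=1e-14)
        for band in (lh, hl, hh):
            np.testing.assert_allclose(band.numpy(), 0.0, atol=1e-14)

    def test_odd_sizes_pad_and_crop(self):
        block = nn.WTConvBlock(1, np.random.default_rng(1), identity_init=True)
        x = ad.Tensor(RNG.normal(size=(1, 1, 9, 7)))
        out = block(x)
        assert out.shape == x.shape
        np.testing.assert_allclose(out.numpy()[..., :8, :6], x.numpy()[..., :8, :6], atol=1e-10)


class TestFSFF:
    def test_identity_at_initialization(self):
        fuse = FSFF(4, np.random.default_rng(0))
        f_s = ad.Tensor(RNG.normal(size=(1, 4, 8, 8)).astype(np.float32))
        f_f = ad.Tensor(RNG.normal(size=(1, 4, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(fuse(f_s, f_f).numpy(), f_s.numpy())

    def test_equal_inputs_feed_zero_difference(self):
        fuse = FSFF(4, np.random.default_rng(0))
        # make the output conv nonzero so a nonzero difference would show
        fuse.out.weight.data = np.random.default_rng(1).normal(
            size=fuse.out.weight.shape).astype(np.float32)
        f = ad.Tensor(RNG.normal(size=(1, 4, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(fuse(f, f).numpy(), f.numpy(), atol=1e-6)

    def test_shape_mismatch_raises(self):
        fuse = FSFF(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            fuse(ad.Tensor(np.zeros((1, 4, 8, 8))), ad.Tensor(np.zeros((1, 4, 4, 4))))


class TestSEBlock:
    def test_gates_strictly_inside_unit_interval(self):
        se = nn.SEBlock(8, np.random.default_rng(0))
        x = ad.Tensor(RNG.normal(size=(2, 8, 6, 6)).astype(np.float32))
        out = se(x)
        ratio = np.abs(out.numpy()) / np.maximum(np.abs(x.numpy()), 1e-12)
        assert ratio.max() < 1.0
        assert ratio.min() > 0.0

    def test_zero_input_gives_zero_output(self):
        se = nn.SEBlock(8, np.random.default_rng(0))
        out = se(ad.Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.numpy(), 0.0)

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError):
            nn.SEBlock(6, np.random.default_rng(0), reduction=4)


class TestGenerator:
    def test_output_shape_and_range(self):
        g = MultiStainGenerator(GeneratorConfig(base_width=8, seed=0))
        i_int = RNG.uniform(0, 1, (32, 32)).astype(np.float32)
        bundle = g.generate(i_int)
        assert bundle.channels.shape == (4, 32, 32)
        assert bundle.channels.min() >= 0.0 and bundle.channels.max() <= 1.0

    def test_feature_branch_requires_features(self):
        g = MultiStainGenerator(GeneratorConfig(base_width=8, use_bip_features=True, seed=0),
                                feature_channels=(8, 16, 32))
        with pytest.raises(ValueError):
            g.generate(RNG.uniform(0, 1, (32, 32)).astype(np.float32))

    def test_feature_branch_keeps_output_shape(self):
        g = MultiStainGenerator(GeneratorConfig(base_width=8, use_bip_features=True, seed=0),
                                feature_channels=(8, 16, 32))
        feats = [RNG.normal(size=(8, 32, 32)).astype(np.float32),
                 RNG.normal(size=(16, 16, 16)).astype(np.float32),
                 RNG.normal(size=(32, 8, 8)).astype(np.float32)]
        bundle = g.generate(RNG.uniform(0, 1, (32, 32)).astype(np.float32), feats)
        assert bundle.channels.shape == (4, 32, 32)

    def test_ablation_flags_change_only_internals(self):
        i_int = RNG.uniform(0, 1, (32, 32)).astype(np.float32)
        for kwargs in ({"use_wtconv": False}, {"use_fsff": False}, {"use_se": False}):
            g = MultiStainGenerator(GeneratorConfig(base_width=8, seed=0, **kwargs))
            assert g.generate(i_int).channels.shape == (4, 32, 32)


class TestAdversarialLosses:
    def test_half_confidence_generator_loss(self):
        d_fake = ad.Tensor(np.full((1, 1, 6, 6), 0.5))
        rep = adversarial_losses(d_fake)
        assert rep["g_gan"] == pytest.approx(0.25, abs=1e-12)

    def test_perfect_discriminator_loss_is_zero(self):
        rep = adversarial_losses(ad.Tensor(np.zeros((1, 1, 6, 6))),
                                 ad.Tensor(np.ones((1, 1, 6, 6))))
        assert rep["d_loss"] == pytest.approx(0.0, abs=1e-12)

    def test_receptive_field_is_70x70_by_gradient_footprint(self):
        d = PatchDiscriminator(1, np.random.default_rng(0), width=4, use_norm=False)
        x = ad.Tensor(RNG.normal(size=(1, 1, 128, 128)).astype(np.float64),
                      requires_grad=True)
        out = d(x)
        cy, cx = out.shape[2] // 2, out.shape[3] // 2
        seed = np.zeros(out.shape)
        seed[0, 0, cy, cx] = 1.0
        out.backward(seed)
        footprint = np.abs(x.grad[0, 0]) > 0
        rows = np.where(footprint.any(axis=1))[0]
        cols = np.where(footprint.any(axis=0))[0]
        h = rows[-1] - rows[0] + 1
        w = cols[-1] - cols[0] + 1
        assert 63 <= h <= 70 and 63 <= w <= 70


class TestCrossTaskLosses:
    def test_identical_dapi_he_gives_zero_consistency(self):
        m = RNG.uniform(0, 1, (8, 8))
        rep = cross_task_losses({"dapi": m, "he": m.copy(), "lap2": m, "panck": m})
        assert rep["consistency"] == 0.0

    def test_exclusivity_extremes(self):
        ones = np.ones((4, 4))
        rep = cross_task_losses({"dapi": ones, "he": ones, "lap2": ones, "panck": ones})
        assert rep["exclusive"] == pytest.approx(1.0)
        left = np.zeros((4, 4)); left[:, :2] = 1.0
        right = np.zeros((4, 4)); right[:, 2:] = 1.0
        rep = cross_task_losses({"dapi": ones, "he": ones, "lap2": left, "panck": right})
        assert rep["exclusive"] == 0.0

    def test_two_by_two_masked_mean_arithmetic(self):
        dapi = np.array([[0.9, 0.1], [0.2, 0.8]])
        he = dapi - np.array([[0.5, 0.0], [0.0, 0.5]])
        rep = cross_task_losses({"dapi": dapi, "he": he,
                                 "lap2": np.zeros((2, 2)), "panck": np.zeros((2, 2))})
        # mask = dapi > 0.5 -> diagonal; masked mean of 0.25 over 2 pixels
        assert rep["consistency"] == pytest.approx(0.25, abs=1e-12)

    def test_printed_weights_compose_to_1p7_with_unit_sublosses(self):
        report = LossReport()
        report.add("consistency", 1.0, 1.0)
        report.add("exclusive", 1.0, 0.5)
        report.add("relative", 1.0, 0.2)
        assert report.total == pytest.approx(1.7, abs=1e-12)

    def test_empty_nuclear_mask_warns_and_zeroes(self):
        low = np.full((4, 4), 0.1)
        with pytest.warns(UserWarning):
            rep = cross_task_losses({"dapi": low, "he": low, "lap2": low, "panck": low})
        assert rep["consistency"] == 0.0


class TestStainObjective:
    def _unit_components(self):
        return {name: {"gan": 1.0, "l1": 1.0, "iqa": 1.0} for name in STAIN_CHANNELS}

    def _unit_cross(self):
        rep = LossReport()
        rep.add("consistency", 1.0, 1.0)
        rep.add("exclusive", 1.0, 0.5)
        rep.add("relative", 1.0, 0.2)
        return rep

    def test_printed_weights_total_46p5(self):
        rep = stain_objective(self._unit_components(), self._unit_cross())
        assert rep.total == pytest.approx(4 * (1 + 10.0 + 0.2) + 1.0 * 1.7, abs=1e-12)
        assert rep.total == pytest.approx(46.5, abs=1e-12)

    def test_zero_loss_fixed_point(self):
        comps = {name: {"gan": 0.0, "l1": 0.0, "iqa": 0.0} for name in STAIN_CHANNELS}
        cross = LossReport()
        cross.add("consistency", 0.0, 1.0)
        cross.add("exclusive", 0.0, 0.5)
        cross.add("relative", 0.0, 0.2)
        assert stain_objective(comps, cross).total == 0.0

    def test_total_recomposes_from_report_to_machine_precision(self):
        rng = np.random.default_rng(3)
        comps = {name: {"gan": rng.uniform(), "l1": rng.uniform(), "iqa": rng.uniform()}
                 for name in STAIN_CHANNELS}
        cross = self._unit_cross()
        rep = stain_objective(comps, cross)
        recomposed = sum(rep.weighted(k) for k in rep.terms)
        assert rep.extras["total_tensor"].item() == pytest.approx(recomposed, rel=1e-12)

    def test_missing_component_names_channel(self):
        comps = self._unit_components()
        del comps["dapi"]["l1"]
        with pytest.raises(KeyError, match="dapi"):
            stain_objective(comps, self._unit_cross())


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.1), (5, 0.3), (10, 0.5), (20, 0.5)])
    def test_lambda_s_warmup(self, epoch, expected):
        assert lambda_s_schedule(epoch) == pytest.approx(expected, abs=1e-12)


class TestTrainerSmoke:
    def test_few_steps_reduce_l1(self):
        bundles = [generate_bundle(TissuePhantomSpec(size=32, n_cells=2,
                                                     nucleus_radius=(3.0, 4.0),
                                                     seed=s))[0] for s in range(4)]
        tr = StainTrainer(GeneratorConfig(base_width=8, seed=0), batch_size=4,
                          disc_width=4, seed=0)
        inputs = np.stack([b.interface for b in bundles])[:, None]
        targets = np.stack([b.channels for b in bundles])
        first = tr.step(inputs, targets, augment=False)
        for _ in range(20):
            last = tr.step(inputs, targets, augment=False)
        l1_first = np.mean([first[f"{c}_l1"] for c in STAIN_CHANNELS])
        l1_last = np.mean([last[f"{c}_l1"] for c in STAIN_CHANNELS])
        assert l1_last < l1_first

    def test_fit_is_seed_reproducible(self):
        bundles = [generate_bundle(TissuePhantomSpec(size=32, n_cells=2,
                                                     nucleus_radius=(3.0, 4.0),
                                                     seed=s))[0] for s in range(2)]
        hists = []
        for _ in range(2):
            tr = StainTrainer(GeneratorConfig(base_width=4, seed=1), batch_size=2,
                              disc_width=4, seed=5)
            hists.append(tr.fit(bundles, epochs=2))
        assert hists[0] == hists[1]


@pytest.fixture(scope="module")
def paired_data():
    from ptystain.bip_fpm import BipFpmReconstructor, BipFpmTrainConfig
    from ptystain.optics import LEDArrayGeometry, OpticalSystem, led_wavevectors
    from ptystain.tissue import degrade_bundle
    system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                           camera_pixel_size=6.5e-6, hr_shape=(32, 32), upsample_factor=2)
    illum = led_wavevectors(LEDArrayGeometry(3, 3, 3e-3, 45e-3), system)
    bundles, stacks = [], []
    for s in range(2):
        b, _ = generate_bundle(TissuePhantomSpec(size=32, n_cells=2,
                                                 nucleus_radius=(3.0, 4.0), seed=s))
        stack, _ = degrade_bundle(b, system, illum)
        bundles.append(b)
        stacks.append(stack)
    stage1 = BipFpmReconstructor(system, illum,
                                 BipFpmTrainConfig(epochs=4, freeze_epochs=1, seed=0,
                                                   base_width=4, n_res_blocks=1))
    return stage1, stacks, bundles


class TestJointTraining:

    def test_joint_fit_runs_and_schedules_lambda_s(self, paired_data):
        from ptystain.stain_net import JointTrainer
        stage1, stacks, bundles = paired_data
        stain = StainTrainer(GeneratorConfig(base_width=4, seed=0), seed=0, batch_size=2)
        joint = JointTrainer(stage1, stain)
        history = joint.fit(stacks, bundles, epochs=2)
        assert len(history) == 2
        assert history[0].extras["lambda_s"] == pytest.approx(0.1)
        assert history[1].extras["lambda_s"] == pytest.approx(0.14)
        assert all(np.isfinite(list(h.terms.values())).all() for h in history)

    def test_unpaired_samples_rejected(self, paired_data):
        from ptystain.stain_net import JointTrainer
        stage1, stacks, bundles = paired_data
        stain = StainTrainer(GeneratorConfig(base_width=4, seed=0), seed=0, batch_size=2)
        with pytest.raises(ValueError, match="paired"):
            JointTrainer(stage1, stain).fit(stacks[:1], bundles, epochs=1)
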