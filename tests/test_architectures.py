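import numpy as np
import pytest

import informrc as rc
from informrc.architectures import (ARCHITECTURE_NAMES, build_architecture,
                                    external_information, init_architecture,
                                    network_seed, run_test_closed_loop,
                                    train_teacher_forced)
from informrc.rls import TrainConfig


class TestBuild:
    def test_inform_single_network_27_outputs(self):
        spec = build_architecture("InFoRM")
        assert len(spec.networks) == 1
        assert spec.n_output_channels == 27

    def test_control_two_networks_routing(self):
        spec = build_architecture("Control")
        inv, fwd = spec.networks
        assert inv.name == "inverse" and fwd.name == "forward"
        assert "afference" not in inv.inputs       # no afferent feedback
        assert "goal_window" not in fwd.inputs     # no goal information
        assert inv.outputs == ("efference",) and fwd.outputs == ("afference",)

    def test_augmented_variants_add_inputs(self):
        a = build_architecture("Control+A")
        g = build_architecture("Control+G")
        ag = build_architecture("Control+AG")
        assert "afference" in a.networks[0].inputs
        assert "goal_window" in g.networks[1].inputs
        assert "afference" in ag.networks[0].inputs
        assert "goal_window" in ag.networks[1].inputs

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_architecture("Smith-predictor")

    @pytest.mark.parametrize("name", ARCHITECTURE_NAMES)
    def test_routing_audit_input_dimensions(self, name, tiny_configs):
        """Realised W_in/W_fb dimensions equal the declared routing."""
        spec = build_architecture(name, configs=tiny_configs(name))
        params = init_architecture(spec)
        for net in spec.networks:
            expected = sum(3 * spec.n_taps if s == "goal_window"
                           else spec.dims[s] for s in net.inputs)
            assert params[net.name].n_in == expected == spec.input_dim(net)
            assert params[net.name].n_out == spec.output_dim(net)

    def test_information_parity_inform_vs_control_ag(self):
        """Every Control+AG subnetwork sees the same signal set as InFoRM's
        reservoir: any remaining performance difference is architectural."""
        from informrc.architectures import has_full_information
        full = frozenset({"goal", "efference", "afference"})
        assert external_information(build_architecture("InFoRM")) == \
            {"inform": full}
        assert has_full_information(build_architecture("Control+AG"))
        assert not has_full_information(build_architecture("Control"))
        assert not has_full_information(build_architecture("Control+A"))
        assert not has_full_information(build_architecture("Control+G"))

    def test_spec_round_trip_through_dict(self, tiny_configs):
        spec = build_architecture("Control+G", configs=tiny_configs("Control+G"))
        back = rc.ArchitectureSpec.from_dict(spec.to_dict())
        assert back == spec


class TestSeeding:
    def test_network_seed_deterministic_and_architecture_independent(self):
        assert network_seed(42, 0) == network_seed(42, 0)
        assert network_seed(42, 0) != network_seed(42, 1)
        assert network_seed(42, 0) < 2 ** 31

    def test_matched_instance_seeds_across_architectures(self, tiny_configs):
        """The same instance seed yields the same per-slot reservoir seeds
        for every architecture."""
        s_inform = build_architecture("InFoRM", configs=tiny_configs("InFoRM"))
        s_control = build_architecture("Control", configs=tiny_configs("Control"))
        p1 = init_architecture(s_inform, instance_seed=7)
        p2 = init_architecture(s_control, instance_seed=7)
        assert (p1["inform"].config.seed == p2["inverse"].config.seed
                == network_seed(7, 0))
        assert p2["forward"].config.seed == network_seed(7, 1)


def _mini_series(n_t=240, n_taps=3, seed=0):
    """A small normalised bundle with smooth structure for fast training."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_t) / 120.0
    goal = np.vstack([0.5 + 0.4 * np.sin(2 * np.pi * t),
                      0.5 + 0.4 * np.cos(2 * np.pi * t),
                      np.zeros(n_t)])
    eff = 0.5 + 0.3 * np.sin(2 * np.pi * np.outer(np.arange(1, 9) / 4.0, t)
                             + rng.uniform(0, np.pi, (8, 1)))
    aff = 0.5 + 0.3 * np.cos(2 * np.pi * np.outer(np.arange(1, 17) / 6.0, t)
                             + rng.uniform(0, np.pi, (16, 1)))
    return rc.SignalBundle(goal, eff, aff)


class TestClosedLoop:
    @pytest.mark.parametrize("name", ARCHITECTURE_NAMES)
    def test_output_shapes_and_mask(self, name, tiny_configs):
        bundle = _mini_series()
        spec = build_architecture(name, configs=tiny_configs(name), n_taps=3)
        trained = train_teacher_forced(spec, bundle,
                                       TrainConfig(n_iterations=1, seed=0))
        from informrc.partition import build_lookahead_inputs
        gw = build_lookahead_inputs(bundle.goal, n_taps=3)
        outputs, mask = run_test_closed_loop(trained, bundle.goal, gw,
                                             init_prefix_len=40)
        assert outputs["efference"].shape == (8, bundle.n_samples)
        assert outputs["afference"].shape == (16, bundle.n_samples)
        assert ("goal" in outputs) == (name == "InFoRM")
        assert mask.sum() == bundle.n_samples - 40

    def test_zeroed_inverse_readout_silences_forward_input(self, tiny_configs):
        """Routing check: the forward network consumes the inverse network's
        efference output, so zeroing that readout zeroes the efference."""
        bundle = _mini_series()
        spec = build_architecture("Control", configs=tiny_configs("Control"),
                                  n_taps=3)
        trained = train_teacher_forced(spec, bundle,
                                       TrainConfig(n_iterations=1, seed=0))
        trained.readouts["inverse"] = np.zeros_like(trained.readouts["inverse"])
        from informrc.partition import build_lookahead_inputs
        gw = build_lookahead_inputs(bundle.goal, n_taps=3)
        outputs, _ = run_test_closed_loop(trained, bundle.goal, gw)
        np.testing.assert_array_equal(outputs["efference"], 0)

    def test_inform_recognition_tracks_constant_goal(self, tiny_configs):
        """With a constant goal the recognition output reproduces it."""
        bundle = _mini_series()
        const = rc.SignalBundle(np.full_like(bundle.goal, 0.5),
                                np.full_like(bundle.efference, 0.3),
                                np.full_like(bundle.afference, 0.6))
        spec = build_architecture("InFoRM", configs=tiny_configs("InFoRM"),
                                  n_taps=3)
        trained = train_teacher_forced(spec, const,
                                       TrainConfig(n_iterations=1,
                                                   noise_scale=0.01, seed=0))
        from informrc.partition import build_lookahead_inputs
        gw = build_lookahead_inputs(const.goal, n_taps=3)
        outputs, mask = run_test_closed_loop(trained, const.goal, gw,
                                             init_prefix_len=60)
        err = np.abs(outputs["goal"][:, mask] - 0.5)
        assert err.max() < 1e-2

    def test_closed_loop_deterministic(self, tiny_configs):
        bundle = _mini_series()
        spec = build_architecture("Control+AG", configs=tiny_configs("Control+AG"),
                                  n_taps=3)
        trained = train_teacher_forced(spec, bundle,
                                       TrainConfig(n_iterations=1, seed=1))
        from informrc.partition import build_lookahead_inputs
        gw = build_lookahead_inputs(bundle.goal, n_taps=3)
        o1, _ = run_test_closed_loop(trained, bundle.goal, gw)
        o2, _ = run_test_closed_loop(trained, bundle.goal, gw)
        for g in o1:
            np.testing.assert_array_equal(o1[g], o2[g])

    def test_missing_readout_reported(self, tiny_configs):
        bundle = _mini_series()
        spec = build_architecture("Control", configs=tiny_configs("Control"),
                                  n_taps=3)
        trained = train_teacher_forced(spec, bundle,
                                       TrainConfig(n_iterations=1, seed=0))
        del trained.readouts["forward"]
        from informrc.partition import build_lookahead_inputs
        gw = build_lookahead_inputs(bundle.goal, n_taps=3)
        with pytest.raises(KeyError, match="forward"):
            run_test_closed_loop(trained, bundle.goal, gw)
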