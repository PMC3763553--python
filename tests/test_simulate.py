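import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fretkin.simulate import (
    EmissionModel,
    RateModel,
    SimulationParams,
    StatePath,
    TimeTrace,
    build_end_dynamics_model,
    build_nucleation_model,
    render_intensities,
    simulate_experiment,
    simulate_state_path,
)


class TestStatePath:
    def test_valid_path(self):
        p = StatePath((("A", 0.0, 2.0), ("B", 2.0, 3.0)), 5.0)
        assert p.states == ("A", "B")
        assert p.occupancy_time() == {"A": 2.0, "B": 3.0}

    def test_rejects_gap(self):
        with pytest.raises(ValueError, match="contiguous"):
            StatePath((("A", 0.0, 1.0), ("B", 1.5, 1.0)), 2.5)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError, match="duration"):
            StatePath((("A", 0.0, 0.0),), 0.0)

    def test_rejects_repeated_state(self):
        with pytest.raises(ValueError, match="share a state"):
            StatePath((("A", 0.0, 1.0), ("A", 1.0, 1.0)), 2.0)

    def test_rejects_bad_total(self):
        with pytest.raises(ValueError, match="sum"):
            StatePath((("A", 0.0, 1.0),), 2.0)

    def test_truncated(self):
        p = StatePath((("A", 0.0, 2.0), ("B", 2.0, 3.0)), 5.0)
        q = p.truncated(3.0)
        assert q.total_duration == 3.0
        assert q.segments == (("A", 0.0, 2.0), ("B", 2.0, 1.0))


class TestRateModel:
    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError, match=">= 0"):
            RateModel(states=("A", "B"), rates={("A", "B"): -1.0})

    def test_rejects_self_rate(self):
        with pytest.raises(ValueError, match="self-transition"):
            RateModel(states=("A", "B"), rates={("A", "A"): 1.0})

    def test_stationary_two_state(self):
        m = RateModel(states=("A", "B"), rates={("A", "B"): 1.0, ("B", "A"): 3.0})
        # pi_A = r(B->A) / (r(A->B) + r(B->A))
        assert np.allclose(m.stationary_distribution(), [0.75, 0.25])


class TestSimulateStatePath:
    def test_absorbing_state_single_segment(self):
        m = RateModel(states=("A", "B"), rates={("B", "A"): 1.0})
        p = simulate_state_path(m, 10.0, seed=0, initial_state="A")
        assert p.segments == (("A", 0.0, 10.0),)

    def test_rejects_nonpositive_duration(self):
        m = RateModel(states=("A",), rates={})
        with pytest.raises(ValueError):
            simulate_state_path(m, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_state_path(m, float("inf"), seed=0)

    def test_two_state_stationary_occupancy(self):
        # analytic stationary occupancy of A is 0.5; the time-average over a
        # window T has asymptotic variance 2 p^2 (1-p)^2 (1/ra + 1/rb) / T
        m = RateModel(states=("A", "B"), rates={("A", "B"): 1.0, ("B", "A"): 1.0})
        T = 1e4
        p = simulate_state_path(m, T, seed=11)
        frac_a = p.occupancy_time().get("A", 0.0) / T
        se = np.sqrt(2 * 0.25 * 0.25 * 2.0 / T)
        assert abs(frac_a - 0.5) < 3 * se

    def test_chain_mean_dwell(self):
        # exponential dwell in M2 has mean 1 / exit rate = 2 s
        m = build_end_dynamics_model(k_on=0.5, k_off=0.5, reca_concentration=1.0)
        dwells = []
        seed = 0
        while len(dwells) < 1000:
            p = simulate_state_path(m, 2000.0, seed=seed)
            segs = p.segments
            dwells += [d for (s, _, d) in segs[1:-1] if s == "M2"]
            seed += 1
        dwells = np.array(dwells[:1500])
        mean = dwells.mean()
        assert abs(mean - 2.0) < 3 * 2.0 / np.sqrt(len(dwells))

    def test_dwell_distribution_is_exponential(self):
        # KS test of complete dwells against Exp(exit rate), per state
        m = RateModel(states=("A", "B"), rates={("A", "B"): 2.0, ("B", "A"): 0.5})
        p = simulate_state_path(m, 6000.0, seed=5)
        for state, rate in (("A", 2.0), ("B", 0.5)):
            dwells = np.array(
                [d for (s, _, d) in p.segments[1:-1] if s == state]
            )
            assert len(dwells) >= 1000
            res = stats.kstest(dwells, "expon", args=(0, 1 / rate))
            assert res.pvalue > 0.01

    def test_reproducible_for_seed(self):
        m = build_nucleation_model(0.1, 0.2)
        p1 = simulate_state_path(m, 100.0, seed=3)
        p2 = simulate_state_path(m, 100.0, seed=3)
        assert p1 == p2


@settings(max_examples=30, deadline=None)
@given(
    r_ab=st.floats(0.01, 5.0),
    r_ba=st.floats(0.01, 5.0),
    seed=st.integers(0, 10**6),
)
def test_state_path_invariants(r_ab, r_ba, seed):
    m = RateModel(states=("A", "B"), rates={("A", "B"): r_ab, ("B", "A"): r_ba})
    p = simulate_state_path(m, 50.0, seed=seed)
    starts = [s for _, s, _ in p.segments]
    durs = [d for _, _, d in p.segments]
    assert all(d > 0 for d in durs)
    assert np.isclose(sum(durs), 50.0)
    for (s1, t1, d1), (s2, t2, _) in zip(p.segments, p.segments[1:]):
        assert s1 != s2
        assert np.isclose(t1 + d1, t2)


class TestBuildNucleationModel:
    def test_zero_nucleation_never_leaves_unbound(self):
        m = build_nucleation_model(0.0, 0.1)
        p = simulate_state_path(m, 500.0, seed=1)
        assert p.states == ("unbound",)

    def test_mean_nucleated_dwell(self):
        # 1 / k_disassembly = 20 s
        m = build_nucleation_model(k_nuc=0.5, k_disassembly=0.05)
        dwells = []
        for seed in range(40):
            p = simulate_state_path(m, 2000.0, seed=seed)
            dwells += [d for (s, _, d) in p.segments[1:-1] if s == "nucleated"]
        dwells = np.array(dwells)
        assert len(dwells) > 300
        assert abs(dwells.mean() - 20.0) < 3 * 20.0 / np.sqrt(len(dwells))

    def test_poisson_event_count(self):
        # k_nuc = 0.01/s over ~100 molecules x 100 s of (mostly) unbound time
        # gives ~100 events, Poisson, so within 3 * sqrt(100)
        m = build_nucleation_model(k_nuc=0.01, k_disassembly=50.0)
        events = 0
        for seed in range(100):
            p = simulate_state_path(m, 100.0, seed=seed, initial_state="unbound")
            events += sum(
                1
                for (a, _, _), (b, _, _) in zip(p.segments, p.segments[1:])
                if a == "unbound" and b == "nucleated"
            )
        assert abs(events - 100) < 3 * np.sqrt(100)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            build_nucleation_model(-0.1, 0.1)


class TestBuildEndDynamicsModel:
    def test_zero_concentration_only_dissociation(self):
        m = build_end_dynamics_model(0.5, 0.3, reca_concentration=0.0)
        assert m.transitions_from("M0") == []
        assert dict(m.transitions_from("M1")) == {"M0": 0.3}
        assert dict(m.transitions_from("M2")) == {"M1": 0.3}

    def test_symmetric_chain_uniform_stationary(self):
        # detailed balance of the symmetric birth-death chain: uniform
        m = build_end_dynamics_model(0.2, 0.2, reca_concentration=1.0)
        assert np.allclose(m.stationary_distribution(), np.ones(3) / 3)
        p = simulate_state_path(m, 2e4, seed=9)
        occ = p.occupancy_time()
        for s in ("M0", "M1", "M2"):
            assert abs(occ[s] / 2e4 - 1 / 3) < 0.03

    def test_no_direct_m0_m2(self):
        m = build_end_dynamics_model(1.0, 1.0, 1.0)
        assert ("M0", "M2") not in m.rates
        assert ("M2", "M0") not in m.rates

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_chain_transition_parity(self, seed):
        m = build_end_dynamics_model(0.4, 0.3, 1.0)
        p = simulate_state_path(m, 500.0, seed=seed)
        pairs = list(zip(p.states, p.states[1:]))
        for a, b in (("M0", "M1"), ("M1", "M2")):
            up = pairs.count((a, b))
            down = pairs.count((b, a))
            assert abs(up - down) <= 1


class TestRenderIntensities:
    def test_noiseless_single_state(self):
        path = StatePath((("A", 0.0, 1.0),), 1.0)
        em = EmissionModel(
            mean_fret={"A": 0.7}, total_intensity=100.0, noise_sd=0.0, bleach_rate=0.0
        )
        tr = render_intensities(path, em, frame_time=0.1, seed=0)
        assert len(tr) == 10
        assert np.allclose(tr.donor, 30.0)
        assert np.allclose(tr.acceptor, 70.0)

    def test_midframe_switch_integrates(self):
        # switch exactly at the frame midpoint: frame FRET = (0.7 + 0.5) / 2
        path = StatePath((("A", 0.0, 0.05), ("B", 0.05, 0.05)), 0.1)
        em = EmissionModel(
            mean_fret={"A": 0.7, "B": 0.5},
            total_intensity=100.0,
            noise_sd=0.0,
            bleach_rate=0.0,
        )
        tr = render_intensities(path, em, frame_time=0.1, seed=0)
        assert np.allclose(tr.acceptor, [60.0])

    def test_noiseless_fret_equals_time_weighted_mean(self, rng):
        # oracle: integrate the piecewise-constant level over each frame by
        # explicit segment slicing
        m = build_end_dynamics_model(0.8, 0.9, 1.0)
        levels = {"M0": 0.7, "M1": 0.5, "M2": 0.3}
        path = simulate_state_path(m, 20.0, seed=17)
        em = EmissionModel(
            mean_fret=levels, total_intensity=200.0, noise_sd=0.0, bleach_rate=0.0
        )
        tr = render_intensities(path, em, frame_time=0.1, seed=0)
        for i in range(len(tr)):
            t0, t1 = i * 0.1, (i + 1) * 0.1
            acc = 0.0
            for state, start, dur in path.segments:
                lo, hi = max(start, t0), min(start + dur, t1)
                if hi > lo:
                    acc += levels[state] * (hi - lo)
            assert tr.acceptor[i] == pytest.approx(200.0 * acc / 0.1, abs=1e-9)

    def test_bleach_gives_dark_frames(self):
        path = StatePath((("A", 0.0, 100.0),), 100.0)
        em = EmissionModel(
            mean_fret={"A": 0.7}, total_intensity=100.0, noise_sd=0.0, bleach_rate=0.1
        )
        tr = render_intensities(path, em, frame_time=0.1, seed=4)
        assert tr.bleach_time is not None
        after = tr.times > tr.bleach_time
        assert after.sum() > 0
        assert np.allclose(tr.acceptor[after], 0.0)
        assert np.allclose(tr.donor[after], 100.0)

    def test_rejects_bad_frame_time(self):
        path = StatePath((("A", 0.0, 1.0),), 1.0)
        em = EmissionModel(mean_fret={"A": 0.5}, bleach_rate=0.0)
        with pytest.raises(ValueError):
            render_intensities(path, em, frame_time=0.0, seed=0)


class TestSimulateExperiment:
    def _params(self, **kw):
        defaults = dict(
            rate_model=build_end_dynamics_model(0.3, 0.3, 1.0),
            emission_model=EmissionModel(
                mean_fret={"M0": 0.7, "M1": 0.5, "M2": 0.3}
            ),
            n_molecules=5,
            trace_duration=20.0,
            seed=99,
        )
        defaults.update(kw)
        return SimulationParams(**defaults)

    def test_bit_identical_regeneration(self):
        t1 = simulate_experiment(self._params())
        t2 = simulate_experiment(self._params())
        for a, b in zip(t1, t2):
            assert np.array_equal(a.donor, b.donor)
            assert np.array_equal(a.acceptor, b.acceptor)
            assert a.ground_truth == b.ground_truth

    def test_subset_independence(self):
        # per-trace substreams: trace i is identical regardless of n_molecules
        few = simulate_experiment(self._params(n_molecules=3))
        many = simulate_experiment(self._params(n_molecules=5))
        for a, b in zip(few, many):
            assert np.array_equal(a.donor, b.donor)

    def test_ground_truth_attached(self):
        traces = simulate_experiment(self._params())
        assert all(tr.ground_truth is not None for tr in traces)
        assert all(tr.ground_truth.total_duration == 20.0 for tr in traces)

    def test_donor_only_fraction(self):
        traces = simulate_experiment(
            self._params(
                n_molecules=200,
                donor_only_fraction=0.5,
                emission_model=EmissionModel(
                    mean_fret={"M0": 0.7, "M1": 0.5, "M2": 0.3},
                    noise_sd=0.0,
                    bleach_rate=0.0,
                ),
            )
        )
        dark = sum(1 for tr in traces if np.allclose(tr.acceptor, 0.0))
        assert abs(dark - 100) < 3 * np.sqrt(200 * 0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            self._params(n_molecules=0)
        with pytest.raises(ValueError):
            self._params(frame_time=-0.1)
        with pytest.raises(ValueError):
            self._params(trace_duration=0.01)
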