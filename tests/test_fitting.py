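import itertools

import numpy as np
import pytest

import asersim as a
from asersim.errors import AlignmentError, GenomeError, GridOverflowError
from asersim.fitting import FREE_PARAMS, minmax_unit


def _target(time, d, s, ax):
    return a.TargetTraces(time, np.asarray(d, float), np.asarray(s, float),
                          np.asarray(ax, float))


class TestFitnessDL:
    def test_identity_is_zero(self, fitness_grid_time, noiseless_target):
        assert a.fitness_dL(noiseless_target, noiseless_target) == 0.0

    def test_constant_offset_closed_form(self, fitness_grid_time):
        t = fitness_grid_time
        base = np.linspace(0, 1, t.size)
        tgt = _target(t, base, base, base)
        sim = _target(t, base + 0.01, base + 0.01, base + 0.01)
        # 3 regions x 1201 samples x 0.01
        assert a.fitness_dL(tgt, sim) == pytest.approx(36.03)

    def test_single_region_offset(self, fitness_grid_time):
        t = fitness_grid_time
        z = np.zeros(t.size)
        tgt = _target(t, z, z, z)
        sim = _target(t, z + 0.5, z, z)
        assert a.fitness_dL(tgt, sim) == pytest.approx(600.5)

    def test_mismatched_grids_raise(self, fitness_grid_time):
        t = fitness_grid_time
        z = np.zeros(t.size)
        tgt = _target(t, z, z, z)
        sim = _target(t[:-1], z[:-1], z[:-1], z[:-1])
        with pytest.raises(AlignmentError):
            a.fitness_dL(tgt, sim)


class TestGridSpec:
    def test_default_grid_cardinality(self):
        spec = a.GridSpec()
        assert spec.size == 1_200_000
        assert [spec.axis_values(n).size for n in FREE_PARAMS] == [100, 20, 20, 30]

    def test_inclusive_endpoint_convention(self):
        spec = a.GridSpec(endpoint="inclusive")
        assert spec.size == 101 * 21 * 21 * 31  # 1,380,771

    def test_pilot_grid_cardinality(self):
        assert a.GridSpec.pilot().size == 8_000_000

    def test_single_value_axes(self):
        spec = a.GridSpec(D=(1.0, 2.0, 1.0), Y_s=(0.0, 0.1, 0.1),
                          Y_a=(0.0, 0.1, 0.1), A=(0.0, 0.01, 0.01))
        assert spec.size == 1
        assert list(a.enumerate_grid(spec)) == [(1.0, 0.0, 0.0, 0.0)]

    def test_enumeration_order_and_cap(self):
        spec = a.GridSpec(D=(0.0, 0.2, 0.1), Y_s=(0.0, 0.2, 0.1),
                          Y_a=(0.0, 0.1, 0.1), A=(0.0, 0.01, 0.01))
        combos = list(a.enumerate_grid(spec))
        assert combos == sorted(combos)  # lexicographic in axis order
        assert len(combos) == spec.size == 4
        with pytest.raises(GridOverflowError):
            list(a.enumerate_grid(a.GridSpec(), cap=1000))

    def test_snap_to_grid_steps(self):
        spec = a.GridSpec()
        assert spec.snap((7.098, 0.302, -0.199, 0.0306)) == pytest.approx(
            (7.1, 0.3, -0.2, 0.03))


class TestDecodeGenome:
    def test_range_extremes(self):
        spec = a.GridSpec()
        lo = a.decode_genome("0" * 32, spec)
        hi = a.decode_genome("1" * 32, spec)
        assert lo == pytest.approx((0.0, -1.0, -1.0, 0.0))
        assert hi == pytest.approx((10.0, 1.0, 1.0, 0.3))

    def test_linear_quantization(self):
        bits = "10000000" + "0" * 24  # D field = 128
        d, *_ = a.decode_genome(bits, a.GridSpec())
        assert d == pytest.approx(10 * 128 / 255)  # ~5.0196

    def test_bad_genomes_rejected(self):
        with pytest.raises(GenomeError):
            a.decode_genome("01" * 8, a.GridSpec())
        with pytest.raises(GenomeError):
            a.decode_genome("2" * 32, a.GridSpec())


@pytest.fixture(scope="module")
def tiny_grid():
    # 3^4 grid bracketing the reference parameters
    return a.GridSpec(D=(6.9, 7.5, 0.2), Y_s=(0.1, 0.4, 0.1),
                      Y_a=(-0.3, 0.0, 0.1), A=(0.02, 0.05, 0.01))


class TestBruteForce:
    def test_matches_independent_double_loop(self, tiny_grid, noiseless_target,
                                             step_proto):
        """The BF ranking must agree with a from-scratch nested-loop sweep
        that simulates and scores each point independently."""
        result = a.brute_force_search(tiny_grid, noiseless_target, step_proto,
                                      summary_n=5)
        tgt = noiseless_target.scaled().stacked()
        oracle = []
        axes = [tiny_grid.axis_values(n) for n in FREE_PARAMS]
        for D, Ys, Ya, A in itertools.product(*axes):
            sim = a.integrate(a.ModelParameters(D=D, Y_s=Ys, Y_a=Ya, A=A),
                              step_proto)
            dl = sum(np.abs(tgt[r] - minmax_unit(sim.stacked()[r])).sum()
                     for r in range(3))
            oracle.append(((D, Ys, Ya, A), dl))
        oracle.sort(key=lambda kv: kv[1])
        assert len(result.ranking) == len(oracle) == 81
        for fit, (params, dl) in zip(result.ranking, oracle):
            assert fit.as_tuple() == pytest.approx(params)
            assert fit.dL == pytest.approx(dl, abs=1e-9)

    def test_recovers_in_grid_generating_point(self, tiny_grid, step_proto):
        truth = (7.1, 0.3, -0.2, 0.03)
        target = a.TargetTraces.from_simulated(
            a.integrate(a.ModelParameters(D=truth[0], Y_s=truth[1],
                                          Y_a=truth[2], A=truth[3]), step_proto))
        result = a.brute_force_search(tiny_grid, target, step_proto, summary_n=5)
        assert result.best.as_tuple() == pytest.approx(truth)
        assert result.best.dL < 1e-3

    def test_best_worst_summary_ordering(self, tiny_grid, noiseless_target,
                                         step_proto):
        result = a.brute_force_search(tiny_grid, noiseless_target, step_proto,
                                      summary_n=10)
        dls = [r.dL for r in result.ranking]
        assert dls == sorted(dls)
        assert np.mean(dls[:10]) <= np.mean(dls[-10:])
        assert set(result.best_summary.index) >= set(FREE_PARAMS)


class TestPilotScreen:
    def test_threshold_extremes(self, tiny_grid, noiseless_target, step_proto):
        none = a.pilot_screen(tiny_grid, noiseless_target, step_proto,
                              dL_threshold=-1.0)
        assert none["n_passing"] == 0
        everything = a.pilot_screen(tiny_grid, noiseless_target, step_proto,
                                    dL_threshold=float("inf"))
        assert everything["n_passing"] == tiny_grid.size

    def test_histogram_peaks_at_generating_values(self, tiny_grid,
                                                  noiseless_target, step_proto):
        """With a tight threshold the passing combinations concentrate on the
        generating parameter values."""
        screen = a.pilot_screen(tiny_grid, noiseless_target, step_proto,
                                dL_threshold=10.0)
        assert screen["n_passing"] > 0
        for name, truth in (("D", 7.1), ("A", 0.03)):
            values, counts = screen["histograms"][name]
            at_truth = counts[np.argmin(np.abs(values - truth))]
            assert at_truth == counts.max() > 0


class TestGA:
    SMALL = dict(population=10, generations=8, restart_stall=None)

    def test_seeded_runs_are_identical(self, noiseless_target, step_proto):
        r1 = a.ga_optimize(a.GAConfig(seed=5, **self.SMALL), a.GridSpec(),
                           noiseless_target, step_proto)
        r2 = a.ga_optimize(a.GAConfig(seed=5, **self.SMALL), a.GridSpec(),
                           noiseless_target, step_proto)
        assert r1.best.params == r2.best.params
        assert r1.best.dL == r2.best.dL
        np.testing.assert_array_equal(r1.trajectory, r2.trajectory)

    def test_best_so_far_trajectory_monotone(self, noiseless_target, step_proto):
        res = a.ga_optimize(a.GAConfig(seed=2, population=20, generations=15,
                                       restart_stall=5), a.GridSpec(),
                            noiseless_target, step_proto)
        assert np.all(np.diff(res.trajectory) <= 1e-15)

    def test_evaluation_budget_is_population_times_generations(
            self, noiseless_target, step_proto):
        res = a.ga_optimize(a.GAConfig(seed=1, **self.SMALL), a.GridSpec(),
                            noiseless_target, step_proto)
        assert res.n_evaluations == 10 * 8
        assert a.GAConfig().total_evaluations == 50_000

    def test_config_validation(self):
        with pytest.raises(GenomeError):
            a.GAConfig(population=9)
        with pytest.raises(GenomeError):
            a.GAConfig(p_crossover=1.5)


class TestSummaries:
    def test_single_result_sd_zero(self):
        r = a.FitResult({"D": 7.1, "Y_s": 0.3, "Y_a": -0.2, "A": 0.03}, 1.0, "x")
        table = a.summarize_runs([r])
        assert table.loc["D", "mean"] == 7.1
        assert (table["sd"] == 0.0).all()

    def test_symmetric_pair_mean(self):
        r1 = a.FitResult({"D": 7.0, "Y_s": 0.2, "Y_a": -0.3, "A": 0.02}, 1.0, "x")
        r2 = a.FitResult({"D": 7.2, "Y_s": 0.4, "Y_a": -0.1, "A": 0.04}, 2.0, "y")
        table = a.summarize_runs([r1, r2])
        assert table.loc["D", "mean"] == pytest.approx(7.1)
        assert table.loc["D", "sd"] == pytest.approx(np.std([7.0, 7.2], ddof=1))
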