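"""Population plans, worker invariance, config execution."""

import json

import numpy as np
import pytest

from nervesim.configio import config_hash, load_result, run_config, save_result
from nervesim.errors import ConfigError
from nervesim.fibers import UnmyelinatedFiber
from nervesim.orchestrate import SimulationPlan, simulate_plan
from nervesim.population import AxonPopulation
from nervesim.recording import Recorder
from nervesim.solver import Clamp, SimConfig, simulate_fiber
from nervesim.stimulus import make_pulse


def _tiny_population(n=4):
    rng = np.random.default_rng(0)
    diam = rng.uniform(6.0, 12.0, n)
    y = np.linspace(-20.0, 20.0, n)
    return AxonPopulation(np.ones(n, dtype=bool), diam, y,
                          np.zeros(n))


def _plan(pop, workers=1, recorder=None):
    return SimulationPlan(
        population=pop, fiber_length=8000.0,
        config=SimConfig(dt=0.005, t_sim=1.0),
        clamps=(Clamp("current", 0, make_pulse(0.05, 0.01, 0.1)),),
        recorder=recorder, workers=workers, seed=0,
        keep_results=True)


class TestSimulatePlan:
    def test_empty_population_gives_zero_aggregates(self):
        pop = AxonPopulation(np.zeros(0, dtype=bool), np.zeros(0),
                             np.zeros(0), np.zeros(0))
        out = simulate_plan(SimulationPlan(population=pop,
                                           fiber_length=1000.0,
                                           config=SimConfig(t_sim=0.1)))
        assert out["n_fibers"] == 0 and out["n_recruited"] == 0
        assert out["ecap"] is None

    def test_suprathreshold_broadcast_recruits_all(self):
        out = simulate_plan(_plan(_tiny_population()))
        assert out["n_recruited"] == out["n_fibers"] == 4

    def test_worker_count_invariance(self):
        pop = _tiny_population(6)
        rec = Recorder([(4000.0, 100.0, 0.0)], "endoneurium")
        serial = simulate_plan(_plan(pop, workers=1, recorder=rec))
        parallel = simulate_plan(_plan(pop, workers=3, recorder=rec))
        for r1, r2 in zip(serial["results"], parallel["results"]):
            assert np.array_equal(r1.V, r2.V)
        assert np.array_equal(serial["ecap"], parallel["ecap"])
        assert serial["n_recruited"] == parallel["n_recruited"]

    def test_clamp_subset_limits_recruitment(self):
        pop = _tiny_population(4)
        plan = _plan(pop)
        plan.clamp_subset = [0, 2]
        out = simulate_plan(plan)
        assert out["n_recruited"] == 2
        assert list(out["detected"]) == [True, False, True, False]


class TestResultIO:
    def test_round_trip(self, tmp_path):
        fiber = UnmyelinatedFiber(1.0, length=500.0, n_compartments=12)
        r = simulate_fiber(fiber,
                           clamps=[Clamp("current", 0,
                                         make_pulse(0.1, 0.02, 0.2))],
                           config=SimConfig(dt=0.01, t_sim=1.0,
                                            record_Imem=True,
                                            record_gates=True))
        save_result(r, tmp_path / "res")
        back = load_result(tmp_path / "res")
        assert back.t == pytest.approx(r.t)
        assert back.V == pytest.approx(r.V, abs=1e-6)
        assert back.I_mem == pytest.approx(r.I_mem, abs=1e-9)
        assert set(back.gates) == set(r.gates)


class TestRunConfig:
    def test_missing_task_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            run_config({}, tmp_path)

    def test_missing_keys_named_in_error(self, tmp_path):
        with pytest.raises(ConfigError) as err:
            run_config({"task": "simulate-axon"}, tmp_path)
        assert "fiber" in err.value.keys or "fiber" in str(err.value)

    def test_simulate_axon_round_trip_reproducible(self, tmp_path):
        config = {
            "task": "simulate-axon",
            "fiber": {"type": "unmyelinated", "diameter": 1.0,
                      "length": 500.0, "n_compartments": 12},
            "sim": {"dt": 0.01, "t_sim": 0.5},
            "clamps": [{"kind": "current", "compartment": 0,
                        "stimulus": {"kind": "pulse", "start": 0.1,
                                     "amplitude": 0.02,
                                     "duration": 0.2}}],
        }
        s1 = run_config(config, tmp_path / "a")
        s2 = run_config(config, tmp_path / "b")
        assert s1["v_max"] == s2["v_max"]
        r1 = load_result(tmp_path / "a" / "axon")
        r2 = load_result(tmp_path / "b" / "axon")
        assert np.array_equal(r1.V, r2.V)
        # provenance embeds the config hash
        summary = json.loads((tmp_path / "a" / "summary.json").read_text())
        assert summary["provenance"]["config_hash"] == config_hash(config)

    def test_pack_task_writes_population(self, tmp_path):
        config = {"task": "pack", "seed": 4,
                  "population": {"n": 40, "myelinated_fraction": 1.0}}
        summary = run_config(config, tmp_path)
        assert (tmp_path / "population.csv").exists()
        assert summary["fitted_radius_um"] > 0

    def test_config_hash_canonical(self):
        a = {"x": 1, "y": [1, 2]}
        b = {"y": [1, 2], "x": 1}
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash({"x": 2, "y": [1, 2]})


class TestBlockTraceConfig:
    def test_khz_block_trace_config_runs_end_to_end(self, tmp_path):
        """A 51-node myelinated fiber with a point source over the
        central node (0.2 S/m), an intracellular test clamp at the
        first node, and a kHz sine burst runs through the config layer
        and produces finite voltage and gating traces."""
        from nervesim.fibers import MyelinatedFiber
        fiber = MyelinatedFiber(10.0, n_nodes=51)
        geom = fiber.build()
        center_x = float(geom.x[geom.node_index[25]])
        config = {
            "task": "simulate-axon",
            "fiber": {"type": "myelinated", "diameter": 10.0,
                      "n_nodes": 51},
            "sim": {"dt": 0.002, "t_sim": 4.0, "record_gates": True},
            "context": {
                "material": {"sigma": 0.2, "name": "block-medium"},
                "sources": [{
                    "electrode": {"id": 0,
                                  "position": [center_x, 1000.0, 0.0]},
                    "stimulus": {"kind": "sine", "start": 3.0,
                                 "freq": 4.0, "amplitude_pp": 800.0,
                                 "duration": 1.0},
                }],
            },
            "clamps": [{"kind": "current", "compartment": 0,
                        "stimulus": {"kind": "pulse", "start": 0.5,
                                     "amplitude": 0.02,
                                     "duration": 0.1}}],
            "output_downsample": 10,
        }
        summary = run_config(config, tmp_path)
        assert np.isfinite(summary["v_max"])
        back = load_result(tmp_path / "axon")
        assert back.V.shape[1] == 51 + 50 * 10
        # the test spike is visible somewhere along the fiber
        assert back.V.max() > 0.0


class TestCLI:
    def test_pack_command(self, tmp_path):
        from click.testing import CliRunner
        from nervesim.cli import main
        out_csv = tmp_path / "pop.csv"
        result = CliRunner().invoke(
            main, ["pack", "--n", "20", "--seed", "3",
                   "--out", str(out_csv)])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["n"] == 20
        assert out_csv.exists()

    def test_ecap_fit_command(self, tmp_path):
        import numpy as np
        from click.testing import CliRunner
        from nervesim.cli import main
        t = np.linspace(0, 4, 801)
        lat = np.array([0.5, 1.0, 1.5, 2.0])
        traces = np.zeros((4, t.size))
        for i, l in enumerate(lat):
            traces[i, np.argmin(np.abs(t - l))] = l ** -2.0
        csv = tmp_path / "ecap.csv"
        np.savetxt(csv, np.column_stack([t, traces.T]), delimiter=",")
        result = CliRunner().invoke(
            main, ["ecap-fit", str(csv), "--include-first"])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["slope"] == pytest.approx(-2.0)
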