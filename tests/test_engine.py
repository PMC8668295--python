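"""Network integration: determinism, causality, convergence, spike handling."""

import numpy as np
import pytest

from dgnet import SimConfig, build_stimulation, detect_spikes, run_simulation
from dgnet.config import STIMULUS_SYNAPSES
from dgnet.exceptions import ConfigurationError, SimulationError
from dgnet.fixtures import mini_network, mini_protocol


@pytest.fixture(scope="module")
def mini_run(cell_params):
    net = mini_network(seed=3)
    rng = np.random.default_rng([3, 11])
    stim = build_stimulation(mini_protocol(), net, rng)
    return net, stim


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        assert detect_spikes(np.full(1000, -60.0), 0.1) == []

    def test_single_crossing_interpolated(self):
        dt = 0.1
        t = np.arange(0, 30, dt)
        v = np.full_like(t, -60.0)
        # linear ramp crossing 0 mV exactly at 14.0 ms
        ramp = (t >= 13.0) & (t <= 15.0)
        v[ramp] = -60 + 60 * (t[ramp] - 13.0)
        times = detect_spikes(v, dt)
        assert times == pytest.approx([14.0], abs=1e-9)

    def test_two_close_crossings_merge(self):
        dt = 0.1
        v = np.full(300, -60.0)
        v[100:103] = 10.0  # crossing at ~10 ms
        v[105:108] = 10.0  # second crossing 0.5 ms later
        assert len(detect_spikes(v, dt, refractory=2.0)) == 1
        assert len(detect_spikes(v, dt, refractory=0.1)) == 2


class TestValidation:
    def test_invalid_time_grid_rejected(self, mini_run, cell_params):
        net, stim = mini_run
        with pytest.raises(ConfigurationError):
            run_simulation(net, stim, SimConfig(dt=0.0), cell_params=cell_params)
        with pytest.raises(ConfigurationError):
            run_simulation(net, stim, SimConfig(duration=0.0), cell_params=cell_params)
        with pytest.raises(ConfigurationError):
            run_simulation(net, stim, SimConfig(duration=10.05), cell_params=cell_params)

    def test_missing_synapse_params_fail_before_integration(self, mini_run, cell_params):
        net, stim = mini_run
        with pytest.raises(ConfigurationError, match="GC->"):
            run_simulation(net, stim, SimConfig(), synapse_table={},
                           cell_params=cell_params)

    def test_numerical_abort_names_cell_and_time(self, mini_run, cell_params):
        net, stim = mini_run
        # an absurdly low abort ceiling turns the first spike into an abort
        with pytest.raises(SimulationError, match="diverged"):
            run_simulation(net, stim, SimConfig(abort_v=20.0), cell_params=cell_params)


class TestDynamics:
    def test_no_stimulation_means_empty_raster(self, mini_run, cell_params):
        net, _ = mini_run
        res = run_simulation(net, [], SimConfig(seed=3), cell_params=cell_params)
        assert res.raster == []

    def test_identical_seed_gives_bit_identical_raster(self, mini_run, cell_params):
        net, stim = mini_run
        a = run_simulation(net, stim, SimConfig(seed=3), cell_params=cell_params)
        b = run_simulation(net, stim, SimConfig(seed=3), cell_params=cell_params)
        assert a.raster == b.raster
        for key in a.traces:
            assert np.array_equal(a.traces[key], b.traces[key])

    def test_causality_no_spike_before_stimulus_delay(self, mini_run, cell_params):
        net, stim = mini_run
        res = run_simulation(net, stim, SimConfig(seed=3), cell_params=cell_params)
        onset = 5.0
        min_delay = min(p.delay for p in STIMULUS_SYNAPSES.values())
        assert res.n_spikes > 0
        assert min(t for _, t in res.raster) >= onset + min_delay

    def test_halving_dt_shifts_spikes_under_half_ms(self, mini_run, cell_params):
        net, stim = mini_run
        a = run_simulation(net, stim, SimConfig(seed=3, dt=0.1), cell_params=cell_params)
        b = run_simulation(net, stim, SimConfig(seed=3, dt=0.05), cell_params=cell_params)
        ra, rb = sorted(a.raster), sorted(b.raster)
        assert [g for g, _ in ra] == [g for g, _ in rb]
        assert max(abs(ta - tb) for (_, ta), (_, tb) in zip(ra, rb)) < 0.5

    def test_trace_length_and_window(self, mini_run, cell_params):
        net, stim = mini_run
        cfg = SimConfig(seed=3, duration=50.0, dt=0.1)
        res = run_simulation(net, stim, cfg, cell_params=cell_params)
        for v in res.traces.values():
            assert len(v) == 501
        assert all(0 <= t <= 50.0 for _, t in res.raster)


class TestNetworkProperties:
    def test_healthy_basket_cells_fire_only_from_direct_input(self, healthy_run):
        net, stim, res = healthy_run
        stim_ids = {s.cell_id for s in stim}
        for g in net.populations["BC"].global_ids():
            n = len(res.spikes_of(int(g)))
            assert n == (1 if g in stim_ids else 0)

    def test_pathological_basket_cells_receive_network_drive(
        self, healthy_run, pathological_run
    ):
        # in the healthy run at least one unstimulated BC never leaves rest;
        # with sprouting every unstimulated BC is strongly depolarized by
        # granule-cell barrages even though it may stay subthreshold
        for label, (net, stim, res), expect_drive in (
            ("healthy", healthy_run, False),
            ("pathological", pathological_run, True),
        ):
            stim_ids = {s.cell_id for s in stim}
            rest = -60.0
            depol = [
                float(res.traces[f"{net.cell_label(g)}:soma"].max()) - rest
                for g in net.populations["BC"].global_ids()
                if g not in stim_ids
            ]
            if expect_drive:
                assert min(depol) > 5.0
            else:
                assert min(depol) < 1.5

    def test_mossy_cell_spikes_are_delayed_relative_to_granule_cells(self, healthy_run):
        net, stim, res = healthy_run
        stim_mcs = [s.cell_id for s in stim if s.cell_type == "MC"]
        stim_gcs = [s.cell_id for s in stim if s.cell_type == "GC"]
        mc_first = min(res.first_spike(g) for g in stim_mcs)
        gc_first = min(res.first_spike(g) for g in stim_gcs)
        assert mc_first > 0 and gc_first > 0

    def test_raster_and_trace_io(self, tmp_path, healthy_run):
        _, _, res = healthy_run
        raster_path = tmp_path / "raster.tsv"
        traces_path = tmp_path / "traces.csv"
        res.write_raster(raster_path)
        res.write_traces(traces_path)
        import pandas as pd

        raster = pd.read_csv(raster_path, sep="\t")
        assert list(raster.columns) == ["cell_id", "time_ms"]
        assert len(raster) == res.n_spikes
        traces = pd.read_csv(traces_path)
        assert traces.columns[0] == "time_ms"
        assert len(traces) == len(res.time)
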