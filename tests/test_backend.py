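"""Backend: worker pools, reference pipelines, hot reload, resilience."""

import numpy as np
import pytest
import yaml

from fxmon import (
    ConfigError,
    Parameters,
    load_config,
    read_dark_file,
    read_run_file,
)
from fxmon.backend import (
    BackendRunner,
    WorkerRole,
    build_catalog,
    dark_pipeline_config,
    diffraction_pipeline_config,
    run_backend,
)
from fxmon.config import PipelineConfig, StageSpec, register_stage
from fxmon.data_sources import SourceSpec
from fxmon.streaming import LocalChannel, MonitorClient


def test_exactly_one_master():
    roles = [WorkerRole(r) for r in range(4)]
    assert sum(r.is_master for r in roles) == 1
    assert roles[0].is_master


class TestDarkPipeline:
    @pytest.mark.parametrize("n_workers", [1, 2, 4])
    def test_dark_average_matches_stack_mean_oracle(
        self, small_dark_run, tmp_path, n_workers
    ):
        out = str(tmp_path / f"dark_w{n_workers}.h5")
        report = run_backend(
            dark_pipeline_config([small_dark_run], out), n_workers=n_workers
        )
        oracle = read_run_file(small_dark_run)["frames"].mean(axis=0, dtype=np.float64)
        dark, n_frames, _ = read_dark_file(out)
        assert n_frames == report.n_events == 60
        assert np.abs(dark - oracle).max() < 1e-9

    def test_empty_run_exits_cleanly(self, small_model, tmp_path):
        from fxmon import RunRecipe, generate_dark_run

        run = str(tmp_path / "empty.h5")
        generate_dark_run(small_model, RunRecipe(0, seed=0), run)
        report = run_backend(dark_pipeline_config([run], str(tmp_path / "d.h5")), 1)
        assert report.n_events == 0
        assert report.dark_path is None  # nothing accumulated, nothing written

    def test_process_executor_matches_serial(self, small_dark_run, tmp_path):
        out_s = str(tmp_path / "serial.h5")
        out_p = str(tmp_path / "proc.h5")
        run_backend(dark_pipeline_config([small_dark_run], out_s), 2, executor="serial")
        run_backend(dark_pipeline_config([small_dark_run], out_p), 2, executor="process")
        a, _, _ = read_dark_file(out_s)
        b, _, _ = read_dark_file(out_p)
        assert np.array_equal(a, b)


class TestDiffractionPipeline:
    def test_missing_dark_file_refused_at_start(self, small_diffraction_run, tmp_path):
        run, _ = small_diffraction_run
        cfg = diffraction_pipeline_config([run], str(tmp_path / "no_such_dark.h5"))
        with pytest.raises(ConfigError, match="dark file"):
            BackendRunner(cfg, n_workers=1)

    def test_recovers_planted_hits_exactly(self, small_model, small_diffraction_run, small_dark_file):
        run, truth = small_diffraction_run
        params = Parameters(
            lit_threshold=small_model.photon_adu / 2, hitscore_threshold=3
        )
        report = run_backend(
            diffraction_pipeline_config([run], small_dark_file, params), 1
        )
        got_hits = {eid for eid, _, hit in report.results if hit}
        expect = {(0, int(i)) for i in np.flatnonzero(truth.is_hit)}
        assert got_hits == expect

    @pytest.mark.parametrize("n_workers", [2, 4])
    def test_worker_count_invariance(
        self, small_diffraction_run, small_dark_file, n_workers
    ):
        """Per-event (hitscore, hit flag) identical for any worker count."""
        run, _ = small_diffraction_run
        cfg = diffraction_pipeline_config([run], small_dark_file)
        base = run_backend(cfg, 1).sorted_results()
        multi = run_backend(cfg, n_workers).sorted_results()
        assert multi == base

    def test_process_executor_same_results(self, small_diffraction_run, small_dark_file):
        run, _ = small_diffraction_run
        cfg = diffraction_pipeline_config([run], small_dark_file)
        serial = run_backend(cfg, 1, executor="serial").sorted_results()
        proc = run_backend(cfg, 3, executor="process").sorted_results()
        assert proc == serial

    def test_crashing_event_logged_and_skipped(self, small_diffraction_run, small_dark_file):
        run, _ = small_diffraction_run

        @register_stage("explode_on_seven")
        def _explode(evt, ctx):
            if evt.event_id[1] == 7:
                raise RuntimeError("boom")

        cfg = diffraction_pipeline_config([run], small_dark_file)
        cfg.stages.insert(0, StageSpec("explode_on_seven"))
        report = run_backend(cfg, 1)
        assert report.n_errors == 1
        assert report.n_events == 50  # every event still consumed
        assert (0, 7) not in {eid for eid, _, _ in report.results}


class TestPlotPublishing:
    def _run_with_client(self, cfg, capacity=5000):
        chan = LocalChannel(queue_size=capacity)
        client = MonitorClient(chan.subscriber())
        runner = BackendRunner(cfg, n_workers=1, channel=chan)
        runner._announce()
        client.poll()
        bufs = {name: client.subscribe(name, capacity) for name in client.catalog.names()}
        runner.run()
        client.poll()
        return client, bufs

    def test_catalog_has_exactly_the_three_monitoring_plots(
        self, small_diffraction_run, small_dark_file
    ):
        run, _ = small_diffraction_run
        cfg = diffraction_pipeline_config([run], small_dark_file)
        cat = build_catalog(cfg, cfg.parameters)
        assert cat.names() == ["histogram", "hitscore", "hit image"]
        kinds = {e.source_name: e.plot_kind for e in cat.entries}
        assert kinds == {
            "histogram": "histogram",
            "hitscore": "history",
            "hit image": "image",
        }
        # threshold markers ride along as plot instructions
        by_name = {e.source_name: e.instructions for e in cat.entries}
        assert by_name["histogram"].vline == cfg.parameters.lit_threshold
        assert by_name["hitscore"].hline == float(cfg.parameters.hitscore_threshold)

    def test_hit_images_published_once_per_planted_hit(
        self, small_model, small_diffraction_run, small_dark_file
    ):
        run, truth = small_diffraction_run
        params = Parameters(lit_threshold=small_model.photon_adu / 2, hitscore_threshold=3)
        cfg = diffraction_pipeline_config([run], small_dark_file, params)
        _, bufs = self._run_with_client(cfg)
        assert len(bufs["hit image"]) == int(truth.is_hit.sum())
        assert len(bufs["hitscore"]) == 50  # every event, hit or not
        assert len(bufs["histogram"]) == 50

    def test_no_hits_means_no_hit_images(self, small_model, small_dark_run, small_dark_file, tmp_path):
        # a dark run processed by the diffraction pipeline has no hits
        cfg = diffraction_pipeline_config(
            [small_dark_run],
            small_dark_file,
            Parameters(lit_threshold=small_model.photon_adu / 2, hitscore_threshold=3),
        )
        _, bufs = self._run_with_client(cfg)
        assert len(bufs["hit image"]) == 0


class TestReload:
    def _write_params(self, path, hitscore_threshold=3, lit_threshold=60.0):
        path.write_text(
            yaml.safe_dump(
                {"lit_threshold": lit_threshold, "hitscore_threshold": hitscore_threshold}
            )
        )

    def _two_phase(self, run, dark_file, params_file, n_events_phase1, new_threshold):
        cfg = diffraction_pipeline_config(
            [run], dark_file,
            parameters=Parameters(lit_threshold=60.0, hitscore_threshold=3),
            parameters_path=str(params_file),
        )
        runner = BackendRunner(cfg, n_workers=2)
        runner.run(max_events=n_events_phase1)
        self._write_params(params_file, hitscore_threshold=new_threshold)
        runner.request_reload()
        return runner.run()

    def test_midrun_change_equals_two_independent_runs(
        self, small_diffraction_run, small_dark_file, tmp_path
    ):
        run, _ = small_diffraction_run
        params_file = tmp_path / "params.yaml"
        self._write_params(params_file, hitscore_threshold=3)
        report = self._two_phase(run, small_dark_file, params_file, 20, 10_000)

        old = run_backend(
            diffraction_pipeline_config([run], small_dark_file, Parameters(60.0, 3)), 1
        )
        new = run_backend(
            diffraction_pipeline_config([run], small_dark_file, Parameters(60.0, 10_000)), 1
        )
        old_map = {eid: (s, h) for eid, s, h in old.results}
        new_map = {eid: (s, h) for eid, s, h in new.results}
        for eid, score, hit in report.results:
            expect = old_map[eid] if eid[1] < 20 else new_map[eid]
            assert (score, hit) == expect

    def test_reload_with_identical_file_changes_nothing(
        self, small_diffraction_run, small_dark_file, tmp_path
    ):
        run, _ = small_diffraction_run
        params_file = tmp_path / "params.yaml"
        self._write_params(params_file)
        report = self._two_phase(run, small_dark_file, params_file, 20, 3)
        plain = run_backend(
            diffraction_pipeline_config([run], small_dark_file, Parameters(60.0, 3)), 1
        )
        assert report.sorted_results() == plain.sorted_results()

    def test_malformed_parameters_keep_old_values(
        self, small_diffraction_run, small_dark_file, tmp_path
    ):
        run, _ = small_diffraction_run
        params_file = tmp_path / "params.yaml"
        self._write_params(params_file)
        cfg = diffraction_pipeline_config(
            [run], small_dark_file,
            parameters=Parameters(60.0, 3),
            parameters_path=str(params_file),
        )
        runner = BackendRunner(cfg, n_workers=1)
        runner.run(max_events=10)
        params_file.write_text("lit_threshold: [not, a, number]")
        runner.request_reload()
        report = runner.run()
        plain = run_backend(
            diffraction_pipeline_config([run], small_dark_file, Parameters(60.0, 3)), 1
        )
        assert report.sorted_results() == plain.sorted_results()

    def test_unknown_parameter_rejected(self, tmp_path):
        from fxmon import load_parameters

        p = tmp_path / "p.yaml"
        p.write_text("hitscore_threshold: 3\nhit_threshold_typo: 9\n")
        with pytest.raises(ConfigError, match="hit_threshold_typo"):
            load_parameters(str(p))


class TestConfigFiles:
    def test_yaml_config_round_trip_and_run(
        self, small_diffraction_run, small_dark_file, tmp_path
    ):
        run, truth = small_diffraction_run
        params = tmp_path / "params.yaml"
        params.write_text("lit_threshold: 60.0\nhitscore_threshold: 3\n")
        conf = tmp_path / "conf.yaml"
        conf.write_text(
            yaml.safe_dump(
                {
                    "source": {"mode": "file_run", "files": [run]},
                    "stages": [
                        {"name": "dark_subtract", "dark_file": small_dark_file},
                        "common_mode",
                        "histogram",
                        "hitscore",
                        "classify",
                    ],
                    "outputs": [
                        {"name": "hitscore", "kind": "history", "record": "analysis/hitscore"},
                    ],
                    "parameters": "params.yaml",
                }
            )
        )
        cfg = load_config(str(conf))
        assert cfg.parameters.hitscore_threshold == 3
        report = run_backend(cfg, 2)
        assert report.n_events == 50
        assert report.n_hits == int(truth.is_hit.sum())

    def test_unknown_stage_rejected_by_name(self, tmp_path):
        conf = tmp_path / "conf.yaml"
        conf.write_text(
            yaml.safe_dump(
                {
                    "source": {"mode": "file_run", "files": ["x.h5"]},
                    "stages": ["no_such_stage"],
                }
            )
        )
        with pytest.raises(ConfigError, match="no_such_stage"):
            load_config(str(conf))

    def test_config_without_source_rejected(self, tmp_path):
        conf = tmp_path / "conf.yaml"
        conf.write_text("stages: []\n")
        with pytest.raises(ConfigError, match="source"):
            load_config(str(conf))


class TestScaling:
    def test_throughput_does_not_degrade_with_workers(
        self, model, tmp_path, dark_file_1k
    ):
        """Smoke property: adding workers never reduces processing capacity.

        Wall-clock comparison uses best-of-3 per worker count and a 5%
        scheduling-noise margin; no absolute rates are asserted.
        """
        from fxmon import RunRecipe, generate_diffraction_run

        run = str(tmp_path / "bench.h5")
        generate_diffraction_run(
            model, RunRecipe(240, hit_fraction=0.1, seed=31), run
        )
        cfg = diffraction_pipeline_config([run], dark_file_1k)
        best = {}
        for w in (1, 2, 4):
            best[w] = max(
                run_backend(cfg, w, executor="process").events_per_second
                for _ in range(3)
            )
        assert best[2] >= 0.95 * best[1]
        assert best[4] >= 0.95 * best[2]
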