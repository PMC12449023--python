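"""Tabular I/O round trips and the command-line interface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from nlrl.cli import main
from nlrl.environments import OutcomeSchedule, gen_random_env
from nlrl.io import read_table, write_table
from nlrl.models import ModelParams, run_model


class TestIO:
    def test_trace_round_trip(self, tmp_path):
        sched = gen_random_env(seed=1)
        tr = run_model(sched, ModelParams(model_id="RW", eta0=0.32))
        path = tmp_path / "trace.csv"
        write_table(tr.to_frame(), path, kind="trace", meta={"seed": 1})
        df, meta = read_table(path, kind="trace")
        assert meta["seed"] == "1"
        assert np.allclose(df["p"], tr.p[:-1])
        assert np.allclose(df["eta"], tr.eta)

    def test_schedule_round_trip(self, tmp_path):
        sched = gen_random_env(seed=2, n_switches=3)
        path = tmp_path / "sched.csv"
        write_table(sched.to_frame(), path, kind="schedule", meta={"seed": 2})
        df, _ = read_table(path, kind="schedule")
        back = OutcomeSchedule.from_frame(df)
        assert np.allclose(back.outcomes, sched.outcomes)
        assert np.array_equal(back.switch_points, sched.switch_points)

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"trial": [1], "outcome": [0.5]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="pe_signed"):
            read_table(path, kind="trace")

    def test_decimal_handling_is_locale_independent(self, tmp_path):
        path = tmp_path / "dec.csv"
        write_table(pd.DataFrame({"x": [0.125, 1e-8]}), path)
        text = path.read_text()
        assert "0.125" in text          # dot decimal separator, never comma
        df, _ = read_table(path)
        assert df["x"].iloc[0] == 0.125 and df["x"].iloc[1] == 1e-8


class TestCLI:
    def test_simulate_env_factorial_writes_1500_rows(self, tmp_path):
        out = tmp_path / "env.csv"
        res = CliRunner().invoke(main, ["simulate-env", "--kind", "factorial",
                                        "--seed", "7", "--out", str(out)])
        assert res.exit_code == 0, res.output
        df, meta = read_table(out, kind="schedule")
        assert len(df) == 1500
        assert meta["seed"] == "7"
        assert "config_hash" in meta

    def test_fixtures_deterministic(self, tmp_path):
        r = CliRunner()
        for d in ("a", "b"):
            res = r.invoke(main, ["fixtures", "--outdir", str(tmp_path / d),
                                  "--seed", "3"])
            assert res.exit_code == 0, res.output
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_fit_missing_file_exits_2(self, tmp_path):
        res = CliRunner().invoke(main, ["fit", "--records", str(tmp_path / "no.csv"),
                                        "--model", "RW", "--seed", "1",
                                        "--out", str(tmp_path / "out.csv")])
        assert res.exit_code == 2

    def test_run_model_over_schedule(self, tmp_path):
        r = CliRunner()
        env = tmp_path / "env.csv"
        r.invoke(main, ["simulate-env", "--kind", "random", "--seed", "4",
                        "--out", str(env)])
        out = tmp_path / "trace.csv"
        res = r.invoke(main, ["run-model", "--schedule", str(env), "--model",
                              "EXPLOG", "--params", "delta=0.83,lam=1.45",
                              "--out", str(out)])
        assert res.exit_code == 0, res.output
        df, _ = read_table(out, kind="trace")
        assert len(df) == 60

    def test_fit_and_compare_pipeline(self, tmp_path):
        r = CliRunner()
        # two synthetic subjects, two models each
        from nlrl.choice import ChoiceParams, records_to_frame, simulate_choices
        from nlrl.environments import gen_magnitude_task
        fits_dir = tmp_path / "fits"
        fits_dir.mkdir()
        for subj in (0, 1):
            sched = gen_magnitude_task(seed=subj)
            recs, _ = simulate_choices(sched, ModelParams(model_id="RW", eta0=0.3),
                                       ChoiceParams(rho=1.0, inv_temp=8.0),
                                       seed=subj, task="magnitude")
            rec_path = tmp_path / f"s{subj}.csv"
            write_table(records_to_frame(recs), rec_path, kind="choices")
            for model in ("RW", "CUBIC"):
                res = r.invoke(main, ["fit", "--records", str(rec_path),
                                      "--model", model, "--task", "magnitude",
                                      "--n-starts", "3", "--seed", "5",
                                      "--subject", f"s{subj}",
                                      "--out", str(fits_dir / f"s{subj}_{model}.csv")])
                assert res.exit_code == 0, res.output
        out = tmp_path / "compare.csv"
        res = r.invoke(main, ["compare", "--fits", str(fits_dir), "--out", str(out)])
        assert res.exit_code == 0, res.output
        df, _ = read_table(out)
        assert set(df["model_id"]) == {"RW", "CUBIC"}
        assert df["xp"].sum() == pytest.approx(1.0)

    def test_pupil_fit_smoke(self, tmp_path):
        from nlrl.pupillometry import synth_pupil_session
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"outcome": rng.random(20),
                               "learning_rate": rng.random(20)})
        sess = synth_pupil_session(design, {"outcome": 1.0, "learning_rate": -0.5},
                                   noise_sd=0.1, blink_rate=0.02, seed=1)
        n = len(sess.samples)
        write_table(pd.DataFrame({"time_ms": np.arange(n) * 2.0,
                                  "pupil": sess.samples,
                                  "is_gap": sess.is_gap.astype(int)}),
                    tmp_path / "samples.csv", kind="pupil_samples",
                    meta={"fs": 500, "seed": 1})
        write_table(pd.DataFrame({"trial": np.arange(20) + 1,
                                  "onset_ms": sess.event_onsets * 2.0,
                                  **{c: design[c] for c in design}}),
                    tmp_path / "events.csv", kind="pupil_events")
        out = tmp_path / "coef.csv"
        res = CliRunner().invoke(main, ["pupil-fit", "--samples",
                                        str(tmp_path / "samples.csv"),
                                        "--events", str(tmp_path / "events.csv"),
                                        "--out", str(out)])
        assert res.exit_code == 0, res.output
        df, _ = read_table(out)
        assert {"outcome", "learning_rate"} <= set(df.columns)
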