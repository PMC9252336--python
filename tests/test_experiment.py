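"""Configuration handling, the experiment harness, the model API and the CLI."""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from pdresnet import (CohortConfig, ConfigError, ExperimentConfig,
                      PDResNetClassifier, load_config, save_config,
                      validate_config)
from pdresnet.cli import gaitgen, main
from pdresnet.config import CohortSource, config_from_dict
from pdresnet.experiment import run_experiment
from pdresnet.model import task_subset


def _tiny_config(task="pd_vs_hc", seed=5, **cohort_overrides):
    coh = CohortConfig(n_pd=40, n_hc=24, n_early=30, n_modadv=10,
                       effect_size=1.5, **cohort_overrides)
    return ExperimentConfig.compact(task=task, seed=seed, cohort=coh, max_epochs=3)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def test_minimal_config_fills_reference_defaults(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("task: pd_vs_hc\n")
    cfg = load_config(path)
    assert cfg.training.initial_lr == 1e-3
    assert cfg.training.batch_size == 23
    assert cfg.training.decay_every == 10
    assert cfg.training.decay_factor == pytest.approx(0.2)
    assert cfg.preprocessing.test_fraction == 0.3
    assert cfg.preprocessing.elevation_side == 117
    assert cfg.preprocessing.image_side == 112
    assert cfg.loss.name == "improved_focal" and cfg.loss.tau == 0.05
    assert cfg.cohort.config.n_pd == 296 and cfg.cohort.config.n_hc == 161


def test_validation_reports_all_invariant_violations_at_once():
    cfg = ExperimentConfig(
        task="nope",
        training=replace(ExperimentConfig().training, batch_size=0),
        cohort=CohortSource(config=CohortConfig(correlation=1.5)),
    )
    with pytest.raises(ConfigError) as err:
        validate_config(cfg)
    message = str(err.value)
    assert "task" in message and "batch_size" in message and "correlation" in message


def test_unknown_keys_are_rejected():
    with pytest.raises(ConfigError, match="unknown"):
        config_from_dict({"task": "pd_vs_hc", "typo_key": 1})
    with pytest.raises(ConfigError, match="unknown"):
        config_from_dict({"training": {"learning_rate": 0.1}})


def test_config_yaml_round_trip(tmp_path):
    cfg = _tiny_config()
    path = tmp_path / "echo.yaml"
    save_config(cfg, path)
    assert load_config(path) == cfg


# ---------------------------------------------------------------------------
# Task subsetting and the model API
# ---------------------------------------------------------------------------


def test_task_subsets_reference_row_counts(default_cohort):
    assert len(task_subset(default_cohort, "pd_vs_hc")) == 457
    assert len(task_subset(default_cohort, "early_vs_modadv")) == 296
    assert len(task_subset(default_cohort, "early_pd_vs_hc")) == 161 + 230 == 391
    with pytest.raises(ValueError):
        task_subset(default_cohort, "other")


@pytest.mark.parametrize("task,n_rows", [
    ("pd_vs_hc", 64), ("early_vs_modadv", 40), ("early_pd_vs_hc", 54),
])
def test_fit_runs_every_task(small_cohort, task, n_rows):
    cfg = _tiny_config(task=task)
    res = PDResNetClassifier(small_cohort, config=cfg).fit()
    assert res.n_input_rows == n_rows
    assert res.confusion.total == res.n_test
    assert res.metrics.auc is not None
    assert len(res.predictions) == res.n_test


def test_results_summary_and_predict(small_cohort):
    res = PDResNetClassifier(small_cohort, config=_tiny_config()).fit()
    text = res.summary()
    assert "PD-ResNet Classification Results" in text
    assert "Accuracy" in text and "Seed: 5" in text
    labels, scores = res.predict(small_cohort.head(5), return_scores=True)
    assert labels.shape == (5,) and np.all((scores >= 0) & (scores <= 1))
    assert np.array_equal(labels, (scores >= 0.5).astype(int))


def test_split_first_mode_keeps_test_free_of_synthetic_rows(small_cohort):
    cfg = _tiny_config()
    cfg = replace(cfg, preprocessing=replace(cfg.preprocessing, split_first=True))
    res = PDResNetClassifier(small_cohort, config=cfg).fit()
    assert not res.predictions.synthetic.any()
    assert res.n_test == round(0.3 * 64)


# ---------------------------------------------------------------------------
# Harness
# ---------------------------------------------------------------------------


def test_run_experiment_writes_reproducible_artifacts(tmp_path):
    cfg = _tiny_config()
    out1, out2 = tmp_path / "a", tmp_path / "b"
    res = run_experiment(cfg, out1)
    run_experiment(cfg, out2)
    for name in ("metrics.json", "history.csv", "roc.csv",
                 "config_echo.yaml", "run.log"):
        assert (out1 / name).exists()
    assert (out1 / "metrics.json").read_bytes() == (out2 / "metrics.json").read_bytes()

    payload = json.loads((out1 / "metrics.json").read_text())
    assert payload["seed"] == 5
    assert payload["task"] == "pd_vs_hc"
    assert payload["n_input_rows"] == 64
    assert payload["metrics"]["accuracy"] == res.metrics.rounded()["accuracy"]
    # history.csv carries the seed header and the per-epoch schedule
    lines = (out1 / "history.csv").read_text().splitlines()
    assert lines[0].startswith("# seed=5")
    hist = pd.read_csv(out1 / "history.csv", comment="#")
    assert len(hist) == res.history.stopped_epoch
    echo = yaml.safe_load((out1 / "config_echo.yaml").read_text())
    assert echo["seed"] == 5 and echo["task"] == "pd_vs_hc"


def test_run_experiment_stage_diagnostics(tmp_path):
    cfg = replace(_tiny_config(), cohort=CohortSource(kind="csv", path=str(tmp_path / "missing.csv")))
    with pytest.raises(RuntimeError, match="stage 'cohort'"):
        run_experiment(cfg)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_gaitgen_cli_writes_cohort(tmp_path):
    out = tmp_path / "cohort.csv"
    result = CliRunner().invoke(gaitgen, [
        "--n-pd", "12", "--n-hc", "8", "--n-early", "9", "--n-modadv", "3",
        "--seed", "3", "-o", str(out)])
    assert result.exit_code == 0, result.output
    table = pd.read_csv(out)
    assert table.shape == (20, 197)


def test_pdresnet_run_cli(tmp_path):
    cfg = _tiny_config()
    cfg_path = tmp_path / "cfg.yaml"
    save_config(cfg, cfg_path)
    outdir = tmp_path / "run"
    result = CliRunner().invoke(main, ["run", "-c", str(cfg_path),
                                       "-o", str(outdir), "--seed", "9"])
    assert result.exit_code == 0, result.output
    assert "PD-ResNet Classification Results" in result.output
    assert json.loads((outdir / "metrics.json").read_text())["seed"] == 9


def test_pdresnet_evaluate_cli(tmp_path):
    scores = tmp_path / "scores.csv"
    pd.DataFrame({"score": [0.9, 0.8, 0.3, 0.6], "label": [1, 1, 0, 0]}
                 ).to_csv(scores, index=False)
    result = CliRunner().invoke(main, ["evaluate", "--scores", str(scores)])
    assert result.exit_code == 0, result.output
    report = json.loads(result.output)
    assert report["accuracy"] == 75.0
    assert report["confusion"] == {"t_hc": 1, "t_pd": 2, "f_hc": 0, "f_pd": 1}
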