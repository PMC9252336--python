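"""Experiment harness: run one task end-to-end and archive its artifacts.

A run directory receives everything needed to reproduce and inspect the
run: ``metrics.json`` (metrics, confusion cells, sizes, seed, package
version), ``history.csv`` (per-epoch curves, seed header), ``roc.csv``,
``config_echo.yaml`` (the fully resolved configuration) and ``run.log``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import ExperimentConfig, save_config, validate_config
from .model import PDResNetClassifier, PDResNetResults

logger = logging.getLogger(__name__)

__all__ = ["run_experiment"]


def _write_artifacts(results: PDResNetResults, config: ExperimentConfig,
                     outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cm = results.confusion
    payload = {
        "task": config.task,
        "seed": config.seed,
        "package_version": __version__,
        "n_input_rows": results.n_input_rows,
        "n_synthetic": results.n_synthetic,
        "n_train": results.n_train,
        "n_test": results.n_test,
        "epochs_run": results.history.stopped_epoch,
        "best_epoch": results.history.best_epoch,
        "metrics": results.metrics.rounded(),
        "confusion": {"t_hc": cm.t_hc, "t_pd": cm.t_pd,
                      "f_hc": cm.f_hc, "f_pd": cm.f_pd},
    }
    (outdir / "metrics.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")

    header = f"# seed={config.seed} package=pdresnet-{__version__}\n"
    (outdir / "history.csv").write_text(
        header + results.history.to_frame().to_csv(index=False))
    (outdir / "roc.csv").write_text(header + results.roc_curve.to_csv(index=False))
    save_config(config, outdir / "config_echo.yaml")


def run_experiment(config: ExperimentConfig,
                   output_dir: str | Path | None = None) -> PDResNetResults:
    """Execute generate/load -> preprocess -> train -> evaluate for one task.

    Returns the fitted :class:`~pdresnet.model.PDResNetResults`; if an
    output directory is configured (argument wins over ``config.output_dir``)
    the artifact files are written there. Re-running an identical config
    rewrites byte-identical ``metrics.json``.
    """
    config = validate_config(config)
    outdir = Path(output_dir or config.output_dir) \
        if (output_dir or config.output_dir) else None

    handler = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        pkg_logger = logging.getLogger("pdresnet")
        pkg_logger.addHandler(handler)
        pkg_logger.setLevel(logging.INFO)

    try:
        logger.info("run_experiment task=%s seed=%d pdresnet=%s",
                    config.task, config.seed, __version__)
        stage = "cohort"
        try:
            model = PDResNetClassifier.from_config(config)
            stage = "fit"
            results = model.fit()
        except Exception as exc:
            raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc
        if outdir is not None:
            _write_artifacts(results, config, outdir)
            logger.info("artifacts written to %s", outdir)
        return results
    finally:
        if handler is not None:
            logging.getLogger("pdresnet").removeHandler(handler)
            handler.close()
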