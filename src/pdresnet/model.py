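"""Model/Results interface to the full gait-classification pipeline.

:class:`PDResNetClassifier` is built from a subject table plus an
:class:`~pdresnet.config.ExperimentConfig`; :meth:`fit` runs the whole
pipeline — task subsetting, SMOTE balancing, stratified 70/30 split,
min-max normalization, polynomial elevation, image conversion and resize,
network training, and test-set evaluation — and returns a
:class:`PDResNetResults` carrying the trained network, the training
history, the confusion matrix, the metric report with AUC, and the
per-sample test predictions, with ``summary()``, ``predict()`` and
plotting helpers.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .config import ExperimentConfig, validate_config
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics, roc_auc
from .network import PDResNet, classify
from .preprocessing import (ElevationSpec, Normalizer, SmoteParams,
                            infer_feature_columns, polynomial_elevate,
                            resize_image, smote_balance, split_train_test)
from .training import TrainHistory, derive_seeds, evaluate_network, train
from .losses import get_loss

logger = logging.getLogger(__name__)

__all__ = ["PDResNetClassifier", "PDResNetResults", "task_subset"]

# Positive-class mapping per task: the label column SMOTE balances on and
# the value read as the positive class (scored by output neuron 1).
_TASK_RULES = {
    "pd_vs_hc": {"label_col": "diagnosis", "positive": "PD"},
    "early_vs_modadv": {"label_col": "severity", "positive": "moderate_advanced"},
    "early_pd_vs_hc": {"label_col": "diagnosis", "positive": "PD"},
}


def task_subset(table: pd.DataFrame, task: str) -> pd.DataFrame:
    """Rows entering a task: all subjects, the PD group, or HC + early PD."""
    if task == "pd_vs_hc":
        out = table
    elif task == "early_vs_modadv":
        out = table[table["diagnosis"] == "PD"]
    elif task == "early_pd_vs_hc":
        out = table[(table["diagnosis"] == "HC") | (table["severity"] == "early")]
    else:
        raise ValueError(f"unknown task {task!r}")
    return out.reset_index(drop=True)


class PDResNetClassifier:
    """Residual-network gait classifier over a per-subject feature table."""

    def __init__(self, table: pd.DataFrame,
                 config: ExperimentConfig | None = None,
                 task: str | None = None):
        config = config or ExperimentConfig()
        if task is not None:
            config = replace(config, task=task)
        self.config = validate_config(config)
        self.table = table.reset_index(drop=True)
        self.task = self.config.task

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "PDResNetClassifier":
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PDResNetClassifier":
        from .cohort import csv_to_cohort
        return cls(csv_to_cohort(path), **kwargs)

    @classmethod
    def from_config(cls, config: ExperimentConfig) -> "PDResNetClassifier":
        """Build the model and its cohort entirely from a config."""
        config = validate_config(config)
        if config.cohort.kind == "synthetic":
            table = generate_cohort(config.cohort.config)
        else:
            from .cohort import csv_to_cohort
            table = csv_to_cohort(config.cohort.path)
        return cls(table, config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "PDResNetResults":
        cfg = self.config
        pp = cfg.preprocessing
        rule = _TASK_RULES[self.task]
        s_smote, s_split, s_val, s_net, s_train = derive_seeds(cfg.seed, 5)

        df = task_subset(self.table, self.task)
        n_input = len(df)
        logger.info("task %s: %d rows before balancing", self.task, n_input)

        smote = SmoteParams(pp.smote_k, s_smote)
        if pp.split_first:
            y0 = (df[rule["label_col"]] == rule["positive"]).to_numpy().astype(int)
            raw_split = split_train_test(len(df), pp.test_fraction, True,
                                         s_split, labels=y0)
            train_df = smote_balance(df.iloc[raw_split.train_ids], smote,
                                     rule["label_col"])
            test_df = df.iloc[raw_split.test_ids].copy()
            test_df["synthetic"] = False
            bal = pd.concat([train_df, test_df], ignore_index=True)
            train_ids = np.arange(len(train_df))
            test_ids = np.arange(len(train_df), len(bal))
        else:
            # Reference protocol: balance the whole table, then split.
            bal = smote_balance(df, smote, rule["label_col"])
            y_all = (bal[rule["label_col"]] == rule["positive"]).to_numpy().astype(int)
            split = split_train_test(len(bal), pp.test_fraction, True,
                                     s_split, labels=y_all)
            train_ids, test_ids = split.train_ids, split.test_ids
        y = (bal[rule["label_col"]] == rule["positive"]).to_numpy().astype(int)

        feats = infer_feature_columns(bal)
        normalizer = Normalizer().fit(bal.iloc[train_ids][feats])
        X = normalizer.transform(bal[feats])

        elev_spec = ElevationSpec(target_side=pp.elevation_side)
        elevated = polynomial_elevate(X, elev_spec)
        images = elevated.reshape(len(bal), pp.elevation_side, pp.elevation_side)
        images = resize_image(images, pp.image_side)[:, None, :, :]
        logger.info("shape chain: %d -> %d -> %dx%d -> %dx%d",
                    len(feats), pp.elevation_side ** 2,
                    pp.elevation_side, pp.elevation_side,
                    pp.image_side, pp.image_side)

        if pp.paper_faithful:
            fit_ids, val_ids = train_ids, test_ids
        else:
            inner = split_train_test(len(train_ids), pp.val_fraction, True,
                                     s_val, labels=y[train_ids])
            fit_ids = train_ids[inner.train_ids]
            val_ids = train_ids[inner.test_ids]

        net = PDResNet(cfg.network.spec(pp.image_side), seed=s_net)
        train_cfg = replace(cfg.training, seed=s_train)
        net, history = train(net, images[fit_ids], y[fit_ids],
                             images[val_ids], y[val_ids],
                             config=train_cfg, loss=cfg.loss.name,
                             loss_params=cfg.loss.params(),
                             erase_params=pp.erase_params())

        loss_fn, _ = get_loss(cfg.loss.name, cfg.loss.params())
        _, test_acc, p_plus = evaluate_network(net, images[test_ids],
                                               y[test_ids], loss_fn)
        pred = classify(p_plus)
        cm = confusion(pred, y[test_ids])
        report = metrics(cm)
        roc_curve, auc = roc_auc(p_plus, y[test_ids])
        report = MetricsReport(**{**report.as_dict(), "auc": auc})

        predictions = pd.DataFrame({
            "subject_id": bal.iloc[test_ids]["subject_id"].to_numpy(),
            "score": p_plus,
            "predicted": pred,
            "true": y[test_ids],
            "synthetic": bal.iloc[test_ids]["synthetic"].to_numpy(),
        })
        return PDResNetResults(
            model=self, network=net, history=history, normalizer=normalizer,
            elevation_spec=elev_spec, image_side=pp.image_side,
            metrics=report, confusion=cm, roc_curve=roc_curve,
            predictions=predictions, positive_class=rule["positive"],
            n_input_rows=n_input, n_synthetic=int(bal["synthetic"].sum()),
            n_train=len(train_ids), n_test=len(test_ids), seed=cfg.seed)


class PDResNetResults:
    """Fit results: trained network, history, metrics and predictions."""

    def __init__(self, *, model, network, history: TrainHistory, normalizer,
                 elevation_spec, image_side, metrics: MetricsReport,
                 confusion: ConfusionMatrix, roc_curve, predictions,
                 positive_class, n_input_rows, n_synthetic, n_train, n_test,
                 seed):
        self.model = model
        self.network = network
        self.history = history
        self.normalizer = normalizer
        self.elevation_spec = elevation_spec
        self.image_side = image_side
        self.metrics = metrics
        self.confusion = confusion
        self.roc_curve = roc_curve
        self.predictions = predictions
        self.positive_class = positive_class
        self.n_input_rows = n_input_rows
        self.n_synthetic = n_synthetic
        self.n_train = n_train
        self.n_test = n_test
        self.seed = seed

    def predict(self, features, return_scores: bool = False):
        """Classify raw 194-feature row(s) with the fitted pipeline."""
        if isinstance(features, pd.DataFrame):
            features = features[infer_feature_columns(features)].to_numpy()
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Xn = self.normalizer.transform(X)
        side = self.elevation_spec.target_side
        imgs = polynomial_elevate(Xn, self.elevation_spec).reshape(-1, side, side)
        imgs = resize_image(imgs, self.image_side)[:, None, :, :]
        q = np.asarray(self.network.forward(imgs, train=False), dtype=float)
        scores = q[:, 1]
        labels = classify(scores)
        return (labels, scores) if return_scores else labels

    def summary(self) -> str:
        m = self.metrics.rounded()
        cm = self.confusion

        def fmt(v, unit="%"):
            return "undefined" if v is None else f"{v:.2f} {unit}".strip()

        lines = [
            "               PD-ResNet Classification Results",
            "=" * 63,
            f"Task:            {self.model.task:<20} Positive class: {self.positive_class}",
            f"Input rows:      {self.n_input_rows:<20} Synthetic (SMOTE): {self.n_synthetic}",
            f"Train / test:    {self.n_train} / {self.n_test:<13} Seed: {self.seed}",
            f"Epochs run:      {self.history.stopped_epoch:<20} Best epoch: {self.history.best_epoch}",
            f"Parameters:      {self.network.num_parameters():,}",
            "-" * 63,
            f"Accuracy         {fmt(m['accuracy'])}",
            f"Precision        {fmt(m['precision'])}",
            f"Recall           {fmt(m['recall'])}",
            f"Specificity      {fmt(m['specificity'])}",
            f"F1-score         {fmt(m['f1'])}",
            f"AUC              {fmt(m['auc'], '')}",
            "-" * 63,
            f"Confusion        T_HC={cm.t_hc}  T_PD={cm.t_pd}  "
            f"F_HC={cm.f_hc}  F_PD={cm.f_pd}",
            "=" * 63,
            f"pdresnet {__version__}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Accuracy and loss curves over epochs (training and held-out)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h.epoch, h.train_loss, label="train loss")
        ax.plot(h.epoch, h.val_loss, label="held-out loss")
        ax2 = ax.twinx()
        ax2.plot(h.epoch, h.train_accuracy, "--", label="train accuracy")
        ax2.plot(h.epoch, h.val_accuracy, "--", label="held-out accuracy")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("accuracy")
        ax.legend(loc="upper right")
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_curve["fpr"], self.roc_curve["tpr"],
                label=f"AUC = {self.metrics.auc:.3f}")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
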