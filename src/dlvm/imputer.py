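"""MLP imputation of missing race/ethnicity labels.

A softmax multilayer perceptron with PReLU hidden units is trained on the
patients with self-reported race and used to predict labels (with class
probabilities) for the rest — the same pattern used to recover the labels of
unannotated patients in public prostate cohorts.  The reference topology is
112 input features, two hidden layers of 512 PReLU units and a 3-class
softmax head (EA / AA / Asian); all dimensions are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .data import CohortTable
from .model import _Preprocessor

__all__ = ["ImputerConfig", "RaceImputer", "fit_imputer", "impute_race"]


@dataclass
class ImputerConfig:
    """Hyperparameters of the race-imputation MLP.

    ``input_dim=None`` (default) infers the width from the encoded feature
    table; the reference configuration uses 112.
    """

    input_dim: int | None = None
    hidden_sizes: tuple[int, ...] = (512, 512)
    hidden_activation: str = "prelu"
    n_classes: int = 3
    epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 1e-3
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_dim is not None and self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)


class RaceImputer:
    """Trained softmax classifier over the cohort's proxy features."""

    def __init__(self, config: ImputerConfig, classes: tuple[str, ...],
                 preprocessor: _Preprocessor, net: nn.MLP):
        self.config = config
        self.classes = classes
        self.preprocessor = preprocessor
        self.net = net

    def _features(self, cohort: CohortTable) -> np.ndarray:
        x1, x2, _, _, _ = self.preprocessor.transform(cohort)
        x = np.concatenate([x1, x2], axis=1)
        if self.config.input_dim is not None and x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"encoded feature count {x.shape[1]} does not match the "
                f"configured input_dim {self.config.input_dim}"
            )
        return x

    def predict_proba(self, cohort: CohortTable) -> np.ndarray:
        x = self._features(cohort)
        logits = self.net(nn.Tensor(x)).data
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, cohort: CohortTable) -> np.ndarray:
        proba = self.predict_proba(cohort)
        # np.argmax takes the first maximum; classes are stored sorted, so
        # ties break lexicographically by construction
        return np.array([self.classes[i] for i in np.argmax(proba, axis=1)])


def fit_imputer(labeled: CohortTable, config: ImputerConfig | None = None) -> RaceImputer:
    """Train the imputer on rows whose race label is known.

    Rows labeled ``unknown`` are dropped with a warning; a vocabulary class
    absent from the training labels triggers a warning (it can never be
    predicted with calibrated probability) but training proceeds.
    Deterministic given ``config.seed``.
    """
    config = config or ImputerConfig()
    known = labeled.race != "unknown"
    if not known.all():
        warnings.warn(f"dropping {int((~known).sum())} unlabeled row(s) from "
                      "imputer training", UserWarning)
    table = labeled.subset(np.flatnonzero(known))
    if table.n == 0:
        raise ValueError("no labeled rows to train on")

    classes = tuple(sorted(set(table.race)))
    if len(classes) < config.n_classes:
        warnings.warn(
            f"only {len(classes)} of {config.n_classes} race classes present in "
            "training labels; absent classes cannot be predicted", UserWarning
        )
    labels = np.array([classes.index(r) for r in table.race])

    pp = _Preprocessor().fit(table)
    x1, x2, _, _, _ = pp.transform(table)
    x = np.concatenate([x1, x2], axis=1)
    if config.input_dim is not None and x.shape[1] != config.input_dim:
        raise ValueError(
            f"encoded feature count {x.shape[1]} does not match the "
            f"configured input_dim {config.input_dim}"
        )

    children = np.random.SeedSequence(config.seed).spawn(2)
    init_rng = np.random.default_rng(children[0])
    batch_rng = np.random.default_rng(children[1])
    net = nn.MLP(x.shape[1], config.hidden_sizes, len(classes), init_rng,
                 activation=config.hidden_activation)

    onehot = np.eye(len(classes))[labels]
    if config.class_weighting:
        freq = onehot.mean(axis=0)
        row_w = (1.0 / np.maximum(freq, 1e-12))[labels]
        row_w = row_w / row_w.mean()
    else:
        row_w = np.ones(len(labels))

    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    n = x.shape[0]
    for _ in range(config.epochs):
        order = batch_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net(nn.Tensor(x[idx]))
            logp = logits - nn.logsumexp(logits, axis=1, keepdims=True)
            ce = -(nn.Tensor(onehot[idx] * row_w[idx, None]) * logp).sum(axis=1).mean()
            opt.zero_grad()
            ce.backward()
            opt.step()

    return RaceImputer(config, classes, pp, net)


def impute_race(imputer: RaceImputer, unlabeled: CohortTable):
    """Predicted label and class probabilities for every row.

    Returns ``(labels, proba)`` with ``proba`` rows on the simplex, columns
    ordered as ``imputer.classes``; the label is the argmax class with
    lexicographic tie-break.
    """
    proba = imputer.predict_proba(unlabeled)
    labels = np.array([imputer.classes[i] for i in np.argmax(proba, axis=1)])
    return labels, proba


def impute_cohort(imputer: RaceImputer, cohort: CohortTable) -> CohortTable:
    """Write imputed labels back: rows with known race keep it (provenance
    column ``race_source="self-reported"``); unknown rows get the predicted
    label (``race_source="imputed"``) plus per-class probability columns."""
    labels, proba = impute_race(imputer, cohort)
    frame = cohort.frame.copy()
    known = frame[cohort.schema.race_column] != "unknown"
    frame["race_source"] = np.where(known, "self-reported", "imputed")
    col = frame[cohort.schema.race_column].to_numpy(dtype=object)
    col[~known.to_numpy()] = labels[~known.to_numpy()]
    frame[cohort.schema.race_column] = col
    for j, cls in enumerate(imputer.classes):
        frame[f"race_prob_{cls}"] = proba[:, j]
    return CohortTable(cohort.schema, frame)
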