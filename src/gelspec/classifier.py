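"""Gel-state naive-Bayes classifier over 6 kHz impedance features.

The model is a two-node-class Bayesian network whose structure reduces
to naive Bayes: the gel-state class node is the sole parent of each
feature node, so the joint factorises into a class prior times a product
of class-conditional feature densities.  Two variants are provided:

* ``gaussian`` (default) — each class-conditional density is a Gaussian
  with the class sample mean and variance;
* ``discretized`` — each feature is split into 10 equal-frequency bins
  computed on the pooled training data, with Laplace-smoothed
  class-conditional bin counts.

Posterior accumulation is in the log domain.  An exact posterior tie is
broken toward "gelled" so predictions are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .spectra import GELLED, NON_GELLED, FeatureVector

logger = logging.getLogger(__name__)

CLASSES = (GELLED, NON_GELLED)
DEFAULT_FEATURES = ("resistance_6k", "reactance_6k")
ALL_FEATURES = ("impedance_6k", "resistance_6k", "reactance_6k", "decay_rate")

#: relative variance floor: var >= VARIANCE_FLOOR_FACTOR * (feature range)^2
VARIANCE_FLOOR_FACTOR = 1e-9

N_BINS = 10


class ClassifierError(ValueError):
    """Raised for invalid training data or prediction inputs."""


@dataclass
class ClassifierModel:
    """Trained naive-Bayes model.

    ``gaussians[cls][feat] = (mean, variance)`` for the gaussian variant;
    ``bin_edges[feat]`` (interior edges) and
    ``bin_logprobs[cls][feat]`` (length-``N_BINS`` log probabilities) for
    the discretized variant.
    """

    feature_subset: tuple[str, ...]
    class_priors: dict[str, float]
    variant: str = "gaussian"
    gaussians: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    bin_logprobs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "feature_subset": list(self.feature_subset),
            "class_priors": dict(self.class_priors),
            "variant": self.variant,
        }
        if self.variant == "gaussian":
            d["gaussians"] = {c: {f: list(mv) for f, mv in per.items()}
                              for c, per in self.gaussians.items()}
        else:
            d["bin_edges"] = {f: [float(v) for v in e]
                              for f, e in self.bin_edges.items()}
            d["bin_logprobs"] = {c: {f: [float(v) for v in lp]
                                     for f, lp in per.items()}
                                 for c, per in self.bin_logprobs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        model = cls(
            feature_subset=tuple(d["feature_subset"]),
            class_priors={k: float(v) for k, v in d["class_priors"].items()},
            variant=d["variant"],
        )
        if model.variant == "gaussian":
            model.gaussians = {c: {f: (mv[0], mv[1]) for f, mv in per.items()}
                               for c, per in d["gaussians"].items()}
        else:
            model.bin_edges = {f: np.asarray(e, dtype=float)
                               for f, e in d["bin_edges"].items()}
            model.bin_logprobs = {c: {f: np.asarray(lp, dtype=float)
                                      for f, lp in per.items()}
                                  for c, per in d["bin_logprobs"].items()}
        return model


def _feature_matrix(features: Sequence[FeatureVector],
                    subset: Sequence[str]) -> np.ndarray:
    rows = []
    for fv in features:
        d = fv.as_dict()
        missing = [name for name in subset if name not in d]
        if missing:
            raise ClassifierError(f"missing feature(s) {missing}")
        rows.append([d[name] for name in subset])
    return np.asarray(rows, dtype=float)


def train(features: Sequence[FeatureVector],
          subset: Sequence[str] = DEFAULT_FEATURES,
          variant: str = "gaussian") -> ClassifierModel:
    """Fit class priors and class-conditional densities from labelled eggs.

    Requires at least two examples of each class.  A zero-variance
    feature has its variance floored at ``1e-9 * range^2`` (range over
    the pooled training data) with a logged warning.
    """
    if variant not in ("gaussian", "discretized"):
        raise ClassifierError(f"unknown variant {variant!r}")
    subset = tuple(subset)
    if not subset:
        raise ClassifierError("feature subset must be non-empty")
    labels = np.array([fv.label for fv in features])
    for cls in CLASSES:
        if int((labels == cls).sum()) < 2:
            raise ClassifierError(f"need >= 2 training examples of class {cls!r}")
    x = _feature_matrix(features, subset)
    n = len(features)
    priors = {cls: float((labels == cls).sum()) / n for cls in CLASSES}
    model = ClassifierModel(feature_subset=subset, class_priors=priors,
                            variant=variant)

    pooled_range = x.max(axis=0) - x.min(axis=0)
    floor = VARIANCE_FLOOR_FACTOR * np.maximum(pooled_range, 1e-300) ** 2

    if variant == "gaussian":
        for cls in CLASSES:
            sub = x[labels == cls]
            mean = sub.mean(axis=0)
            var = sub.var(axis=0, ddof=1)
            low = var < floor
            if low.any():
                for j in np.flatnonzero(low):
                    logger.warning(
                        "variance of %s within class %s floored (%.3g -> %.3g)",
                        subset[j], cls, var[j], floor[j])
                var = np.where(low, floor, var)
            model.gaussians[cls] = {
                name: (float(mean[j]), float(var[j]))
                for j, name in enumerate(subset)
            }
        return model

    # discretized variant: equal-frequency bins on pooled data
    for j, name in enumerate(subset):
        # N_BINS-quantile interior edges over the pooled training column
        qs = np.quantile(x[:, j], np.linspace(0, 1, N_BINS + 1)[1:-1])
        model.bin_edges[name] = qs
    for cls in CLASSES:
        sub = x[labels == cls]
        model.bin_logprobs[cls] = {}
        for j, name in enumerate(subset):
            idx = np.searchsorted(model.bin_edges[name], sub[:, j], side="right")
            counts = np.bincount(idx, minlength=N_BINS).astype(float)
            probs = (counts + 1.0) / (counts.sum() + N_BINS)  # Laplace
            model.bin_logprobs[cls][name] = np.log(probs)
    return model


def _log_likelihood(model: ClassifierModel, cls: str,
                    values: dict[str, float]) -> float:
    total = 0.0
    if model.variant == "gaussian":
        for name in model.feature_subset:
            mean, var = model.gaussians[cls][name]
            v = values[name]
            total += -0.5 * (math.log(2 * math.pi * var)
                             + (v - mean) ** 2 / var)
    else:
        for name in model.feature_subset:
            idx = int(np.searchsorted(model.bin_edges[name], values[name],
                                      side="right"))
            total += float(model.bin_logprobs[cls][name][idx])
    return total


def predict(model: ClassifierModel,
            feature: FeatureVector) -> tuple[str, float]:
    """Label one egg; returns (label, posterior probability of "gelled").

    Posterior is prior times the product of per-feature class
    conditionals, accumulated in the log domain; exact ties go to
    "gelled".
    """
    values = feature.as_dict()
    missing = [n for n in model.feature_subset if n not in values
               or not math.isfinite(values[n])]
    if missing:
        raise ClassifierError(f"missing or non-finite feature(s) {missing}")
    log_post = np.array([
        math.log(model.class_priors[cls]) + _log_likelihood(model, cls, values)
        for cls in CLASSES
    ])
    # tie-break on the raw log posteriors (exact tie -> "gelled") so the
    # decision is immune to normalisation round-off
    i_gelled = CLASSES.index(GELLED)
    label = GELLED if log_post[i_gelled] >= log_post[1 - i_gelled] else NON_GELLED
    log_post -= logsumexp(log_post)
    p_gelled = float(np.exp(log_post[i_gelled]))
    return label, p_gelled


def predict_many(model: ClassifierModel,
                 features: Sequence[FeatureVector]) -> tuple[list[str], np.ndarray]:
    """Vector convenience wrapper over :func:`predict`."""
    labels, posteriors = [], []
    for fv in features:
        lab, p = predict(model, fv)
        labels.append(lab)
        posteriors.append(p)
    return labels, np.asarray(posteriors)


def save_model(model: ClassifierModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    return ClassifierModel.from_dict(json.loads(Path(path).read_text()))
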