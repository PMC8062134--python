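"""Penalized multinomial cell-type classifier with doublet/low-quality rules.

Cells with manually curated (or simulated) labels train an L2-penalized
multinomial logistic regression on highly variable genes. Preprocessing
follows the standard single-cell recipe: drop genes seen in fewer than 10
cells, scale each cell to 10,000 total counts, log(1+x), select highly
variable genes by mean window and dispersion, then z-score per gene with
values clipped at 20. Fold-wise cross-validated class probabilities feed
two decision rules, applied in order: a cell with probability > 0.2 for
two or more classes is a doublet; a cell whose best class has probability
< 0.4 is low quality; otherwise it gets the argmax class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

logger = logging.getLogger(__name__)

DOUBLET = "doublet"
LOW_QUALITY = "low_quality"


@dataclass
class ClassifierConfig:
    """Preprocessing and model hyperparameters.

    The inverse regularization strength ``C`` defaults to the value
    estimated on the full training corpus of the motivating study.
    """

    target_sum: float = 10_000.0
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_disp: float = 0.5
    scale_clip: float = 20.0
    C: float = 7.74e-4
    cv_folds: int = 5
    doublet_prob: float = 0.2
    lowq_prob: float = 0.4
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.doublet_prob < self.lowq_prob < 1):
            raise ValueError("need 0 < doublet_prob < lowq_prob < 1")
        if self.scale_clip <= 0 or self.C <= 0:
            raise ValueError("scale_clip and C must be positive")


def _normalized_log(adata: ad.AnnData, config: ClassifierConfig) -> ad.AnnData:
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = np.asarray(adata.obs_names)[totals <= 0]
        raise ValueError(f"cell(s) with zero total counts: {list(bad[:5])}")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=config.target_sum)
    sc.pp.log1p(out)
    return out


def preprocess(
    adata: ad.AnnData, config: ClassifierConfig | None = None
) -> tuple[np.ndarray, list[str], dict]:
    """Training-time preprocessing.

    Returns (scaled feature matrix, HVG names, state) where ``state``
    carries the gene list and per-gene mean/std needed to transform new
    data identically.
    """
    config = config or ClassifierConfig()
    counts = adata.copy()
    sc.pp.filter_genes(counts, min_cells=config.min_cells_per_gene)
    norm = _normalized_log(counts, config)
    sc.pp.highly_variable_genes(
        norm,
        flavor="seurat",
        min_mean=config.hvg_min_mean,
        max_mean=config.hvg_max_mean,
        min_disp=config.hvg_min_disp,
    )
    hvg = list(norm.var_names[norm.var["highly_variable"]])
    if not hvg:
        raise ValueError("no highly variable genes under the configured bounds")
    X = norm[:, hvg].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Xs = np.minimum((X - mean) / std, config.scale_clip)
    state = {"genes": hvg, "mean": mean, "std": std}
    return Xs, hvg, state


def transform(adata: ad.AnnData, state: dict, config: ClassifierConfig) -> np.ndarray:
    """Apply a stored preprocessing state to new cells."""
    norm = _normalized_log(adata, config)
    missing = [g for g in state["genes"] if g not in norm.var_names]
    if missing:
        raise ValueError(f"{len(missing)} training gene(s) absent from new data")
    X = norm[:, state["genes"]].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return np.minimum((X - state["mean"]) / state["std"], config.scale_clip)


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> LogisticRegression:
    """L2-penalized multinomial logistic regression at the configured C."""
    config = config or ClassifierConfig()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    small = classes[counts < config.cv_folds]
    if len(small):
        raise ValueError(f"classes with fewer members than folds: {list(small)}")
    model = LogisticRegression(
        C=config.C, solver="lbfgs", max_iter=2000, random_state=seed
    )
    model.fit(features, labels)
    return model


def cross_val_probabilities(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fold-wise held-out class probabilities (stratified K-fold)."""
    config = config or ClassifierConfig()
    model = LogisticRegression(
        C=config.C, solver="lbfgs", max_iter=2000, random_state=seed
    )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    return cross_val_predict(model, features, labels, cv=cv, method="predict_proba")


def call_cells(
    probabilities: np.ndarray,
    classes: np.ndarray,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Apply the doublet / low-quality decision rules to probabilities.

    Doublet takes precedence: >= 2 class probabilities above
    ``doublet_prob``. Then low quality: best class below ``lowq_prob``.
    Otherwise the argmax class.
    """
    config = config or ClassifierConfig()
    P = np.asarray(probabilities, float)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    n_high = (P > config.doublet_prob).sum(axis=1)
    best = P.max(axis=1)
    label = np.asarray(classes)[P.argmax(axis=1)].astype(object)
    label[best < config.lowq_prob] = LOW_QUALITY
    label[n_high >= 2] = DOUBLET
    return pd.DataFrame(
        {"label": label, "max_prob": best, "n_above_doublet_prob": n_high}
    )


class CellTypeClassifier:
    """Convenience wrapper: preprocessing state + fitted model.

    ``fit`` trains on labeled cells and stores cross-validated calls for
    the training set; ``predict`` transfers labels to a new dataset with
    the same decision rules.
    """

    def __init__(self, config: ClassifierConfig | None = None, seed: int = 0):
        self.config = config or ClassifierConfig()
        self.seed = seed
        self.state: dict | None = None
        self.model: LogisticRegression | None = None
        self.train_calls: pd.DataFrame | None = None

    def fit(self, adata: ad.AnnData, labels: np.ndarray) -> "CellTypeClassifier":
        X, _, self.state = preprocess(adata, self.config)
        probs = cross_val_probabilities(X, labels, self.config, self.seed)
        self.model = fit_classifier(X, labels, self.config, self.seed)
        self.train_calls = call_cells(probs, self.model.classes_, self.config)
        self.train_calls.index = adata.obs_names
        return self

    def predict_proba(self, adata: ad.AnnData) -> np.ndarray:
        if self.model is None or self.state is None:
            raise RuntimeError("classifier is not fitted")
        X = transform(adata, self.state, self.config)
        return self.model.predict_proba(X)

    def predict(self, adata: ad.AnnData) -> pd.DataFrame:
        calls = call_cells(self.predict_proba(adata), self.model.classes_, self.config)
        calls.index = adata.obs_names
        return calls
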