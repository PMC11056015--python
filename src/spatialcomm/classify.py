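"""Keyword labeling of genes and MLP classification.

Genes are labeled communication-related (1) when their annotation text
contains any strong keyword (receptor/ligand vocabulary, cell-cell
adhesion, intercellular interaction); weak keywords (pathway, regulation,
signal transduction, ...) are recorded but do not set the label. Matching
is case-insensitive substring matching after normalizing hyphen/en-dash/
space between tokens, so "cell-cell adhesion", "cell–cell adhesion" and
"cell cell adhesion" are equivalent.

An MLP (one hidden layer of 64 rectified units, early stopping) is
evaluated by stratified seeded k-fold cross-validation.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .exceptions import ValidationError

STRONG_KEYWORDS = (
    "receptor",
    "ligand",
    "receptors",
    "ligands",
    "cell–cell adhesion",
    "intercellular interaction",
)
WEAK_KEYWORDS = (
    "surfaces of many cells and extracellular matrices",
    "Participates in cellular",
    "Pathway",
    "regulation",
    "signal transduction",
)


def _canon(text: str) -> str:
    text = text.lower().replace("–", " ").replace("—", " ").replace("-", " ")
    return re.sub(r"\s+", " ", text).strip()


def label_genes_by_keywords(
    annotations: dict,
    strong_list=STRONG_KEYWORDS,
    weak_list=WEAK_KEYWORDS,
) -> pd.DataFrame:
    """Label genes from annotation text via keyword matching.

    Parameters
    ----------
    annotations : mapping gene -> annotation text (missing/empty -> label 0).

    Returns
    -------
    DataFrame with columns gene, strong_tags, weak_tags, label; label is 1
    iff at least one strong keyword matches.
    """
    strong = [(kw, _canon(kw)) for kw in strong_list]
    weak = [(kw, _canon(kw)) for kw in weak_list]
    rows = []
    for gene, text in annotations.items():
        canon = _canon(text or "")
        strong_tags = [kw for kw, ck in strong if ck in canon]
        weak_tags = [kw for kw, ck in weak if ck in canon]
        rows.append(
            {
                "gene": gene,
                "strong_tags": ";".join(strong_tags),
                "weak_tags": ";".join(weak_tags),
                "label": int(bool(strong_tags)),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "strong_tags", "weak_tags", "label"])


def load_annotations(path) -> dict:
    """Read a (gene, annotation_text) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene", "annotation_text"):
        if col not in df.columns:
            raise ValidationError(f"annotation file missing column {col!r}")
    return dict(zip(df["gene"], df["annotation_text"]))


def build_gene_features(dataset, filtered_coefficients: dict, hvg_ids: dict,
                        gene_set) -> np.ndarray:
    """Per-gene feature matrix: coefficient profile plus expression summaries.

    For each gene: its filtered coefficient toward each of the A neighbor
    types, averaged over the cell types in which it is a retained HVG
    (0 where absent), followed by mean expression, log1p variance and
    dropout fraction across all cells. Feature length A + 3.

    Parameters
    ----------
    dataset : SpatialExpressionDataset
    filtered_coefficients : mapping cell type -> (A, H_a) filtered matrix.
    hvg_ids : mapping cell type -> H_a gene ids (column order).
    gene_set : genes to featurize (must exist in the dataset).
    """
    gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    a = dataset.n_types
    feats = np.zeros((len(gene_set), a + 3))
    for row, gene in enumerate(gene_set):
        if gene not in gene_pos:
            raise ValidationError(f"gene {gene!r} absent from dataset")
        vecs = []
        for cell_type, coef in filtered_coefficients.items():
            ids = hvg_ids[cell_type]
            hit = np.flatnonzero(np.asarray(ids, dtype=object) == gene)
            if hit.size:
                vecs.append(np.asarray(coef)[:, hit[0]])
        if vecs:
            feats[row, :a] = np.mean(vecs, axis=0)
        expr = dataset.expression[:, gene_pos[gene]]
        feats[row, a] = expr.mean()
        feats[row, a + 1] = np.log1p(expr.var(ddof=0))
        feats[row, a + 2] = float(np.mean(expr == 0))
    return feats


@dataclass
class ClassifierReport:
    folds: int
    seed: int
    architecture: str
    accuracy: list
    precision: list
    recall: list
    f1: list
    auroc: list
    mean_accuracy: float
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_auroc: float

    def to_dict(self) -> dict:
        return asdict(self)


class CommunicationGeneMLP(ClassifierMixin, BaseEstimator):
    """MLP classifier for communication-related genes.

    One hidden layer of ``hidden_units`` rectified units, early stopping on
    a 10% validation split, at most 500 epochs.
    """

    def __init__(self, hidden_units: int = 64, max_epochs: int = 500,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.random_state = random_state

    def _make(self):
        return MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            activation="relu",
            early_stopping=True,
            validation_fraction=0.1,
            max_iter=self.max_epochs,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        self.model_ = self._make().fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def train_eval_mlp(features, labels, folds: int = 10, seed: int = 0,
                   hidden_units: int = 64) -> ClassifierReport:
    """Stratified k-fold evaluation of the MLP; per-fold and mean metrics."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    if folds > len(y):
        raise ValidationError(f"folds={folds} exceeds sample count {len(y)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    metrics = {k: [] for k in ("accuracy", "precision", "recall", "f1", "auroc")}
    for train, test in skf.split(x, y):
        clf = CommunicationGeneMLP(hidden_units=hidden_units, random_state=seed)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        proba = clf.predict_proba(x[test])[:, 1]
        metrics["accuracy"].append(accuracy_score(y[test], pred))
        metrics["precision"].append(precision_score(y[test], pred, zero_division=0))
        metrics["recall"].append(recall_score(y[test], pred, zero_division=0))
        metrics["f1"].append(f1_score(y[test], pred, zero_division=0))
        if len(np.unique(y[test])) == 2:
            metrics["auroc"].append(roc_auc_score(y[test], proba))
        else:
            metrics["auroc"].append(float("nan"))
    return ClassifierReport(
        folds=folds,
        seed=seed,
        architecture=f"MLP(hidden=({hidden_units},), relu, early_stopping)",
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        auroc=metrics["auroc"],
        mean_accuracy=float(np.mean(metrics["accuracy"])),
        mean_precision=float(np.mean(metrics["precision"])),
        mean_recall=float(np.mean(metrics["recall"])),
        mean_f1=float(np.mean(metrics["f1"])),
        mean_auroc=float(np.nanmean(metrics["auroc"])),
    )
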