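"""Retrospective water labelling and bagged classification trees.

Sites predicted in the ligand-stripped pocket are labelled against the
bound complex: *conserved* if within 1.5 A of a crystallographic water of
the complex, otherwise *displaced* if within 1.5 A of a ligand atom (by a
*polar* atom if the nearest such atom is a hydrogen-bond donor/acceptor,
else *non-polar*), otherwise *ambiguous* and excluded from training.

Classification is by bagging: many CART trees fit to bootstrap resamples
of the (energy, hydrophilicity, lipophilicity) feature vectors; the
predicted class probability is the mean over trees of the training-class
proportions in the leaf the query falls into.  Two binary models are used
in cascade — conserved vs displaced, then polar vs non-polar given
displaced — mirroring the two questions a ligand designer asks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

FEATURE_NAMES = ("energy", "hydrophilicity", "lipophilicity")

_MODEL_FORMAT_VERSION = 1


@dataclass
class WaterLabel:
    """Ground-truth label for one predicted site."""

    label: str                       # conserved | displaced | ambiguous
    displaced_by: str | None = None  # polar | nonpolar, iff displaced
    match_distance: float = float("inf")

    def __post_init__(self):
        if self.label not in ("conserved", "displaced", "ambiguous"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.displaced_by is not None) != (self.label == "displaced"):
            raise ValueError("displaced_by must be present iff label is displaced")


@dataclass
class FeatureVector:
    energy: float
    hydrophilicity: float
    lipophilicity: float

    def __post_init__(self):
        if not all(np.isfinite([self.energy, self.hydrophilicity, self.lipophilicity])):
            raise ValueError("features must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.energy, self.hydrophilicity, self.lipophilicity])

    @classmethod
    def from_site(cls, site) -> "FeatureVector":
        if site.scores is None:
            raise ValueError("site has not been scored")
        return cls(energy=site.scores.energy,
                   hydrophilicity=site.scores.hydrophilicity,
                   lipophilicity=site.scores.lipophilicity)


def label_sites(sites, crystal_waters, ligand, cutoff: float = 1.5) -> list:
    """Label predicted sites against the bound complex (1.5 A rules).

    ``crystal_waters`` is an (n, 3) array of water oxygen positions from
    the complex; ``ligand`` a Structure whose atoms carry role flags.
    Order-independent per site and idempotent.
    """
    waters = np.asarray(crystal_waters, dtype=float).reshape(-1, 3)
    lig_atoms = [a for a in ligand.atoms if a.element.upper() != "H"]
    lig_xyz = np.array([a.coords for a in lig_atoms]) if lig_atoms else np.empty((0, 3))

    labels = []
    for site in sites:
        pos = np.asarray(site.position, dtype=float)
        d_wat = np.linalg.norm(waters - pos, axis=1) if len(waters) else np.array([np.inf])
        if d_wat.min() <= cutoff:
            labels.append(WaterLabel("conserved", match_distance=float(d_wat.min())))
            continue
        d_lig = np.linalg.norm(lig_xyz - pos, axis=1) if len(lig_xyz) else np.array([np.inf])
        if d_lig.min() <= cutoff:
            nearest = lig_atoms[int(d_lig.argmin())]
            polar = bool(nearest.roles & {"hbond_donor", "hbond_acceptor"})
            labels.append(WaterLabel("displaced",
                                     displaced_by="polar" if polar else "nonpolar",
                                     match_distance=float(d_lig.min())))
        else:
            labels.append(WaterLabel("ambiguous"))
    return labels


# ---------------------------------------------------------------------------
# Bagged trees

@dataclass
class _Tree:
    """One CART tree flattened to arrays; -1 children mark leaves."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    counts: np.ndarray           # (n_nodes, n_classes) training sample counts

    def leaf_proportions(self, x: np.ndarray) -> np.ndarray:
        node = 0
        while self.children_left[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        c = self.counts[node]
        return c / c.sum()


@dataclass
class BaggedTreeModel:
    """Bagging ensemble over CART trees with recorded bootstrap indices."""

    classes: list
    trees: list = field(default_factory=list)
    bootstrap_indices: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self, path=None) -> str:
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "classes": self.classes,
            "seed": self.seed,
            "bootstrap_indices": [idx.tolist() for idx in self.bootstrap_indices],
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "counts": t.counts.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BaggedTreeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        trees = [
            _Tree(
                children_left=np.array(t["children_left"]),
                children_right=np.array(t["children_right"]),
                feature=np.array(t["feature"]),
                threshold=np.array(t["threshold"]),
                counts=np.array(t["counts"], dtype=float),
            )
            for t in payload["trees"]
        ]
        return cls(classes=payload["classes"], trees=trees,
                   bootstrap_indices=[np.array(i) for i in payload["bootstrap_indices"]],
                   seed=payload["seed"])


def _as_feature_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=float)
    return np.array([x.as_array() if isinstance(x, FeatureVector) else np.asarray(x)
                     for x in X], dtype=float)


def train_bagged_trees(X, y, n_trees: int = 100, seed: int = 0,
                       min_samples_leaf: int = 5) -> BaggedTreeModel:
    """Fit a bagged CART ensemble; deterministic given the seed.

    Each tree is fit (Gini impurity, minimum leaf size 5, no depth cap,
    no pruning) on a bootstrap sample of size n drawn with replacement.
    Leaf class counts are stored against the global class list so trees
    whose bootstrap missed a class still emit full probability vectors.
    """
    from sklearn.tree import DecisionTreeClassifier

    Xm = _as_feature_matrix(X)
    y = np.asarray(y)
    if len(Xm) != len(y):
        raise ValueError("X and y must have equal length")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    class_index = {c: i for i, c in enumerate(classes)}

    rng = np.random.default_rng(seed)
    model = BaggedTreeModel(classes=classes, seed=seed)
    n = len(Xm)
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        clf = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(Xm[idx], y[idx])
        tr = clf.tree_
        # re-index the tree's value counts into the global class order
        counts = np.zeros((tr.node_count, len(classes)))
        for local, cls_label in enumerate(clf.classes_):
            counts[:, class_index[cls_label]] = tr.value[:, 0, local] * tr.n_node_samples
        model.trees.append(_Tree(
            children_left=tr.children_left.copy(),
            children_right=tr.children_right.copy(),
            feature=tr.feature.copy(),
            threshold=tr.threshold.copy(),
            counts=counts,
        ))
        model.bootstrap_indices.append(idx)
    return model


def predict_proba(model: BaggedTreeModel, x) -> dict:
    """Mean over trees of the leaf class proportions for one feature vector."""
    xv = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    probs = np.mean([t.leaf_proportions(xv) for t in model.trees], axis=0)
    return dict(zip(model.classes, probs.tolist()))


def predict_class(model: BaggedTreeModel, x) -> tuple:
    """(argmax class, its probability) for one feature vector."""
    probs = predict_proba(model, x)
    cls = max(probs, key=probs.get)
    return cls, probs[cls]


@dataclass
class CVResult:
    fold_accuracies: dict          # protein id -> accuracy
    mean_accuracy: float           # folds weighted equally
    pooled_accuracy: float         # waters weighted equally
    per_class_accuracy: dict       # class -> pooled accuracy
    predictions: list              # (protein, true, predicted, max probability)


def leave_protein_out_cv(rows: Sequence, n_trees: int = 100, seed: int = 0,
                         min_samples_leaf: int = 5) -> CVResult:
    """Grouped CV with one fold per protein.

    ``rows`` is a sequence of (protein_id, FeatureVector, label).  Each
    fold trains on every other protein's waters and classifies the
    held-out protein's by argmax probability.  Folds whose protein has no
    labelled waters, or whose complement collapses to one class, are
    skipped with a warning.  Accuracy is reported both fold-equal (the
    mean over partitions) and pooled over waters, plus per-class.
    """
    rows = list(rows)
    proteins = sorted({r[0] for r in rows})
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins for leave-protein-out CV")

    fold_acc = {}
    predictions = []
    for p in proteins:
        test = [r for r in rows if r[0] == p]
        train = [r for r in rows if r[0] != p]
        if not test:
            warnings.warn(f"protein {p!r} has no labelled waters; fold skipped")
            continue
        train_labels = {r[2] for r in train}
        if len(train_labels) < 2:
            warnings.warn(f"training complement of {p!r} is single-class; fold skipped")
            continue
        model = train_bagged_trees([r[1] for r in train], [r[2] for r in train],
                                   n_trees=n_trees, seed=seed,
                                   min_samples_leaf=min_samples_leaf)
        hits = 0
        for _, feats, true_label in test:
            pred, prob = predict_class(model, feats)
            predictions.append((p, true_label, pred, prob))
            hits += int(pred == true_label)
        fold_acc[p] = hits / len(test)

    if not fold_acc:
        raise ValueError("no usable folds")
    pooled_hits = sum(t == pr for _, t, pr, _ in predictions)
    per_class = {}
    for c in sorted({t for _, t, _, _ in predictions}):
        cls_rows = [(t, pr) for _, t, pr, _ in predictions if t == c]
        per_class[c] = sum(t == pr for t, pr in cls_rows) / len(cls_rows)
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(list(fold_acc.values()))),
        pooled_accuracy=pooled_hits / len(predictions),
        per_class_accuracy=per_class,
        predictions=predictions,
    )


def confidence_bins(predictions: Sequence) -> list:
    """Accuracy by max-probability bin: [0.5,0.6) ... [0.9,1.0].

    ``predictions`` is a sequence of (max probability, correct?) pairs.
    Returns one dict per bin with lo/hi edges, count and accuracy (None
    when the bin is empty).  For a binary classifier max probability is
    >= 0.5, so the bins cover the whole range.
    """
    if not len(predictions):
        raise ValueError("no predictions to bin")
    edges = [(0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]
    out = []
    for lo, hi in edges:
        members = [ok for p, ok in predictions
                   if (lo <= p < hi) or (hi == 1.0 and p == 1.0)]
        out.append({
            "lo": lo, "hi": hi, "count": len(members),
            "accuracy": (sum(members) / len(members)) if members else None,
        })
    return out


def cascade_predict_proba(model_conserved: BaggedTreeModel,
                          model_polarity: BaggedTreeModel, x) -> dict:
    """Chain the two binary models into P over {conserved, displaced_polar, displaced_nonpolar}."""
    p1 = predict_proba(model_conserved, x)
    p2 = predict_proba(model_polarity, x)
    p_disp = p1.get("displaced", 0.0)
    return {
        "conserved": p1.get("conserved", 0.0),
        "displaced_polar": p_disp * p2.get("polar", 0.0),
        "displaced_nonpolar": p_disp * p2.get("nonpolar", 0.0),
    }
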