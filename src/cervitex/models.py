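"""The six classifiers benchmarked on the fused texture features.

Four map directly onto scikit-learn estimators; the remaining two —
a tree-augmented naive Bayes ("Bayes net") and a decision table with greedy
forward feature selection — follow the classic Weka semantics and are
implemented here as scikit-learn-compatible estimators.  Both rely on
Fayyad-Irani MDL supervised entropy discretization of the continuous
features.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array

from .exceptions import DegenerateLabelError, ParameterError

__all__ = [
    "CLASSIFIER_NAMES",
    "mdl_cut_points",
    "TreeAugmentedNB",
    "DecisionTableClassifier",
    "make_classifier",
    "train_classifier",
]

CLASSIFIER_NAMES = (
    "naive_bayes",
    "bayes_net",
    "random_tree",
    "random_forest",
    "decision_table",
    "logistic",
)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def mdl_cut_points(x: np.ndarray, y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Fayyad-Irani recursive entropy discretization cut points for one feature.

    Returns a sorted array of thresholds (possibly empty when no cut passes
    the MDL stopping criterion).  Bins are then ``searchsorted`` indices.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    onehot = np.zeros((len(ys), n_classes), dtype=np.int64)
    onehot[np.arange(len(ys)), ys] = 1
    cum = np.vstack([np.zeros(n_classes, dtype=np.int64), np.cumsum(onehot, axis=0)])

    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:  # half-open [lo, hi)
        n = hi - lo
        if n < 2:
            return
        total = cum[hi] - cum[lo]
        ent_s = _entropy(total)
        # candidate split positions: between distinct adjacent values
        idx = np.arange(lo + 1, hi)
        idx = idx[xs[idx] > xs[idx - 1]]
        if idx.size == 0:
            return
        left = cum[idx] - cum[lo]
        right = cum[hi] - cum[idx]
        nl = left.sum(axis=1).astype(np.float64)
        nr = right.sum(axis=1).astype(np.float64)

        def ent_rows(c):
            tot = c.sum(axis=1, keepdims=True).astype(np.float64)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(tot > 0, c / np.maximum(tot, 1), 0.0)
                lg = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
            return -(p * lg).sum(axis=1)

        cand_ent = (nl * ent_rows(left) + nr * ent_rows(right)) / n
        best = int(np.argmin(cand_ent))
        gain = ent_s - cand_ent[best]
        i = int(idx[best])
        k = int((total > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        e1 = _entropy(left[best])
        e2 = _entropy(right[best])
        delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * e1 - k2 * e2)
        threshold = (np.log2(n - 1.0) + delta) / n
        if gain <= threshold:
            return
        cuts.append(float((xs[i - 1] + xs[i]) / 2.0))
        recurse(lo, i)
        recurse(i, hi)

    recurse(0, len(xs))
    return np.sort(np.asarray(cuts, dtype=np.float64))


class _DiscretizingClassifier(BaseEstimator, ClassifierMixin):
    """Shared MDL-discretization plumbing for the table and network models."""

    def _discretize_fit(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        self.cuts_ = [mdl_cut_points(X[:, j], y) for j in range(X.shape[1])]
        self.arity_ = np.array([len(c) + 1 for c in self.cuts_], dtype=np.int64)
        return self._discretize(X)

    def _discretize(self, X: np.ndarray) -> np.ndarray:
        Xd = np.empty(X.shape, dtype=np.int64)
        for j, cuts in enumerate(self.cuts_):
            Xd[:, j] = np.searchsorted(cuts, X[:, j])
        return Xd

    def _check_fit_inputs(self, X, y):
        X, y = check_X_y(X, y)
        classes, yi = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise DegenerateLabelError("training labels contain a single class")
        self.classes_ = classes
        return np.asarray(X, dtype=np.float64), yi

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class TreeAugmentedNB(_DiscretizingClassifier):
    """Tree-augmented naive Bayes on MDL-discretized features.

    A Chow-Liu tree over the features (maximizing conditional mutual
    information given the class) augments the naive-Bayes structure; each
    feature's conditional probability table is estimated with Laplace
    smoothing.  Features that the discretizer leaves with a single bin carry
    no information and effectively drop out.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y):
        X, yi = self._check_fit_inputs(X, y)
        Xd = self._discretize_fit(X, yi)
        n, p = Xd.shape
        n_classes = self.classes_.size
        cls_counts = np.bincount(yi, minlength=n_classes)
        self.log_prior_ = np.log(
            (cls_counts + self.alpha) / (n + n_classes * self.alpha)
        )

        informative = np.flatnonzero(self.arity_ > 1)
        cmi = np.zeros((p, p))
        for ai_pos, i in enumerate(informative):
            for j in informative[ai_pos + 1 :]:
                cmi[i, j] = self._cond_mutual_info(Xd[:, i], Xd[:, j], yi)
        self.parent_ = np.full(p, -1, dtype=np.int64)
        if informative.size > 1:
            sub = cmi[np.ix_(informative, informative)]
            sub = sub + sub.T
            # maximum spanning tree by Prim's algorithm, rooted at the first
            # informative feature; ties break towards lower feature indices
            m = informative.size
            in_tree = np.zeros(m, dtype=bool)
            in_tree[0] = True
            best_w = sub[0].copy()
            best_from = np.zeros(m, dtype=np.int64)
            for _ in range(m - 1):
                masked = np.where(in_tree, -np.inf, best_w)
                v = int(np.argmax(masked))
                in_tree[v] = True
                self.parent_[informative[v]] = informative[best_from[v]]
                better = sub[v] > best_w
                best_w[better] = sub[v][better]
                best_from[better] = v

        # CPTs: log P(x_j | parent value, class), Laplace-smoothed
        self.cpt_ = []
        for j in range(p):
            aj = int(self.arity_[j])
            pa = int(self.parent_[j])
            ap = int(self.arity_[pa]) if pa >= 0 else 1
            counts = np.zeros((n_classes, ap, aj))
            pa_vals = Xd[:, pa] if pa >= 0 else np.zeros(n, dtype=np.int64)
            np.add.at(counts, (yi, pa_vals, Xd[:, j]), 1.0)
            counts += self.alpha
            self.cpt_.append(np.log(counts / counts.sum(axis=2, keepdims=True)))
        return self

    def _cond_mutual_info(self, xi, xj, y) -> float:
        total = 0.0
        n = len(y)
        for c in range(self.classes_.size):
            m = y == c
            nc = int(m.sum())
            if nc == 0:
                continue
            joint = np.zeros((xi[m].max() + 1, xj[m].max() + 1))
            np.add.at(joint, (xi[m], xj[m]), 1.0)
            joint /= nc
            pi = joint.sum(axis=1, keepdims=True)
            pj = joint.sum(axis=0, keepdims=True)
            nz = joint > 0
            total += (nc / n) * float(
                (joint[nz] * np.log(joint[nz] / (pi @ pj)[nz])).sum()
            )
        return total

    def predict_proba(self, X):
        X = check_array(np.asarray(X, dtype=np.float64))
        Xd = self._discretize(X)
        n, p = Xd.shape
        log_post = np.tile(self.log_prior_, (n, 1))
        for j in range(p):
            pa = int(self.parent_[j])
            pa_vals = Xd[:, pa] if pa >= 0 else np.zeros(n, dtype=np.int64)
            for c in range(self.classes_.size):
                log_post[:, c] += self.cpt_[j][c, pa_vals, Xd[:, j]]
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


class DecisionTableClassifier(_DiscretizingClassifier):
    """Decision table with greedy forward selection on leave-one-out accuracy.

    Features are MDL-discretized; starting from the empty table (majority
    class), features are added one at a time whenever they strictly improve
    the leave-one-out table accuracy.  Prediction looks up the cell of the
    selected features and returns its training class frequencies; unseen
    cells fall back to the global class distribution.
    """

    def fit(self, X, y):
        X, yi = self._check_fit_inputs(X, y)
        Xd = self._discretize_fit(X, yi)
        n, p = Xd.shape
        self.global_counts_ = np.bincount(yi, minlength=self.classes_.size).astype(
            np.float64
        )

        selected: list[int] = []
        cells = np.zeros(n, dtype=np.int64)
        best = self._loo_accuracy(cells, yi)
        improved = True
        while improved and len(selected) < p:
            improved = False
            best_j, best_acc, best_cells = -1, best, None
            for j in range(p):
                if j in selected or self.arity_[j] < 2:
                    continue
                cand = self._compact(cells * self.arity_[j] + Xd[:, j])
                acc = self._loo_accuracy(cand, yi)
                if acc > best_acc:
                    best_j, best_acc, best_cells = j, acc, cand
            if best_j >= 0:
                selected.append(best_j)
                cells, best = best_cells, best_acc
                improved = True
        self.selected_ = np.asarray(selected, dtype=np.int64)

        keys = [tuple(row) for row in Xd[:, self.selected_]]
        table: dict[tuple, np.ndarray] = {}
        for key, cls in zip(keys, yi):
            table.setdefault(key, np.zeros(self.classes_.size))[cls] += 1.0
        self.table_ = table
        return self

    @staticmethod
    def _compact(cells: np.ndarray) -> np.ndarray:
        _, inv = np.unique(cells, return_inverse=True)
        return inv

    def _loo_accuracy(self, cells: np.ndarray, yi: np.ndarray) -> float:
        n = len(yi)
        ncells = int(cells.max()) + 1 if n else 0
        counts = np.zeros((ncells, self.classes_.size))
        np.add.at(counts, (cells, yi), 1.0)
        totals = np.bincount(yi, minlength=self.classes_.size).astype(np.float64)
        correct = 0
        for i in range(n):
            row = counts[cells[i]].copy()
            row[yi[i]] -= 1.0
            if row.sum() == 0:
                glob = totals.copy()
                glob[yi[i]] -= 1.0
                pred = int(np.argmax(glob))
            else:
                top = np.flatnonzero(row == row.max())
                if top.size == 1:
                    pred = int(top[0])
                else:
                    glob = totals.copy()
                    glob[yi[i]] -= 1.0
                    pred = int(top[np.argmax(glob[top])])
            correct += int(pred == yi[i])
        return correct / n

    def predict_proba(self, X):
        X = check_array(np.asarray(X, dtype=np.float64))
        Xd = self._discretize(X)
        global_freq = self.global_counts_ / self.global_counts_.sum()
        out = np.empty((len(Xd), self.classes_.size))
        for i, row in enumerate(Xd[:, self.selected_]):
            counts = self.table_.get(tuple(row))
            out[i] = global_freq if counts is None else counts / counts.sum()
        return out


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the six benchmark classifiers by name."""
    if name == "naive_bayes":
        return GaussianNB()
    if name == "bayes_net":
        return TreeAugmentedNB()
    if name == "random_tree":
        return DecisionTreeClassifier(max_features="sqrt", random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if name == "decision_table":
        return DecisionTableClassifier()
    if name == "logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(C=1.0, max_iter=2000)),
            ]
        )
    raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def train_classifier(name: str, X, y, seed: int = 0):
    """Fit a named classifier; errors on unknown names and single-class labels."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelError("training labels contain a single class")
    model = make_classifier(name, seed)
    model.fit(X, y)
    return model
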