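"""Pairwise repertoire classification on binary feature vectors.

Single TCR sequences carry only weak stage information; the protocol
here mirrors that setting: feature-identical sequences shared by the two
classes are removed, class sizes are balanced, a stratified 70/30 split
is made, and a logistic (single-layer sigmoid) model is trained on the
sparse binary features.  Aggregating the predictions of m sequences
from the same repertoire (summing log-odds, equivalent to multiplying
predicted probabilities) sharpens discrimination as m grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .feature_encoding import FeatureScheme, encode_matrix
from .repertoire_io import Repertoire


@dataclass
class PairDataset:
    """Balanced, deduplicated train/test splits for two stages.

    ``y`` is 1 for the first repertoire's class, 0 for the second.
    """

    X_train: sp.csr_matrix
    y_train: np.ndarray
    X_test: sp.csr_matrix
    y_test: np.ndarray
    label_a: str
    label_b: str
    n_shared_removed: int

    def class_sizes(self) -> tuple[int, int]:
        y = np.concatenate([self.y_train, self.y_test])
        return int((y == 1).sum()), int((y == 0).sum())


def _signatures(X: sp.csr_matrix) -> np.ndarray:
    """A hashable signature per row (the exact active-index tuple)."""
    return np.array([X.indices[X.indptr[i]:X.indptr[i + 1]].tobytes()
                     for i in range(X.shape[0])], dtype=object)


def prepare_pair(rep_a: Repertoire, rep_b: Repertoire, scheme: FeatureScheme,
                 seed: int = 0, balance: str = "loose",
                 test_fraction: float = 0.3) -> PairDataset:
    """Build a classification dataset for two repertoires.

    All sequences whose feature vectors appear in both classes are
    removed from both.  The larger class is then subsampled: with
    ``balance='loose'`` (default) so that it exceeds the smaller by at
    most 25%, with ``balance='literal'`` down to 25% of the smaller.
    Finally a stratified 70/30 train/test split is drawn.
    """
    Xa = encode_matrix(rep_a, scheme)
    Xb = encode_matrix(rep_b, scheme)
    sig_a, sig_b = _signatures(Xa), _signatures(Xb)
    shared = set(sig_a) & set(sig_b)
    keep_a = np.array([s not in shared for s in sig_a], bool)
    keep_b = np.array([s not in shared for s in sig_b], bool)
    n_removed = int((~keep_a).sum() + (~keep_b).sum())
    Xa, Xb = Xa[keep_a], Xb[keep_b]
    if Xa.shape[0] == 0 or Xb.shape[0] == 0:
        raise ValueError("a class was emptied by shared-sequence removal")

    rng = np.random.default_rng(seed)
    na, nb = Xa.shape[0], Xb.shape[0]
    if balance == "loose":
        cap = lambda small: int(np.floor(1.25 * small))
    elif balance == "literal":
        cap = lambda small: max(1, int(np.floor(0.25 * small)))
    else:
        raise ValueError(f"unknown balance mode {balance!r}")
    if na > nb and na > cap(nb):
        Xa = Xa[rng.choice(na, size=cap(nb), replace=False)]
    elif nb > na and nb > cap(na):
        Xb = Xb[rng.choice(nb, size=cap(na), replace=False)]

    X = sp.vstack([Xa, Xb]).tocsr()
    y = np.concatenate([np.ones(Xa.shape[0], dtype=np.int64),
                        np.zeros(Xb.shape[0], dtype=np.int64)])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed)
    return PairDataset(X_tr, y_tr, X_te, y_te,
                       rep_a.stage, rep_b.stage, n_removed)


class LinearRepertoireClassifier:
    """Logistic model over sparse binary features (sigmoid single layer)."""

    def __init__(self, model: LogisticRegression):
        self._model = model

    @property
    def weights(self) -> np.ndarray:
        return self._model.coef_.ravel()

    def log_odds(self, X: sp.csr_matrix) -> np.ndarray:
        return self._model.decision_function(X)

    def predict_proba(self, X: sp.csr_matrix) -> np.ndarray:
        return self._model.predict_proba(X)[:, 1]

    def auc(self, X: sp.csr_matrix, y: np.ndarray) -> float:
        return float(roc_auc_score(y, self.log_odds(X)))


def train_linear_classifier(ds: PairDataset, seed: int = 0,
                            c: float = 1.0) -> LinearRepertoireClassifier:
    """Train the logistic classifier on a prepared pair dataset."""
    if len(np.unique(ds.y_train)) < 2:
        raise ValueError("training set does not contain both classes")
    model = LogisticRegression(C=c, max_iter=2000, random_state=seed)
    model.fit(ds.X_train, ds.y_train)
    return LinearRepertoireClassifier(model)


def group_auc(classifier: LinearRepertoireClassifier, ds: PairDataset,
              m: int, n_groups: int = 2000, seed: int = 0) -> float:
    """AUC for classifying groups of m same-class test sequences.

    Each group's score is the sum of per-sequence log-odds (equivalent
    to multiplying the predicted probabilities); groups are drawn
    without replacement within a group.
    """
    rng = np.random.default_rng(seed)
    scores, labels = [], []
    lo = classifier.log_odds(ds.X_test)
    for cls in (1, 0):
        idx = np.nonzero(ds.y_test == cls)[0]
        if len(idx) < m:
            raise ValueError(f"class {cls} test set smaller than m={m}")
        for _ in range(n_groups):
            pick = rng.choice(idx, size=m, replace=False)
            scores.append(lo[pick].sum())
            labels.append(cls)
    return float(roc_auc_score(labels, scores))


def shuffle_labels(rep_a: Repertoire, rep_b: Repertoire,
                   seed: int = 0) -> tuple[Repertoire, Repertoire]:
    """Control: pool the two repertoires and randomly reassign the class
    labels, preserving the class sizes."""
    pooled = rep_a.clonotypes + rep_b.clonotypes
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pooled))
    na = len(rep_a)
    a = Repertoire([pooled[i] for i in perm[:na]],
                   stage=f"{rep_a.stage}-shuffled", chain=rep_a.chain)
    b = Repertoire([pooled[i] for i in perm[na:]],
                   stage=f"{rep_b.stage}-shuffled", chain=rep_b.chain)
    return a, b


def pca_gene_usage(usage_vectors: np.ndarray, gene_labels=None,
                   n_top_loadings: int = 5):
    """Centered PCA of per-(mouse, stage) gene-usage vectors.

    Returns ``(coordinates, loadings)``: coordinates on the first two
    components and first-axis loadings of the requested number of most
    loaded genes (all genes if ``gene_labels`` is None).
    """
    u = np.asarray(usage_vectors, dtype=float)
    if u.ndim != 2 or u.shape[0] < 3:
        raise ValueError("need at least 3 usage vectors of equal dimension")
    if np.allclose(u.var(axis=0), 0.0):
        raise ValueError("usage matrix has no variance")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(u)
    axis = pca.components_[0]
    if gene_labels is not None:
        order = np.argsort(-np.abs(axis))[:n_top_loadings]
        loadings = {gene_labels[i]: float(axis[i]) for i in order}
    else:
        loadings = {i: float(v) for i, v in enumerate(axis)}
    return coords, loadings
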