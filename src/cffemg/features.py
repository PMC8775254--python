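"""Classic time-domain sEMG features and shallow baseline classifiers.

The four canonical Hudgins-style features, computed per channel over each
window:

* MAV — mean absolute value, ``(1/N) sum |x_t|``;
* ZC  — zero crossings: sign changes ``x_t * x_{t+1} < 0`` whose jump exceeds
  an amplitude threshold;
* SSC — slope sign changes: interior points where
  ``(x_t - x_{t-1})(x_t - x_{t+1})`` is positive (and above threshold);
* WL  — waveform length, ``sum |x_t - x_{t-1}|``.

Baselines project the 4C-dimensional feature vectors with PCA or LDA and
classify with KNN, or use a small fully connected network (100-200-160 with
ReLU, dropout 0.5 and softmax).  Projections and scalers are always fitted on
the training fold only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier

from . import nn

FEATURE_ORDER = ("mav", "zc", "ssc", "wl")


def feature_names(C: int) -> list[str]:
    return [f"{f}_ch{c}" for f in FEATURE_ORDER for c in range(C)]


def extract_features(window: np.ndarray, zc_threshold: float = 0.0,
                     ssc_threshold: float = 0.0) -> np.ndarray:
    """Feature vector ``[MAV x C, ZC x C, SSC x C, WL x C]`` for one ``N x C``
    window.  Needs ``N >= 3`` (SSC uses interior points)."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("window must be N x C with N >= 3")
    d = np.diff(x, axis=0)
    mav = np.abs(x).mean(axis=0)
    wl = np.abs(d).sum(axis=0)
    zc = np.sum((x[:-1] * x[1:] < 0) & (np.abs(d) >= zc_threshold), axis=0)
    prod = -d[:-1] * d[1:]  # (x_t - x_{t-1})(x_t - x_{t+1})
    ssc = np.sum((prod > 0) & (prod >= ssc_threshold), axis=0)
    return np.concatenate([mav, zc, ssc, wl]).astype(float)


def extract_feature_table(windows, **kw) -> np.ndarray:
    """Stack :func:`extract_features` over an iterable of windows."""
    return np.stack([extract_features(w, **kw) for w in windows])


def write_feature_csv(path, table: np.ndarray, labels=None) -> pd.DataFrame:
    """Write a feature table as CSV with ``<feature>_ch<i>`` column names
    (plus a ``label`` column when given); returns the DataFrame."""
    C = table.shape[1] // len(FEATURE_ORDER)
    df = pd.DataFrame(table, columns=feature_names(C))
    if labels is not None:
        df.insert(0, "label", np.asarray(labels))
    df.to_csv(path, index=False)
    return df


def _ann_classify(Xtr, ytr, Xte, G, *, epochs=100, batch_size=32, seed=0,
                  lr=0.002, momentum=0.95, weight_decay=0.0005):
    """100-200-160 fully connected net with ReLU, dropout 0.5, softmax,
    trained with the same SGDM optimizer family as the deep models."""
    rng = np.random.default_rng(seed)
    d = Xtr.shape[1]
    layers = []
    for width in (100, 200, 160):
        layers += [nn.Dense(d, width, rng=rng.integers(2**31)), nn.ReLU()]
        d = width
    layers += [nn.Dropout(0.5, rng=rng.integers(2**31)),
               nn.Dense(d, G, rng=rng.integers(2**31))]
    y1h = np.zeros((len(ytr), G))
    y1h[np.arange(len(ytr)), ytr] = 1.0
    opt = nn.SGDM(lr=lr, momentum=momentum, weight_decay=weight_decay)
    n = len(Xtr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            h = Xtr[idx]
            for layer in layers:
                h = layer.forward(h, True)
            probs = nn.softmax(h)
            _, gz = nn.cross_entropy(probs, y1h[idx])
            g = gz
            for layer in reversed(layers):
                g = layer.backward(g)
            opt.step(layers)
    h = Xte
    for layer in layers:
        h = layer.forward(h, False)
    return nn.softmax(h).argmax(axis=1)


def baseline_classify(train_X, train_y, test_X, test_y, method: str,
                      *, n_components: int | None = None, k: int = 5,
                      seed: int = 0, ann_epochs: int = 100) -> float:
    """Fit a shallow baseline on training features and return held-out accuracy.

    ``method`` is one of ``pca_knn``, ``lda_knn``, ``ann``.  Component counts
    default to ``min(dim, 20)`` for PCA and ``G - 1`` for LDA; KNN uses
    Euclidean distance with ``k`` neighbours.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("need at least two classes in the training data")
    G = int(classes.max()) + 1
    if method == "pca_knn":
        nc = n_components or min(train_X.shape[1], 20)
        nc = min(nc, train_X.shape[1], len(train_X))
        proj = PCA(n_components=nc, random_state=seed).fit(train_X)
        clf = KNeighborsClassifier(n_neighbors=min(k, len(train_X)))
        clf.fit(proj.transform(train_X), train_y)
        pred = clf.predict(proj.transform(test_X))
    elif method == "lda_knn":
        nc = n_components or classes.size - 1
        nc = min(nc, classes.size - 1, train_X.shape[1])
        proj = LinearDiscriminantAnalysis(n_components=nc).fit(train_X, train_y)
        clf = KNeighborsClassifier(n_neighbors=min(k, len(train_X)))
        clf.fit(proj.transform(train_X), train_y)
        pred = clf.predict(proj.transform(test_X))
    elif method == "ann":
        pred = _ann_classify(train_X, train_y, test_X, G,
                             epochs=ann_epochs, seed=seed)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return float(np.mean(pred == test_y))
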