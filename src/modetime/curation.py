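"""Dataset curation: test/train/validation splitting with diversity selection.

The test set is a uniform random sample of the whole frame set.  From the
remaining 90%, the training set is chosen to be maximally separated in a
reduced PCA space (greedy farthest-point selection); the frames not selected
become the validation set.  Feature and label standardization constants are
fitted on the training split only.

Split sizes use floor rounding with the remainder going to validation, so
11 650 frames at 80/10/10 give exactly 9320/1165/1165.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CuratedDataset",
    "random_test_split",
    "pca_reduce",
    "maxmin_select",
    "assemble",
]


@dataclass
class CuratedDataset:
    """Standardized train/validation/test splits of a labelled frame set.

    Features and labels are stored raw; ``x_mean``/``x_scale`` and
    ``y_mean``/``y_scale`` (fitted on the training split) standardize them.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    feature_names: list[str]
    pca_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_train.shape[1]

    def standardize_x(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_mean) / self.x_scale

    def standardize_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_scale

    def destandardize_y(self, z: np.ndarray) -> np.ndarray:
        return z * self.y_scale + self.y_mean

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return {
            "train": (self.x_train, self.y_train),
            "val": (self.x_val, self.y_val),
            "test": (self.x_test, self.y_test),
        }[name]

    def manifest(self) -> dict:
        return {
            "sizes": {
                "train": int(self.y_train.size),
                "val": int(self.y_val.size),
                "test": int(self.y_test.size),
            },
            "n_features": int(self.n_features),
            "feature_names": self.feature_names,
            "pca": self.pca_meta,
        }

    def save(self, outdir: str | Path) -> None:
        """Write split index files and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, idx in (
            ("train", self.idx_train),
            ("val", self.idx_val),
            ("test", self.idx_test),
        ):
            np.savetxt(outdir / f"indices_{name}.txt", idx, fmt="%d")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def random_test_split(
    n: int, fraction: float = 0.10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Choose floor(fraction*n) test indices uniformly without replacement.

    Returns (test indices, remainder indices), both sorted.
    """
    if n == 0:
        raise ValueError("cannot split an empty frame set")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_test = int(np.floor(fraction * n))
    if n_test == 0:
        warnings.warn("test fraction rounds down to an empty test set")
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=n_test, replace=False))
    rest = np.setdiff1d(np.arange(n), test)
    return test, rest


def pca_reduce(features: np.ndarray, variance_target: float = 0.90) -> np.ndarray:
    """Scores on the leading principal components.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance_target``.  Features are centred by the PCA.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.allclose(x, x[0], atol=1e-12):
        raise ValueError("feature matrix is constant; PCA undefined")
    pca = PCA()
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, scores.shape[1])
    pca_reduce.last_meta = {
        "n_components": k,
        "explained_variance_ratio": pca.explained_variance_ratio_[:k].tolist(),
    }
    return scores[:, :k]


def maxmin_select(scores: np.ndarray, k: int) -> np.ndarray:
    """Greedy farthest-point selection of ``k`` rows of ``scores``.

    Starts from the two mutually farthest points, then repeatedly adds the
    point with the largest minimum Euclidean distance to the selected set.
    Deterministic: ties are broken toward the lowest index.  Returns indices
    in selection order.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} of {n} points")
    if k <= 0:
        return np.empty(0, dtype=int)
    if k == 1:
        return np.array([0])

    # seed pair: the two mutually farthest points, found in row chunks so the
    # full n x n distance matrix is never materialised
    sq = np.sum(x * x, axis=1)
    best = (-1.0, 0, 0)
    chunk = max(1, int(2**22 // max(n, 1)))
    for start in range(0, n, chunk):
        rows = slice(start, min(start + chunk, n))
        d2 = sq[rows, None] + sq[None, :] - 2.0 * (x[rows] @ x.T)
        flat = int(np.argmax(d2))
        i_loc, j = divmod(flat, n)
        val = float(d2[i_loc, j])
        if val > best[0]:
            best = (val, start + i_loc, j)
    i, j = best[1], best[2]
    first, second = (i, j) if i < j else (j, i)

    selected = [int(first), int(second)]
    min_d2 = np.minimum(
        np.sum((x - x[first]) ** 2, axis=1), np.sum((x - x[second]) ** 2, axis=1)
    )
    min_d2[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
        selected.append(nxt)
        cand = np.sum((x - x[nxt]) ** 2, axis=1)
        min_d2 = np.minimum(min_d2, cand)
        min_d2[nxt] = -np.inf
    return np.array(selected)


def assemble(
    frames: pd.DataFrame,
    seed: int = 0,
    train_frac: float = 0.80,
    val_frac: float = 0.10,
    test_frac: float = 0.10,
    variance_target: float = 0.90,
    label_column: str = "label",
) -> CuratedDataset:
    """Split labelled frames into standardized train/validation/test sets.

    The test split is random; the training split is the farthest-point
    selection of floor(train_frac*n) frames from the remainder in reduced PCA
    space (labels excluded from the PCA); leftovers form the validation set.
    """
    if abs(train_frac + val_frac + test_frac - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    feature_cols = [
        c for c in frames.columns
        if c not in ("trajectory_id", "frame_time", label_column)
    ]
    x = frames[feature_cols].to_numpy(dtype=float)
    y = frames[label_column].to_numpy(dtype=float)
    n = x.shape[0]

    idx_test, idx_rest = random_test_split(n, test_frac, seed)
    n_train = int(np.floor(train_frac * n))
    scores = pca_reduce(x[idx_rest], variance_target)
    pca_meta = dict(pca_reduce.last_meta)
    sel = maxmin_select(scores, n_train)
    idx_train = idx_rest[np.sort(sel)]
    idx_val = np.setdiff1d(idx_rest, idx_train)

    x_mean = x[idx_train].mean(axis=0)
    x_scale = x[idx_train].std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    y_mean = float(y[idx_train].mean())
    y_scale = float(y[idx_train].std())
    if y_scale < 1e-12:
        y_scale = 1.0

    return CuratedDataset(
        x_train=x[idx_train], y_train=y[idx_train],
        x_val=x[idx_val], y_val=y[idx_val],
        x_test=x[idx_test], y_test=y[idx_test],
        idx_train=idx_train, idx_val=idx_val, idx_test=idx_test,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        feature_names=feature_cols,
        pca_meta=pca_meta,
    )
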