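"""DJNP feature extraction, classifier training, and the model grid sweep.

The grid protocol evaluates every combination of feature extractor,
classifier (logistic regression, naive Bayes, support vector machine), batch
size and random 70/30 split, scoring each cell's held-out test set with the
six confusion-matrix indices and ranking rows by Cohen's kappa.

The built-in ``block_stats`` extractor is fully deterministic: the image is
resized to the extractor's input size, divided into a 16x16 block grid, and
described by per-block mean and variance plus the seven Hu moment invariants
(519 dimensions). The eight pretrained-CNN names from the original grid are
registered as input-size-faithful aliases of ``block_stats``; loading real
CNN weights requires the optional torch backend and fails loudly when torch
is absent, never silently.

``batch_size`` does not influence non-trained extractors; it is retained as
a grid dimension for protocol fidelity and forwarded to backends that
fine-tune.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KernelDensity
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import BackendMissingError
from .eval_metrics import confusion, performance_indices
from .pose_io import round_half_up

BLOCK_GRID = 16
N_HU_MOMENTS = 7
FEATURE_DIM = 2 * BLOCK_GRID * BLOCK_GRID + N_HU_MOMENTS  # 519

DEFAULT_BATCH_SIZES = (5, 8, 11, 14)


@dataclass(frozen=True)
class ExtractorSpec:
    name: str
    input_size: int = 224
    feature_dim: int = FEATURE_DIM
    backend: str = "builtin"  # builtin | torch

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")


#: extractor registry: the built-in extractor plus the eight CNN aliases,
#: each at the input size its namesake expects (AlexNet crops to 227 px)
EXTRACTORS: dict[str, ExtractorSpec] = {
    "block_stats": ExtractorSpec("block_stats", 224),
    "alexnet": ExtractorSpec("alexnet", 227),
    "densenet201": ExtractorSpec("densenet201", 224),
    "googlenet": ExtractorSpec("googlenet", 224),
    "mobilenetv2": ExtractorSpec("mobilenetv2", 224),
    "resnet101": ExtractorSpec("resnet101", 224),
    "resnet50": ExtractorSpec("resnet50", 224),
    "vgg16": ExtractorSpec("vgg16", 224),
    "vgg19": ExtractorSpec("vgg19", 224),
}


def get_extractor(name) -> ExtractorSpec:
    if isinstance(name, ExtractorSpec):
        return name
    key = str(name).lower()
    if key not in EXTRACTORS:
        raise ValueError(f"unknown extractor {name!r}; choose from {sorted(EXTRACTORS)}")
    return EXTRACTORS[key]


def _to_gray_float(img) -> np.ndarray:
    if isinstance(img, (str, Path)):
        from PIL import Image

        return np.asarray(Image.open(img).convert("L"), dtype=float) / 255.0
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _resize(arr: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    im = Image.fromarray((arr * 255.0).astype(np.float32), mode="F")
    out = im.resize((size, size), Image.BILINEAR)
    return np.asarray(out, dtype=float) / 255.0


def _block_reduce(arr: np.ndarray, grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block mean and variance on a grid x grid partition (row-major)."""
    n = arr.shape[0]
    edges = np.linspace(0, n, grid + 1).astype(int)
    widths = np.diff(edges).astype(float)
    counts = np.outer(widths, widths)
    s1 = np.add.reduceat(np.add.reduceat(arr, edges[:-1], axis=0), edges[:-1], axis=1)
    s2 = np.add.reduceat(np.add.reduceat(arr * arr, edges[:-1], axis=0), edges[:-1], axis=1)
    means = s1 / counts
    variances = s2 / counts - means**2
    return means, np.maximum(variances, 0.0)


def _hu_moments(arr: np.ndarray) -> np.ndarray:
    from skimage.measure import moments_central, moments_hu, moments_normalized

    if arr.sum() <= 0:
        return np.zeros(N_HU_MOMENTS)
    mu = moments_central(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = moments_normalized(mu)
    hu = moments_hu(nu)
    return np.nan_to_num(hu, nan=0.0, posinf=0.0, neginf=0.0)


def extract_features(img, spec: ExtractorSpec | str = "block_stats") -> np.ndarray:
    """Fixed-length feature vector of a DJNP raster.

    ``img`` is a 2D array, an RGB array, or a path to a PNG. The builtin
    extractor is deterministic; a spec with backend="torch" requires torch
    and raises BackendMissingError when it is unavailable.
    """
    spec = get_extractor(spec)
    if spec.backend == "torch":
        try:
            import torch  # noqa: F401
        except ImportError as e:
            raise BackendMissingError(
                f"extractor {spec.name!r} requested the torch backend, which is not installed"
            ) from e
        raise BackendMissingError(
            f"no pretrained weights are bundled for {spec.name!r}; install/point to a torchvision model"
        )
    arr = _resize(_to_gray_float(img), spec.input_size)
    means, variances = _block_reduce(arr, BLOCK_GRID)
    return np.concatenate([means.ravel(), variances.ravel(), _hu_moments(arr)])


def random_split(
    n: int, train_fraction: float = 0.7, seed: int = 0, labels: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test index split.

    The train size is round-half-up(n * train_fraction) — per class when
    ``labels`` are given (stratified), which reproduces the printed 71/31 and
    76/32 splits of 102- and 108-sample classes at 70%. Deterministic per
    seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    groups = [np.arange(n)]
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels length must equal n")
        groups = [np.nonzero(labels == c)[0] for c in np.unique(labels)]
    train_parts, test_parts = [], []
    for idx in groups:
        perm = idx[rng.permutation(len(idx))]
        k = round_half_up(len(idx) * train_fraction)
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    if len(train) == 0 or len(test) == 0:
        raise ValueError("split produced an empty train or test set")
    return train, test


class KernelDensityNB(BaseEstimator, ClassifierMixin):
    """Naive-Bayes-style classifier with per-class kernel density estimates.

    Replaces the Gaussian class-conditional of plain NB with a Gaussian KDE
    over the whole feature vector (bandwidth by Scott's rule on the pooled
    data); class priors are the training frequencies.
    """

    def __init__(self, bandwidth: float | str = "scott"):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.kdes_ = []
        self.log_priors_ = []
        for c in self.classes_:
            Xc = X[y == c]
            kde = KernelDensity(kernel="gaussian", bandwidth=self.bandwidth)
            kde.fit(Xc)
            self.kdes_.append(kde)
            self.log_priors_.append(math.log(len(Xc) / len(X)))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.stack(
            [kde.score_samples(X) + lp for kde, lp in zip(self.kdes_, self.log_priors_)],
            axis=1,
        )
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "LR"                 # LR | NB | SVM
    nb_mode: str = "kernel-density"  # kernel-density | gaussian
    svm_kernel: str = "linear"     # linear | rbf
    batch_size: int | None = None  # grid metadata; see module docstring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LR", "NB", "SVM"):
            raise ValueError("classifier kind must be LR, NB or SVM")
        if self.nb_mode not in ("gaussian", "kernel-density"):
            raise ValueError("nb_mode must be gaussian or kernel-density")
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValueError("svm_kernel must be linear or rbf")


def _make_estimator(spec: ClassifierSpec) -> Pipeline:
    if spec.kind == "LR":
        clf = LogisticRegression(max_iter=5000, solver="lbfgs")
    elif spec.kind == "NB":
        clf = GaussianNB() if spec.nb_mode == "gaussian" else KernelDensityNB()
    else:
        clf = SVC(kernel=spec.svm_kernel, random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(features, labels, spec: ClassifierSpec | None = None) -> Pipeline:
    """Fit a standardize-then-classify pipeline. Deterministic given the spec."""
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(spec)
    est.fit(np.asarray(features, dtype=float), labels)
    return est


@dataclass
class SweepResult:
    extractor: str
    classifier: str
    batch_size: int
    split_seed: int
    kappa: float = math.nan
    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    error: str | None = None


def _load_manifest(manifest, images_root=None) -> tuple[list, np.ndarray]:
    if isinstance(manifest, (str, Path)):
        root = Path(manifest).parent if images_root is None else Path(images_root)
        df = pd.read_csv(manifest)
    else:
        df = manifest
        root = Path(images_root) if images_root is not None else Path(".")
    files = [root / f for f in df["file"]]
    return files, df["label"].to_numpy()


def _feature_matrix(files, spec: ExtractorSpec, cache: dict) -> np.ndarray:
    key = (spec.backend, spec.input_size)
    if key not in cache:
        cache[key] = np.stack([extract_features(f, spec) for f in files])
    return cache[key]


def sweep(
    manifest,
    extractors: Sequence = ("block_stats",),
    classifiers: Sequence = ("LR", "NB", "SVM"),
    batch_sizes: Sequence[int] = DEFAULT_BATCH_SIZES,
    n_seeds: int = 20,
    images_root=None,
    train_fraction: float = 0.7,
    base_seed: int = 0,
    positive_label=None,
) -> list[SweepResult]:
    """Evaluate the full extractor x classifier x batch x split grid.

    ``manifest`` is a DataFrame or CSV path with ``file`` and ``label``
    columns. Returns exactly len(extractors) * len(classifiers) *
    len(batch_sizes) * n_seeds rows; a failed cell carries its error message
    and NaN indices instead of being dropped. The same n_seeds random splits
    are shared across the other grid axes, mirroring the 20-splits protocol.
    By default the positive class is the one with the smaller test set (ties
    to the alphabetically first).
    """
    if not extractors or not classifiers or not batch_sizes or n_seeds < 1:
        raise ValueError("all grid dimensions must be non-empty")
    files, labels = _load_manifest(manifest, images_root)
    n = len(files)
    cache: dict = {}
    splits = [
        random_split(n, train_fraction, seed=base_seed + k, labels=labels)
        for k in range(n_seeds)
    ]
    results: list[SweepResult] = []
    for ext_name in extractors:
        ext = get_extractor(ext_name)
        X = _feature_matrix(files, ext, cache)
        for clf_name in classifiers:
            for batch in batch_sizes:
                for k, (train, test) in enumerate(splits):
                    seed = base_seed + k
                    row = SweepResult(ext.name, str(clf_name), int(batch), seed)
                    try:
                        cspec = ClassifierSpec(kind=str(clf_name), batch_size=int(batch), seed=seed)
                        model = train_classifier(X[train], labels[train], cspec)
                        pred = model.predict(X[test])
                        pos = positive_label
                        if pos is None:
                            classes, counts = np.unique(labels[test], return_counts=True)
                            pos = classes[np.argmin(counts)]
                        idx = performance_indices(confusion(labels[test], pred, pos))
                        row.kappa = idx.kappa
                        row.accuracy = idx.accuracy
                        row.sensitivity = math.nan if idx.sensitivity is None else idx.sensitivity
                        row.specificity = math.nan if idx.specificity is None else idx.specificity
                        row.ppv = math.nan if idx.ppv is None else idx.ppv
                        row.npv = math.nan if idx.npv is None else idx.npv
                    except Exception as e:  # record, never drop silently
                        row.error = f"{type(e).__name__}: {e}"
                    results.append(row)
    return results


def sweep_results_frame(results: Sequence[SweepResult], sort: bool = True) -> pd.DataFrame:
    """Results as a DataFrame, sorted ascending by kappa for export."""
    df = pd.DataFrame([vars(r) for r in results])
    if sort and len(df):
        df = df.sort_values("kappa", ascending=True, kind="mergesort").reset_index(drop=True)
    return df


def summarize_sweep(results, kappa_threshold: float, inclusive: bool = True) -> dict:
    """Count well-performing grid rows per extractor and per classifier.

    Rows pass when kappa >= threshold (default inclusive, so tables whose
    kappa values are printed rounded to the threshold reproduce their own
    counts). Extractor percentages are of the selected rows, at 1 decimal.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = sweep_results_frame(results, sort=False)
    if len(df) == 0:
        raise ValueError("no sweep results to summarize")
    kap = df["kappa"].to_numpy(dtype=float)
    keep = kap >= kappa_threshold if inclusive else kap > kappa_threshold
    sel = df[keep]
    n = int(len(sel))
    by_ext = {}
    if n:
        for name, cnt in sel["extractor"].value_counts().items():
            by_ext[str(name)] = (int(cnt), round(100.0 * cnt / n, 1))
    by_clf = {str(k): int(v) for k, v in sel["classifier"].value_counts().items()}
    return {"n_selected": n, "by_extractor": by_ext, "by_classifier": by_clf}
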