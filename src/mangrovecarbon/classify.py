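"""Gaussian maximum-likelihood species classification.

Each land-cover class is modelled as a multivariate normal over a named
feature combination; a pixel is assigned to the class with the highest
quadratic discriminant

    gₖ(x) = ln πₖ − ½ ln|Σₖ| − ½ (x−μₖ)ᵀ Σₖ⁻¹ (x−μₖ).

Fifteen standard feature combinations (V1–V15) pair the visible bands,
the red-edge/NIR bands, vegetation indices and canopy height so the
contribution of each feature family to accuracy can be ranked.
Accuracy is scored with a confusion matrix: overall accuracy (OA),
producer's accuracy (PA, per reference class) and user's accuracy (UA,
per predicted class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CANONICAL_FEATURES, FeatureStack
from .raster import Raster

LABEL_COLUMN = "label"
NO_CLASS = -1.0  # label emitted for nodata pixels


@dataclass(frozen=True)
class FeatureCombination:
    """Named, ordered set of feature layers used as classifier input."""

    name: str
    layer_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.layer_names:
            raise ValueError("combination must name at least one layer")
        bad = [n for n in self.layer_names if n not in CANONICAL_FEATURES]
        if bad:
            raise ValueError(f"non-canonical layers in {self.name}: {bad}")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError(f"duplicate layers in {self.name}")


def _combo(name: str, *layers: str) -> FeatureCombination:
    return FeatureCombination(name, tuple(layers))


_VIS = ("R", "G", "B")
_ALL_BANDS = ("B", "G", "R", "RE", "NIR")
_ALL_IDX = ("NDVI", "GNDVI", "NDRE", "OSAVI", "LCI", "RVI", "MACI", "VREI", "SR")
_NO_RE_IDX = ("NDVI", "GNDVI", "OSAVI", "RVI", "MACI", "SR")
_NORM_IDX = ("NDVI", "GNDVI", "NDRE", "OSAVI", "LCI")

#: V1–V15: visible bands (V1) through full spectral+index+height fusion (V15).
DEFAULT_COMBINATIONS: dict[str, FeatureCombination] = {
    c.name: c
    for c in (
        _combo("V1", *_VIS),
        _combo("V2", *_VIS, "RE"),
        _combo("V3", *_VIS, "NIR"),
        _combo("V4", *_VIS, "RE", "NIR"),
        _combo("V5", "NDVI", "GNDVI"),
        _combo("V6", "NDVI", "NDRE"),
        _combo("V7", *_NORM_IDX),
        _combo("V8", *_VIS, "H_Mean"),
        _combo("V9", "NDVI", "NDRE", "H_Mean"),
        _combo("V10", "NDVI", "GNDVI", "H_Mean"),
        _combo("V11", *_NORM_IDX, "H_Mean"),
        _combo("V12", *_ALL_BANDS, *_ALL_IDX),
        _combo("V13", *_ALL_BANDS, *_NO_RE_IDX),
        _combo("V14", *_ALL_BANDS, *_NORM_IDX, "H_Mean"),
        _combo("V15", *_ALL_BANDS, *_ALL_IDX, "H_Mean"),
    )
}


@dataclass
class ClassModel:
    label: float
    mean: np.ndarray
    cov: np.ndarray
    prior: float
    # precomputed discriminant pieces
    _inv: np.ndarray = field(repr=False, default=None)
    _logdet: float = field(repr=False, default=0.0)


@dataclass
class MLCModel:
    """Per-class Gaussians over one feature combination."""

    combination: FeatureCombination
    classes: list[ClassModel]
    ridge: float

    def __post_init__(self) -> None:
        priors = np.array([c.prior for c in self.classes])
        if np.any(priors <= 0) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be positive and sum to 1")

    @property
    def labels(self) -> list[float]:
        return [c.label for c in self.classes]

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """gₖ(x) for every row of X; shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes)))
        for k, cm in enumerate(self.classes):
            diff = X - cm.mean
            maha = np.einsum("ij,jk,ik->i", diff, cm._inv, diff)
            out[:, k] = np.log(cm.prior) - 0.5 * cm._logdet - 0.5 * maha
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels for feature rows; ties go to the lowest class index."""
        g = self.discriminants(X)
        return np.array(self.labels)[np.argmax(g, axis=1)]


def mlc_from_parameters(
    combination: FeatureCombination,
    classes: list[tuple[float, np.ndarray, np.ndarray, float]],
) -> MLCModel:
    """Build an MLC model directly from (label, mean, cov, prior) tuples."""
    out = []
    for label, mean, cov, prior in classes:
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        chol = np.linalg.cholesky(cov)
        cm = ClassModel(label=float(label), mean=mean, cov=cov, prior=float(prior))
        cm._inv = np.linalg.inv(cov)
        cm._logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        out.append(cm)
    return MLCModel(combination=combination, classes=out, ridge=0.0)


def split_samples(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-class random train/validation split of labelled pixels."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label, grp in table.groupby(LABEL_COLUMN, sort=True):
        n = len(grp)
        n_train = int(round(n * train_fraction))
        if n_train < 2 or n_train >= n:
            raise ValueError(
                f"class {label!r}: split {n_train}/{n - n_train} leaves an "
                "empty or undersized stratum"
            )
        perm = rng.permutation(n)
        idx = grp.index.to_numpy()
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    return (
        table.loc[np.concatenate(train_idx)],
        table.loc[np.concatenate(test_idx)],
    )


def fit_mlc(
    train_table: pd.DataFrame,
    combination: FeatureCombination,
    priors: str | dict = "equal",
    ridge: float = 1e-6,
) -> MLCModel:
    """Fit per-class sample means/covariances (denominator n−1).

    Singular covariances are repaired by escalating the ridge on the
    diagonal until a Cholesky factorization succeeds (with a warning).
    """
    missing = [n for n in combination.layer_names if n not in train_table]
    if missing:
        raise ValueError(f"train table missing layers {missing}")
    d = len(combination.layer_names)
    classes: list[ClassModel] = []
    groups = list(train_table.groupby(LABEL_COLUMN, sort=True))
    n_total = len(train_table)
    for label, grp in groups:
        X = grp[list(combination.layer_names)].to_numpy(float)
        if len(X) < d + 2:
            raise ValueError(
                f"class {label!r} has {len(X)} samples; needs ≥ {d + 2} "
                f"for a {d}-dimensional covariance"
            )
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
        if priors == "equal":
            prior = 1.0 / len(groups)
        elif priors == "frequency":
            prior = len(X) / n_total
        else:
            prior = float(priors[label])
        svals = np.linalg.svd(cov, compute_uv=False)
        raw_singular = svals[-1] <= svals[0] * 1e-14
        eps = ridge
        for _ in range(30):
            try:
                chol = np.linalg.cholesky(cov + eps * np.eye(d))
                break
            except np.linalg.LinAlgError:
                eps *= 10.0
        else:
            raise ValueError(f"class {label!r}: covariance irreparably singular")
        if raw_singular:
            warnings.warn(
                f"class {label!r}: singular covariance regularized with "
                f"ridge {eps:g}",
                stacklevel=2,
            )
        reg = cov + eps * np.eye(d)
        cm = ClassModel(label=float(label), mean=mean, cov=reg, prior=prior)
        cm._inv = np.linalg.inv(reg)
        cm._logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        classes.append(cm)
    return MLCModel(combination=combination, classes=classes, ridge=ridge)


def classify(
    model: MLCModel, stack: FeatureStack, return_discriminant: bool = False
):
    """Label raster from per-pixel maximum discriminant; nodata propagates."""
    for name in model.combination.layer_names:
        if name not in stack:
            raise ValueError(f"stack missing layer {name!r}")
    ref = stack[model.combination.layer_names[0]]
    X = stack.pixel_table(model.combination.layer_names)
    valid = np.ones(X.shape[0], dtype=bool)
    for name in model.combination.layer_names:
        valid &= stack[name].mask.ravel()
    labels = np.full(X.shape[0], NO_CLASS)
    g = model.discriminants(X[valid])
    labels[valid] = np.array(model.labels)[np.argmax(g, axis=1)]
    label_raster = ref.like(labels.reshape(ref.shape))
    label_raster.nodata = NO_CLASS
    if return_discriminant:
        best = np.full(X.shape[0], np.nan)
        best[valid] = g.max(axis=1)
        return label_raster, ref.like(best.reshape(ref.shape))
    return label_raster


@dataclass
class ConfusionMatrix:
    """K×K counts; rows = predicted class, columns = reference class."""

    counts: np.ndarray
    labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_and_accuracy(
    predicted: np.ndarray, reference: np.ndarray, class_labels=None
) -> tuple[ConfusionMatrix, float, dict, dict]:
    """Confusion matrix + OA, per-class PA (reference) and UA (predicted).

    Ratios with a zero denominator are reported as NaN and must be
    excluded from any averaging by the caller.
    """
    predicted = np.asarray(predicted).ravel()
    reference = np.asarray(reference).ravel()
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must have equal length")
    if class_labels is None:
        class_labels = sorted(set(reference.tolist()) | set(predicted.tolist()))
    labels = list(class_labels)
    lut = {lab: k for k, lab in enumerate(labels)}
    try:
        p_idx = np.array([lut[v] for v in predicted.tolist()])
        r_idx = np.array([lut[v] for v in reference.tolist()])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside the class set") from None
    K = len(labels)
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (p_idx, r_idx), 1)
    oa = float(np.trace(counts)) / counts.sum()
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa_v = np.where(col > 0, diag / col, np.nan)
        ua_v = np.where(row > 0, diag / row, np.nan)
    pa = {lab: float(pa_v[k]) for k, lab in enumerate(labels)}
    ua = {lab: float(ua_v[k]) for k, lab in enumerate(labels)}
    return ConfusionMatrix(counts, labels), oa, pa, ua


def labeled_pixel_table(
    stack: FeatureStack,
    truth: Raster,
    max_per_class: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pixel feature table with a truth-label column.

    Pixels invalid in any layer are dropped; classes may be subsampled to
    ``max_per_class`` for tractable training.
    """
    X = stack.pixel_table()
    y = truth.values.ravel()
    valid = truth.mask.ravel()
    for name in stack.names:
        valid &= stack[name].mask.ravel()
    df = pd.DataFrame(X[valid], columns=stack.names)
    df[LABEL_COLUMN] = y[valid]
    if max_per_class is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for _, grp in df.groupby(LABEL_COLUMN, sort=True):
            idx = grp.index.to_numpy()
            if len(idx) > max_per_class:
                idx = np.sort(rng.choice(idx, size=max_per_class, replace=False))
            keep.append(idx)
        df = df.loc[np.concatenate(keep)]
    return df.reset_index(drop=True)


def evaluate_combinations(
    table: pd.DataFrame,
    combinations: list[FeatureCombination],
    seed: int = 0,
    train_fraction: float = 0.7,
    class_names: dict | None = None,
) -> pd.DataFrame:
    """Split → fit → score each combination; ranked by OA descending.

    One stratified split per call (same seed for every combination so the
    comparison is paired); the returned table carries OA plus per-class
    PA/UA columns.
    """
    if not combinations:
        raise ValueError("need at least one combination")
    train, test = split_samples(table, train_fraction, seed)
    rows = []
    for combo in combinations:
        try:
            model = fit_mlc(train, combo)
            pred = model.predict(test[list(combo.layer_names)].to_numpy(float))
            _, oa, pa, ua = confusion_and_accuracy(
                pred, test[LABEL_COLUMN].to_numpy()
            )
        except Exception as exc:
            raise RuntimeError(f"combination {combo.name}: {exc}") from exc
        row = {"combination": combo.name, "n_features": len(combo.layer_names),
               "OA": oa}
        for lab in sorted(pa):
            name = class_names.get(lab, lab) if class_names else lab
            row[f"PA_{name}"] = pa[lab]
            row[f"UA_{name}"] = ua[lab]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("OA", ascending=False, kind="stable")
    return out.reset_index(drop=True)
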