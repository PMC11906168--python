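"""Temporal feature fusion, random-forest classification, grouped CV, metrics.

The evaluation scheme is a grouped leave-one-unit-out cross-validation: all
samples from one steppe survey plot form a single unit (low intra-plot
variance would otherwise leak between train and test), while the sparse
point/transect classes are each split into five random disjoint subsets that
act as units.  Each unit is held out exactly once and the pooled test
predictions of all folds fill a single 4x4 confusion matrix, from which
overall accuracy, Cohen's kappa (with a delta-method 95% CI), and per-class
producer's/user's accuracy, binary accuracy and F-measure are derived.

The modelling surface follows the fit/results idiom:
``HabitatClassificationModel(...).fit()`` -> :class:`ClassificationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .imagery import CLASS_CODES
from .sampling import GroundTruthSet


# ---------------------------------------------------------------------------
# descriptor stacks


@dataclass
class DescriptorStack:
    """Named per-pixel feature layers: values (..., D) + D unique names."""

    values: np.ndarray
    names: list[str]
    date: str | None = None

    def __post_init__(self) -> None:
        if self.values.shape[-1] != len(self.names):
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")

    @property
    def D(self) -> int:
        return len(self.names)


def fuse_time_series(per_date_stacks: list[DescriptorStack]) -> DescriptorStack:
    """Concatenate per-date descriptor stacks in date-major order.

    All stacks must share the pixel grid and the per-date feature set; fused
    layer names are ``<date>_<feature>`` and D = T x d.
    """
    if not per_date_stacks:
        raise ValueError("no stacks to fuse")
    ref = per_date_stacks[0]
    for s in per_date_stacks[1:]:
        if s.values.shape[:-1] != ref.values.shape[:-1]:
            raise ValueError("inconsistent pixel grids across dates")
        if s.names != ref.names:
            raise ValueError("inconsistent per-date feature sets")
    order = np.argsort([s.date or "" for s in per_date_stacks], kind="stable")
    stacks = [per_date_stacks[i] for i in order]
    values = np.concatenate([s.values for s in stacks], axis=-1)
    names = [f"{s.date}_{n}" for s in stacks for n in s.names]
    return DescriptorStack(values=values, names=names)


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = true class C0-C3, columns = predicted."""

    counts: np.ndarray
    class_codes: tuple[str, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_codes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, class_codes: tuple[str, ...] = CLASS_CODES
    ) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(class_codes)}
        counts = np.zeros((len(class_codes), len(class_codes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, class_codes)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def fn(self) -> np.ndarray:
        return self.row_sums - np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.col_sums - np.diag(self.counts)


@dataclass
class MetricsReport:
    """Thematic-map accuracy metrics derived from one confusion matrix."""

    oa: float  # overall accuracy, percent
    kappa: float
    kappa_ci95: float  # half-width of the 95% CI
    pa: np.ndarray  # producer's accuracy (recall) per class
    ua: np.ndarray  # user's accuracy (precision) per class
    acc: np.ndarray  # per-class binary accuracy
    f: np.ndarray  # F-measure per class
    class_codes: tuple[str, ...] = CLASS_CODES
    n: int = 0

    @property
    def avg_pa(self) -> float:
        return float(np.mean(self.pa))

    @property
    def avg_ua(self) -> float:
        return float(np.mean(self.ua))

    @property
    def avg_acc(self) -> float:
        return float(np.mean(self.acc))

    @property
    def avg_f(self) -> float:
        return float(np.mean(self.f))

    def rounded(self, decimals: int = 2) -> dict:
        """Display values rounded half-up, as in standard accuracy tables."""
        r = lambda v: round_half_up(v, decimals)
        return {
            "OA": r(self.oa),
            "kappa": r(self.kappa),
            "kappa_ci95": round_half_up(self.kappa_ci95, 3),
            "PA": [r(v) for v in self.pa],
            "UA": [r(v) for v in self.ua],
            "ACC": [r(v) for v in self.acc],
            "F": [r(v) for v in self.f],
            "avg_PA": r(self.avg_pa),
            "avg_UA": r(self.avg_ua),
            "avg_ACC": r(self.avg_acc),
            "avg_F": r(self.avg_f),
        }

    def summary(self) -> str:
        d = self.rounded()
        lines = [
            "Thematic accuracy assessment",
            f"  n = {self.n}   OA = {d['OA']:.2f}%   "
            f"kappa = {d['kappa']:.2f} +/- {d['kappa_ci95']:.3f} (95% CI)",
            "  class            PA     UA     ACC    F",
        ]
        for i, c in enumerate(self.class_codes):
            lines.append(
                f"  {c:<14s} {d['PA'][i]:>5.2f}  {d['UA'][i]:>5.2f}  "
                f"{d['ACC'][i]:>5.2f}  {d['F'][i]:>5.2f}"
            )
        lines.append(
            f"  {'average':<14s} {d['avg_PA']:>5.2f}  {d['avg_UA']:>5.2f}  "
            f"{d['avg_ACC']:>5.2f}  {d['avg_F']:>5.2f}"
        )
        return "\n".join(lines)


def round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def kappa_variance(cm: ConfusionMatrix) -> float:
    """Large-sample delta-method variance of Cohen's kappa.

    Full four-term form with theta_1..theta_4 computed from the joint cell
    proportions and both marginals (not the simplified binomial-style
    approximation, which understates the variance on imbalanced matrices).
    """
    p = cm.counts.astype(np.float64) / cm.n
    pi_ = p.sum(axis=1)
    p_j = p.sum(axis=0)
    t1 = float(np.trace(p))
    t2 = float(pi_ @ p_j)
    t3 = float(np.sum(np.diag(p) * (pi_ + p_j)))
    t4 = float(np.sum(p * (p_j[:, None] + pi_[None, :]) ** 2))
    if t2 >= 1.0:
        raise ValueError("degenerate matrix: chance agreement is 1")
    var = (
        t1 * (1 - t1) / (1 - t2) ** 2
        + 2 * (1 - t1) * (2 * t1 * t2 - t3) / (1 - t2) ** 3
        + (1 - t1) ** 2 * (t4 - 4 * t2**2) / (1 - t2) ** 4
    ) / cm.n
    return max(var, 0.0)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All accuracy metrics of one confusion matrix.

    OA is in percent; kappa = (p_o - p_e) / (1 - p_e); the kappa CI half-width
    is 1.96 * sqrt(delta-method variance).  PA_i = diag_i / row_sum_i,
    UA_j = diag_j / col_sum_j, F = harmonic mean of PA and UA, ACC is the
    per-class one-vs-rest binary accuracy.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    n = cm.n
    diag = np.diag(counts)
    rows, cols = cm.row_sums.astype(float), cm.col_sums.astype(float)
    p_o = diag.sum() / n
    p_e = float(rows @ cols) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), 0.0)
        ua = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), 0.0)
        f = np.where(pa + ua > 0, 2 * pa * ua / np.where(pa + ua > 0, pa + ua, 1), 0.0)
    tn = n - rows - cols + diag
    acc = (diag + tn) / n
    return MetricsReport(
        oa=100.0 * p_o,
        kappa=float(kappa),
        kappa_ci95=1.96 * float(np.sqrt(kappa_variance(cm))),
        pa=pa,
        ua=ua,
        acc=acc,
        f=f,
        class_codes=cm.class_codes,
        n=n,
    )


def compare_models(cm_a: ConfusionMatrix, cm_b: ConfusionMatrix, alpha: float = 0.05) -> dict:
    """Two-sided kappa z-test between two accuracy-assessment matrices."""
    ma, mb = compute_metrics(cm_a), compute_metrics(cm_b)
    va, vb = kappa_variance(cm_a), kappa_variance(cm_b)
    se = np.sqrt(va + vb)
    if se == 0:
        if ma.kappa == mb.kappa:
            return {"z": 0.0, "p_value": 1.0, "significant": False,
                    "kappa_a": ma.kappa, "kappa_b": mb.kappa}
        raise ValueError("zero-variance degenerate input")
    z = (ma.kappa - mb.kappa) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return {
        "z": float(z),
        "p_value": float(p),
        "significant": bool(p < alpha),
        "kappa_a": ma.kappa,
        "kappa_b": mb.kappa,
    }


# ---------------------------------------------------------------------------
# random forest and grouped CV


@dataclass
class RFConfig:
    """Random-forest hyperparameters (canonical defaults)."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    seed: int = 0
    class_weight: str | dict | None = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def make_estimator(self, seed: int | None = None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=self.seed if seed is None else seed,
            class_weight=self.class_weight,
            n_jobs=self.n_jobs,
        )


def train_rf(
    features: np.ndarray, labels: np.ndarray, config: RFConfig | None = None
) -> RandomForestClassifier:
    """Fit a random forest; ``predict_proba`` exposes per-class vote fractions
    (trees are grown to purity, so averaged leaf probabilities are votes)."""
    if config is None:
        config = RFConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate single-class training set")
    est = config.make_estimator()
    est.fit(np.asarray(features), labels)
    return est


def build_cv_units(
    gt: GroundTruthSet, seed: int = 0, n_subsets: int = 5
) -> list[np.ndarray]:
    """Evaluation units for grouped leave-one-unit-out CV.

    Every plot-circle unit (steppe plot) is one unit; samples of each
    point/transect class are randomly partitioned into ``n_subsets`` disjoint
    subsets, each a unit.  Returned as a list of sample-index arrays covering
    every sample exactly once.
    """
    df = gt.samples.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    units: list[np.ndarray] = []
    plot_mask = df["source"] == "plot_circle"
    for _, idx in df[plot_mask].groupby("unit").groups.items():
        units.append(np.asarray(idx, dtype=np.intp))
    if plot_mask.any() and len(df[plot_mask]["unit"].unique()) < 2:
        raise ValueError("a class with a single unit cannot be cross-validated")
    for cls, grp in df[~plot_mask].groupby("class"):
        idx = np.asarray(grp.index, dtype=np.intp)
        if len(idx) < n_subsets:
            raise ValueError(f"class {cls} has too few samples for {n_subsets} subsets")
        perm = rng.permutation(idx)
        units.extend(np.array_split(perm, n_subsets))
    return units


def cross_validate(
    features: np.ndarray,
    gt: GroundTruthSet,
    rf_config: RFConfig | None = None,
    units: list[np.ndarray] | None = None,
    seed: int = 0,
) -> ConfusionMatrix:
    """Grouped leave-one-unit-out CV; pooled predictions in one matrix."""
    if rf_config is None:
        rf_config = RFConfig()
    features = np.asarray(features)
    labels = gt.samples["class"].to_numpy()
    if units is None:
        units = build_cv_units(gt, seed=seed)
    n = len(labels)
    covered = np.concatenate(units)
    if len(covered) != n or len(np.unique(covered)) != n:
        raise ValueError("units must cover every sample exactly once")
    y_pred = np.empty(n, dtype=object)
    all_idx = np.arange(n)
    for k, held in enumerate(units):
        train = np.setdiff1d(all_idx, held, assume_unique=False)
        est = rf_config.make_estimator(seed=rf_config.seed + k)
        est.fit(features[train], labels[train])
        y_pred[held] = est.predict(features[held])
    return ConfusionMatrix.from_predictions(labels, y_pred)


# ---------------------------------------------------------------------------
# model / results surface


class HabitatClassificationModel:
    """Random-forest habitat classification model over a descriptor stack.

    Parameters
    ----------
    features : (n_samples, D) array of per-pixel descriptors at GT pixels.
    gt : GroundTruthSet with class labels and CV grouping units.
    feature_names : the D fused descriptor names.
    config : RFConfig, optional.
    """

    def __init__(
        self,
        features: np.ndarray,
        gt: GroundTruthSet,
        feature_names: list[str] | None = None,
        config: RFConfig | None = None,
    ) -> None:
        self.features = np.asarray(features)
        self.gt = gt
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.features.shape[1])]
        )
        if self.features.shape[0] != len(gt):
            raise ValueError("one feature row per GT sample required")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature column required")
        self.config = config if config is not None else RFConfig()

    @classmethod
    def from_stack(
        cls,
        stack: DescriptorStack,
        gt: GroundTruthSet,
        config: RFConfig | None = None,
    ) -> "HabitatClassificationModel":
        values = stack.values
        if values.ndim == 3:  # (H, W, D) raster stack -> rows at GT pixels
            px = gt.pixels
            values = values[px[:, 0], px[:, 1], :]
        return cls(values, gt, stack.names, config)

    def subset(self, names: list[str]) -> "HabitatClassificationModel":
        """Model restricted to a feature subset (e.g. after selection)."""
        idx = [self.feature_names.index(n) for n in names]
        return HabitatClassificationModel(
            self.features[:, idx], self.gt, names, self.config
        )

    def fit(self, seed: int | None = None) -> "ClassificationResults":
        """Run grouped leave-one-unit-out CV, then refit on all samples."""
        seed = self.config.seed if seed is None else seed
        units = build_cv_units(self.gt, seed=seed)
        cm = cross_validate(self.features, self.gt, self.config, units=units)
        estimator = train_rf(
            self.features, self.gt.samples["class"].to_numpy(), self.config
        )
        return ClassificationResults(self, cm, compute_metrics(cm), estimator, seed)


@dataclass
class ClassificationResults:
    """Fit results: pooled-CV confusion matrix, metrics, deployed estimator."""

    model: HabitatClassificationModel
    confusion_matrix: ConfusionMatrix
    metrics: MetricsReport
    estimator: RandomForestClassifier
    seed: int

    def summary(self) -> str:
        head = (
            f"HabitatClassificationModel: D={len(self.model.feature_names)} "
            f"features, {self.model.config.n_trees} trees, seed={self.seed}\n"
        )
        return head + self.metrics.summary()

    def confusion_frame(self) -> pd.DataFrame:
        codes = list(self.confusion_matrix.class_codes)
        return pd.DataFrame(
            self.confusion_matrix.counts,
            index=codes,
            columns=[f"pred_{c}" for c in codes],
        )
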