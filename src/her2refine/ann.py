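"""Cut-point derivation from a Monte Carlo cross-validated network population.

The task: given per-case HER2 staining percentages and a binary mRNA
cluster label (low vs high), learn which scoring parameters predict the
high cluster and at what percentage each parameter's threshold sits.  A
population of small feed-forward networks (inputs -> one tanh hidden layer
-> sigmoid output) is trained under Monte Carlo cross-validation: each
resample draws a fresh train / validation / blind-test split, standardises
inputs on the training fold, fits candidate hidden widths by damped least
squares (Levenberg-Marquardt on the output residuals, with an L2 weight
penalty folded into the residual vector) and early-stops on validation
loss.  Test-fold predictions stay blind to training and supply the
population's ROC/AUC.

Per-parameter response curves sweep one input over a percentage grid with
the remaining inputs pinned at the cohort reference (median) profile, plus
empirical sensitivity/specificity of thresholding the raw parameter
against the cluster label.  Cut-points are placed where the class-separating
quality (Youden's J) of a single-threshold rule on the parameter is
maximal, with the rule direction (a lower bound ">= theta" vs a bounded
interval "0 < x <= theta") chosen by the better-separating form.
Parameters that neither separate the clusters beyond a margin nor carry
weight inside the trained networks (permutation importance) are marked as
not participating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .profiles import PATTERN_FIELDS, RefinedRuleSet

__all__ = [
    "FEATURES",
    "UnlearnableTargetError",
    "AnnConfig",
    "ModelFit",
    "AnnPopulation",
    "train_population",
    "roc_auc",
    "permutation_importance",
    "ResponseCurve",
    "response_curve",
    "CutpointRule",
    "derive_cutpoints",
    "ruleset_from_cutpoints",
]

#: Model inputs: the eight membranous pattern percentages, cytoplasmic
#: staining, and the total percentage of positive cells.
PATTERN_COLUMNS = tuple(f"pct_{name}" for name in PATTERN_FIELDS)
FEATURES = PATTERN_COLUMNS + ("pct_cytoplasmic", "pct_total_positive")

#: Derived sweep parameter: faint staining pooled across completeness.
FAINT_TOTAL = "faint_total"


class UnlearnableTargetError(ValueError):
    """The cluster label has a single class; nothing can be learned."""


@dataclass(frozen=True)
class AnnConfig:
    """Training configuration for the network population.

    ``test_fraction`` defaults to a blind test set of roughly 38 cases out
    of ~346 eligible.  ``hidden_nodes`` is the width sweep; the width with
    the best validation loss wins within each resample.  Early stopping
    monitors validation loss between Levenberg-Marquardt rounds of
    ``round_nfev`` function evaluations each.
    """

    hidden_nodes: tuple[int, ...] = (2, 4, 8, 16)
    n_models: int = 50
    test_fraction: float = 38.0 / 346.0
    val_fraction: float = 0.15
    early_stopping_patience: int = 4
    max_rounds: int = 30
    round_nfev: int = 30
    l2_penalty: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not (0.0 < self.test_fraction < 1.0 and 0.0 < self.val_fraction < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        if any(w < 1 for w in self.hidden_nodes):
            raise ValueError("hidden widths must be >= 1")


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training of a single tanh-hidden-layer network
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class _TanhNet:
    """inputs -> tanh hidden layer -> sigmoid output, with input scaler."""

    w1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    mean: np.ndarray  # scaler, fit on the training fold
    scale: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.scale
        A = np.tanh(Z @ self.w1.T + self.b1)
        return _sigmoid(A @ self.w2 + self.b2)


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, h: int, d: int):
    w1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _fit_lm(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    hidden: int,
    config: AnnConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Staged Levenberg-Marquardt fit with validation-based early stopping.

    Residuals are (predicted probability - label) per training case plus
    sqrt(l2) * w for every weight (not bias), so the damped least-squares
    step minimises the penalised squared error.  Training proceeds in
    rounds of ``round_nfev`` evaluations; the parameter vector with the
    best validation loss is kept and training stops once ``patience``
    rounds pass without improvement.
    """
    m, d = Xtr.shape
    h = hidden
    sql2 = np.sqrt(config.l2_penalty)
    n_weights = h * d + h  # w1 and w2 entries are penalised, biases are not

    def residuals(theta: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = _unpack(theta, h, d)
        A = np.tanh(Xtr @ w1.T + b1)
        p = _sigmoid(A @ w2 + b2)
        reg = sql2 * np.concatenate([w1.ravel(), w2])
        return np.concatenate([p - ytr, reg])

    def jacobian(theta: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = _unpack(theta, h, d)
        A = np.tanh(Xtr @ w1.T + b1)  # (m, h)
        p = _sigmoid(A @ w2 + b2)
        g = p * (1.0 - p)  # (m,)
        T = g[:, None] * (1.0 - A**2) * w2[None, :]  # (m, h)
        J = np.empty((m + n_weights, theta.size))
        J[:m, : h * d] = np.einsum("mh,md->mhd", T, Xtr).reshape(m, h * d)
        J[:m, h * d : h * d + h] = T
        J[:m, h * d + h : h * d + 2 * h] = g[:, None] * A
        J[:m, -1] = g
        reg = np.zeros((n_weights, theta.size))
        reg[: h * d, : h * d] = sql2 * np.eye(h * d)
        reg[h * d :, h * d + h : h * d + 2 * h] = sql2 * np.eye(h)
        J[m:] = reg
        return J

    def val_loss(theta: np.ndarray) -> float:
        w1, b1, w2, b2 = _unpack(theta, h, d)
        A = np.tanh(Xval @ w1.T + b1)
        p = _sigmoid(A @ w2 + b2)
        return float(np.mean((p - yval) ** 2))

    theta = _pack(
        rng.normal(scale=1.0 / np.sqrt(d), size=(h, d)),
        np.zeros(h),
        rng.normal(scale=1.0 / np.sqrt(h), size=h),
        0.0,
    )
    best_theta, best_loss = theta, val_loss(theta)
    stale = 0
    for _ in range(config.max_rounds):
        res = least_squares(
            residuals,
            theta,
            jac=jacobian,
            method="lm",
            max_nfev=config.round_nfev,
        )
        theta = res.x
        loss = val_loss(theta)
        if loss < best_loss - 1e-12:
            best_theta, best_loss = theta, loss
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
        if res.status in (1, 2, 3, 4):  # converged before exhausting the round
            if res.nfev < config.round_nfev:
                break
    return best_theta, best_loss


# ---------------------------------------------------------------------------
# Monte Carlo cross-validated population
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """One resample's winning network and its blind-test predictions."""

    net: _TanhNet
    hidden: int
    val_loss: float
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    test_proba: np.ndarray


@dataclass
class AnnPopulation:
    """The trained model population plus the cohort it was trained on."""

    models: list[ModelFit]
    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    config: AnnConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean predicted probability of the high cluster over the population."""
        X = np.asarray(X, dtype=float)
        return np.mean([m.net.predict_proba(X) for m in self.models], axis=0)

    @property
    def pooled_test(self) -> tuple[np.ndarray, np.ndarray]:
        y = np.concatenate([self.y[m.test_idx] for m in self.models])
        p = np.concatenate([m.test_proba for m in self.models])
        return y, p

    def pooled_test_auc(self) -> float:
        y, p = self.pooled_test
        return roc_auc(y, p)

    def mean_test_auc(self) -> float:
        aucs = [
            roc_auc(self.y[m.test_idx], m.test_proba)
            for m in self.models
            if len(np.unique(self.y[m.test_idx])) == 2
        ]
        return float(np.mean(aucs))

    def classification_rate(self, threshold: float = 0.5) -> float:
        y, p = self.pooled_test
        return float(np.mean((p >= threshold) == (y == 1)))

    def reference_profile(self) -> np.ndarray:
        """Per-feature cohort median, the default curve-sweep anchor."""
        return np.median(self.X, axis=0)


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extract the model inputs from a cohort frame.

    Adds ``pct_total_positive`` (sum of the eight membranous pattern
    percentages) when absent.
    """
    df = cohort.copy()
    if "pct_total_positive" not in df.columns:
        df["pct_total_positive"] = df[list(PATTERN_COLUMNS)].sum(axis=1)
    missing = [c for c in FEATURES if c not in df.columns]
    if missing:
        raise KeyError(f"cohort is missing feature columns: {missing}")
    return df[list(FEATURES)]


def _split(
    y: np.ndarray, test_fraction: float, val_fraction: float, rng: np.random.Generator
):
    """Class-stratified train/val/test split of indices."""
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_test = max(1, int(round(test_fraction * n)))
        n_val = max(1, int(round(val_fraction * n)))
        test.append(idx[:n_test])
        val.append(idx[n_test : n_test + n_val])
        train.append(idx[n_test + n_val :])
    return (
        np.concatenate(train),
        np.concatenate(val),
        np.concatenate(test),
    )


def train_population(
    cohort: pd.DataFrame | np.ndarray,
    labels: Sequence,
    config: AnnConfig | None = None,
) -> AnnPopulation:
    """Train the Monte Carlo cross-validated network population.

    ``cohort`` is either a cohort frame (features are extracted with
    :func:`design_matrix`) or a ready feature matrix aligned with
    ``FEATURES``.  ``labels`` is the binary cluster label (``"low"`` /
    ``"high"`` or 0/1), the high cluster being the positive class.
    Reproducible given ``config.seed``.
    """
    config = config or AnnConfig()
    if isinstance(cohort, pd.DataFrame):
        Xdf = design_matrix(cohort)
        X = Xdf.to_numpy(dtype=float)
        names = tuple(Xdf.columns)
    else:
        X = np.asarray(cohort, dtype=float)
        names = FEATURES[: X.shape[1]]
    y = _as_binary(labels)
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and labels have different lengths")
    if X.shape[0] < 50:
        raise ValueError(f"need at least 50 labelled cases, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise UnlearnableTargetError("cluster label has a single class")

    rng = np.random.default_rng(config.seed)
    models: list[ModelFit] = []
    for _ in range(config.n_models):
        tr, va, te = _split(y, config.test_fraction, config.val_fraction, rng)
        mean = X[tr].mean(axis=0)
        scale = X[tr].std(axis=0)
        scale[scale == 0] = 1.0
        Ztr, Zva = (X[tr] - mean) / scale, (X[va] - mean) / scale
        fits = [
            (*_fit_lm(Ztr, y[tr], Zva, y[va], width, config, rng), width)
            for width in config.hidden_nodes
        ]
        best_loss = min(f[1] for f in fits)
        # Validation folds are small; among widths whose validation loss is
        # indistinguishable from the best, keep the largest (the target rule
        # is a union of several thresholds and needs the capacity).
        theta, vloss, width = max(
            (f for f in fits if f[1] <= best_loss + 1e-6), key=lambda f: f[2]
        )
        w1, b1, w2, b2 = _unpack(theta, width, X.shape[1])
        net = _TanhNet(w1, b1, w2, float(b2), mean, scale)
        models.append(
            ModelFit(
                net=net,
                hidden=width,
                val_loss=vloss,
                train_idx=tr,
                val_idx=va,
                test_idx=te,
                test_proba=net.predict_proba(X[te]),
            )
        )
    return AnnPopulation(models=models, feature_names=names, X=X, y=y, config=config)


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        mapped = np.where(arr.astype(str) == "high", 1, 0)
        bad = ~np.isin(arr.astype(str), ("low", "high"))
        if bad.any():
            raise ValueError(f"unrecognised cluster labels: {set(arr[bad])}")
        return mapped.astype(float)
    return (arr.astype(float) > 0.5).astype(float)


def roc_auc(labels: Sequence, scores: Sequence) -> float:
    """Area under the ROC curve as Mann-Whitney concordance (ties count 1/2)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
        / (pos.size * neg.size)
    )


def permutation_importance(
    population: AnnPopulation,
    n_repeats: int = 3,
    seed: int | None = None,
) -> dict[str, float]:
    """Mean pooled-test AUC drop when one input column is shuffled.

    Measures whether the trained networks actually rely on a parameter,
    complementing the marginal (single-parameter) separability measure.
    """
    rng = np.random.default_rng(
        population.config.seed + 1 if seed is None else seed
    )
    base = population.pooled_test_auc()
    out: dict[str, float] = {}
    for j, name in enumerate(population.feature_names):
        drops = []
        for _ in range(n_repeats):
            preds, ys = [], []
            for m in population.models:
                Xp = population.X[m.test_idx].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                preds.append(m.net.predict_proba(Xp))
                ys.append(population.y[m.test_idx])
            drops.append(base - roc_auc(np.concatenate(ys), np.concatenate(preds)))
        out[name] = float(np.mean(drops))
    return out


# ---------------------------------------------------------------------------
# Response curves and cut-points
# ---------------------------------------------------------------------------


@dataclass
class ResponseCurve:
    """One parameter's model response and empirical screening curves.

    ``mean_predicted_probability``: population-mean predicted probability
    as the parameter sweeps ``grid`` with all other inputs pinned at the
    reference profile.  ``sensitivity`` / ``specificity`` are the empirical
    operating characteristics of the rule "parameter >= t" against the
    cluster labels, per grid threshold.  ``values`` holds the parameter's
    observed per-case values for downstream threshold placement.
    """

    parameter: str
    grid: np.ndarray
    mean_predicted_probability: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    values: np.ndarray
    labels: np.ndarray


def default_grid() -> np.ndarray:
    """1-percentage-point grid over [0, 100]."""
    return np.arange(0.0, 100.0 + 0.5, 1.0)


def _parameter_values(population: AnnPopulation, parameter: str) -> np.ndarray:
    names = list(population.feature_names)
    if parameter == FAINT_TOTAL:
        fc = population.X[:, names.index("pct_faint_complete")]
        fi = population.X[:, names.index("pct_faint_incomplete")]
        return fc + fi
    if parameter not in names:
        raise KeyError(f"unknown model parameter {parameter!r}")
    return population.X[:, names.index(parameter)]


def response_curve(
    population: AnnPopulation,
    parameter: str,
    grid: np.ndarray | None = None,
    reference: np.ndarray | None = None,
) -> ResponseCurve:
    """Sweep one parameter over a percentage grid.

    The sweep holds every other input at the reference profile (cohort
    median by default).  Sweeping a membranous pattern keeps the
    ``pct_total_positive`` input consistent with the pattern percentages;
    sweeping ``pct_total_positive`` itself leaves the patterns fixed, which
    asks specifically whether the total percentage carries information
    beyond the patterns.  ``faint_total`` sweeps the pooled faint
    percentage, split between complete/incomplete in the reference
    proportion.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    names = list(population.feature_names)
    ref = population.reference_profile() if reference is None else np.asarray(reference)

    sweep = np.tile(ref, (grid.size, 1))
    i_total = names.index("pct_total_positive") if "pct_total_positive" in names else None
    pattern_ix = [names.index(c) for c in PATTERN_COLUMNS if c in names]

    if parameter == FAINT_TOTAL:
        i_fc, i_fi = names.index("pct_faint_complete"), names.index("pct_faint_incomplete")
        ref_total = ref[i_fc] + ref[i_fi]
        frac_c = ref[i_fc] / ref_total if ref_total > 0 else 0.5
        sweep[:, i_fc] = grid * frac_c
        sweep[:, i_fi] = grid * (1.0 - frac_c)
    else:
        if parameter not in names:
            raise KeyError(f"unknown model parameter {parameter!r}")
        sweep[:, names.index(parameter)] = grid
    if i_total is not None and parameter != "pct_total_positive":
        sweep[:, i_total] = sweep[:, pattern_ix].sum(axis=1)

    proba = population.predict(sweep)

    values = _parameter_values(population, parameter)
    y = population.y
    pos, neg = values[y == 1], values[y == 0]
    sens = np.array([np.mean(pos >= t) for t in grid])
    spec = np.array([np.mean(neg < t) for t in grid])
    return ResponseCurve(
        parameter=parameter,
        grid=grid,
        mean_predicted_probability=proba,
        sensitivity=sens,
        specificity=spec,
        values=values,
        labels=y,
    )


@dataclass(frozen=True)
class CutpointRule:
    """A derived per-parameter threshold rule.

    ``direction`` is ">=" (parameter at or above the threshold predicts the
    high cluster) or "<=" (parameter present, i.e. > 0, and at or below the
    threshold).  ``selected`` records whether the parameter participates in
    defining the cluster at all.
    """

    parameter: str
    direction: str
    threshold: float
    selected: bool
    balanced_accuracy: float = float("nan")
    importance: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in (">=", "<="):
            raise ValueError(f"direction must be '>=' or '<=', got {self.direction!r}")
        if not (0.0 < self.threshold < 100.0):
            raise ValueError(f"threshold must lie in (0, 100), got {self.threshold}")


def _youden_curves(values: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """Youden's J over the grid for both rule forms.

    ``ge``: predict high when value >= t.  ``le``: predict high when
    0 < value <= t (the strictly-positive guard mirrors the refined rules).
    """
    pos, neg = values[y == 1], values[y == 0]
    sens_ge = np.array([np.mean(pos >= t) for t in grid])
    spec_ge = np.array([np.mean(neg < t) for t in grid])
    j_ge = sens_ge + spec_ge - 1.0
    sens_le = np.array([np.mean((pos > 0) & (pos <= t)) for t in grid])
    spec_le = np.array([1.0 - np.mean((neg > 0) & (neg <= t)) for t in grid])
    j_le = sens_le + spec_le - 1.0
    return j_ge, j_le


def _best_threshold(values, y, grid, criterion, proba):
    """Pick (direction, threshold, balanced_accuracy) for one parameter."""
    inner = grid[(grid > 0.0) & (grid < 100.0)]
    j_ge, j_le = _youden_curves(values, y, inner)
    best_ge = float(j_ge.max())
    best_le = float(j_le.max())
    # Smallest grid value attaining the maximum; on an exact tie between
    # forms prefer the bounded "<=" rule (an upper limit is only ever
    # identified by where the positive class stops occurring).
    if best_ge > best_le + 1e-12:
        direction, j = ">=", j_ge
    else:
        direction, j = "<=", j_le
    t_youden = float(inner[int(np.argmax(j))])
    j_best = float(j.max())

    if criterion == "youden":
        t = t_youden
    elif criterion == "crossing":
        t = _sens_spec_crossing(values, y, inner, t_youden)
    elif criterion == "probability":
        t = _probability_crossing(inner, proba, direction, t_youden)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return direction, t, (1.0 + j_best) / 2.0


def _sens_spec_crossing(values, y, grid, t_youden) -> float:
    pos, neg = values[y == 1], values[y == 0]
    sens = np.array([np.mean(pos >= t) for t in grid])
    spec = np.array([np.mean(neg < t) for t in grid])
    diff = sens - spec
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:
        warnings.warn(
            "sensitivity and specificity curves do not cross; "
            "falling back to the Youden maximum",
            stacklevel=3,
        )
        return t_youden
    crossings = grid[sign_change]
    if crossings.size > 1:
        warnings.warn(
            f"multiple sensitivity/specificity crossings at {crossings.tolist()}; "
            "picking the one nearest the Youden maximum",
            stacklevel=3,
        )
    return float(crossings[np.argmin(np.abs(crossings - t_youden))])


def _probability_crossing(grid, proba, direction, t_youden) -> float:
    above = proba >= 0.5
    change = np.flatnonzero(np.diff(above.astype(int)) != 0)
    if change.size == 0:
        warnings.warn(
            "model response curve never crosses probability 0.5; "
            "falling back to the Youden maximum",
            stacklevel=3,
        )
        return t_youden
    crossings = grid[change + 1]
    if direction == "<=":
        down = crossings[np.diff(above.astype(int))[change] < 0]
        crossings = down if down.size else crossings
    else:
        up = crossings[np.diff(above.astype(int))[change] > 0]
        crossings = up if up.size else crossings
    return float(crossings[np.argmin(np.abs(crossings - t_youden))])


def _rule_fires(values: np.ndarray, direction: str, threshold: float) -> np.ndarray:
    if direction == ">=":
        return values >= threshold
    return (values > 0) & (values <= threshold)


def derive_cutpoints(
    curves: Sequence[ResponseCurve],
    criterion: str = "youden",
    margin: float = 0.01,
    eliminate: bool = True,
    importances: dict[str, float] | None = None,
) -> list[CutpointRule]:
    """Place a threshold rule on each swept parameter and flag participation.

    Each parameter first receives its best single-threshold rule (direction
    and percentage).  A parameter is then ``selected`` -- it participates in
    defining the cluster -- when (a) its rule beats chance by more than
    ``margin`` balanced accuracy and (b) it survives backward elimination:
    the retained rules, OR-combined, predict the high cluster, and a rule
    whose removal does not reduce agreement with the cluster labels is
    discarded (weakest first, until stable).  Elimination is what rejects
    inputs that are marginally informative yet redundant given the staining
    patterns -- notably the total percentage of positive cells, whose
    threshold rule only adds false positives once the per-pattern rules are
    in place -- while keeping rare but necessary patterns such as moderate
    incomplete staining.

    ``importances`` (see :func:`permutation_importance`) are attached to
    the emitted rules as a cross-check diagnostic when provided.
    """
    proto = []
    for curve in curves:
        direction, threshold, bal_acc = _best_threshold(
            curve.values, curve.labels, curve.grid, criterion,
            curve.mean_predicted_probability,
        )
        proto.append((curve, direction, threshold, bal_acc))

    y = curves[0].labels.astype(bool) if curves else np.zeros(0, dtype=bool)
    candidate = [p for p in proto if p[3] > 0.5 + margin]
    retained = list(candidate)
    if eliminate and retained:
        def accuracy(rules_) -> float:
            if not rules_:
                return float(np.mean(~y))
            fired = np.any(
                [_rule_fires(c.values, d, t) for c, d, t, _ in rules_], axis=0
            )
            return float(np.mean(fired == y))

        # Phase 1: drop rules whose removal strictly improves agreement --
        # their unique firings are predominantly false positives (this is
        # what rejects the marginally-correlated total-percentage input,
        # whose coverage the per-pattern rules already provide without its
        # false alarms).  Phase 2: prune rules that are exactly redundant.
        for strict in (True, False):
            changed = True
            while changed and retained:
                changed = False
                for p in sorted(retained, key=lambda p: p[3]):
                    rest = [q for q in retained if q is not p]
                    better = (
                        accuracy(rest) > accuracy(retained)
                        if strict
                        else accuracy(rest) >= accuracy(retained)
                    )
                    if better:
                        retained = rest
                        changed = True
                        break
    kept = {id(p) for p in retained}

    rules = []
    for p in proto:
        curve, direction, threshold, bal_acc = p
        if importances is None:
            imp = float("nan")
        elif curve.parameter == FAINT_TOTAL:
            imp = importances.get("pct_faint_complete", 0.0) + importances.get(
                "pct_faint_incomplete", 0.0
            )
        else:
            imp = importances.get(curve.parameter, 0.0)
        rules.append(
            CutpointRule(
                parameter=curve.parameter,
                direction=direction,
                threshold=threshold,
                selected=(id(p) in kept) if eliminate else bal_acc > 0.5 + margin,
                balanced_accuracy=bal_acc,
                importance=imp,
            )
        )
    return rules


#: Mapping from swept parameter to the RefinedRuleSet field it feeds.
_RULE_FIELDS = {
    FAINT_TOTAL: "faint_total_threshold",
    "pct_weak_complete": "weak_complete_max",
    "pct_weak_incomplete": "weak_incomplete_min",
    "pct_moderate_incomplete": "moderate_incomplete_max",
}


def ruleset_from_cutpoints(
    rules: Sequence[CutpointRule], base: RefinedRuleSet | None = None
) -> RefinedRuleSet:
    """Assemble selected cut-points into a refined rule set.

    Only the four parameters of the refined 1+ definition feed thresholds;
    unselected or unrelated parameters leave the base rule set untouched.
    """
    base = base or RefinedRuleSet()
    overrides = {}
    for rule in rules:
        fld = _RULE_FIELDS.get(rule.parameter)
        if fld is not None and rule.selected:
            overrides[fld] = rule.threshold
    return replace(base, **overrides)
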