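"""Feature selection and classification with nested cross-validation.

Two-stage selection — a two-sample t-test filter followed by LASSO — feeds
a linear soft-margin SVM.  Hyperparameters (t-test threshold p, LASSO λ,
SVM cost) are tuned in an inner stratified k-fold loop by mean accuracy;
the outer loop estimates generalization.  Normalization statistics, the
t-test, the LASSO fit and the SVM all see training rows only within each
fold, so no test information leaks into selection.

Selected features are traced back through their provenance to count each
sub-network's contribution and to rank the most frequently selected
connectivity edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError
from .feature_hierarchy import FeatureTable
from .io_formats import LabelTable


def _default_p_grid() -> list[float]:
    return [round(0.01 * i, 2) for i in range(1, 11)]


def _default_lambda_grid() -> list[float]:
    return [round(0.1 * i, 1) for i in range(1, 10)]


def _default_cost_grid() -> list[float]:
    return [2.0 ** e for e in range(-4, 5)]


@dataclass
class SelectionConfig:
    """Hyperparameter grids and fold geometry for the nested CV."""

    p_grid: list[float] = field(default_factory=_default_p_grid)
    lambda_grid: list[float] = field(default_factory=_default_lambda_grid)
    cost_grid: list[float] = field(default_factory=_default_cost_grid)
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 1
    seed: int = 0
    global_norm: bool = False  # normalize on the whole cohort (leaky; off by default)

    def __post_init__(self) -> None:
        if not (self.p_grid and self.lambda_grid and self.cost_grid):
            raise ValidationError("hyperparameter grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("folds must be ≥ 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be ≥ 1")


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    metrics: dict
    params: dict
    selected_columns: list[int]  # indices into the FeatureTable columns


@dataclass
class CvResult:
    folds: list[FoldRecord]
    summary: dict
    config: SelectionConfig

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "summary": self.summary,
            "folds": [
                {
                    "repeat": f.repeat,
                    "fold": f.fold,
                    "metrics": f.metrics,
                    "params": f.params,
                    "selected_columns": f.selected_columns,
                }
                for f in self.folds
            ],
            "config": {
                "p_grid": self.config.p_grid,
                "lambda_grid": self.config.lambda_grid,
                "cost_grid": self.config.cost_grid,
                "outer_folds": self.config.outer_folds,
                "inner_folds": self.config.inner_folds,
                "repeats": self.config.repeats,
                "seed": self.config.seed,
                "global_norm": self.config.global_norm,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# building blocks


class BlockScaler:
    """Per-block min–max normalization fitted on training rows only.

    The min/max are pooled over all entries of a block across the training
    subjects, mirroring the per-block normalization of the fused feature
    vector; test values are mapped with the training statistics and are
    not clipped.
    """

    def __init__(self, block_slices: dict[str, tuple[int, int]] | None, n_features: int):
        if not block_slices:
            block_slices = {"all": (0, n_features)}
        self.block_slices = block_slices
        self.stats_: dict[str, tuple[float, float]] = {}

    def fit(self, x: np.ndarray) -> "BlockScaler":
        for tag, (a, b) in self.block_slices.items():
            sub = x[:, a:b]
            self.stats_[tag] = (float(sub.min()), float(sub.max())) if sub.size else (0.0, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(float).copy()
        for tag, (a, b) in self.block_slices.items():
            lo, hi = self.stats_[tag]
            if hi > lo:
                out[:, a:b] = (out[:, a:b] - lo) / (hi - lo)
            else:
                out[:, a:b] = 0.0
        return out


def ttest_filter(x: np.ndarray, y: np.ndarray, p_threshold: float) -> np.ndarray:
    """Columns whose two-sample t-test p-value is below the threshold.

    Columns with zero variance in both groups have no defined p-value and
    are dropped.  Returns sorted column indices.
    """
    y = np.asarray(y)
    pos, neg = x[y == 1], x[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need at least 2 subjects in each class for the t-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=True)
    keep = np.isfinite(pvals) & (pvals < p_threshold)
    return np.nonzero(keep)[0]


def lasso_select(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Sparse weights minimizing ½ Σ (yᵢ − xᵢᵀw)² + λ‖w‖₁ (no intercept).

    Returns (w, indices of nonzero coefficients).  λ = 0 degenerates to
    ordinary (minimum-norm) least squares.
    """
    if lam < 0:
        raise ValidationError(f"λ must be ≥ 0, got {lam}")
    y = np.asarray(y, dtype=float)
    if x.shape[1] == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    if lam == 0:
        w = np.linalg.lstsq(x, y, rcond=None)[0]
    else:
        model = Lasso(alpha=lam / len(y), fit_intercept=False, tol=1e-7, max_iter=100000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
        w = model.coef_
    nz = np.nonzero(np.abs(w) > 1e-12)[0]
    return w, nz


class MajorityClassifier:
    """Fallback when feature selection leaves nothing: predict the
    training majority class (ties go to the negative class)."""

    def __init__(self, y: np.ndarray):
        self.label = 1 if int(np.sum(np.asarray(y) == 1)) > len(y) / 2 else -1

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.full(x.shape[0], self.label, dtype=int)


def train_svm(x: np.ndarray, y: np.ndarray, cost: float):
    """Linear soft-margin SVM; falls back to majority vote on empty input."""
    if x.shape[1] == 0:
        warnings.warn("empty feature set; falling back to majority-class prediction")
        return MajorityClassifier(y)
    clf = SVC(kernel="linear", C=cost)
    clf.fit(x, np.asarray(y, dtype=int))
    return clf


def predict(classifier, x: np.ndarray) -> np.ndarray:
    return np.asarray(classifier.predict(x), dtype=int)


def metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """ACC/TPR/TNR/PPV/NPV from a confusion matrix.

    Ratios with zero denominator are reported as ``None`` with an entry in
    ``undefined``.
    """
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    if any(v < 0 for v in counts.values()):
        raise ValidationError(f"negative confusion counts: {counts}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    out = {
        "ACC": (tp + tn) / total,
        "TPR": ratio(tp, tp + fn),
        "TNR": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }
    out["undefined"] = sorted(k for k, v in out.items() if v is None)
    return out


# ---------------------------------------------------------------------------
# nested cross-validation


def _fit_pipeline(x_tr, y_tr, p_thr, lam, cost, scaler):
    """Normalize → t-test → LASSO → SVM, all on training rows."""
    xn = scaler.transform(x_tr)
    cols_t = ttest_filter(xn, y_tr, p_thr)
    if cols_t.size:
        _, nz = lasso_select(xn[:, cols_t], y_tr, lam)
        cols = cols_t[nz]
    else:
        cols = cols_t
    clf = train_svm(xn[:, cols], y_tr, cost)
    return cols, clf


def _apply_pipeline(clf, cols, scaler, x_te):
    xn = scaler.transform(x_te)
    return predict(clf, xn[:, cols])


def nested_cv(
    table: FeatureTable,
    labels: LabelTable,
    cfg: SelectionConfig,
    audit=None,
) -> CvResult:
    """Nested stratified k-fold cross-validation with grid search.

    The inner loop scores every (p, λ, cost) combination by mean accuracy;
    ties prefer the simpler model (larger p, larger λ, smaller cost).  The
    winner is refit on the full outer-training set — normalization and
    selection included — and scored on the held-out outer fold.  ``repeats``
    reshuffles the folds with fresh sub-seeds.

    ``audit``, if given, must expose ``record(stage, repeat, fold,
    row_indices)`` and is called with the training rows used at each stage
    (for leakage instrumentation in tests).
    """
    x = table.values
    y = labels.vector_for(table.subject_ids)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == -1))
    if min(n_pos, n_neg) < cfg.outer_folds:
        raise ValidationError(
            f"need ≥ {cfg.outer_folds} subjects per class for stratified "
            f"{cfg.outer_folds}-fold CV, got {n_pos} positive / {n_neg} negative"
        )
    # smallest per-class count an outer-training set can have
    worst_train = min(n_pos, n_neg) - (min(n_pos, n_neg) // cfg.outer_folds + 1)
    if worst_train + 1 < cfg.inner_folds:
        raise ValidationError(
            f"inner {cfg.inner_folds}-fold split impossible: an outer training "
            f"set may hold only {worst_train + 1} subjects of one class"
        )

    global_scaler = None
    if cfg.global_norm:
        global_scaler = BlockScaler(table.block_slices, x.shape[1]).fit(x)

    folds: list[FoldRecord] = []
    for rep in range(cfg.repeats):
        rep_seed = int(np.random.SeedSequence([cfg.seed, rep]).generate_state(1)[0] % (2**31))
        outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=rep_seed)
        for fold_id, (tr, te) in enumerate(outer.split(x, y)):
            x_tr, y_tr = x[tr], y[tr]
            inner_seed = (rep_seed + fold_id + 1) % (2**31)
            inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                                    random_state=inner_seed)
            inner_splits = list(inner.split(x_tr, y_tr))

            best = None  # (acc, p, lam, -cost) maximized
            for p_thr in cfg.p_grid:
                for lam in cfg.lambda_grid:
                    for cost in cfg.cost_grid:
                        accs = []
                        for itr, ite in inner_splits:
                            if audit is not None:
                                audit.record("inner_fit", rep, fold_id, tr[itr])
                            scaler = (global_scaler or
                                      BlockScaler(table.block_slices, x.shape[1])
                                      .fit(x_tr[itr]))
                            cols, clf = _fit_pipeline(
                                x_tr[itr], y_tr[itr], p_thr, lam, cost, scaler)
                            pred = _apply_pipeline(clf, cols, scaler, x_tr[ite])
                            accs.append(float(np.mean(pred == y_tr[ite])))
                        key = (float(np.mean(accs)), p_thr, lam, -cost)
                        if best is None or key > best[0]:
                            best = (key, {"p": p_thr, "lambda": lam, "cost": cost})
            params = best[1]

            if audit is not None:
                audit.record("outer_fit", rep, fold_id, tr)
            scaler = global_scaler or BlockScaler(table.block_slices, x.shape[1]).fit(x_tr)
            cols, clf = _fit_pipeline(
                x_tr, y_tr, params["p"], params["lambda"], params["cost"], scaler)
            pred = _apply_pipeline(clf, cols, scaler, x[te])
            y_te = y[te]
            tp = int(np.sum((pred == 1) & (y_te == 1)))
            fp = int(np.sum((pred == 1) & (y_te == -1)))
            tn = int(np.sum((pred == -1) & (y_te == -1)))
            fn = int(np.sum((pred == -1) & (y_te == 1)))
            folds.append(FoldRecord(
                repeat=rep, fold=fold_id,
                metrics=metrics(tp, fp, tn, fn),
                params=params,
                selected_columns=[int(c) for c in cols],
            ))

    summary = _summarize(folds, cfg)
    return CvResult(folds=folds, summary=summary, config=cfg)


def _summarize(folds: list[FoldRecord], cfg: SelectionConfig) -> dict:
    names = ["ACC", "TPR", "TNR", "PPV", "NPV"]
    per_fold = {m: [f.metrics[m] for f in folds if f.metrics[m] is not None] for m in names}
    over_folds = {
        m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for m, v in per_fold.items() if v
    }
    rep_means: dict[str, list[float]] = {m: [] for m in names}
    for rep in range(cfg.repeats):
        for m in names:
            vals = [f.metrics[m] for f in folds if f.repeat == rep and f.metrics[m] is not None]
            if vals:
                rep_means[m].append(float(np.mean(vals)))
    over_repeats = {
        m: {"mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for m, v in rep_means.items() if v
    }
    return {"over_folds": over_folds, "over_repeats": over_repeats}


# ---------------------------------------------------------------------------
# provenance tracing


def contribution_trace(result: CvResult, provenance: list[dict],
                       networks: list[str] | None = None) -> dict[str, float]:
    """Per-sub-network share of selected features across all folds/repeats.

    An intra feature credits its sub-network with weight 1; an inter
    feature credits each endpoint network with ½.  Baseline features carry
    no network provenance and are ignored.  Rates sum to 1 (all zero when
    nothing with network provenance was selected).
    """
    counts: dict[str, float] = {n: 0.0 for n in (networks or [])}
    for f in result.folds:
        for col in f.selected_columns:
            entry = provenance[col]
            if "network" in entry:
                counts[entry["network"]] = counts.get(entry["network"], 0.0) + 1.0
            elif "network_i" in entry:
                for endpoint in (entry["network_i"], entry["network_j"]):
                    counts[endpoint] = counts.get(endpoint, 0.0) + 0.5
    total = sum(counts.values())
    if total > 0:
        counts = {n: c / total for n, c in counts.items()}
    return counts


def top_edges(result: CvResult, provenance: list[dict], n: int = 10,
              roi_names: list[str] | None = None) -> list[dict]:
    """Most frequently selected low-order ROI–ROI edges across repeats.

    A feature counts once per repeat in which it was selected in any fold.
    Ranked by descending frequency, ties broken lexicographically by the
    (ROI_i, ROI_j) pair so the output is deterministic.
    """
    per_repeat: dict[int, set[int]] = {}
    for f in result.folds:
        per_repeat.setdefault(f.repeat, set()).update(f.selected_columns)
    freq: dict[int, int] = {}
    for cols in per_repeat.values():
        for col in cols:
            entry = provenance[col]
            if entry.get("role") == "mean" and "i" in entry and "j" in entry:
                freq[col] = freq.get(col, 0) + 1

    def edge_name(col: int) -> tuple[str, str]:
        e = provenance[col]
        if roi_names is not None:
            return (roi_names[e["i"]], roi_names[e["j"]])
        return (f"{e['i']:05d}", f"{e['j']:05d}")

    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], edge_name(kv[0])))
    if n > len(ranked):
        warnings.warn(f"requested top {n} edges but only {len(ranked)} were selected")
        n = len(ranked)
    out = []
    for col, count in ranked[:n]:
        e = provenance[col]
        name_i, name_j = edge_name(col)
        out.append({
            "column": col, "frequency": count,
            "roi_i": name_i, "roi_j": name_j,
            "network": e.get("network"), "block": e.get("block"),
        })
    return out
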