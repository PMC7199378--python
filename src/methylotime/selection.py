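"""Marker selection and pseudo-time regression.

Three stages, run per context class (CpG, non-CpG) and then combined:

1. univariate F-test pre-filter: for each genomic interval, regress
   pseudo-time on the interval's methylation level and keep intervals with
   F-test p < 0.05 (F = regression sum of squares over mean squared error,
   df (1, N-2));
2. bootstrap-lasso stability selection: B bootstrap resamples, a lasso with
   cross-validated penalty per resample; intervals with a nonzero
   coefficient in at least `threshold` resamples become markers;
3. final elastic-net fit on the selected markers,

       min over (b0, b) of  (1/2N) sum_i (y_i - b0 - x_i'b)^2
                            + lambda * sum_j [ (1-alpha)/2 * b_j^2 + alpha*|b_j| ],

   with alpha fixed at 1 (pure lasso) and lambda chosen by seeded 10-fold
   cross-validation minimizing held-out RMSE.

The combined model takes the union of the CpG- and non-CpG-selected markers
and refits jointly.  Coordinate-descent solving is delegated to
scikit-learn, whose penalized objective is exactly the one above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, Lasso, LassoCV, enet_path
from sklearn.model_selection import KFold

from .quant import GenomicInterval, MethylationMatrix


@dataclass(frozen=True)
class FilterResult:
    interval: GenomicInterval
    F: float
    p: float
    retained: bool


@dataclass(frozen=True)
class StabilityResult:
    interval: GenomicInterval
    selection_count: int
    B: int
    selected: bool


@dataclass(frozen=True)
class ElasticNetConfig:
    """Penalty mix alpha, penalty weight lambda, CV grid and fold settings."""

    alpha: float = 1.0  # 1 = lasso, 0 = ridge
    lam: float | None = None  # None = choose by CV
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class PluripotencyModel:
    """Affine pseudo-time predictor over marker intervals.

    Prediction is yhat = intercept + sum_i coef_i * x_i over the marker
    intervals; only markers with nonzero coefficients are kept.
    """

    intercept: float
    coefficients: np.ndarray  # aligned with markers, all nonzero
    markers: list[tuple[GenomicInterval, str]]  # (interval, context class)
    alpha: float
    lam: float
    n_samples: int
    n_features: int  # features offered to the fit (before zeroing)
    selection_frequency: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.markers):
            raise ValueError("coefficients and markers misaligned")

    @property
    def marker_intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.markers]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "markers": [
                {
                    "interval": iv.id,
                    "context_class": ctx,
                    "coefficient": float(c),
                    "selection_count": self.selection_frequency.get(iv.id),
                }
                for (iv, ctx), c in zip(self.markers, self.coefficients)
            ],
        }

    def save(self, path: str | Path) -> None:
        payload = {"format": "methylotime-model", "version": 1, **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PluripotencyModel":
        d = json.loads(Path(path).read_text())
        markers = [(GenomicInterval.from_id(m["interval"]), m["context_class"]) for m in d["markers"]]
        coefs = np.array([m["coefficient"] for m in d["markers"]], float)
        freq = {
            m["interval"]: m["selection_count"]
            for m in d["markers"]
            if m.get("selection_count") is not None
        }
        return cls(
            intercept=float(d["intercept"]),
            coefficients=coefs,
            markers=markers,
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            n_samples=int(d["n_samples"]),
            n_features=int(d["n_features"]),
            selection_frequency=freq,
        )


# ---------------------------------------------------------------------------
# univariate F-test pre-filter
# ---------------------------------------------------------------------------

def f_test_filter(
    matrix: MethylationMatrix, y: Sequence[float], cutoff: float = 0.05
) -> list[FilterResult]:
    """Univariate linear-regression F-test of pseudo-time on each interval.

    For interval level x: F = SSR / MSE with df (1, N-2), where SSR is the
    regression sum of squares of the fit y ~ x and MSE = SSE / (N-2).
    Intervals with p < cutoff are retained.  Zero-variance intervals have an
    undefined F and are never retained.
    """
    X = matrix.values
    t = np.asarray(y, float)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 samples for the F-test")
    if X.shape[0] != n:
        raise ValueError("pseudo-time length does not match matrix samples")
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((tc**2).sum())
    sxy = xc.T @ tc
    with np.errstate(divide="ignore", invalid="ignore"):
        ssr = sxy**2 / sxx
        sse = np.maximum(syy - ssr, 0.0)  # exact fits cancel to ~-1e-16
        mse = sse / (n - 2)
        F = np.where(mse > 0, ssr / np.where(mse > 0, mse, 1.0), np.inf)
    p = stats.f.sf(F, 1, n - 2)
    out = []
    for iv, fj, pj, sj in zip(matrix.intervals, F, p, sxx):
        if sj <= 0:
            out.append(FilterResult(iv, float("nan"), float("nan"), False))
        else:
            out.append(FilterResult(iv, float(fj), float(pj), bool(pj < cutoff)))
    return out


def apply_filter(matrix: MethylationMatrix, results: Sequence[FilterResult]) -> MethylationMatrix:
    """Subset a matrix to the intervals retained by the F-test."""
    kept = [r.interval for r in results if r.retained]
    if not kept:
        raise ValueError("F-test retained no intervals")
    return matrix.subset_intervals(kept)


# ---------------------------------------------------------------------------
# elastic net and lambda selection
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which the elastic-net solution is all-zero
    (exact for alpha > 0): max_j |x_j'(y - ybar)| / (N * alpha)."""
    Xc = X - X.mean(axis=0)
    yc = np.asarray(y, float) - np.mean(y)
    a = max(alpha, 1e-3)  # ridge limit: finite surrogate grid anchor
    return float(np.max(np.abs(Xc.T @ yc)) / (len(yc) * a))


def lambda_grid(X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig) -> np.ndarray:
    lmax = lambda_max(X, y, cfg.alpha)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)


def fit_elastic_net(
    X: np.ndarray,
    y: Sequence[float],
    cfg: ElasticNetConfig,
    lam: float | None = None,
    feature_meta: Sequence[tuple[GenomicInterval, str]] | None = None,
    selection_frequency: dict[str, int] | None = None,
) -> PluripotencyModel:
    """Fit the penalized linear model at a fixed (alpha, lambda).

    With ``cfg.standardize`` the penalty is applied on unit-variance features
    (glmnet convention) and coefficients are returned on the original
    methylation scale.  lambda = 0 falls back to ordinary least squares.
    """
    X = np.asarray(X, float)
    t = np.asarray(y, float)
    if X.shape[0] != len(t):
        raise ValueError("X rows must match y length")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    lam = cfg.lam if lam is None else lam
    if lam is None:
        lam, _ = select_lambda_cv(X, t, cfg)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n_features = X.shape[1]
    if cfg.standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(n_features), np.ones(n_features)
    if lam == 0.0:
        A = np.column_stack([np.ones(len(t)), Xs])
        beta, *_ = np.linalg.lstsq(A, t, rcond=None)
        b0s, bs = float(beta[0]), beta[1:]
    else:
        est = ElasticNet(
            alpha=lam, l1_ratio=cfg.alpha, fit_intercept=True, tol=1e-10, max_iter=500_000
        )
        est.fit(Xs, t)
        b0s, bs = float(est.intercept_), est.coef_
    coef = bs / sd
    intercept = b0s - float(np.dot(coef, mu))
    if feature_meta is None:
        feature_meta = [
            (GenomicInterval("feature", j, j + 1), "combined") for j in range(n_features)
        ]
    nz = np.flatnonzero(coef != 0.0)
    return PluripotencyModel(
        intercept=intercept,
        coefficients=coef[nz],
        markers=[feature_meta[j] for j in nz],
        alpha=cfg.alpha,
        lam=float(lam),
        n_samples=X.shape[0],
        n_features=n_features,
        selection_frequency=selection_frequency or {},
    )


def select_lambda_cv(
    X: np.ndarray, y: Sequence[float], cfg: ElasticNetConfig
) -> tuple[float, pd.DataFrame]:
    """Choose lambda by seeded k-fold CV minimizing held-out RMSE.

    The grid runs from lambda_max down over ``n_lambda`` log-spaced values.
    Ties (within 1e-12) break toward the largest lambda, i.e. the most
    parsimonious model.  Returns the chosen lambda and the CV curve.
    """
    X = np.asarray(X, float)
    t = np.asarray(y, float)
    n = len(t)
    if n < cfg.cv_folds:
        raise ValueError(f"need N >= cv_folds={cfg.cv_folds}")
    if np.std(t) == 0:
        raise ValueError("constant response: lambda selection is degenerate")
    grid = lambda_grid(X, t, cfg)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed % (2**31))
    sq_err = np.zeros(len(grid))
    for train, test in kf.split(X):
        Xtr, ttr = X[train], t[train]
        if cfg.standardize:
            Xtr_s, mu, sd = _standardize(Xtr)
        else:
            Xtr_s, mu, sd = Xtr, np.zeros(X.shape[1]), np.ones(X.shape[1])
        xm = Xtr_s.mean(axis=0)
        ym = ttr.mean()
        _, coefs, _ = enet_path(
            Xtr_s - xm, ttr - ym, l1_ratio=max(cfg.alpha, 1e-6), alphas=grid, tol=1e-8
        )
        Xte_s = (X[test] - mu) / sd
        preds = (Xte_s - xm) @ coefs + ym  # (n_test, n_lambda)
        sq_err += ((preds - t[test][:, None]) ** 2).sum(axis=0)
    rmse = np.sqrt(sq_err / n)
    best = rmse.min()
    # grid is descending, so the first index within tolerance is the largest lambda
    chosen = float(grid[np.flatnonzero(rmse <= best + 1e-12)[0]])
    curve = pd.DataFrame({"lambda": grid, "cv_rmse": rmse})
    return chosen, curve


def kkt_residual(
    X: np.ndarray,
    y: Sequence[float],
    intercept: float,
    coef: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Max violation of the subgradient optimality conditions of the
    penalized objective at (intercept, coef).

    With g = X'(y - b0 - Xb)/N, optimality requires g_j = lam*(1-alpha)*b_j
    + lam*alpha*sign(b_j) for active coefficients, |g_j| <= lam*alpha for
    inactive ones, and a zero mean residual for the intercept.
    """
    X = np.asarray(X, float)
    t = np.asarray(y, float)
    coef = np.asarray(coef, float)
    r = t - intercept - X @ coef
    n = len(t)
    g = X.T @ r / n
    worst = abs(float(r.mean()))
    for j in range(X.shape[1]):
        if coef[j] != 0.0:
            v = abs(g[j] - lam * (1 - alpha) * coef[j] - lam * alpha * np.sign(coef[j]))
        else:
            v = max(0.0, abs(g[j]) - lam * alpha)
        worst = max(worst, float(v))
    return worst


# ---------------------------------------------------------------------------
# bootstrap-lasso stability selection
# ---------------------------------------------------------------------------

def bootstrap_lasso_select(
    matrix: MethylationMatrix,
    y: Sequence[float],
    B: int = 1000,
    threshold: int = 500,
    seed: int = 0,
    cv_folds: int = 10,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> list[StabilityResult]:
    """Stability selection: B bootstrap lassos, each with CV-chosen penalty.

    Each resample draws N samples with replacement (redrawn if the response
    is constant), standardizes the resampled features, and fits a lasso with
    the penalty chosen by ``cv_folds``-fold CV on the resample under the
    one-standard-error rule (largest penalty whose CV error is within one SE
    of the minimum — the sparse convention; plain CV-minimum lassos
    over-select and would defeat the stability threshold).  An interval
    counts as selected in that run iff its coefficient is nonzero; intervals
    selected in at least ``threshold`` of the B runs are the final markers.
    """
    if B < 1 or not 0 <= threshold <= B:
        raise ValueError("require B >= 1 and 0 <= threshold <= B")
    X = matrix.values
    t = np.asarray(y, float)
    n = len(t)
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1], dtype=np.int64)
    redraws = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.std(t[idx]) > 0:
                break
            redraws += 1
        Xb, tb = X[idx], t[idx]
        Xb_s, _, _ = _standardize(Xb)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        est = LassoCV(
            alphas=n_lambda,  # grid size; sklearn builds the log-spaced path
            eps=lambda_min_ratio,
            cv=KFold(cv_folds, shuffle=True, random_state=fold_seed),
            tol=1e-6,
            max_iter=50_000,
        )
        est.fit(Xb_s, tb)
        # one-SE rule on the CV curve (alphas_ is descending)
        mse_mean = est.mse_path_.mean(axis=1)
        mse_se = est.mse_path_.std(axis=1, ddof=1) / np.sqrt(est.mse_path_.shape[1])
        k_min = int(np.argmin(mse_mean))
        bound = mse_mean[k_min] + mse_se[k_min]
        k_1se = int(np.flatnonzero(mse_mean <= bound)[0])
        lasso = Lasso(alpha=float(est.alphas_[k_1se]), tol=1e-6, max_iter=50_000)
        lasso.fit(Xb_s, tb)
        counts += lasso.coef_ != 0.0
    return [
        StabilityResult(iv, int(c), B, bool(c >= threshold))
        for iv, c in zip(matrix.intervals, counts)
    ]


def selected_intervals(results: Sequence[StabilityResult]) -> list[GenomicInterval]:
    return [r.interval for r in results if r.selected]


# ---------------------------------------------------------------------------
# per-class and combined model building
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Everything the three-stage pipeline decided for one context class."""

    context_class: str
    filter_results: list[FilterResult]
    stability_results: list[StabilityResult]
    model: PluripotencyModel | None


def run_selection(
    matrix: MethylationMatrix,
    y: Sequence[float],
    cfg: ElasticNetConfig,
    ftest_cutoff: float = 0.05,
    B: int = 1000,
    threshold: int = 500,
) -> SelectionReport:
    """F-test filter -> bootstrap-lasso stability selection -> elastic-net fit
    for one context class.  Returns a report with a None model when no
    interval survives selection."""
    filt = f_test_filter(matrix, y, cutoff=ftest_cutoff)
    kept = [r.interval for r in filt if r.retained]
    if not kept:
        return SelectionReport(matrix.context_class, filt, [], None)
    filtered = matrix.subset_intervals(kept)
    stab = bootstrap_lasso_select(filtered, y, B=B, threshold=threshold, seed=cfg.seed)
    markers = selected_intervals(stab)
    if not markers:
        return SelectionReport(matrix.context_class, filt, stab, None)
    sub = filtered.subset_intervals(markers)
    freq = {r.interval.id: r.selection_count for r in stab if r.selected}
    model = fit_elastic_net(
        sub.values,
        y,
        cfg,
        feature_meta=[(iv, matrix.context_class) for iv in markers],
        selection_frequency=freq,
    )
    return SelectionReport(matrix.context_class, filt, stab, model)


def build_models(
    cpg_matrix: MethylationMatrix,
    noncpg_matrix: MethylationMatrix,
    y: Sequence[float],
    cfg: ElasticNetConfig = ElasticNetConfig(),
    ftest_cutoff: float = 0.05,
    B: int = 1000,
    threshold: int = 500,
) -> dict[str, SelectionReport]:
    """Build the CpG, non-CpG and combined pseudo-time models.

    The combined model's feature set is the union of the markers selected by
    the class-wise pipelines (CpG first, then non-CpG), refit jointly with a
    CV-chosen penalty.  A class whose selection comes up empty is reported
    with a None model and contributes nothing to the union.
    """
    if list(cpg_matrix.samples) != list(noncpg_matrix.samples):
        raise ValueError("CpG and non-CpG matrices must share the sample set")
    reports = {
        "cpg": run_selection(cpg_matrix, y, cfg, ftest_cutoff, B, threshold),
        "noncpg": run_selection(noncpg_matrix, y, cfg, ftest_cutoff, B, threshold),
    }
    features: list[tuple[GenomicInterval, str]] = []
    cols: list[np.ndarray] = []
    freq: dict[str, int] = {}
    for key, mat in (("cpg", cpg_matrix), ("noncpg", noncpg_matrix)):
        rep = reports[key]
        if rep.model is None:
            continue
        sel = selected_intervals(rep.stability_results)
        sub = mat.subset_intervals(sel)
        for j, iv in enumerate(sel):
            features.append((iv, mat.context_class))
            cols.append(sub.values[:, j])
        freq.update(
            {r.interval.id: r.selection_count for r in rep.stability_results if r.selected}
        )
    if features:
        Xc = np.column_stack(cols)
        combined_model = fit_elastic_net(
            Xc, y, cfg, feature_meta=features, selection_frequency=freq
        )
        reports["combined"] = SelectionReport("combined", [], [], combined_model)
    else:
        reports["combined"] = SelectionReport("combined", [], [], None)
    return reports


def marker_matrix(
    model: PluripotencyModel,
    cpg_matrix: MethylationMatrix | None = None,
    noncpg_matrix: MethylationMatrix | None = None,
) -> np.ndarray:
    """Assemble the samples x model-marker design from context matrices."""
    by_class = {}
    if cpg_matrix is not None:
        by_class["CpG"] = cpg_matrix
    if noncpg_matrix is not None:
        by_class["nonCpG"] = noncpg_matrix
    cols = []
    for iv, ctx in model.markers:
        src = by_class.get(ctx)
        if src is None:
            raise KeyError(f"no matrix provided for context class {ctx}")
        j = src.intervals.index(iv)
        cols.append(src.values[:, j])
    return np.column_stack(cols)
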