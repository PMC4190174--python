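"""Model validation: cross-validated complexity selection and residual checks.

Complexity selection follows the study design used for normative TT
modelling: the pooled data are split at random into five equally sized
subsets; rational polynomials with 3-11 free parameters are trained on
four subsets and scored on the held-out one; the parameter count whose
held-out mean squared error is smallest (ties to the simpler model) is
selected.  Residual diagnostics check the Gaussianity assumption behind
the centile construction, overall and per age band, and a LOESS comparator
tests whether an ensemble of local fits would out-predict the single
global curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import log_adjust
from .model import FitSettings, FitSummary, RationalPolynomialModel, fit

#: Default free-parameter counts explored by cross-validation.
DEFAULT_PARAM_COUNTS = tuple(range(3, 12))

#: Age bands for the per-band residual summaries: childhood 3-11, then
#: teens and decades through 80-89.
DECADE_BANDS = ((3, 11), (12, 19)) + tuple((lo, lo + 9) for lo in range(20, 90, 10))


def degrees_for_params(n_params: int) -> tuple[int, int]:
    """Numerator/denominator degree allocation for a free-parameter count.

    The numerator takes the extra degree when the count is even, so seven
    parameters give the cubic-over-cubic family of the validated model.
    """
    if n_params < 2:
        raise ValueError("a rational polynomial needs at least 2 free parameters")
    num_degree = (n_params - 1 + 1) // 2
    den_degree = (n_params - 1) // 2
    return num_degree, den_degree


def kfold_split(data: pd.DataFrame, k: int = 5, seed: int = 0) -> list[pd.DataFrame]:
    """Random partition into k subsets whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(data) < k:
        raise ValueError(f"cannot split {len(data)} rows into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    return [data.iloc[np.sort(idx)].reset_index(drop=True) for idx in np.array_split(order, k)]


@dataclass
class CVResult:
    """Cross-validation errors for one model complexity.

    MSEs are on the log-adjusted scale with anchors excluded, averaged
    over folds; per-fold values are kept for plotting validation curves.
    """

    n_params: int
    train_mse: float
    test_mse: float
    fold_train: list[float] = field(default_factory=list)
    fold_test: list[float] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)


def _mse(model: RationalPolynomialModel, data: pd.DataFrame) -> float:
    obs = data.loc[~data["is_anchor"]]
    resid = log_adjust(obs["tt_value"].to_numpy()) - model.evaluate(
        obs["age_years"].to_numpy()
    )
    return float(np.mean(resid**2))


def _pad_init(model: RationalPolynomialModel, num_deg: int, den_deg: int) -> np.ndarray:
    """Embed a fitted lower-complexity model into a larger nested family."""
    num = list(model.num_coeffs) + [0.0] * (num_deg + 1 - len(model.num_coeffs))
    den = list(model.den_coeffs) + [0.0] * (den_deg - len(model.den_coeffs))
    return np.asarray(num + den)


def cross_validate(
    data: pd.DataFrame,
    param_counts=DEFAULT_PARAM_COUNTS,
    k: int = 5,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> list[CVResult]:
    """k-fold cross-validation over rational-polynomial complexity.

    Within each fold, complexities are fit in increasing order and each fit
    is warm-started from the previous one embedded in the larger nested
    family; this keeps high-degree denominators pole-free and makes the
    training-error monotonicity of nested families hold in practice.
    """
    folds = kfold_split(data, k=k, seed=seed)
    param_counts = sorted(param_counts)
    cells_train = {p: [] for p in param_counts}
    cells_test = {p: [] for p in param_counts}
    failures = {p: [] for p in param_counts}
    for i in range(k):
        train = pd.concat([folds[j] for j in range(k) if j != i], ignore_index=True)
        prev_model = None
        for n_params in param_counts:
            num_deg, den_deg = degrees_for_params(n_params)
            init = (
                _pad_init(prev_model, num_deg, den_deg)
                if prev_model is not None
                else None
            )
            try:
                summary = fit(train, num_deg, den_deg, settings, init=init)
            except (ValueError, RuntimeError) as exc:
                failures[n_params].append(f"fold {i}: {exc}")
                continue
            prev_model = summary.model
            cells_train[n_params].append(summary.mse)
            cells_test[n_params].append(_mse(summary.model, folds[i]))
    return [
        CVResult(
            n_params=p,
            train_mse=float(np.mean(cells_train[p])) if cells_train[p] else np.nan,
            test_mse=float(np.mean(cells_test[p])) if cells_test[p] else np.nan,
            fold_train=cells_train[p],
            fold_test=cells_test[p],
            failures=failures[p],
        )
        for p in param_counts
    ]


def select_optimal(cv_results: list[CVResult]) -> int:
    """Parameter count with the lowest held-out MSE (ties -> fewer params).

    Complexities with failed folds are only considered when no complexity
    completed all folds: a mean over fewer folds is not comparable with a
    mean over all of them.
    """
    if not cv_results:
        raise ValueError("no cross-validation results to select from")
    complete = [r for r in cv_results if np.isfinite(r.test_mse) and not r.failures]
    usable = complete or [r for r in cv_results if np.isfinite(r.test_mse)]
    if not usable:
        raise ValueError("every cross-validation cell failed")
    best = min(usable, key=lambda r: (r.test_mse, r.n_params))
    return best.n_params


def cv_table(cv_results: list[CVResult]) -> pd.DataFrame:
    """Tidy per-complexity train/test MSE table for reporting."""
    return pd.DataFrame(
        {
            "n_params": [r.n_params for r in cv_results],
            "train_mse": [r.train_mse for r in cv_results],
            "test_mse": [r.test_mse for r in cv_results],
        }
    )


@dataclass
class ResidualSummary:
    """Gaussianity diagnostics for log-adjusted model residuals."""

    residuals: np.ndarray
    sd: float
    within_1sd: float
    within_2sd: float
    within_3sd: float
    gaussian_fit_r2: float
    degenerate: bool
    n: int


def residual_analysis(model: RationalPolynomialModel, data: pd.DataFrame) -> ResidualSummary:
    """Residual spread and Gaussian goodness of fit, anchors excluded.

    The fractions of residuals within 1, 2 and 3 sample SDs are compared
    against the Gaussian ideal (68% / 95% / 99.7%); ``gaussian_fit_r2``
    measures how well a normal density with the sample moments matches the
    Freedman-Diaconis histogram of the residuals.
    """
    obs = data.loc[~data["is_anchor"]]
    if len(obs) == 0:
        raise ValueError("no non-anchor points to analyse")
    resid = log_adjust(obs["tt_value"].to_numpy()) - model.evaluate(
        obs["age_years"].to_numpy()
    )
    sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    if sd < 1e-12:  # numerically zero spread: a perfect (degenerate) fit
        return ResidualSummary(
            residuals=resid,
            sd=0.0,
            within_1sd=1.0,
            within_2sd=1.0,
            within_3sd=1.0,
            gaussian_fit_r2=np.nan,
            degenerate=True,
            n=len(resid),
        )
    mu = float(np.mean(resid))
    centred = np.abs(resid - mu)
    props = [float(np.mean(centred <= m * sd)) for m in (1, 2, 3)]

    counts, edges = np.histogram(resid, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ideal = stats.norm.pdf(centers, mu, sd)
    ss_res = float(np.sum((counts - ideal) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    gauss_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    return ResidualSummary(
        residuals=resid,
        sd=sd,
        within_1sd=props[0],
        within_2sd=props[1],
        within_3sd=props[2],
        gaussian_fit_r2=gauss_r2,
        degenerate=False,
        n=len(resid),
    )


def residuals_by_decade(
    model: RationalPolynomialModel, data: pd.DataFrame, bands=DECADE_BANDS
) -> list[tuple[tuple[int, int], ResidualSummary | None]]:
    """Residual summaries per age band; empty bands report ``None``."""
    obs = data.loc[~data["is_anchor"]]
    out = []
    for lo, hi in bands:
        sub = obs.loc[(obs["age_years"] >= lo) & (obs["age_years"] < hi + 1)]
        if len(sub) == 0:
            out.append(((lo, hi), None))
        else:
            out.append(((lo, hi), residual_analysis(model, sub)))
    return out


def _loess_smooth(x, y, span, degree, n_grid=201):
    """Tricube-weighted local polynomial regression evaluated on a grid.

    Classic LOESS: at each grid point the ``span`` fraction of nearest
    observations is fit with a weighted degree-1 or degree-2 polynomial;
    the fitted surface is then linearly interpolated back to the data.
    """
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.empty(n_grid)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        xs = x[idx] - g
        design = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted


def loess_r2(
    data: pd.DataFrame, span: float = 0.5, degree: int = 1, n_grid: int = 201
) -> float:
    """r-squared of a LOESS fit of log-adjusted TT on age (anchors excluded)."""
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    obs = data.loc[~data["is_anchor"]]
    if len(obs) == 0:
        raise ValueError("no non-anchor points to fit")
    x = obs["age_years"].to_numpy(dtype=float)
    y = log_adjust(obs["tt_value"].to_numpy(dtype=float))
    grid, fitted = _loess_smooth(x, y, span, degree, n_grid)
    pred = np.interp(x, grid, fitted)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def best_loess_r2(
    data: pd.DataFrame,
    spans=(0.2, 0.3, 0.5, 0.75),
    degrees=(1, 2),
) -> tuple[float, dict]:
    """Best LOESS r-squared over a small span x degree grid."""
    best = -np.inf
    best_cfg = {}
    for span in spans:
        for degree in degrees:
            r2 = loess_r2(data, span=span, degree=degree)
            if r2 > best:
                best, best_cfg = r2, {"span": span, "degree": degree}
    return best, best_cfg
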