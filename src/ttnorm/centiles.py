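"""Age-dependent spread estimation, centile curves, and individual scoring.

The normative distribution at age ``x`` is Gaussian on the log-adjusted
scale: ``log10(TT+1) ~ N(mean(x), sigma(x))``.  The mean comes from the
rational-polynomial model; the spread ``sigma(x)`` is estimated from the
residuals, either as a kernel-weighted local SD (the default, which
captures the rise in TT variability after age 40), a binned SD, or a
single global constant.  Centile curves, a normative reference table over
ages 3-88, and z-score/centile scoring of individual measurements all
derive from the same pair (mean model, SD profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import inverse_log_adjust, log_adjust
from .model import TABLE_AGES, RationalPolynomialModel

#: Percentile columns of the normative reference table.
PERCENTILES = (1, 2.5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 97.5, 99)

#: Printed 2.5th/97.5th reference band (nmol/L) at three anchor ages; the
#: default SD profile is recovered from these under the Gaussian-in-log model.
_BAND_ANCHORS = {19.0: (7.2, 31.1), 40.0: (6.6, 25.3), 88.0: (5.5, 30.0)}

#: Printed 97.5th-percentile value at age 3 (the 2.5th is clipped at zero
#: there, so the childhood SD anchor is recovered one-sidedly).
_CHILD_ANCHOR = (3.0, 0.9)


@dataclass
class SDProfile:
    """Age-dependent standard deviation of log-adjusted residuals.

    ``method`` is one of ``kernel`` (Gaussian-kernel local SD), ``binned``
    (piecewise-constant per age bin), ``interp`` (linear interpolation
    through anchor points), or ``constant``.
    """

    method: str
    ages: np.ndarray | None = None
    values: np.ndarray | None = None
    constant: float | None = None
    bandwidth: float | None = None
    bin_edges: np.ndarray | None = None

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if self.method == "constant":
            return np.full(age.shape, float(self.constant))
        if self.method in ("kernel", "interp"):
            return np.interp(age, self.ages, self.values)
        if self.method == "binned":
            idx = np.clip(
                np.searchsorted(self.bin_edges, age, side="right") - 1,
                0,
                len(self.values) - 1,
            )
            return self.values[idx]
        raise ValueError(f"unknown SD profile method {self.method!r}")


def default_sd_profile() -> SDProfile:
    """SD profile anchored to the published 2.5-97.5 percentile bands.

    At ages 19, 40 and 88 the printed band (lo, hi) is inverted under the
    Gaussian-in-log model, ``sigma = (log10(hi+1) - log10(lo+1)) / (2 z)``
    with ``z`` the 97.5% normal quantile, giving roughly 0.151, 0.138 and
    0.173.  At age 3 the lower band is clipped at zero, so sigma is
    recovered one-sidedly from the upper band alone,
    ``sigma = (log10(hi+1) - mean(3)) / z`` (about 0.071): spread in
    childhood is far smaller than in adulthood.  Values between anchors are
    linearly interpolated and held constant beyond them; the rise after
    age 40 encodes the increasing variability of TT in older men.
    """
    from .model import published_model

    z = stats.norm.ppf(0.975)
    pairs = {
        age: (np.log10(hi + 1) - np.log10(lo + 1)) / (2 * z)
        for age, (lo, hi) in _BAND_ANCHORS.items()
    }
    child_age, child_hi = _CHILD_ANCHOR
    pairs[child_age] = (
        np.log10(child_hi + 1) - published_model().evaluate(child_age)
    ) / z
    ages = np.array(sorted(pairs))
    sig = np.array([pairs[a] for a in ages])
    return SDProfile(method="interp", ages=ages, values=sig)


def estimate_sd_profile(
    residuals,
    ages,
    method: str = "kernel",
    bandwidth: float = 5.0,
    query_ages=None,
    bin_width: float = 10.0,
    min_points: int = 30,
) -> SDProfile:
    """Estimate sigma(age) from log-adjusted residuals.

    kernel: at each query age, the SD of residuals weighted by a Gaussian
    kernel in age (``bandwidth`` in years), centred about the local
    weighted mean.  binned: sample SD per fixed-width age bin.  constant:
    the global sample SD everywhere.
    """
    residuals = np.asarray(residuals, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if residuals.shape != ages.shape:
        raise ValueError("residuals and ages must have equal length")
    if len(residuals) < min_points:
        raise ValueError(f"need at least {min_points} residuals, got {len(residuals)}")

    if method == "constant":
        return SDProfile(method="constant", constant=float(np.std(residuals, ddof=1)))

    if method == "binned":
        lo = np.floor(ages.min())
        edges = np.arange(lo, ages.max() + bin_width, bin_width)
        vals = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (ages >= a) & (ages < b)
            vals.append(np.std(residuals[sel], ddof=1) if sel.sum() > 1 else np.nan)
        vals = np.asarray(vals)
        if np.any(np.isnan(vals)):  # borrow the nearest populated bin
            ok = np.flatnonzero(~np.isnan(vals))
            if ok.size == 0:
                raise ValueError("no age bin holds enough residuals")
            for i in np.flatnonzero(np.isnan(vals)):
                vals[i] = vals[ok[np.argmin(np.abs(ok - i))]]
        return SDProfile(method="binned", bin_edges=edges, values=vals)

    if method == "kernel":
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if query_ages is None:
            query_ages = np.arange(np.floor(ages.min()), np.ceil(ages.max()) + 1.0)
        query_ages = np.asarray(query_ages, dtype=float)
        sig = np.empty(query_ages.shape)
        for i, a0 in enumerate(query_ages):
            w = np.exp(-0.5 * ((ages - a0) / bandwidth) ** 2)
            sw = w.sum()
            mu = np.sum(w * residuals) / sw
            sig[i] = np.sqrt(np.sum(w * (residuals - mu) ** 2) / sw)
        return SDProfile(method="kernel", ages=query_ages, values=sig, bandwidth=bandwidth)

    raise ValueError(f"unknown method {method!r}")


def centile_curve(
    mean_model: RationalPolynomialModel,
    sd_profile,
    percentile: float,
    ages=None,
    residuals=None,
    residual_ages=None,
):
    """TT values (nmol/L) of one centile curve over ``ages``.

    Gaussian mode (default): ``inverse_log_adjust(mean + z_p * sigma)``.
    If standardised residuals are supplied, the normal quantile ``z_p`` is
    replaced by the empirical quantile of ``residual / sigma(age)``, which
    tracks asymmetric tails better at extreme percentiles.  Values are
    clipped below at zero.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    ages = TABLE_AGES if ages is None else np.asarray(ages, dtype=float)
    if residuals is not None:
        residuals = np.asarray(residuals, dtype=float)
        ra = np.asarray(residual_ages, dtype=float)
        zscores = residuals / sd_profile(ra)
        q = float(np.quantile(zscores, percentile / 100.0))
    else:
        q = float(stats.norm.ppf(percentile / 100.0))
    vals = inverse_log_adjust(mean_model.evaluate(ages) + q * sd_profile(ages))
    return np.clip(vals, 0.0, None)


@dataclass
class CentileTable:
    """Ages x percentiles matrix of normative TT values in nmol/L."""

    ages: np.ndarray
    percentiles: tuple[float, ...]
    values: np.ndarray  # unrounded, shape (len(ages), len(percentiles))

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        vals = self.values if decimals is None else np.round(self.values, decimals)
        df = pd.DataFrame(vals, columns=[_fmt_pct(p) for p in self.percentiles])
        df.insert(0, "age", self.ages.astype(int))
        return df

    def to_csv(self, path, decimals: int | None = 1) -> None:
        self.to_frame(decimals).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CentileTable":
        df = pd.read_csv(path)
        pcts = tuple(float(c) for c in df.columns[1:])
        return cls(
            ages=df["age"].to_numpy(dtype=float),
            percentiles=pcts,
            values=df.iloc[:, 1:].to_numpy(dtype=float),
        )


def _fmt_pct(p: float) -> str:
    return f"{p:g}"


def normative_table(
    mean_model: RationalPolynomialModel,
    sd_profile,
    ages=None,
    percentiles=PERCENTILES,
    **curve_kwargs,
) -> CentileTable:
    """Full normative reference table (default ages 3-88, 13 percentiles)."""
    ages = TABLE_AGES if ages is None else np.asarray(ages)
    values = np.column_stack(
        [
            centile_curve(mean_model, sd_profile, p, ages=ages, **curve_kwargs)
            for p in percentiles
        ]
    )
    return CentileTable(
        ages=np.asarray(ages, dtype=float), percentiles=tuple(percentiles), values=values
    )


def score_individual(
    tt: float,
    age: float,
    mean_model: RationalPolynomialModel,
    sd_profile,
) -> tuple[float, float]:
    """z-score and centile of one TT measurement against the normative model.

    ``z = (log10(tt+1) - mean(age)) / sigma(age)``; the centile is the
    standard normal CDF of z, times 100.
    """
    if tt < 0:
        raise ValueError("TT must be non-negative")
    sigma = float(np.asarray(sd_profile(age)))
    if sigma <= 0:
        raise ValueError(f"degenerate SD profile at age {age:g} (sigma = {sigma:g})")
    z = float((log_adjust(tt) - mean_model.evaluate(age)) / sigma)
    return z, float(stats.norm.cdf(z) * 100.0)
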