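"""Synthetic pooled multi-study testosterone datasets with known truth.

Real normative-range studies pool cross-sectional TT measurements from many
published cohorts, each with its own sample size, age distribution and
assay platform.  This module emulates such a pool: thirteen study profiles
(sample size, median and range of ages, assay) mirror the published data
summary; subject ages are drawn from a scaled Beta distribution matched to
each study's median and range; log-adjusted TT is Gaussian around a known
mean curve with an age-dependent SD; and raw values are written on each
study's *native* assay scale by inverting the published conversion, so the
harmonization stage has real work to do.

Everything is driven by a single integer seed with deterministic per-study
substreams, so any dataset is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .harmonize import (
    NG_DL_TO_NMOL_L,
    REFERENCE_ASSAY,
    get_conversion,
    inverse_log_adjust,
)
from .model import RationalPolynomialModel, published_model


@dataclass(frozen=True)
class StudyProfile:
    """Sample size, age structure, and assay of one source study."""

    study_id: str
    n: int
    age_median: float
    age_min: float
    age_max: float
    assay: str = REFERENCE_ASSAY
    unit: str = "nmol/L"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"{self.study_id}: n must be >= 1")
        if not (self.age_min <= self.age_median <= self.age_max):
            raise ValueError(f"{self.study_id}: require age_min <= median <= age_max")
        get_conversion(self.assay)  # raises for unregistered assays
        if self.unit not in ("nmol/L", "ng/dL"):
            raise ValueError(f"{self.study_id}: unit must be nmol/L or ng/dL")


def default_study_profiles() -> list[StudyProfile]:
    """The thirteen source-study profiles of the pooled dataset.

    Sample sizes and age medians/ranges reproduce the published data
    summary (total n = 10,360 before age censoring).
    """
    rows = [
        ("Abdelrahaman", 47, 6.2, 4.9, 9.0, "DPC"),
        ("Bergada", 94, 0.02, 0.0, 0.1, "DSL"),
        ("Elmlinger", 623, 40.1, 0.0, 98.9, "Centaur"),
        ("Friedrich", 971, 47.4, 20.3, 79.8, "Centaur"),
        ("Kyriakopoulou", 172, 8.3, 0.0, 18.6, "LC-MS/MS"),
        ("Leifke", 572, 40.5, 20.0, 80.0, "DSL"),
        ("Harman", 890, 56.9, 22.9, 94.4, "DSL"),
        ("Morley", 287, 76.2, 61.2, 101.1, "DPC"),
        ("Yeap", 3645, 76.6, 70.8, 87.8, "DPC"),
        ("Pierik", 113, 0.2, 0.1, 0.4, "Centaur"),
        ("Halmenschlager", 428, 51.9, 29.8, 83.0, "Roche"),
        ("Sartorius", 324, 59.8, 40.1, 86.9, "LC-MS/MS"),
        ("Travison", 2194, 61.5, 44.9, 80.0, "RIA"),
    ]
    return [StudyProfile(s, n, med, lo, hi, assay) for s, n, med, lo, hi, assay in rows]


class SDProfileLike:
    """Anything evaluable as sigma(age); see :mod:`ttnorm.centiles`."""

    def __call__(self, age):  # pragma: no cover - interface stub
        raise NotImplementedError


def _constant_sd(value: float):
    def sd(age):
        return np.full_like(np.asarray(age, dtype=float), float(value))

    return sd


@dataclass
class GroundTruth:
    """Known generating process for a synthetic dataset.

    ``mean_model`` is the true mean curve on the log-adjusted scale;
    ``sd_profile`` maps age to the SD of the Gaussian log-adjusted noise.
    A float ``sd_profile`` is shorthand for a constant profile.
    """

    mean_model: RationalPolynomialModel = field(default_factory=published_model)
    sd_profile: object = 0.15
    seed: int = 0

    def sigma(self, age):
        if callable(self.sd_profile):
            return np.asarray(self.sd_profile(age), dtype=float)
        return _constant_sd(float(self.sd_profile))(age)


def _beta_shape_for_median(rel_median: float, concentration: float = 6.0) -> tuple[float, float]:
    """Beta(a, b) with a+b fixed whose median matches ``rel_median``.

    The Beta median is strictly increasing in ``a`` at fixed ``a+b``, so a
    bracketed root-find suffices.  ``rel_median`` at the boundary collapses
    the distribution towards that endpoint.
    """
    rel_median = float(np.clip(rel_median, 1e-4, 1 - 1e-4))

    def median_gap(a):
        return stats.beta.median(a, concentration - a) - rel_median

    lo, hi = 1e-3, concentration - 1e-3
    return (a := brentq(median_gap, lo, hi)), concentration - a


def _draw_ages(profile: StudyProfile, rng: np.random.Generator) -> np.ndarray:
    span = profile.age_max - profile.age_min
    if span <= 0:
        return np.full(profile.n, profile.age_min)
    rel = (profile.age_median - profile.age_min) / span
    a, b = _beta_shape_for_median(rel)
    return profile.age_min + span * rng.beta(a, b, size=profile.n)


def generate_dataset(
    profiles: list[StudyProfile] | None = None,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a pooled cross-sectional dataset on native assay scales.

    For each study: draw ages from the matched Beta distribution; draw
    log-adjusted TT ~ N(mean(age), sigma(age)); back-transform to nmol/L on
    the LC-MS/MS scale; then apply the *inverse* of the study's assay
    conversion (and unit conversion if the study reports ng/dL) so that
    ``tt_value`` is on the study's native scale.  Negative values after the
    inverse map are clipped at zero.  The result round-trips exactly through
    harmonization when the noise is zero.
    """
    profiles = default_study_profiles() if profiles is None else profiles
    truth = truth or GroundTruth()
    if seed is None:
        seed = truth.seed

    for p in profiles:
        grid = np.linspace(p.age_min, p.age_max, 512)
        den = np.polynomial.polynomial.polyval(
            grid, (1.0,) + truth.mean_model.den_coeffs
        )
        if np.any(den <= 0):
            bad = float(grid[den <= 0][0])
            raise ValueError(
                f"mean model has a pole near age {bad:.2f} inside the range of "
                f"study {p.study_id!r}"
            )

    frames = []
    for i, p in enumerate(profiles):
        rng = np.random.default_rng([int(seed), i])
        ages = _draw_ages(p, rng)
        mu = truth.mean_model.evaluate(ages)
        sigma = truth.sigma(ages)
        if np.any(sigma < 0):
            raise ValueError("sd_profile must be non-negative")
        y = rng.normal(mu, sigma)
        tt_ref = np.clip(inverse_log_adjust(y), 0.0, None)
        tt_native = get_conversion(p.assay).inverse(tt_ref)
        if p.unit == "ng/dL":
            tt_native = tt_native / NG_DL_TO_NMOL_L
        frames.append(
            pd.DataFrame(
                {
                    "age_years": ages,
                    "tt_value": tt_native,
                    "unit": p.unit,
                    "study_id": p.study_id,
                    "assay": p.assay,
                    "is_anchor": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
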