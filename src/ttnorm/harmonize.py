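"""Harmonization of pooled multi-assay testosterone data.

Serum total testosterone (TT) measured on different immunoassay platforms
(DPC, DSL, Centaur, Roche, RIA) is not directly comparable with the
gold-standard LC-MS/MS assay.  This module standardises units
(ng/dL -> nmol/L), converts every study's native assay scale to LC-MS/MS
equivalents via published method-comparison equations, censors young ages
where extracted data are unreliable, and appends artificial zero-TT anchor
points at the origin so that fitted curves pass through the one TT level
known exactly at any age (zero at conception).

The in-memory container is a :class:`pandas.DataFrame` with columns
``age_years, tt_value, unit, study_id, assay, is_anchor`` — the same layout
the CSV readers/writers use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: Unit conversion factor: 1 ng/dL of testosterone equals 0.0347 nmol/L.
NG_DL_TO_NMOL_L = 0.0347

#: Default censoring age in years: data below this age are discarded.
DEFAULT_CENSOR_AGE = 3.0

#: Name of the reference assay; conversion to it is the identity.
REFERENCE_ASSAY = "LC-MS/MS"

#: Canonical column order for the tabular dataset.
COLUMNS = ["age_years", "tt_value", "unit", "study_id", "assay", "is_anchor"]


@dataclass(frozen=True)
class AssayConversion:
    """A published mapping from a study assay scale to the LC-MS/MS scale.

    Two functional forms occur in the method-comparison literature:

    * ``linear``: ``y = slope * x + intercept`` where ``x`` is the study
      assay value and ``y`` the LC-MS/MS equivalent.
    * ``power``: published as ``x = k * y**p`` (study assay as a function of
      the reference), so the forward map is ``y = (x / k)**(1 / p)``.

    Parameters are stored exactly as published; ``r`` is the published
    correlation coefficient of the comparison.
    """

    name: str
    form: Literal["linear", "power"]
    params: tuple[float, ...]
    r: float | None = None

    def __post_init__(self) -> None:
        if self.form == "linear":
            slope, _ = self.params
            if slope <= 0:
                raise ValueError(f"linear conversion {self.name!r}: slope must be > 0")
        elif self.form == "power":
            k, p = self.params
            if k <= 0 or p <= 0:
                raise ValueError(f"power conversion {self.name!r}: k and p must be > 0")
        else:
            raise ValueError(f"unknown conversion form {self.form!r}")

    def forward(self, value):
        """Map study-assay values (nmol/L) to the LC-MS/MS scale.

        Negative results of a linear map near zero are clipped at 0:
        concentrations are non-negative.
        """
        value = np.asarray(value, dtype=float)
        if np.any(value < 0):
            raise ValueError("assay conversion requires non-negative input")
        if self.form == "linear":
            slope, intercept = self.params
            out = slope * value + intercept
        else:
            k, p = self.params
            out = (value / k) ** (1.0 / p)
        return np.clip(out, 0.0, None)

    def inverse(self, value):
        """Map LC-MS/MS-scale values back to the study's native scale."""
        value = np.asarray(value, dtype=float)
        if np.any(value < 0):
            raise ValueError("assay conversion requires non-negative input")
        if self.form == "linear":
            slope, intercept = self.params
            out = (value - intercept) / slope
        else:
            k, p = self.params
            out = k * value**p
        return np.clip(out, 0.0, None)


def _identity_conversion() -> AssayConversion:
    return AssayConversion(REFERENCE_ASSAY, "linear", (1.0, 0.0), r=None)


#: Published assay-to-LC-MS/MS conversions keyed by assay name.
CONVERSIONS: dict[str, AssayConversion] = {
    "DPC": AssayConversion("DPC", "linear", (1.098, -0.1), r=0.945),
    "DSL": AssayConversion("DSL", "linear", (1.791, -0.178), r=0.85),
    "Centaur": AssayConversion("Centaur", "linear", (1.195, -0.05), r=0.945),
    "Roche": AssayConversion("Roche", "linear", (1.167, -2.62), r=0.945),
    "RIA": AssayConversion("RIA", "power", (0.706, 1.077), r=0.96),
    REFERENCE_ASSAY: _identity_conversion(),
}


def get_conversion(name: str) -> AssayConversion:
    """Look up a registered assay conversion by name."""
    try:
        return CONVERSIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown assay {name!r}; registered: {sorted(CONVERSIONS)}"
        ) from None


def standardise_units(value, unit: str = "ng/dL"):
    """Convert TT concentrations to nmol/L.

    ``value`` in ng/dL is multiplied by 0.0347; values already in nmol/L
    pass through unchanged.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("TT concentrations must be non-negative")
    if unit == "nmol/L":
        return value
    if unit == "ng/dL":
        return value * NG_DL_TO_NMOL_L
    raise ValueError(f"unknown unit {unit!r}; expected 'nmol/L' or 'ng/dL'")


def to_reference_assay(value, conversion: AssayConversion | str):
    """Convert study-assay TT values (nmol/L) to the LC-MS/MS scale."""
    if isinstance(conversion, str):
        conversion = get_conversion(conversion)
    return conversion.forward(value)


def log_adjust(tt):
    """Log-adjust a TT concentration: ``log10(tt + 1)``.

    The +1 offset maps zero testosterone to zero on the adjusted scale;
    the log stabilises the level-dependent variance.
    """
    tt = np.asarray(tt, dtype=float)
    if np.any(tt < 0):
        raise ValueError("TT concentrations must be non-negative")
    return np.log10(tt + 1.0)


def inverse_log_adjust(v):
    """Invert :func:`log_adjust`: ``10**v - 1``."""
    return np.power(10.0, np.asarray(v, dtype=float)) - 1.0


def censor_by_age(data: pd.DataFrame, min_age: float = DEFAULT_CENSOR_AGE) -> pd.DataFrame:
    """Drop records younger than ``min_age`` years (boundary inclusive).

    Anchor points are exempt: they sit at the configured anchor age by
    construction and must survive censoring.
    """
    if min_age < 0:
        raise ValueError("min_age must be non-negative")
    keep = (data["age_years"] >= min_age) | data["is_anchor"]
    return data.loc[keep].reset_index(drop=True)


def add_conception_anchors(
    data: pd.DataFrame, count: int | None = None, anchor_age: float = 0.0
) -> pd.DataFrame:
    """Append artificial zero-TT anchor points at ``anchor_age``.

    Anchors force fitted curves through the only exactly known TT level
    (zero at the origin of life); they carry ``is_anchor=True`` so that all
    fit statistics (MSE, r-squared) can exclude them.  ``count`` defaults to
    1% of the dataset size.
    """
    if count is None:
        count = max(1, round(0.01 * len(data)))
    if count < 0:
        raise ValueError("anchor count must be non-negative")
    if count == 0:
        return data.copy()
    anchors = pd.DataFrame(
        {
            "age_years": np.full(count, float(anchor_age)),
            "tt_value": np.zeros(count),
            "unit": "nmol/L",
            "study_id": "anchor",
            "assay": REFERENCE_ASSAY,
            "is_anchor": True,
        }
    )
    return pd.concat([data, anchors], ignore_index=True)


def harmonize(
    data: pd.DataFrame,
    min_age: float = DEFAULT_CENSOR_AGE,
    anchor_count: int | None = None,
    anchor_age: float = 0.0,
) -> pd.DataFrame:
    """Full harmonization pipeline on a raw pooled dataset.

    Steps, applied once and in order: unit standardisation to nmol/L,
    assay conversion to the LC-MS/MS scale, age censoring, anchor
    attachment.  Converted rows are re-tagged ``assay='LC-MS/MS'`` and
    ``unit='nmol/L'`` so a second pass is a no-op.
    """
    out = data.copy()
    if "is_anchor" not in out.columns:
        out["is_anchor"] = False
    out["is_anchor"] = out["is_anchor"].astype(bool)

    tt = np.empty(len(out), dtype=float)
    for unit, idx in out.groupby("unit").groups.items():
        tt[out.index.get_indexer(idx)] = standardise_units(
            out.loc[idx, "tt_value"].to_numpy(), str(unit)
        )
    out["tt_value"] = tt
    out["unit"] = "nmol/L"

    for assay, idx in out.groupby("assay").groups.items():
        conv = get_conversion(str(assay))
        pos = out.index.get_indexer(idx)
        out.iloc[pos, out.columns.get_loc("tt_value")] = conv.forward(
            out.loc[idx, "tt_value"].to_numpy()
        )
    out["assay"] = REFERENCE_ASSAY

    out = censor_by_age(out, min_age)
    out = add_conception_anchors(out, count=anchor_count, anchor_age=anchor_age)
    return out


def interobserver_agreement(
    extract_a: pd.DataFrame,
    extract_b: pd.DataFrame,
    rel_tol: float = 0.01,
    threshold: float = 0.99,
) -> dict:
    """Agreement between two independent extractions of the same chart.

    A pair of records agrees on a quantity when the relative difference is
    at most ``rel_tol``.  Returns the agreeing fraction for age and TT and a
    pass flag at ``threshold`` (boundary inclusive), mirroring a 99%
    inter-observer agreement limit.
    """
    if len(extract_a) != len(extract_b):
        raise ValueError(
            f"extractions differ in length: {len(extract_a)} vs {len(extract_b)}"
        )

    def _frac(a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        scale = np.maximum(np.abs(a), np.abs(b))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(scale > 0, np.abs(a - b) / scale, 0.0)
        return float(np.mean(rel <= rel_tol))

    age_frac = _frac(extract_a["age_years"], extract_b["age_years"])
    tt_frac = _frac(extract_a["tt_value"], extract_b["tt_value"])
    return {
        "age_agreement": age_frac,
        "tt_agreement": tt_frac,
        "passed": age_frac >= threshold and tt_frac >= threshold,
        "threshold": threshold,
    }


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV in the package dialect."""
    df = pd.read_csv(path, dtype={"study_id": str, "assay": str, "unit": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV missing columns: {missing}")
    df["is_anchor"] = df["is_anchor"].astype(bool)
    return df[COLUMNS]


def write_dataset(data: pd.DataFrame, path) -> None:
    """Write a dataset CSV in the package dialect."""
    data[COLUMNS].to_csv(path, index=False)


def make_dataset(
    age_years: Iterable[float],
    tt_value: Iterable[float],
    unit: str = "nmol/L",
    study_id: str = "study",
    assay: str = REFERENCE_ASSAY,
    is_anchor: bool | Iterable[bool] = False,
) -> pd.DataFrame:
    """Convenience constructor for a dataset frame from parallel arrays."""
    age = np.asarray(list(age_years), dtype=float)
    tt = np.asarray(list(tt_value), dtype=float)
    if age.shape != tt.shape:
        raise ValueError("age_years and tt_value must have equal length")
    if np.isscalar(is_anchor) or isinstance(is_anchor, bool):
        anchor = np.full(age.shape, bool(is_anchor))
    else:
        anchor = np.asarray(list(is_anchor), dtype=bool)
    return pd.DataFrame(
        {
            "age_years": age,
            "tt_value": tt,
            "unit": unit,
            "study_id": study_id,
            "assay": assay,
            "is_anchor": anchor,
        }
    )
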