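"""LMS growth-reference machinery.

Anthropometric indicators (weight-for-age, height-for-age, weight-for-height,
BMI-for-age) are conventionally expressed as z-scores against a growth
reference parameterised by the LMS triple: a Box-Cox power ``L``, a median
``M`` and a coefficient of variation ``S``, tabulated per sex along an axis
of age (completed months) or length/height (cm).  The z-score of a
measurement ``X`` is

    z = ((X / M)**L - 1) / (L * S)        if L != 0
    z = ln(X / M) / S                     if L == 0

For weight-based indicators the WHO survey convention applies a "restricted"
adjustment beyond |z| > 3, linearising the scale against the distance between
the 2-SD and 3-SD curves so that extreme measurements do not produce
implausibly large z-scores.

This module provides the scalar/vector LMS transforms, tabulated references
with linear interpolation between grid rows, and the categorical growth bins
used for subgroup analysis (wasting/stunting/underweight grades and a
five-level BMI-for-age habitus classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "WEIGHT_BASED_INDICATORS",
    "SEXES",
    "SCHEMES",
    "GrowthDomainError",
    "GrowthRangeError",
    "LmsTable",
    "GrowthReference",
    "lms_zscore",
    "zscore_to_value",
    "interpolate_lms",
    "classify",
    "classify_many",
]

INDICATORS = ("bmi-for-age", "weight-for-age", "height-for-age", "weight-for-height")
#: indicators subject to the restricted |z| > 3 adjustment (WHO convention)
WEIGHT_BASED_INDICATORS = frozenset({"bmi-for-age", "weight-for-age", "weight-for-height"})
SEXES = ("male", "female")

_L_ZERO_TOL = 1e-12


class GrowthDomainError(ValueError):
    """A measurement or LMS parameter is outside the mathematical domain."""


class GrowthRangeError(ValueError):
    """An axis value falls outside the tabulated grid; carries the valid interval."""

    def __init__(self, axis_value, lo, hi, what="axis value"):
        self.axis_value = axis_value
        self.valid_interval = (lo, hi)
        super().__init__(f"{what} {axis_value!r} outside tabulated range [{lo}, {hi}]")


def _as_array(x):
    a = np.asarray(x, dtype=float)
    return a, a.ndim == 0


def _maybe_scalar(a, scalar):
    return float(a) if scalar else a


def lms_zscore(value, L, M, S, *, restricted=False):
    """z-score of ``value`` under LMS parameters.

    Parameters
    ----------
    value, L, M, S : float or array-like
        Measurement and Box-Cox parameters; ``value``, ``M`` and ``S`` must be
        strictly positive.
    restricted : bool
        Apply the WHO restricted adjustment beyond |z| > 3 (use for
        weight-based indicators).
    """
    value, sv = _as_array(value)
    L, _ = _as_array(L)
    M, _ = _as_array(M)
    S, _ = _as_array(S)
    if np.any(value <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise GrowthDomainError("value, M and S must be strictly positive")
    value, L, M, S = np.broadcast_arrays(value, L, M, S)
    near_zero = np.abs(L) < _L_ZERO_TOL
    Lsafe = np.where(near_zero, 1.0, L)
    z = np.where(
        near_zero,
        np.log(value / M) / S,
        ((value / M) ** Lsafe - 1.0) / (Lsafe * S),
    )
    if restricted:
        z = _restrict(z, value, L, M, S)
    return _maybe_scalar(z, sv and np.ndim(z) == 0)


def _restrict(z, value, L, M, S):
    """WHO restricted adjustment: linearise the z scale beyond +/-3 SD."""
    hi = z > 3
    lo = z < -3
    if not (np.any(hi) or np.any(lo)):
        return z
    z = np.array(z, dtype=float, copy=True)
    if np.any(hi):
        sd3 = zscore_to_value(3.0, L, M, S)
        sd2 = zscore_to_value(2.0, L, M, S)
        adj = 3.0 + (value - sd3) / (sd3 - sd2)
        z[hi] = np.broadcast_to(adj, z.shape)[hi]
    if np.any(lo):
        sd3n = zscore_to_value(-3.0, L, M, S)
        sd2n = zscore_to_value(-2.0, L, M, S)
        adj = -3.0 + (value - sd3n) / (sd2n - sd3n)
        z[lo] = np.broadcast_to(adj, z.shape)[lo]
    return z


def zscore_to_value(z, L, M, S):
    """Invert the (unrestricted) LMS transform: the measurement at z-score ``z``.

    Raises :class:`GrowthDomainError` when ``1 + L*S*z <= 0`` (the z-score is
    outside the representable Box-Cox range for these parameters).
    """
    z, sz = _as_array(z)
    L, _ = _as_array(L)
    M, _ = _as_array(M)
    S, _ = _as_array(S)
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthDomainError("M and S must be strictly positive")
    z, L, M, S = np.broadcast_arrays(z, L, M, S)
    near_zero = np.abs(L) < _L_ZERO_TOL
    base = 1.0 + L * S * z
    if np.any(~near_zero & (base <= 0)):
        raise GrowthDomainError("z outside representable range: 1 + L*S*z <= 0")
    Lsafe = np.where(near_zero, 1.0, L)
    base = np.where(near_zero, 1.0, base)
    value = np.where(near_zero, M * np.exp(S * z), M * base ** (1.0 / Lsafe))
    return _maybe_scalar(value, sz and np.ndim(value) == 0)


@dataclass(frozen=True)
class LmsTable:
    """Tabulated (L, M, S) grid for one indicator and sex.

    The axis is age in completed months for age-based indicators and
    length/height in cm for weight-for-height.  Rows are linearly
    interpolated; queries outside the grid raise :class:`GrowthRangeError`.
    """

    indicator: str
    sex: str
    axis: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        for name in ("axis", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        n = self.axis.size
        if n == 0:
            raise ValueError("LMS grid must be non-empty")
        if not (self.L.size == self.M.size == self.S.size == n):
            raise ValueError("axis, L, M, S must have equal length")
        if n > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis values must be strictly increasing")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise ValueError("M and S must be strictly positive")

    @property
    def axis_range(self):
        return float(self.axis[0]), float(self.axis[-1])

    @property
    def restricted(self) -> bool:
        return self.indicator in WEIGHT_BASED_INDICATORS

    def lms_at(self, axis_value):
        """Interpolated (L, M, S) at ``axis_value`` (scalar or array)."""
        av, scalar = _as_array(axis_value)
        lo, hi = self.axis_range
        if np.any(av < lo) or np.any(av > hi):
            bad = av[(av < lo) | (av > hi)] if av.ndim else av
            raise GrowthRangeError(
                bad if np.ndim(bad) == 0 else float(np.atleast_1d(bad)[0]), lo, hi,
                what=f"{self.indicator}/{self.sex} axis value",
            )
        L = np.interp(av, self.axis, self.L)
        M = np.interp(av, self.axis, self.M)
        S = np.interp(av, self.axis, self.S)
        if scalar:
            return float(L), float(M), float(S)
        return L, M, S

    def zscore(self, axis_value, value, *, restricted=None):
        L, M, S = self.lms_at(axis_value)
        if restricted is None:
            restricted = self.restricted
        return lms_zscore(value, L, M, S, restricted=restricted)

    def value_at(self, axis_value, z):
        L, M, S = self.lms_at(axis_value)
        return zscore_to_value(z, L, M, S)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator,
                "sex": self.sex,
                "axis_value": self.axis,
                "L": self.L,
                "M": self.M,
                "S": self.S,
            }
        )


def interpolate_lms(table: LmsTable, axis_value):
    """Functional form of :meth:`LmsTable.lms_at`."""
    return table.lms_at(axis_value)


@dataclass
class GrowthReference:
    """A bundle of LMS tables keyed by (indicator, sex)."""

    tables: dict = field(default_factory=dict)

    def add(self, table: LmsTable) -> "GrowthReference":
        self.tables[(table.indicator, table.sex)] = table
        return self

    def table(self, indicator: str, sex: str) -> LmsTable:
        try:
            return self.tables[(indicator, sex)]
        except KeyError:
            raise KeyError(f"no LMS table for indicator={indicator!r}, sex={sex!r}") from None

    def zscore(self, indicator, sex, axis_value, value, *, restricted=None):
        return self.table(indicator, sex).zscore(axis_value, value, restricted=restricted)

    def value(self, indicator, sex, axis_value, z):
        return self.table(indicator, sex).value_at(axis_value, z)

    # -- delimited-text interchange: columns indicator, sex, axis_value, L, M, S

    def to_frame(self) -> pd.DataFrame:
        frames = [t.to_frame() for _, t in sorted(self.tables.items())]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GrowthReference":
        required = {"indicator", "sex", "axis_value", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        ref = cls()
        for (indicator, sex), grp in df.groupby(["indicator", "sex"], sort=True):
            grp = grp.sort_values("axis_value")
            ref.add(
                LmsTable(
                    indicator=str(indicator),
                    sex=str(sex),
                    axis=grp["axis_value"].to_numpy(),
                    L=grp["L"].to_numpy(),
                    M=grp["M"].to_numpy(),
                    S=grp["S"].to_numpy(),
                )
            )
        return ref

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls.from_frame(pd.read_csv(Path(path)))


# ---------------------------------------------------------------------------
# Categorical growth bins

#: label sets per classification scheme, in order from highest to lowest z
SCHEMES = {
    "bmi_for_age_5bin": ("underweight", "thin", "normal", "overweight", "obese"),
    "wfh_3bin": ("no wasting", "moderate wasting", "severe wasting"),
    "wfa_3bin": ("normal weight", "moderately underweight", "severely underweight"),
    "hfa_3bin": ("no stunting", "moderate stunting", "severe stunting"),
}


def classify(z: float, scheme: str) -> str:
    """Assign a finite z-score to its growth category.

    ``bmi_for_age_5bin``: Z<=-2.0 underweight; -2.0<Z<=-1.4 thin;
    -1.4<Z<1.4 normal; 1.4<=Z<2.0 overweight; Z>=2.0 obese.
    The three-level schemes grade deficit: Z>=-2.0 normal, -3.0<=Z<-2.0
    moderate, Z<-3.0 severe.
    """
    if scheme not in SCHEMES:
        raise KeyError(f"unknown classification scheme {scheme!r}")
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    labels = SCHEMES[scheme]
    if scheme == "bmi_for_age_5bin":
        if z <= -2.0:
            return labels[0]
        if z <= -1.4:
            return labels[1]
        if z < 1.4:
            return labels[2]
        if z < 2.0:
            return labels[3]
        return labels[4]
    if z >= -2.0:
        return labels[0]
    if z >= -3.0:
        return labels[1]
    return labels[2]


def classify_many(z, scheme: str) -> np.ndarray:
    """Vectorised :func:`classify`; non-finite entries map to empty string."""
    if scheme not in SCHEMES:
        raise KeyError(f"unknown classification scheme {scheme!r}")
    z = np.asarray(z, dtype=float)
    labels = SCHEMES[scheme]
    out = np.full(z.shape, "", dtype=object)
    ok = np.isfinite(z)
    if scheme == "bmi_for_age_5bin":
        conds = [z <= -2.0, z <= -1.4, z < 1.4, z < 2.0, np.ones_like(z, bool)]
    else:
        conds = [z >= -2.0, z >= -3.0, np.ones_like(z, bool)]
    assigned = np.zeros(z.shape, bool)
    for cond, label in zip(conds, labels):
        pick = ok & cond & ~assigned
        out[pick] = label
        assigned |= cond
    return out
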