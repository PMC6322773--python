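"""Synthetic growth-reference tables and NON-CLINICAL fixture calibrations.

Everything here is synthetic.  The LMS grids are smooth anchor curves shaped
like the WHO under-five growth standards (plausible medians, conventional
Box-Cox powers and coefficients of variation) so that the whole toolchain —
simulation, indicator derivation, tape lookup, accuracy analysis — runs
offline and self-consistently.  They are NOT the WHO tables and must not be
used to assess real children; load real reference grids through
:meth:`tapeweight.growth.GrowthReference.from_csv` for that.

Likewise the fixture tape calibrations are derived from these synthetic
grids (per-segment median weight-for-length, habitus categories offset in
weight-for-height z units).  They are NOT the published clinical tapes:
every fixture object carries ``clinical=False`` and a "synthetic-fixture"
source tag, and the loader preserves those flags.
"""

from __future__ import annotations

import numpy as np

from .estimators import (
    BroselowCalibration,
    LengthSegment,
    PawperCalibration,
    PawperSegmentRow,
    RalstonCalibration,
)
from .growth import GrowthReference, LmsTable, zscore_to_value

__all__ = [
    "fixture_reference",
    "fixture_pawper_calibration",
    "fixture_broselow_calibration",
    "fixture_ralston_calibration",
    "fixture_calibrations",
    "FIXTURE_SOURCE",
]

FIXTURE_SOURCE = "synthetic-fixture"

# Anchor curves: (axis anchors, median anchors) per sex, interpolated onto a
# dense grid.  Axis is months for age-based indicators, cm for
# weight-for-height.  L and S are held constant per indicator, in the range
# conventional for that indicator's reference.

_HFA_ANCHORS = {
    "male": ([0, 6, 12, 24, 36, 48, 60, 72],
             [49.9, 67.6, 75.7, 87.1, 96.1, 103.3, 110.0, 115.5]),
    "female": ([0, 6, 12, 24, 36, 48, 60, 72],
               [49.1, 65.7, 74.0, 85.7, 95.1, 102.7, 109.4, 115.0]),
}
_HFA_L, _HFA_S = 1.0, 0.035

_WFH_ANCHORS = {
    "male": ([45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100, 105, 110, 115, 120, 130, 140],
             [2.44, 3.37, 4.40, 5.67, 7.43, 8.44, 9.57, 10.9, 11.9, 13.0,
              14.1, 15.4, 16.8, 18.4, 20.3, 22.4, 27.0, 32.5]),
    "female": ([45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100, 105, 110, 115, 120, 130, 140],
               [2.40, 3.31, 4.32, 5.55, 7.24, 8.24, 9.37, 10.7, 11.7, 12.8,
                13.9, 15.2, 16.7, 18.3, 20.3, 22.5, 27.2, 32.8]),
}
_WFH_L, _WFH_S = -0.35, 0.082

_WFA_ANCHORS = {
    "male": ([0, 6, 12, 24, 36, 48, 60, 72],
             [3.3, 7.9, 9.6, 12.2, 14.3, 16.3, 18.3, 20.5]),
    "female": ([0, 6, 12, 24, 36, 48, 60, 72],
               [3.2, 7.3, 8.9, 11.5, 13.9, 16.1, 18.2, 20.4]),
}
_WFA_L, _WFA_S = -0.1, 0.12

_BAZ_ANCHORS = {
    "male": ([0, 6, 12, 24, 36, 48, 60, 72],
             [13.4, 17.3, 16.8, 16.0, 15.6, 15.3, 15.2, 15.3]),
    "female": ([0, 6, 12, 24, 36, 48, 60, 72],
               [13.3, 16.9, 16.4, 15.7, 15.4, 15.2, 15.1, 15.2]),
}
_BAZ_L, _BAZ_S = -1.6, 0.085


def _dense_table(indicator, sex, anchors, L, S, step):
    ax_anchor, m_anchor = anchors[sex]
    axis = np.arange(ax_anchor[0], ax_anchor[-1] + step / 2, step)
    M = np.interp(axis, ax_anchor, m_anchor)
    return LmsTable(
        indicator=indicator, sex=sex, axis=axis,
        L=np.full_like(axis, L), M=M, S=np.full_like(axis, S),
    )


def fixture_reference() -> GrowthReference:
    """Synthetic LMS reference covering ages 0–72 months, lengths 45–140 cm."""
    ref = GrowthReference()
    for sex in ("male", "female"):
        ref.add(_dense_table("height-for-age", sex, _HFA_ANCHORS, _HFA_L, _HFA_S, 1.0))
        ref.add(_dense_table("weight-for-height", sex, _WFH_ANCHORS, _WFH_L, _WFH_S, 0.5))
        ref.add(_dense_table("weight-for-age", sex, _WFA_ANCHORS, _WFA_L, _WFA_S, 1.0))
        ref.add(_dense_table("bmi-for-age", sex, _BAZ_ANCHORS, _BAZ_L, _BAZ_S, 1.0))
    return ref


# ---------------------------------------------------------------------------
# Fixture tapes

#: length segment edges shared by the fixture tapes, cm
FIXTURE_SEGMENT_EDGES = np.arange(50.0, 131.0, 5.0)

#: representative weight-for-height z-score per PAWPER habitus category (7)
_PAWPER_HABITUS_Z = (-3.5, -2.5, -1.5, 0.0, 1.5, 2.5, 3.5)

#: habitus boundaries in weight-for-height z units -> MAC cut-offs via the
#: fixture MAC model (see simulate module defaults)
_PAWPER_CUTOFF_Z = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)

_MAC_INTERCEPT = 14.655  # cm at WHZ 0, age 32.5 months
_MAC_AGE_SLOPE = 0.02    # cm per month
_MAC_WHZ_SLOPE = 0.758   # cm per WHZ unit


def _unisex_wfh_weight(ref: GrowthReference, length_cm: float, z: float) -> float:
    """Sex-averaged weight at a weight-for-height z (tapes are unisex)."""
    return 0.5 * sum(
        ref.value("weight-for-height", sex, length_cm, z) for sex in ("male", "female")
    )


def _age_at_length(ref: GrowthReference, length_cm: float) -> float:
    """Representative age (months) whose unisex median height is length_cm."""
    tb = ref.table("height-for-age", "male")
    tg = ref.table("height-for-age", "female")
    med = 0.5 * (tb.M + tg.M)
    return float(np.clip(np.interp(length_cm, med, tb.axis), 6.0, 59.0))


def _segments():
    edges = FIXTURE_SEGMENT_EDGES
    return [LengthSegment(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def fixture_pawper_calibration(ref: GrowthReference | None = None) -> PawperCalibration:
    """Non-clinical PAWPER XL-MAC fixture: 7 habitus weights per segment,
    MAC cut-offs from the fixture MAC-vs-WHZ model at the segment's
    representative age."""
    ref = ref or fixture_reference()
    rows = []
    for seg in _segments():
        mid = 0.5 * (seg.lower + seg.upper)
        age = _age_at_length(ref, mid)
        intercept = _MAC_INTERCEPT + _MAC_AGE_SLOPE * (age - 32.5)
        cutoffs = tuple(round(intercept + _MAC_WHZ_SLOPE * z, 2) for z in _PAWPER_CUTOFF_Z)
        weights = tuple(
            round(_unisex_wfh_weight(ref, mid, z), 2) for z in _PAWPER_HABITUS_Z
        )
        rows.append(PawperSegmentRow(seg, cutoffs, weights))
    return PawperCalibration(tuple(rows), source=FIXTURE_SOURCE, clinical=False)


def fixture_broselow_calibration(edition: str, ref: GrowthReference | None = None) -> BroselowCalibration:
    """Non-clinical Broselow fixture: median weight-for-length per segment.

    The 2011A edition reads half a z-unit heavier than 2007B, mimicking the
    documented upward recalibration between editions.
    """
    if edition not in ("2007B", "2011A"):
        raise ValueError(f"unknown edition {edition!r}")
    ref = ref or fixture_reference()
    z = 0.0 if edition == "2007B" else 0.5
    rows = tuple(
        (seg, round(_unisex_wfh_weight(ref, 0.5 * (seg.lower + seg.upper), z), 2))
        for seg in _segments()
    )
    return BroselowCalibration(edition, rows, source=FIXTURE_SOURCE, clinical=False)


_RALSTON_BAND_Z = {"severe": -2.5, "moderate": -1.5, "normal": 0.0}


def fixture_ralston_calibration(ref: GrowthReference | None = None) -> RalstonCalibration:
    """Non-clinical Ralston fixture: three length tapes offset in WHZ."""
    ref = ref or fixture_reference()
    tapes = {
        band: tuple(
            (seg, round(_unisex_wfh_weight(ref, 0.5 * (seg.lower + seg.upper), z), 2))
            for seg in _segments()
        )
        for band, z in _RALSTON_BAND_Z.items()
    }
    return RalstonCalibration(tapes, source=FIXTURE_SOURCE, clinical=False)


def fixture_calibrations(ref: GrowthReference | None = None) -> dict:
    """All four fixture tapes keyed by method identifier."""
    ref = ref or fixture_reference()
    pawper = fixture_pawper_calibration(ref)
    b07 = fixture_broselow_calibration("2007B", ref)
    b11 = fixture_broselow_calibration("2011A", ref)
    ralston = fixture_ralston_calibration(ref)
    return {
        pawper.method: pawper,
        b07.method: b07,
        b11.method: b11,
        ralston.method: ralston,
    }
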