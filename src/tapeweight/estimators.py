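"""Calibration-table-driven tape weight estimators.

Three families of length-based ("tape") weight estimation systems are
supported, each driven by a pluggable calibration artifact:

* **PAWPER XL-MAC** — the child's length selects a tape segment; within the
  segment, mid-arm circumference (MAC) cut-offs select one of up to seven
  habitus categories, each printing its own weight.
* **Broselow** (editions 2007B and 2011A) — length-only: one weight per
  segment.
* **Ralston** — three parallel length tapes selected by a MAC band
  (severe < 115 mm, moderate 115–125 mm inclusive, normal > 125 mm).

Conventions (stated once, applied everywhere): length segments are half-open
``[lower, upper)`` in cm; a MAC exactly equal to a cut-off belongs to the
higher habitus category; MAC is stored in cm internally with mm accepted at
the boundary.  Lengths outside a tape's range yield an out-of-range result,
not an error — downstream analysis excludes and counts them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "CalibrationError",
    "LengthSegment",
    "PawperSegmentRow",
    "PawperCalibration",
    "BroselowCalibration",
    "RalstonCalibration",
    "EstimateResult",
    "RALSTON_SEVERE_MAX_MM",
    "RALSTON_MODERATE_MAX_MM",
    "locate_segment",
    "pawper_xl_mac_estimate",
    "broselow_estimate",
    "ralston_estimate",
    "load_calibration",
    "save_calibration",
    "estimate_many",
]

#: Ralston MAC band edges, in mm as printed on the device design
RALSTON_SEVERE_MAX_MM = 115.0   # severe band is mac < 115
RALSTON_MODERATE_MAX_MM = 125.0  # moderate band is 115 <= mac <= 125
RALSTON_BANDS = ("severe", "moderate", "normal")

_MAX_HABITUS = 7
_CONTIG_TOL = 1e-9


class CalibrationError(ValueError):
    """A calibration file or object violates its structural invariants."""


@dataclass(frozen=True)
class LengthSegment:
    """Half-open length interval [lower, upper) in cm."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise CalibrationError(f"segment lower {self.lower} must be < upper {self.upper}")

    def __contains__(self, length: float) -> bool:
        return self.lower <= length < self.upper


def _check_segments(segments, context: str):
    """Contiguity + non-overlap; raises naming the offending row."""
    for i in range(1, len(segments)):
        gap = segments[i].lower - segments[i - 1].upper
        if gap < -_CONTIG_TOL:
            raise CalibrationError(
                f"{context}: row {i} segment [{segments[i].lower}, {segments[i].upper}) "
                f"overlaps row {i - 1}"
            )
        if gap > _CONTIG_TOL:
            raise CalibrationError(
                f"{context}: row {i} segment [{segments[i].lower}, {segments[i].upper}) "
                f"leaves a gap after row {i - 1}"
            )


@dataclass(frozen=True)
class PawperSegmentRow:
    """One PAWPER XL-MAC length segment: MAC cut-offs and per-habitus weights."""

    segment: LengthSegment
    mac_cutoffs: tuple
    weights: tuple

    def __post_init__(self):
        object.__setattr__(self, "mac_cutoffs", tuple(float(c) for c in self.mac_cutoffs))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if not 1 <= len(self.weights) <= _MAX_HABITUS:
            raise CalibrationError(
                f"segment [{self.segment.lower}, {self.segment.upper}): "
                f"{len(self.weights)} habitus categories (must be 1-{_MAX_HABITUS})"
            )
        if len(self.weights) != len(self.mac_cutoffs) + 1:
            raise CalibrationError(
                f"segment [{self.segment.lower}, {self.segment.upper}): "
                f"{len(self.weights)} weights require {len(self.weights) - 1} cut-offs, "
                f"got {len(self.mac_cutoffs)}"
            )
        if any(b <= a for a, b in zip(self.mac_cutoffs, self.mac_cutoffs[1:])):
            raise CalibrationError(
                f"segment [{self.segment.lower}, {self.segment.upper}): cut-offs not increasing"
            )
        if any(b <= a for a, b in zip(self.weights, self.weights[1:])):
            raise CalibrationError(
                f"segment [{self.segment.lower}, {self.segment.upper}): weights not increasing"
            )


@dataclass(frozen=True)
class PawperCalibration:
    rows: tuple
    source: str = ""
    clinical: bool = False
    method: str = "pawper_xl_mac"

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        if not self.rows:
            raise CalibrationError("PAWPER calibration has no segments")
        _check_segments([r.segment for r in self.rows], "pawper")

    @property
    def segments(self):
        return [r.segment for r in self.rows]


@dataclass(frozen=True)
class BroselowCalibration:
    """Length-only tape: one weight per segment, non-decreasing with length."""

    edition: str
    rows: tuple  # of (LengthSegment, weight_kg)
    source: str = ""
    clinical: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple((s, float(w)) for s, w in self.rows))
        if not self.rows:
            raise CalibrationError("Broselow calibration has no segments")
        _check_segments([s for s, _ in self.rows], f"broselow {self.edition}")
        weights = [w for _, w in self.rows]
        for i in range(1, len(weights)):
            if weights[i] < weights[i - 1]:
                raise CalibrationError(
                    f"broselow {self.edition}: row {i} weight {weights[i]} decreases"
                )

    @property
    def method(self) -> str:
        return f"broselow_{self.edition}"

    @property
    def segments(self):
        return [s for s, _ in self.rows]


@dataclass(frozen=True)
class RalstonCalibration:
    """Three Broselow-style tapes keyed by MAC band (severe/moderate/normal)."""

    tapes: dict  # band -> tuple of (LengthSegment, weight_kg)
    source: str = ""
    clinical: bool = False
    method: str = "ralston"

    def __post_init__(self):
        tapes = {}
        for band in RALSTON_BANDS:
            if band not in self.tapes:
                raise CalibrationError(f"ralston: missing band {band!r}")
            rows = tuple((s, float(w)) for s, w in self.tapes[band])
            if not rows:
                raise CalibrationError(f"ralston: band {band!r} has no segments")
            _check_segments([s for s, _ in rows], f"ralston/{band}")
            weights = [w for _, w in rows]
            for i in range(1, len(weights)):
                if weights[i] < weights[i - 1]:
                    raise CalibrationError(f"ralston/{band}: row {i} weight decreases")
            tapes[band] = rows
        object.__setattr__(self, "tapes", tapes)


@dataclass(frozen=True)
class EstimateResult:
    """Outcome of one tape lookup; ``in_range`` False means no estimate."""

    method: str
    weight: Optional[float]
    segment_index: Optional[int]
    habitus_index: Optional[int]
    in_range: bool


def _out_of_range(method):
    return EstimateResult(method, None, None, None, False)


def locate_segment(segments, length: float) -> Optional[int]:
    """Index of the segment containing ``length`` (half-open), else None."""
    if length <= 0:
        raise ValueError("length must be positive")
    for i, seg in enumerate(segments):
        if length in seg:
            return i
    return None


def _mac_to_cm(mac: float, unit: str) -> float:
    if unit == "cm":
        return mac
    if unit == "mm":
        return mac / 10.0
    raise ValueError(f"unknown MAC unit {unit!r}")


def pawper_xl_mac_estimate(cal: PawperCalibration, length: float, mac: float,
                           *, mac_unit: str = "cm") -> EstimateResult:
    """Three-step PAWPER XL-MAC lookup: segment by length, habitus by MAC, weight.

    The habitus index is the number of segment cut-offs less than or equal to
    the MAC (ties go to the higher habitus category).
    """
    if length <= 0 or mac <= 0:
        raise ValueError("length and mac must be positive")
    mac_cm = _mac_to_cm(mac, mac_unit)
    idx = locate_segment(cal.segments, length)
    if idx is None:
        return _out_of_range(cal.method)
    row = cal.rows[idx]
    habitus = int(np.searchsorted(row.mac_cutoffs, mac_cm, side="right"))
    return EstimateResult(cal.method, row.weights[habitus], idx, habitus, True)


def broselow_estimate(cal: BroselowCalibration, length: float) -> EstimateResult:
    if length <= 0:
        raise ValueError("length must be positive")
    idx = locate_segment(cal.segments, length)
    if idx is None:
        return _out_of_range(cal.method)
    return EstimateResult(cal.method, cal.rows[idx][1], idx, None, True)


def _ralston_band(mac_mm: float) -> int:
    if mac_mm < RALSTON_SEVERE_MAX_MM:
        return 0
    if mac_mm <= RALSTON_MODERATE_MAX_MM:
        return 1
    return 2


def ralston_estimate(cal: RalstonCalibration, length: float, mac_mm: float) -> EstimateResult:
    """Ralston three-tape lookup: MAC band (mm) selects the tape, length the weight."""
    if length <= 0 or mac_mm <= 0:
        raise ValueError("length and mac_mm must be positive")
    band_idx = _ralston_band(mac_mm)
    rows = cal.tapes[RALSTON_BANDS[band_idx]]
    idx = locate_segment([s for s, _ in rows], length)
    if idx is None:
        return _out_of_range(cal.method)
    return EstimateResult(cal.method, rows[idx][1], idx, band_idx, True)


# ---------------------------------------------------------------------------
# Vectorised lookups (the cohort pipeline path)


def _rows_arrays(segments):
    lowers = np.array([s.lower for s in segments])
    uppers = np.array([s.upper for s in segments])
    return lowers, uppers


def _locate_many(segments, lengths):
    """Vectorised segment location; -1 marks out-of-range.  Requires the
    contiguity already enforced at calibration load."""
    lowers, uppers = _rows_arrays(segments)
    idx = np.searchsorted(lowers, lengths, side="right") - 1
    idx = np.clip(idx, 0, len(segments) - 1)
    ok = (lengths >= lowers[idx]) & (lengths < uppers[idx])
    return np.where(ok, idx, -1)


def estimate_many(cal, lengths, mac_cm=None):
    """Apply one calibration to arrays of measurements.

    Returns ``(weights, in_range, segment_index, habitus_index)`` arrays;
    weight is NaN and indices -1 where out of range.  ``mac_cm`` is required
    for MAC-using methods and ignored by Broselow.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    weights = np.full(n, np.nan)
    habitus = np.full(n, -1, dtype=int)

    if isinstance(cal, BroselowCalibration):
        seg = _locate_many(cal.segments, lengths)
        ok = seg >= 0
        w = np.array([w for _, w in cal.rows])
        weights[ok] = w[seg[ok]]
        return weights, ok, seg, habitus

    if mac_cm is None:
        raise ValueError(f"{cal.method} requires MAC values")
    mac_cm = np.asarray(mac_cm, dtype=float)

    if isinstance(cal, PawperCalibration):
        seg = _locate_many(cal.segments, lengths)
        ok = seg >= 0
        for k, row in enumerate(cal.rows):
            pick = ok & (seg == k)
            if not np.any(pick):
                continue
            h = np.searchsorted(np.asarray(row.mac_cutoffs), mac_cm[pick], side="right")
            weights[pick] = np.asarray(row.weights)[h]
            habitus[pick] = h
        return weights, ok, seg, habitus

    if isinstance(cal, RalstonCalibration):
        mac_mm = mac_cm * 10.0
        band = np.where(
            mac_mm < RALSTON_SEVERE_MAX_MM, 0,
            np.where(mac_mm <= RALSTON_MODERATE_MAX_MM, 1, 2),
        )
        seg = np.full(n, -1, dtype=int)
        for b, name in enumerate(RALSTON_BANDS):
            pick = band == b
            if not np.any(pick):
                continue
            rows = cal.tapes[name]
            s = _locate_many([sg for sg, _ in rows], lengths[pick])
            seg[pick] = s
            w = np.array([w for _, w in rows])
            good = s >= 0
            sub = np.flatnonzero(pick)
            weights[sub[good]] = w[s[good]]
        ok = seg >= 0
        habitus[:] = band
        habitus[~ok] = -1
        return weights, ok, seg, habitus

    raise TypeError(f"unknown calibration type {type(cal).__name__}")


# ---------------------------------------------------------------------------
# Calibration files (JSON; schemas per method)


def _segment_from_row(row, i, context):
    try:
        return LengthSegment(float(row["segment_lower_cm"]), float(row["segment_upper_cm"]))
    except KeyError as e:
        raise CalibrationError(f"{context}: row {i} missing field {e}") from None


def _calibration_from_dict(doc: dict):
    method = doc.get("method")
    source = doc.get("source", "")
    clinical = bool(doc.get("clinical", False))
    if method == "pawper_xl_mac":
        rows = []
        for i, row in enumerate(doc.get("rows", [])):
            seg = _segment_from_row(row, i, "pawper")
            rows.append(PawperSegmentRow(seg, tuple(row["cutoffs_cm"]), tuple(row["weights_kg"])))
        return PawperCalibration(tuple(rows), source=source, clinical=clinical)
    if method == "broselow":
        rows = []
        for i, row in enumerate(doc.get("rows", [])):
            seg = _segment_from_row(row, i, "broselow")
            rows.append((seg, float(row["weight_kg"])))
        edition = doc.get("edition")
        if edition not in ("2007B", "2011A"):
            raise CalibrationError(f"broselow: unknown edition {edition!r}")
        return BroselowCalibration(edition, tuple(rows), source=source, clinical=clinical)
    if method == "ralston":
        tapes = {}
        for band, rows_doc in doc.get("bands", {}).items():
            rows = []
            for i, row in enumerate(rows_doc):
                seg = _segment_from_row(row, i, f"ralston/{band}")
                rows.append((seg, float(row["weight_kg"])))
            tapes[band] = tuple(rows)
        return RalstonCalibration(tapes, source=source, clinical=clinical)
    raise CalibrationError(f"unknown calibration method {method!r}")


def _calibration_to_dict(cal) -> dict:
    if isinstance(cal, PawperCalibration):
        return {
            "method": "pawper_xl_mac",
            "source": cal.source,
            "clinical": cal.clinical,
            "rows": [
                {
                    "segment_lower_cm": r.segment.lower,
                    "segment_upper_cm": r.segment.upper,
                    "cutoffs_cm": list(r.mac_cutoffs),
                    "weights_kg": list(r.weights),
                }
                for r in cal.rows
            ],
        }
    if isinstance(cal, BroselowCalibration):
        return {
            "method": "broselow",
            "edition": cal.edition,
            "source": cal.source,
            "clinical": cal.clinical,
            "rows": [
                {"segment_lower_cm": s.lower, "segment_upper_cm": s.upper, "weight_kg": w}
                for s, w in cal.rows
            ],
        }
    if isinstance(cal, RalstonCalibration):
        return {
            "method": "ralston",
            "source": cal.source,
            "clinical": cal.clinical,
            "bands": {
                band: [
                    {"segment_lower_cm": s.lower, "segment_upper_cm": s.upper, "weight_kg": w}
                    for s, w in rows
                ]
                for band, rows in cal.tapes.items()
            },
        }
    raise TypeError(f"unknown calibration type {type(cal).__name__}")


def load_calibration(path):
    """Load and validate a calibration JSON file; raises
    :class:`CalibrationError` naming the offending row on any violation."""
    with open(Path(path), encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise CalibrationError(f"{path}: not valid JSON ({e})") from None
    return _calibration_from_dict(doc)


def save_calibration(cal, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(_calibration_to_dict(cal), fh, indent=1, sort_keys=True)
        fh.write("\n")
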