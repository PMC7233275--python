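"""Data model and I/O for HRM plate runs.

A plate run couples, per well, a PCR amplification curve (fluorescence vs
cycle) and a high-resolution melt curve (fluorescence vs temperature, 65-95
degC in 0.2 degC increments on the protocol used here).  This module owns the
well-level containers, the long-format plate text I/O, amplification-quality
screening, and melt-curve normalization / melt-peak (Tm) calling.

Normalization follows the usual HRM convention: a linear baseline is fitted
in a pre-melt window (fully double-stranded, high fluorescence) and another
in a post-melt window (fully dissociated, background fluorescence), and the
raw signal is rescaled so the pre-melt baseline maps to 1 and the post-melt
baseline to 0.  The melt peak is the temperature of the maximum of the
smoothed negative derivative -dF/dT of the normalized curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "Well",
    "AmplificationCurve",
    "MeltCurve",
    "MeltFeatures",
    "QCConfig",
    "PlateRecord",
    "PlateParseError",
    "read_plate",
    "write_plate",
    "screen_amplification",
    "screen_plate",
    "normalize_melt",
]

MELT_RANGE = (65.0, 95.0)
DEFAULT_STEP = 0.2


class PlateParseError(ValueError):
    """Raised for malformed or inconsistent plate/metadata files."""


@dataclass(frozen=True)
class Well:
    """Identity and design metadata of a single plate well."""

    plate_id: str
    well_id: str
    sample_id: str
    population_id: str | None = None
    replicate_index: int = 1
    known_haplotype: str | None = None

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)


@dataclass(frozen=True)
class AmplificationCurve:
    """PCR fluorescence vs cycle number (arbitrary units)."""

    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if cycles.shape != fluo.shape or cycles.ndim != 1:
            raise ValueError("cycles and fluorescence must be 1-D and equal length")
        if np.any(np.diff(cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class MeltCurve:
    """Melt fluorescence vs temperature on a uniform grid inside 65-95 degC."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if temps.shape != fluo.shape or temps.ndim != 1:
            raise ValueError("temperatures and fluorescence must be 1-D and equal length")
        steps = np.diff(temps)
        if len(steps) == 0 or np.any(steps <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-6:
            raise ValueError("temperature step must be uniform (tolerance 1e-6)")
        if temps[0] < MELT_RANGE[0] - 1e-9 or temps[-1] > MELT_RANGE[1] + 1e-9:
            raise ValueError(
                f"temperatures must lie within the protocol melt window {MELT_RANGE}"
            )
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "fluorescence", fluo)

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class MeltFeatures:
    """Normalized melt curve, its -dF/dT derivative and the melt peak Tm."""

    tm: float
    normalized: MeltCurve
    derivative: np.ndarray

    def __post_init__(self) -> None:
        if len(self.derivative) != len(self.normalized):
            raise ValueError("derivative length must equal curve length")
        t = self.normalized.temperatures
        if not (t[0] - 1e-9 <= self.tm <= t[-1] + 1e-9):
            raise ValueError("tm must lie within the melt window")


@dataclass(frozen=True)
class QCConfig:
    """Amplification-quality screening thresholds.

    The protocol this mirrors only states that wells with insufficient PCR
    product were excluded, without a numeric rule, so the rule here is an
    explicit configuration: a well passes when its plateau rise (plateau
    minus baseline fluorescence) reaches ``min_plateau_ratio`` of a reference
    plateau rise (normally the plate median) and a sigmoid fit detects an
    exponential phase.  When no reference is supplied, ``min_plateau`` acts
    as an absolute floor.
    """

    min_plateau_ratio: float = 0.10
    min_plateau: float = 10.0
    reference_plateau: float | None = None
    edge_cycles: int = 5


@dataclass(frozen=True)
class PlateRecord:
    well: Well
    amplification: AmplificationCurve
    melt: MeltCurve


# ---------------------------------------------------------------------------
# plate I/O
#
# Long format, comma- or tab-delimited:
#   plate file:    plate_id, well_id, stage (AMP|MELT), x, fluorescence
#   metadata file: plate_id, well_id, sample_id, population_id,
#                  replicate_index, known_haplotype   (last two may be blank)
# ---------------------------------------------------------------------------

_PLATE_COLS = ["plate_id", "well_id", "stage", "x", "fluorescence"]
_META_COLS = [
    "plate_id",
    "well_id",
    "sample_id",
    "population_id",
    "replicate_index",
    "known_haplotype",
]


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_plate(path: str, metadata_path: str) -> list[PlateRecord]:
    """Read a long-format plate file plus well metadata into plate records.

    Wells present in the metadata but lacking melt data are rejected with a
    :class:`PlateParseError` naming the well.  Duplicate (plate, well) pairs
    in the metadata are a validation error.
    """
    meta: dict[tuple[str, str], Well] = {}
    with open(metadata_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(metadata_path))
        missing = set(_META_COLS) - set(reader.fieldnames or [])
        if missing:
            raise PlateParseError(f"metadata file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            key = (row["plate_id"], row["well_id"])
            if key in meta:
                raise PlateParseError(f"duplicate (plate, well) {key} in metadata row {i}")
            try:
                rep = int(row["replicate_index"]) if row["replicate_index"] else 1
            except ValueError as exc:
                raise PlateParseError(
                    f"malformed replicate_index in metadata row {i}: {row['replicate_index']!r}"
                ) from exc
            meta[key] = Well(
                plate_id=row["plate_id"],
                well_id=row["well_id"],
                sample_id=row["sample_id"],
                population_id=row["population_id"] or None,
                replicate_index=rep,
                known_haplotype=row["known_haplotype"] or None,
            )

    series: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        missing = set(_PLATE_COLS) - set(reader.fieldnames or [])
        if missing:
            raise PlateParseError(f"plate file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            stage = row["stage"].upper()
            if stage not in ("AMP", "MELT"):
                raise PlateParseError(f"unknown stage {row['stage']!r} in plate row {i}")
            try:
                x = float(row["x"])
                y = float(row["fluorescence"])
            except ValueError as exc:
                raise PlateParseError(f"malformed numeric field in plate row {i}") from exc
            series.setdefault((row["plate_id"], row["well_id"], stage), []).append((x, y))

    records: list[PlateRecord] = []
    for key, well in meta.items():
        melt_pts = series.get((*key, "MELT"))
        if not melt_pts:
            raise PlateParseError(f"well {key} has no melt data")
        amp_pts = series.get((*key, "AMP"), [])
        melt_arr = np.array(melt_pts)
        try:
            melt = MeltCurve(melt_arr[:, 0], melt_arr[:, 1])
        except ValueError as exc:
            raise PlateParseError(f"well {key}: {exc}") from exc
        if amp_pts:
            amp_arr = np.array(amp_pts)
            amp = AmplificationCurve(amp_arr[:, 0], amp_arr[:, 1])
        else:
            amp = AmplificationCurve(np.arange(1, 3, dtype=float), np.zeros(2))
        records.append(PlateRecord(well=well, amplification=amp, melt=melt))
    return records


def write_plate(records: Iterable[PlateRecord], path: str, metadata_path: str) -> None:
    """Write plate records in the long text format read by :func:`read_plate`.

    Floats are serialized with ``repr`` so a write/read round trip reproduces
    every fluorescence value bit-identically.
    """
    records = list(records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLATE_COLS)
        for rec in records:
            for c, f in zip(rec.amplification.cycles, rec.amplification.fluorescence):
                writer.writerow([rec.well.plate_id, rec.well.well_id, "AMP", repr(float(c)), repr(float(f))])
            for t, f in zip(rec.melt.temperatures, rec.melt.fluorescence):
                writer.writerow([rec.well.plate_id, rec.well.well_id, "MELT", repr(float(t)), repr(float(f))])
    with open(metadata_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_COLS)
        for rec in records:
            w = rec.well
            writer.writerow(
                [w.plate_id, w.well_id, w.sample_id, w.population_id or "",
                 w.replicate_index, w.known_haplotype or ""]
            )


# ---------------------------------------------------------------------------
# amplification screening
# ---------------------------------------------------------------------------

def _sigmoid(c, base, amp, mid, width):
    return base + amp / (1.0 + np.exp(-(c - mid) / width))


def _fit_sigmoid(curve: AmplificationCurve) -> tuple[float, float] | None:
    """Fit a logistic growth model; return (amplitude, midpoint) or None."""
    c = curve.cycles
    f = curve.fluorescence
    span = float(f.max() - f.min())
    if span <= 0:
        return None
    p0 = [float(f.min()), span, float(c[np.argmax(np.diff(f))] if len(c) > 1 else c.mean()), 2.0]
    try:
        popt, _ = curve_fit(_sigmoid, c, f, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        return None
    base, amp, mid, width = popt
    if amp <= 0 or width <= 0 or not (c[0] <= mid <= c[-1]):
        return None
    # reject fits that explain less variance than a flat line plus noise
    resid = f - _sigmoid(c, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot <= 0 or 1.0 - ss_res / ss_tot < 0.8:
        return None
    return float(amp), float(mid)


def plateau_rise(curve: AmplificationCurve, edge_cycles: int = 5) -> float:
    """Plateau minus baseline fluorescence (means of the last/first cycles)."""
    k = min(edge_cycles, max(1, len(curve) // 4))
    return float(np.mean(curve.fluorescence[-k:]) - np.mean(curve.fluorescence[:k]))


def screen_amplification(curve: AmplificationCurve, config: QCConfig = QCConfig()) -> tuple[bool, str]:
    """Pass/fail amplification QC with a human-readable reason.

    Deterministic: fails when the plateau rise is below threshold or when no
    exponential phase can be fitted.
    """
    if len(curve) < 10:
        raise ValueError("amplification curve must span at least 10 cycles")
    rise = plateau_rise(curve, config.edge_cycles)
    if np.allclose(curve.fluorescence, 0.0):
        return False, "no amplification"
    if config.reference_plateau is not None:
        threshold = config.min_plateau_ratio * config.reference_plateau
    else:
        threshold = config.min_plateau
    if rise < threshold:
        return False, f"plateau rise {rise:.3g} below threshold {threshold:.3g}"
    if _fit_sigmoid(curve) is None:
        return False, "no exponential phase detected (sigmoid fit failed)"
    return True, "ok"


def screen_plate(records: Sequence[PlateRecord], config: QCConfig = QCConfig()) -> dict[tuple[str, str], tuple[bool, str]]:
    """Screen every well of a run against the plate-median plateau rise."""
    rises = [plateau_rise(r.amplification, config.edge_cycles) for r in records]
    reference = float(np.median([r for r in rises if r > 0] or [config.min_plateau]))
    cfg = QCConfig(
        min_plateau_ratio=config.min_plateau_ratio,
        min_plateau=config.min_plateau,
        reference_plateau=reference,
        edge_cycles=config.edge_cycles,
    )
    return {rec.well.key: screen_amplification(rec.amplification, cfg) for rec in records}


# ---------------------------------------------------------------------------
# melt normalization and Tm calling
# ---------------------------------------------------------------------------

def _window_mask(temps: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be (low, high) with low < high")
    return (temps >= lo - 1e-9) & (temps <= hi + 1e-9)


def _default_windows(temps: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    return (temps[0], temps[0] + 2.0), (temps[-1] - 2.0, temps[-1])


def normalize_melt(
    curve: MeltCurve,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    tm_smooth_window: float = 2.0,
) -> MeltFeatures:
    """Baseline-normalize a melt curve and call its melt peak.

    Linear baselines are fitted in the pre-melt and post-melt windows
    (defaults: first and last 2 degC of the sweep); the normalized signal is
    ``(F - lower) / (upper - lower)`` clipped to [0, 1].  The reported
    derivative is the smoothed -dF/dT (quadratic local polynomial over a
    1 degC window).  Tm is called from a more heavily smoothed derivative
    (``tm_smooth_window`` degC, default 2) and refined to sub-grid precision
    by a quadratic vertex fit over the points around the peak; melt
    transitions are a couple of degC wide, so the wider smoothing
    suppresses dye noise without shifting the peak.  A tie between two
    equal derivative maxima resolves to the lower temperature.
    """
    temps = curve.temperatures
    if pre_window is None or post_window is None:
        d_pre, d_post = _default_windows(temps)
        pre_window = pre_window or d_pre
        post_window = post_window or d_post
    if pre_window[1] > post_window[0]:
        raise ValueError("pre_window must lie below post_window")
    pre_mask = _window_mask(temps, pre_window)
    post_mask = _window_mask(temps, post_window)
    if pre_mask.sum() < 5 or post_mask.sum() < 5:
        raise ValueError("each baseline window must span at least 5 points")

    upper = np.polynomial.Polynomial.fit(temps[pre_mask], curve.fluorescence[pre_mask], 1)
    lower = np.polynomial.Polynomial.fit(temps[post_mask], curve.fluorescence[post_mask], 1)
    up = upper(temps)
    lo = lower(temps)
    melt_mask = (temps > pre_window[1]) & (temps < post_window[0])
    if np.any(up[melt_mask] <= lo[melt_mask]):
        raise ValueError("degenerate baselines: upper(T) <= lower(T) inside the melt window")
    norm = np.clip((curve.fluorescence - lo) / (up - lo), 0.0, 1.0)
    normalized = MeltCurve(temps, norm)

    step = curve.step

    def smoothed_derivative(window_degC: float) -> np.ndarray:
        pts = max(5, int(round(window_degC / step)) | 1)  # odd point count
        pts = min(pts, len(norm) - (1 - len(norm) % 2))
        return -savgol_filter(norm, window_length=pts, polyorder=2, deriv=1, delta=step)

    deriv = smoothed_derivative(1.0)
    deriv_tm = smoothed_derivative(tm_smooth_window)
    peak = int(np.argmax(deriv_tm))  # argmax returns the first (= lowest T) on ties
    tm = float(temps[peak])
    lo_i, hi_i = max(0, peak - 3), min(len(deriv_tm), peak + 4)
    if hi_i - lo_i >= 3:
        xs = temps[lo_i:hi_i] - temps[peak]
        a, b, _ = np.polyfit(xs, deriv_tm[lo_i:hi_i], 2)
        if a < 0:  # concave: refine by the vertex of the fitted parabola
            vertex = float(-b / (2 * a))
            if abs(vertex) <= step * 1.5:
                tm += vertex
    tm = float(min(max(tm, temps[0]), temps[-1]))
    return MeltFeatures(tm=tm, normalized=normalized, derivative=deriv)
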