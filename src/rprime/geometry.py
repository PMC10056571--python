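"""Per-beat r'-wave detection and triangle geometry.

The r'-wave — the terminal positive deflection of the QRS in V1/V2 — is
modelled as a triangle whose limbs are the straight lines fitted to its
upslope and downslope. All geometry lives in the paper-mm frame (see
:mod:`rprime.io`), the only frame in which the published cut-offs are
meaningful. With angles measured from the vertical, the quantities are

* ``theta_up`` — upslope angle from vertical,
* ``alpha``   — downslope angle from vertical,
* ``beta = theta_up + alpha`` — the apex angle of the triangle,
* ``h``       — apex height above the isoelectric line, in mm,
* base width at depth ``d`` mm below the apex:
  ``d * (tan theta_up + tan alpha)`` mm, hence
  ``DBT-5mm = ms_per_mm * 5 * (tan theta_up + tan alpha)`` and
  ``DBT-iso = ms_per_mm * h * (tan theta_up + tan alpha)`` in ms, and
  ``ratio = DBT-iso(mm) / h = tan theta_up + tan alpha``.

These identities hold *exactly* on every emitted geometry because the
derived quantities are computed from the fitted tangents, not re-measured.

An r'-wave is *measurable* when its apex rises more than 0.1 mV (1 mm)
above the isoelectric line and the descending limb drops by more than
0.1 mV — both strict inequalities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import Calibration, ECGRecord, ICLevel, LeadPlacement

__all__ = [
    "Beat",
    "Limb",
    "RPrimeGeometry",
    "PatientFeatures",
    "CRITERIA",
    "detect_beats",
    "locate_rprime",
    "descent_depth",
    "is_measurable",
    "fit_limbs",
    "compute_geometry",
    "extract_channel",
    "extract_record",
    "aggregate_patient",
]

#: candidate gate: a local maximum this far (mV) above baseline is considered
#: a potential r'; the measurability gate (0.1 mV) is applied afterwards.
CANDIDATE_GATE_MV = 0.05

MEASURABLE_MV = 0.1  # strict ">" per the published rule: >0.1 mV = 1 mm

CRITERIA = ("beta_deg", "alpha_deg", "dbt5_ms", "dbtiso_ms", "ratio")


@dataclass
class Beat:
    """One detected beat inside a channel (all fields are sample indices)."""

    start: int
    stop: int
    r_peak: int
    qrs_onset: int
    qrs_offset: int
    baseline_mv: float

    def __post_init__(self) -> None:
        if not (self.start <= self.qrs_onset < self.r_peak < self.qrs_offset <= self.stop):
            raise ValueError("beat indices must satisfy start <= onset < R < offset <= stop")


@dataclass(frozen=True)
class Limb:
    """A fitted limb line in paper-mm, parameterised as x = x0 + slope_xy * y.

    ``slope_xy = dx/dy`` is the tangent of the angle from vertical; a
    perfectly vertical limb has slope 0.
    """

    angle_deg: float
    x0_mm: float
    slope_xy: float


@dataclass
class RPrimeGeometry:
    """Triangle geometry of one r'-wave.

    The apex is the intersection of the fitted limb lines (it may sit above
    the sampled maximum); coordinates are paper-mm with y measured from the
    isoelectric line.
    """

    apex_x_mm: float
    apex_y_mm: float
    theta_up_deg: float
    alpha_deg: float
    h_mm: float
    measurable: bool
    beta_deg: float = field(init=False)
    dbt5_ms: float = field(init=False)
    dbtiso_ms: float = field(init=False)
    ratio: float = field(init=False)
    ms_per_mm: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_deg < 90.0 and 0.0 <= self.theta_up_deg < 90.0):
            raise ValueError("limb angles must lie in [0, 90) degrees")
        tan_sum = math.tan(math.radians(self.theta_up_deg)) + math.tan(
            math.radians(self.alpha_deg)
        )
        self.beta_deg = self.theta_up_deg + self.alpha_deg
        self.dbt5_ms = self.ms_per_mm * 5.0 * tan_sum
        self.dbtiso_ms = self.ms_per_mm * self.h_mm * tan_sum
        self.ratio = tan_sum


@dataclass
class PatientFeatures:
    """Per-patient "major" criterion values.

    Per lead placement, criterion values are averaged over its measurable
    beats; the patient-level value of each criterion is the maximum of those
    per-placement means ("major value"), taken independently per criterion.
    """

    beta_deg: float | None = None
    alpha_deg: float | None = None
    dbt5_ms: float | None = None
    dbtiso_ms: float | None = None
    ratio: float | None = None
    measurable_by_ic: dict[ICLevel, bool] = field(
        default_factory=lambda: {lv: False for lv in ICLevel}
    )
    any_measurable: bool = False
    patient_id: str = ""


# ---------------------------------------------------------------------------
# beat detection


def detect_beats(
    record: ECGRecord,
    channel: int,
    pre_ms: float = 80.0,
    post_ms: float = 120.0,
    refractory_ms: float = 200.0,
) -> list[Beat]:
    """Detect beats on one channel with a smoothed-derivative threshold.

    The squared first derivative is smoothed over 30 ms; peaks above a
    quarter of its maximum, separated by the refractory period, mark QRS
    complexes. The R peak is refined to the raw-signal maximum within
    ±40 ms; the QRS window is R peak − ``pre_ms`` to R peak + ``post_ms``.
    The isoelectric baseline is the median of the 40 ms window ending 40 ms
    before QRS onset. Beats too close to the record edge are dropped.

    A flat or empty signal yields an empty list, not an error.
    """
    _, sig = record.channels[channel]
    fs = record.sampling_rate
    if record.duration < 2.0:
        raise ValueError("need at least 2 s of signal for beat detection")
    if np.ptp(sig) < CANDIDATE_GATE_MV:
        return []

    deriv = np.gradient(sig) * fs
    energy = uniform_filter1d(deriv**2, size=max(3, int(round(0.030 * fs))))
    distance = max(1, int(round(refractory_ms / 1000.0 * fs)))
    peaks, _ = find_peaks(energy, height=0.25 * float(np.max(energy)), distance=distance)

    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    w40 = int(round(0.040 * fs))

    beats: list[Beat] = []
    last_r = -distance
    for p in peaks:
        lo, hi = max(0, p - w40), min(len(sig), p + w40 + 1)
        r = lo + int(np.argmax(sig[lo:hi]))
        if r - last_r < distance:
            continue
        onset, offset = r - pre, r + post
        if onset - 2 * w40 < 0 or offset >= len(sig):
            continue
        baseline = float(np.median(sig[onset - 2 * w40 : onset - w40]))
        beats.append(
            Beat(
                start=onset - 2 * w40,
                stop=offset,
                r_peak=r,
                qrs_onset=onset,
                qrs_offset=offset,
                baseline_mv=baseline,
            )
        )
        last_r = r
    return beats


# ---------------------------------------------------------------------------
# r' location and measurability


def locate_rprime(sig: np.ndarray, beat: Beat) -> int | None:
    """Locate the r' apex: the *last* local maximum strictly inside
    ``(r_peak, qrs_offset)`` rising more than 0.05 mV above baseline.

    Returns the sample index, or ``None`` when no terminal positive
    deflection exists (monophasic R, or J-point elevation without a
    discrete peak).
    """
    # extrema are detected on a 5-sample moving average so noise wiggles on
    # the limbs or ST segment cannot masquerade as the r'; the index is then
    # refined on the raw samples
    seg = _smooth(sig)[beat.r_peak : beat.qrs_offset + 1]
    peaks, _ = find_peaks(seg, prominence=CANDIDATE_GATE_MV)
    candidates = [
        _refine(sig, beat.r_peak + int(p), "max")
        for p in peaks
    ]
    candidates = [p for p in candidates if sig[p] - beat.baseline_mv > CANDIDATE_GATE_MV]
    return candidates[-1] if candidates else None


def _smooth(sig: np.ndarray, size: int = 5) -> np.ndarray:
    return uniform_filter1d(sig, size=size)


def _refine(sig: np.ndarray, idx: int, kind: str, halfwidth: int = 2) -> int:
    lo, hi = max(0, idx - halfwidth), min(len(sig), idx + halfwidth + 1)
    off = np.argmax(sig[lo:hi]) if kind == "max" else np.argmin(sig[lo:hi])
    return lo + int(off)


def descent_depth(sig: np.ndarray, beat: Beat, apex: int) -> float:
    """Voltage drop (mV) from the apex to the first trough of the downslope.

    The trough is the first local minimum after the apex within the QRS
    window, or the window minimum if the downslope never turns back up.
    """
    seg = sig[apex : beat.qrs_offset + 1]
    if len(seg) < 2:
        return 0.0
    smooth_seg = _smooth(sig)[apex : beat.qrs_offset + 1]
    troughs, _ = find_peaks(-smooth_seg, prominence=CANDIDATE_GATE_MV)
    if len(troughs):
        low = float(sig[_refine(sig, apex + int(troughs[0]), "min")])
    else:
        low = float(np.min(seg))
    return float(sig[apex]) - low


def is_measurable(height_mv: float, descent_mv: float) -> bool:
    """Published measurability rule: apex >0.1 mV above baseline *and*
    descending limb >0.1 mV, both strict."""
    if height_mv < 0 or descent_mv < 0:
        raise ValueError("height and descent must be non-negative")
    return height_mv > MEASURABLE_MV and descent_mv > MEASURABLE_MV


# ---------------------------------------------------------------------------
# limb fitting and triangle geometry


def _band_fit(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    lo_idx: int,
    hi_idx: int,
    extreme_idx: int,
    band: tuple[float, float],
) -> Limb | None:
    """Least-squares line x(y) over samples whose y lies in the vertical band
    between the limb's trough and apex. ``extreme_idx`` is the apex sample.

    The band (default 20–80 %) excludes apex rounding and foot curvature.
    Fewer than 3 in-band samples normally voids the fit, except for the
    (near-)vertical limb degenerate case, which is returned as 0° from
    vertical with a warning.
    """
    idx = np.arange(lo_idx, hi_idx + 1)
    y = y_mm[idx]
    y_top = y_mm[extreme_idx]
    y_bot = float(np.min(y))
    span = y_top - y_bot
    if span <= 0:
        return None
    lo_y = y_bot + band[0] * span
    hi_y = y_bot + band[1] * span
    in_band = idx[(y >= lo_y) & (y <= hi_y)]
    if len(in_band) < 3:
        if hi_idx - lo_idx <= 2:
            warnings.warn(
                "limb spans <=2 samples; treating as vertical (0 deg)", stacklevel=3
            )
            return Limb(angle_deg=0.0, x0_mm=float(x_mm[extreme_idx]), slope_xy=0.0)
        return None
    yy = y_mm[in_band]
    xx = x_mm[in_band]
    if np.ptp(yy) <= 0:
        return None
    slope, intercept = np.polyfit(yy, xx, 1)
    angle = math.degrees(math.atan(abs(slope)))
    return Limb(angle_deg=min(angle, 90.0 - 1e-9), x0_mm=float(intercept), slope_xy=float(slope))


def fit_limbs(
    sig: np.ndarray,
    beat: Beat,
    apex: int,
    calibration: Calibration,
    sampling_rate: float,
    band: tuple[float, float] = (0.2, 0.8),
) -> tuple[Limb, Limb] | None:
    """Fit the upslope and downslope lines of the r' in paper-mm.

    The upslope is fitted between the preceding local minimum (the S/s
    trough) and the apex, the downslope between the apex and the following
    minimum, each over the 20–80 % vertical band. Returns ``None`` when a
    limb cannot be fitted (geometry then counts as unmeasurable).
    """
    t_ms = np.arange(len(sig)) / sampling_rate * 1000.0
    x_mm = t_ms / calibration.ms_per_mm
    y_mm = sig / calibration.mv_per_mm

    smooth = _smooth(sig)
    pre = sig[beat.r_peak : apex + 1]
    if len(pre) < 2:
        return None
    # troughs found on the smoothed trace (noise wiggles must not masquerade
    # as the S trough), indices refined on the raw samples
    pre_troughs, _ = find_peaks(-smooth[beat.r_peak : apex + 1], prominence=CANDIDATE_GATE_MV)
    if len(pre_troughs):
        up_lo = _refine(sig, beat.r_peak + int(pre_troughs[-1]), "min")
    else:
        up_lo = beat.r_peak + int(np.argmin(pre))
    up_lo = min(up_lo, apex - 1)

    post = sig[apex : beat.qrs_offset + 1]
    if len(post) < 2:
        return None
    post_troughs, _ = find_peaks(-smooth[apex : beat.qrs_offset + 1], prominence=CANDIDATE_GATE_MV)
    if len(post_troughs):
        down_hi = _refine(sig, apex + int(post_troughs[0]), "min")
    else:
        # no discrete trough: the limb ends where the smoothed trace returns
        # to (near) baseline, not at the noisiest sample of the flat segment
        height = float(sig[apex]) - beat.baseline_mv
        thresh = beat.baseline_mv + max(0.1 * height, 0.02)
        below = np.nonzero(post <= thresh)[0]
        down_hi = apex + (int(below[0]) if len(below) else int(np.argmin(post)))
    down_hi = max(down_hi, apex + 1)

    up = _band_fit(x_mm, y_mm, up_lo, apex, apex, band)
    down = _band_fit(x_mm, y_mm, apex, down_hi, apex, band)
    if up is None or down is None:
        return None
    return up, down


def compute_geometry(
    upslope: Limb,
    downslope: Limb,
    baseline_mv: float,
    calibration: Calibration,
    measurable: bool = True,
) -> RPrimeGeometry:
    """Intersect the fitted limbs and derive the full triangle geometry.

    The apex is the intersection of the two lines; ``h`` is its height above
    the isoelectric line in mm. Raises ``ValueError`` for parallel limbs; an
    apex at or below the isoelectric line yields an unmeasurable geometry
    with ``h = 0``.
    """
    b_up, b_dn = upslope.slope_xy, downslope.slope_xy
    if abs(b_up - b_dn) < 1e-12:
        raise ValueError("parallel limbs: no triangle apex")
    y_star = (downslope.x0_mm - upslope.x0_mm) / (b_up - b_dn)
    x_star = upslope.x0_mm + b_up * y_star

    theta = math.degrees(math.atan(abs(b_up)))
    alpha = math.degrees(math.atan(abs(b_dn)))
    baseline_mm = baseline_mv / calibration.mv_per_mm
    h = y_star - baseline_mm
    if h <= 0:
        measurable = False
        h = 0.0
    return RPrimeGeometry(
        apex_x_mm=x_star,
        apex_y_mm=y_star - baseline_mm,
        theta_up_deg=theta,
        alpha_deg=alpha,
        h_mm=h,
        measurable=measurable,
        ms_per_mm=calibration.ms_per_mm,
    )


def extract_channel(
    record: ECGRecord,
    channel: int,
    band: tuple[float, float] = (0.2, 0.8),
    pre_ms: float = 80.0,
    post_ms: float = 120.0,
) -> list[RPrimeGeometry]:
    """Full per-channel pipeline: detect beats, locate the r', gate
    measurability, fit limbs and compute the triangle geometry.

    Beats without an r' candidate or with a failed limb fit are skipped;
    candidates failing the 0.1 mV gates are emitted with
    ``measurable=False`` so measurability statistics stay available.
    """
    _, sig = record.channels[channel]
    geoms: list[RPrimeGeometry] = []
    for beat in detect_beats(record, channel, pre_ms=pre_ms, post_ms=post_ms):
        apex = locate_rprime(sig, beat)
        if apex is None:
            continue
        height = float(sig[apex]) - beat.baseline_mv
        descent = descent_depth(sig, beat, apex)
        measurable = is_measurable(height, max(descent, 0.0))
        limbs = fit_limbs(
            sig, beat, apex, record.calibration, record.sampling_rate, band=band
        )
        if limbs is None:
            continue
        try:
            geom = compute_geometry(
                limbs[0], limbs[1], beat.baseline_mv, record.calibration, measurable
            )
        except ValueError:
            continue
        geoms.append(geom)
    return geoms


def extract_record(
    record: ECGRecord, band: tuple[float, float] = (0.2, 0.8), post_ms: float = 120.0
) -> dict[LeadPlacement, list[RPrimeGeometry]]:
    """Run :func:`extract_channel` on every channel of a record."""
    return {
        placement: extract_channel(record, i, band=band, post_ms=post_ms)
        for i, (placement, _) in enumerate(record.channels)
    }


def aggregate_patient(
    geoms_by_placement: Mapping[LeadPlacement, Sequence[RPrimeGeometry]],
    patient_id: str = "",
) -> PatientFeatures:
    """Aggregate per-beat geometries into per-patient major values.

    Per placement: arithmetic mean of each criterion over its measurable
    beats. Per patient: the maximum ("major value") of the placement means,
    taken independently per criterion. Each intercostal level is flagged
    measurable when any beat in V1 or V2 at that level is measurable.
    """
    placement_means: dict[str, list[float]] = {c: [] for c in CRITERIA}
    measurable_by_ic = {lv: False for lv in ICLevel}
    for placement, geoms in geoms_by_placement.items():
        good = [g for g in geoms if g.measurable]
        if not good:
            continue
        measurable_by_ic[placement.ic_level] = True
        for c in CRITERIA:
            placement_means[c].append(float(np.mean([getattr(g, c) for g in good])))
    any_measurable = any(measurable_by_ic.values())
    features = PatientFeatures(
        measurable_by_ic=measurable_by_ic,
        any_measurable=any_measurable,
        patient_id=patient_id,
    )
    if any_measurable:
        for c in CRITERIA:
            setattr(features, c, max(placement_means[c]))
    return features


def features_to_frame(
    patients: Sequence[PatientFeatures],
    labels: Sequence[int | float | None] | None = None,
) -> "pd.DataFrame":
    """Assemble :class:`PatientFeatures` into the standard feature table
    (see :data:`rprime.io.FEATURE_COLUMNS`); NaN encodes missing values."""
    import pandas as pd

    rows = []
    for i, pf in enumerate(patients):
        rows.append(
            {
                "patient_id": pf.patient_id or f"P{i:04d}",
                "beta_deg": np.nan if pf.beta_deg is None else pf.beta_deg,
                "alpha_deg": np.nan if pf.alpha_deg is None else pf.alpha_deg,
                "dbt5_ms": np.nan if pf.dbt5_ms is None else pf.dbt5_ms,
                "dbtiso_ms": np.nan if pf.dbtiso_ms is None else pf.dbtiso_ms,
                "ratio": np.nan if pf.ratio is None else pf.ratio,
                "measurable_ii": pf.measurable_by_ic[ICLevel.II],
                "measurable_iii": pf.measurable_by_ic[ICLevel.III],
                "measurable_iv": pf.measurable_by_ic[ICLevel.IV],
                "scbpt_label": np.nan if labels is None or labels[i] is None else labels[i],
            }
        )
    return pd.DataFrame(rows)
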