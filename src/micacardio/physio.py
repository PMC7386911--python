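"""Physiological signal processing and group statistics.

Covers the autonomic arm of the analysis: pulse band-pass filtering and
semi-automated beat detection, blood-pressure dropout/outlier cleaning,
beat-to-beat series construction, LF/HF band definition from group spectra,
band-limited fractional power, paired t statistics with Cohen's d, and
head-motion quality control from realignment matrices.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .types import (
    BeatSeries,
    DesignBlocks,
    FrequencyBand,
    PairedTestResult,
    PhysioTrace,
    RealignmentTrack,
)

logger = logging.getLogger("micacardio")

__all__ = [
    "bandpass",
    "detect_beats",
    "clean_bp",
    "beat_to_beat",
    "band_fraction_series",
    "welch_psd",
    "band_fraction_psd",
    "define_bands",
    "paired_test",
    "cohens_d_from_summary",
    "motion_rms",
    "compare_motion",
    "QualityError",
    "InsufficientDataError",
    "DegenerateDataError",
]

PULSE_BAND = (0.64, 2.5)  # Hz, scanner-artefact removal band for PPG
LF_WINDOW = (0.04, 0.15)  # Hz, physiologic search window for the Mayer peak
HF_WINDOW = (0.15, 0.5)  # Hz, search window for the respiratory peak
WELCH_SEG_S = 120.0  # Welch segment length cap in seconds
RESAMPLE_FS = 4.0  # Hz, beat-series interpolation rate before PSD
HP_FLOOR = 0.005  # Hz, high-pass floor matching the imaging preprocessing


class QualityError(ValueError):
    """Too much of a trace is unusable."""


class InsufficientDataError(ValueError):
    """Not enough samples/beats/volumes for the requested statistic."""


class DegenerateDataError(ValueError):
    """Zero-variance input where a test statistic is undefined."""


# ---------------------------------------------------------------------------
# Filtering and beat detection


def bandpass(trace: PhysioTrace, f_lo: float, f_hi: float, order: int = 4) -> PhysioTrace:
    """Zero-phase Butterworth band-pass; validity flags are preserved."""
    nyq = trace.fs / 2
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz must lie inside (0, {nyq}) Hz")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=trace.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return PhysioTrace(samples=filtered, fs=trace.fs, kind=trace.kind, valid=trace.valid.copy())


def detect_beats(
    trace: PhysioTrace,
    min_rr: float = 0.4,
    prominence_frac: float = 0.4,
    window_s: float = 2.0,
) -> BeatSeries:
    """Detect pulse peaks on the band-passed plethysmogram.

    Local maxima must exceed ``prominence_frac`` times the rolling signal
    amplitude (maximum of |x| over a ``window_s`` window) and be separated by
    at least the refractory interval ``min_rr``; of two competing peaks the
    larger is kept. The returned :class:`BeatSeries` exposes ``insert_beat`` /
    ``delete_beat`` as the manual-review hook of the semi-automated procedure.
    """
    from scipy.ndimage import maximum_filter1d

    x = trace.samples
    win = max(3, int(round(window_s * trace.fs)))
    env = maximum_filter1d(np.abs(x), size=win, mode="nearest")
    height = prominence_frac * env
    idx, _ = sps.find_peaks(x, height=height, distance=max(1, int(round(min_rr * trace.fs))))
    idx = idx[x[idx] > 0]
    if len(idx) == 0:
        warnings.warn("no beats detected", stacklevel=2)
        return BeatSeries(times=np.array([]), values=np.array([]), kind="beat")
    return BeatSeries(times=idx / trace.fs, values=x[idx], kind="beat")


# ---------------------------------------------------------------------------
# Blood-pressure cleaning


def clean_bp(trace: PhysioTrace, percentiles: tuple[float, float] = (1.0, 99.0)) -> PhysioTrace:
    """Remove dropouts, then percentile-filter outliers, then interpolate.

    Samples flagged invalid (dropouts) and valid samples falling outside the
    [1st, 99th] percentile of the valid samples are replaced by linear
    interpolation between the nearest surviving neighbours; trace ends are
    extended with the nearest surviving value. The output keeps every
    replaced sample flagged invalid (it is not a measurement) and records the
    cleaning in ``meta``, so re-application is an exact no-op: percentile
    thresholds re-estimated from an already-trimmed signal would otherwise
    creep inward on every pass.
    """
    if trace.kind != "bp":
        raise ValueError("clean_bp expects a blood-pressure trace")
    if trace.meta.get("cleaned"):
        return trace
    x = trace.samples.astype(float)
    n = len(x)
    valid = trace.valid.copy()
    if valid.sum() == 0:
        raise QualityError("all samples are invalid")
    p_lo, p_hi = np.percentile(x[valid], percentiles)
    outlier = valid & ((x < p_lo) | (x > p_hi))
    excluded = ~valid | outlier
    if excluded.sum() > 0.5 * n:
        raise QualityError(f"{excluded.sum()}/{n} samples excluded (> 50 %)")
    surviving = ~excluded
    idx = np.arange(n)
    filled = x.copy()
    filled[excluded] = np.interp(idx[excluded], idx[surviving], x[surviving])
    return PhysioTrace(
        samples=filled,
        fs=trace.fs,
        kind="bp",
        valid=surviving,
        meta={"cleaned": True, "p_lo": float(p_lo), "p_hi": float(p_hi)},
    )


# ---------------------------------------------------------------------------
# Beat-to-beat series


def beat_to_beat(
    beats: BeatSeries, bp: PhysioTrace | None = None
) -> tuple[BeatSeries, BeatSeries | None]:
    """Interbeat intervals and, if blood pressure is given, per-beat systolic values.

    IBI value ``i`` is ``times[i+1] - times[i]`` and is timestamped at beat
    ``i``. Systolic pressure per beat is the maximum of the (cleaned) blood
    pressure within that beat interval.
    """
    if len(beats) < 3:
        raise InsufficientDataError("need at least 3 beats")
    ibi = BeatSeries(times=beats.times[:-1], values=np.diff(beats.times), kind="ibi")
    sbp = None
    if bp is not None:
        t = bp.times
        vals = []
        for t0, t1 in zip(beats.times[:-1], beats.times[1:]):
            sel = (t >= t0) & (t < t1)
            vals.append(bp.samples[sel].max() if sel.any() else np.nan)
        vals = np.asarray(vals)
        keep = np.isfinite(vals)
        sbp = BeatSeries(times=beats.times[:-1][keep], values=vals[keep], kind="sbp")
    return ibi, sbp


# ---------------------------------------------------------------------------
# Spectral utilities


def welch_psd(x: np.ndarray, fs: float, seg_s: float = WELCH_SEG_S) -> tuple[np.ndarray, np.ndarray]:
    """Welch averaged periodogram: Hann taper, 50 % overlap, detrended input."""
    nperseg = int(min(len(x), max(8, round(seg_s * fs))))
    f, p = sps.welch(
        sps.detrend(np.asarray(x, dtype=float)),
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    return f, p


def band_fraction_psd(
    freqs: np.ndarray, psd: np.ndarray, band: FrequencyBand, hp_floor: float = HP_FLOOR
) -> float:
    """Band power over total power above the high-pass floor.

    Bin membership is half-open ``lo <= f < hi`` so that fractions over a
    disjoint band partition of the spectrum sum to exactly one.
    """
    above = freqs >= hp_floor
    total = psd[above].sum()
    if total <= 0:
        raise DegenerateDataError("zero total power above the high-pass floor")
    in_band = above & (freqs >= band.lo) & (freqs < band.hi)
    return float(psd[in_band].sum() / total)


def band_fraction_series(
    series: BeatSeries,
    band: FrequencyBand,
    resample_fs: float = RESAMPLE_FS,
    hp_floor: float = HP_FLOOR,
) -> float:
    """Fractional band power of a beat-to-beat series.

    The irregular series is linearly interpolated to a uniform grid at
    ``resample_fs`` (4 Hz default, standard HRV practice), detrended, and its
    Welch PSD integrated over the band relative to all power above the
    high-pass floor.
    """
    if len(series) < 4:
        raise InsufficientDataError("need at least 4 beats")
    span = series.times[-1] - series.times[0]
    if span < 5.0 / band.centre:
        raise InsufficientDataError(
            f"series spans {span:.1f} s; need >= {5.0 / band.centre:.1f} s for {band.centre} Hz"
        )
    t_uni = np.arange(series.times[0], series.times[-1], 1.0 / resample_fs)
    x = np.interp(t_uni, series.times, series.values)
    f, p = welch_psd(x, resample_fs)
    return band_fraction_psd(f, p, band, hp_floor)


def define_bands(
    per_subject_spectra: list[tuple[np.ndarray, np.ndarray]],
    which: str,
) -> FrequencyBand:
    """Define the LF or HF band from per-subject autonomic spectral peaks.

    For each subject the highest interior spectral peak inside the physiologic
    search window (LF: 0.04-0.15 Hz from blood-pressure variability; HF:
    0.15-0.5 Hz from respiration) is located; the band is the mean of the peak
    frequencies +/- their standard deviation. Subjects without a peak in the
    window are skipped with a warning.
    """
    if which not in ("LF", "HF"):
        raise ValueError("which must be 'LF' or 'HF'")
    if len(per_subject_spectra) < 2:
        raise InsufficientDataError("need spectra from at least 2 subjects")
    lo, hi = LF_WINDOW if which == "LF" else HF_WINDOW
    peaks = []
    for s_i, (f, p) in enumerate(per_subject_spectra):
        f = np.asarray(f, dtype=float)
        p = np.asarray(p, dtype=float)
        idx, _ = sps.find_peaks(p)
        idx = idx[(f[idx] >= lo) & (f[idx] <= hi)]
        if len(idx) == 0:
            warnings.warn(f"subject {s_i}: no spectral peak in the {which} window; skipped",
                          stacklevel=2)
            continue
        peaks.append(f[idx[np.argmax(p[idx])]])
    if not peaks:
        raise ValueError(f"no subject shows a {which} peak in ({lo}, {hi}) Hz")
    peaks = np.asarray(peaks)
    half_width = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    return FrequencyBand(centre=float(np.mean(peaks)), half_width=half_width)


def band_fraction_by_condition(
    series: BeatSeries,
    design: DesignBlocks,
    band: FrequencyBand,
    resample_fs: float = RESAMPLE_FS,
    hp_floor: float = HP_FLOOR,
) -> dict[str, float]:
    """Mean fractional band power per design condition.

    The fraction is computed separately within every design block containing
    enough beats and averaged per condition label.
    """
    per_label: dict[str, list[float]] = {}
    for label, start, end in design.blocks:
        sel = (series.times >= start) & (series.times < end)
        if sel.sum() < 4:
            continue
        sub = BeatSeries(series.times[sel], series.values[sel], series.kind)
        try:
            frac = band_fraction_series(sub, band, resample_fs, hp_floor)
        except InsufficientDataError:
            continue
        per_label.setdefault(label, []).append(frac)
    return {label: float(np.mean(v)) for label, v in per_label.items()}


# ---------------------------------------------------------------------------
# Paired statistics


def cohens_d_from_summary(
    mean_rest: float, mean_lbnp: float, sd_rest: float, sd_lbnp: float
) -> float:
    """Cohen's d as mean condition difference over the pooled condition SD."""
    pooled = np.sqrt((sd_rest**2 + sd_lbnp**2) / 2.0)
    if pooled == 0:
        return 0.0
    return float((mean_lbnp - mean_rest) / pooled)


def paired_test(rest, lbnp) -> PairedTestResult:
    """Classical paired t-test of LBNP versus Rest with Cohen's d.

    The test runs on the paired differences (LBNP - Rest); d is the mean
    difference divided by the pooled SD of the two condition samples. If all
    differences are exactly zero the result is the null record (t=0, p=1,
    d=0); constant non-zero differences are degenerate for the t statistic
    and raise.
    """
    rest = np.asarray(rest, dtype=float)
    lbnp = np.asarray(lbnp, dtype=float)
    if rest.shape != lbnp.shape or rest.ndim != 1:
        raise ValueError("rest and lbnp must be equal-length 1D arrays")
    n = len(rest)
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if not (np.isfinite(rest).all() and np.isfinite(lbnp).all()):
        raise ValueError("missing pairs must be dropped upstream")
    diffs = lbnp - rest
    sd_d = np.std(diffs, ddof=1)
    mean_d = diffs.mean()
    summaries = dict(
        n=n,
        df=n - 1,
        mean_rest=float(rest.mean()),
        mean_lbnp=float(lbnp.mean()),
        sd_rest=float(np.std(rest, ddof=1)),
        sd_lbnp=float(np.std(lbnp, ddof=1)),
    )
    if sd_d == 0:
        if mean_d == 0:
            return PairedTestResult(t=0.0, p=1.0, d=0.0, **summaries)
        raise DegenerateDataError("paired differences have zero variance")
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * spstats.t.sf(abs(t), n - 1)
    d = cohens_d_from_summary(
        summaries["mean_rest"], summaries["mean_lbnp"], summaries["sd_rest"], summaries["sd_lbnp"]
    )
    return PairedTestResult(t=float(t), p=float(p), d=d, **summaries)


# ---------------------------------------------------------------------------
# Head-motion quality control


def _default_reference_coords() -> np.ndarray:
    """Corners of an 80 mm cube centred at the origin (conventional choice)."""
    c = 40.0
    return np.array([[sx * c, sy * c, sz * c] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])


def motion_rms(track: RealignmentTrack, reference_coords: np.ndarray | None = None) -> np.ndarray:
    """Per-volume RMS displacement of reference points between consecutive volumes.

    Element 0 is zero (the first volume has no predecessor); element i is the
    root mean square over the reference coordinates of
    ``|M_i x - M_{i-1} x|``.
    """
    if len(track) < 2:
        raise InsufficientDataError("need at least 2 volumes")
    coords = _default_reference_coords() if reference_coords is None else np.asarray(reference_coords, float)
    homo = np.hstack([coords, np.ones((len(coords), 1))])  # (P, 4)
    world = np.einsum("nij,pj->npi", track.matrices, homo)[..., :3]  # (n, P, 3)
    disp = np.zeros(len(track))
    delta = world[1:] - world[:-1]
    disp[1:] = np.sqrt((delta**2).sum(axis=2).mean(axis=1))
    return disp


def compare_motion(
    series: np.ndarray | list[np.ndarray],
    design: DesignBlocks,
    tr: float,
) -> PairedTestResult:
    """Paired test of block-mean head motion, LBNP versus Rest.

    ``series`` is one displacement series (or a list, one per run) as
    returned by :func:`motion_rms`; displacements are averaged within each
    design block and the i-th LBNP block is paired with the i-th Rest block
    across all runs.
    """
    if isinstance(series, np.ndarray):
        series = [series]
    means: dict[str, list[float]] = {"LBNP": [], "Rest": []}
    for s in series:
        times = np.arange(len(s)) * tr
        for label, start, end in design.blocks:
            sel = (times >= start) & (times < end)
            if sel.any():
                means[label].append(float(s[sel].mean()))
    n_pairs = min(len(means["LBNP"]), len(means["Rest"]))
    if n_pairs < 3:
        raise InsufficientDataError("need at least 3 block pairs")
    return paired_test(means["Rest"][:n_pairs], means["LBNP"][:n_pairs])
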