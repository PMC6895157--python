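"""The 21 per-call vocal parameters.

Everything here works frame-wise on the waveform plus the call's
nonlinear-phenomena annotation: the phenomena percentages come from the
annotation (they are judged off the spectrogram, by eye, in field practice —
an automatic detector is deliberately not on the analysis path), while the
remaining 17 parameters are measured from the signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .params import FEATURE_TABLE_COLUMNS, PARAM_NAMES
from .pitch import PitchContour, extract_pitch
from .synth import CallRecording, NLPAnnotation

log = logging.getLogger(__name__)

TRIM_DB = -40.0                 # silence-trim threshold re peak
FM_PROMINENCE_HZ = 10.0         # minimum excursion to count an FM extremum
AM_PROMINENCE_DB = 1.5
INFLEX_RANGE_FRACTION = 1.0 / 3.0


class IncompleteFeatures(Exception):
    """A sub-extractor could not measure its parameters for this call."""


def validate_feature_vector(v: dict[str, float]) -> None:
    """Check the invariants every complete 21-parameter vector must satisfy."""
    missing = [k for k in PARAM_NAMES if k not in v or not np.isfinite(v[k])]
    if missing:
        raise ValueError(f"missing/non-finite parameters: {missing}")
    if v["duration_s"] <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= v["entropy"] <= 1.0:
        raise ValueError("entropy must lie in [0, 1]")
    if not v["f0_min_hz"] - 1e-9 <= v["f0_mean_hz"] <= v["f0_max_hz"] + 1e-9:
        raise ValueError("need f0_min <= f0_mean <= f0_max")
    for k in ("f0_start_hz", "f0_end_hz"):
        if not v["f0_min_hz"] - 1e-9 <= v[k] <= v["f0_max_hz"] + 1e-9:
            raise ValueError(f"{k} outside [f0_min, f0_max]")
    for k in ("jitter_pct", "shimmer_pct", "chaos_pct", "subharmonics_pct",
              "sidebands_pct"):
        if not 0.0 <= v[k] <= 100.0:
            raise ValueError(f"{k} outside [0, 100]")
    for k in ("fm_rate_per_s", "am_rate_per_s", "freq_jumps", "inflex",
              "f0_var_hz_per_s", "am_var_per_s"):
        if v[k] < 0:
            raise ValueError(f"{k} must be >= 0")


# ---------------------------------------------------------------------------
# contour-based F0 features
# ---------------------------------------------------------------------------

def _alternating_extrema(y: np.ndarray, prominence: float,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Indices and kinds (+1 max / -1 min) of alternating extrema whose
    excursion from the previous kept extremum exceeds ``prominence``."""
    idx: list[int] = [0]
    kind: list[int] = [0]
    direction = 0
    for i in range(1, len(y)):
        step = y[i] - y[idx[-1]]
        if direction == 0:
            if abs(step) >= prominence:
                direction = 1 if step > 0 else -1
                idx[0] = int(np.argmin(y[:i + 1]) if direction > 0
                             else np.argmax(y[:i + 1]))
                kind[0] = -direction
                idx.append(i)
                kind.append(direction)
        elif direction > 0:
            if y[i] >= y[idx[-1]]:
                idx[-1] = i
            elif y[idx[-1]] - y[i] >= prominence:
                direction = -1
                idx.append(i)
                kind.append(-1)
        else:
            if y[i] <= y[idx[-1]]:
                idx[-1] = i
            elif y[i] - y[idx[-1]] >= prominence:
                direction = 1
                idx.append(i)
                kind.append(1)
    if direction == 0:
        return np.array([], int), np.array([], int)
    return np.array(idx), np.array(kind)


def _modulation_cycles(y: np.ndarray, duration_s: float, prominence: float,
                       ) -> tuple[float, float, int]:
    """(rate, mean peak-to-peak extent, #alternations) of a contour."""
    idx, _ = _alternating_extrema(y, prominence)
    if len(idx) < 3:
        return 0.0, 0.0, max(len(idx) - 2, 0)
    excursions = np.abs(np.diff(y[idx]))
    if len(excursions) > 2:
        excursions = excursions[1:-1]   # boundary excursions are partial
    rate = ((len(idx) - 1) / 2.0) / duration_s
    extent = float(excursions.mean())
    return rate, extent, len(idx) - 2


def f0_features(contour: PitchContour, duration_s: float) -> dict[str, float]:
    """F0 statistics, cumulative variation, FM cycles and inflection index.

    Cumulative variation sums |ΔF0| over *consecutive* voiced frames only
    (differences across unvoiced gaps are not bridged) and divides by call
    duration.  The inflection index counts contour direction reversals whose
    excursion exceeds a third of the contour's total range.
    """
    if contour.n_voiced < 2:
        raise IncompleteFeatures("fewer than 2 voiced frames")
    f = contour.f0
    v = contour.voiced
    fv = f[v]
    both = v[:-1] & v[1:]
    f0_var = float(np.abs(f[1:][both] - f[:-1][both]).sum() / duration_s)
    # peak-pick per contiguous voiced stretch so unvoiced gaps (chaos
    # segments, jump silences) cannot fake modulation cycles
    rng = float(fv.max() - fv.min())
    inflex_thr = max(INFLEX_RANGE_FRACTION * rng, 1e-9)
    n_half = 0.0
    inflex = 0
    extents: list[float] = []
    vt = contour.voiced_times
    gaps = np.flatnonzero(np.diff(vt) > 0.025)
    bounds = np.concatenate(([0], gaps + 1, [len(fv)]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < 3:
            continue
        smooth = _moving_average(fv[b0:b1], 3)
        idx, _ = _alternating_extrema(smooth, FM_PROMINENCE_HZ)
        if len(idx) >= 3:
            n_half += (len(idx) - 1) / 2.0
            exc = np.abs(np.diff(smooth[idx]))
            # boundary excursions are partial cycles; keep interior ones
            extents.extend(exc[1:-1] if len(exc) > 2 else exc)
        idx2, _ = _alternating_extrema(smooth, inflex_thr)
        inflex += max(len(idx2) - 2, 0)
    fm_rate = n_half / duration_s
    fm_extent = float(np.mean(extents)) if extents else 0.0
    return {
        "f0_mean_hz": float(fv.mean()),
        "f0_min_hz": float(fv.min()),
        "f0_max_hz": float(fv.max()),
        "f0_start_hz": float(fv[0]),
        "f0_end_hz": float(fv[-1]),
        "f0_var_hz_per_s": f0_var,
        "fm_rate_per_s": fm_rate,
        "fm_extent_hz": fm_extent,
        "inflex": inflex,
    }


def _moving_average(y: np.ndarray, k: int) -> np.ndarray:
    if len(y) < k:
        return y.copy()
    pad = k // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, np.ones(k) / k, mode="valid")[:len(y)]


# ---------------------------------------------------------------------------
# intensity features
# ---------------------------------------------------------------------------

def intensity_contour(samples: np.ndarray, sample_rate: int,
                      step_s: float = 0.010, win_s: float = 0.030,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise RMS intensity in dB (arbitrary reference)."""
    x = np.asarray(samples, float)
    win = max(int(win_s * sample_rate), 2)
    hop = max(int(step_s * sample_rate), 1)
    if len(x) < win:
        raise ValueError("signal shorter than one intensity frame")
    starts = np.arange(0, len(x) - win + 1, hop)
    rms = np.array([np.sqrt(np.mean(x[s:s + win] ** 2)) for s in starts])
    if rms.max() <= 0:
        raise ValueError("all-zero signal has no intensity contour")
    db = 20.0 * np.log10(np.maximum(rms, rms.max() * 1e-8))
    times = (starts + win / 2) / sample_rate
    return times, db


def amplitude_features(samples: np.ndarray, sample_rate: int,
                       duration_s: float) -> dict[str, float]:
    """Cumulative intensity variation plus AM cycle rate and extent (dB).

    Frames more than 35 dB below the loudest frame are excluded so that
    onset/offset ramps do not masquerade as amplitude modulation.  All three
    measures are differences of dB values, hence invariant to overall gain.
    """
    _, db = intensity_contour(samples, sample_rate)
    keep = db > db.max() - 35.0
    db = db[keep]
    if len(db) < 2:
        raise IncompleteFeatures("intensity contour too short")
    am_var = float(np.abs(np.diff(db)).sum() / duration_s)
    am_rate, am_extent, _ = _modulation_cycles(db, duration_s,
                                               AM_PROMINENCE_DB)
    return {"am_var_per_s": am_var, "am_rate_per_s": am_rate,
            "am_extent_db": am_extent}


# ---------------------------------------------------------------------------
# periodicity features
# ---------------------------------------------------------------------------

def jitter_percent(periods: np.ndarray) -> float:
    """Mean absolute cycle-to-cycle period difference / mean period, in %."""
    p = np.asarray(periods, float)
    if len(p) < 2:
        raise IncompleteFeatures("need >= 2 periods for jitter")
    return float(np.mean(np.abs(np.diff(p))) / np.mean(p) * 100.0)


def shimmer_percent(amplitudes: np.ndarray) -> float:
    """Mean absolute cycle-to-cycle amplitude difference / mean amplitude."""
    a = np.asarray(amplitudes, float)
    if len(a) < 2:
        raise IncompleteFeatures("need >= 2 cycle amplitudes for shimmer")
    return float(np.mean(np.abs(np.diff(a))) / np.mean(a) * 100.0)


def mark_cycles(samples: np.ndarray, sample_rate: int,
                contour: PitchContour) -> np.ndarray:
    """Period-synchronous peak marks (sample indices) in voiced regions."""
    x = np.asarray(samples, float)
    if contour.n_voiced < 2:
        raise IncompleteFeatures("no voiced region to mark cycles in")
    vt = contour.voiced_times
    vf = contour.voiced_f0
    marks: list[int] = []
    # walk each contiguous voiced stretch
    gaps = np.flatnonzero(np.diff(vt) > 0.025)
    bounds = np.concatenate(([0], gaps + 1, [len(vt)]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < 2:
            continue
        t0, t1 = vt[b0], vt[b1 - 1]
        period = 1.0 / np.interp(t0, vt[b0:b1], vf[b0:b1])
        i = int(t0 * sample_rate)
        j = min(int(i + 1.5 * period * sample_rate), len(x))
        if j - i < 3:
            continue
        pos = i + int(np.argmax(x[i:j]))
        marks.append(pos)
        while True:
            t = pos / sample_rate
            if t >= t1:
                break
            period = 1.0 / np.interp(t, vt[b0:b1], vf[b0:b1])
            centre = pos + int(period * sample_rate)
            half = max(int(period * sample_rate / 4), 1)
            lo, hi = centre - half, min(centre + half + 1, len(x))
            if lo >= len(x) or hi - lo < 2:
                break
            nxt = lo + int(np.argmax(x[lo:hi]))
            if nxt <= pos:
                break
            marks.append(nxt)
            pos = nxt
    return np.asarray(marks, int)


def periodicity_features(samples: np.ndarray, sample_rate: int,
                         contour: PitchContour) -> dict[str, float]:
    """Jitter, shimmer and harmonics-to-noise ratio.

    Jitter and shimmer follow the classic local definitions on
    period-synchronous cycle marks; harmonicity averages the frame-wise
    10·log10(r / (1 - r)) where r is the normalized autocorrelation maximum
    at the pitch period.
    """
    marks = mark_cycles(samples, sample_rate, contour)
    if len(marks) < 4:
        raise IncompleteFeatures("fewer than 3 complete cycles")
    periods = np.diff(marks) / sample_rate
    med = np.median(periods)
    ok = (periods > 0.5 * med) & (periods < 2.0 * med)
    periods = periods[ok]
    amps = np.abs(np.asarray(samples, float)[marks[1:][ok]])
    if len(periods) < 3:
        raise IncompleteFeatures("fewer than 3 usable cycles")
    hnr = _harmonicity_db(samples, sample_rate, contour)
    return {"jitter_pct": min(jitter_percent(periods), 100.0),
            "shimmer_pct": min(shimmer_percent(amps), 100.0),
            "harmonicity_db": hnr}


def _harmonicity_db(samples: np.ndarray, sample_rate: int,
                    contour: PitchContour) -> float:
    x = np.asarray(samples, float)
    vals = []
    for t, f in zip(contour.voiced_times, contour.voiced_f0):
        win = int(6.0 / f * sample_rate)   # long window: accurate r for clean periodicity
        i0 = int(t * sample_rate) - win // 2
        if i0 < 0 or i0 + win > len(x) or win < 8:
            continue
        seg = x[i0:i0 + win]
        seg = (seg - seg.mean()) * np.hanning(win)
        nfft = 1 << int(np.ceil(np.log2(2 * win)))
        r = np.fft.irfft(np.abs(np.fft.rfft(seg, nfft)) ** 2)[:win]
        if r[0] <= 0:
            continue
        rn = r / r[0]
        rw = np.fft.irfft(np.abs(np.fft.rfft(np.hanning(win), nfft)) ** 2)
        rw = rw[:win] / rw[0]
        lag = int(round(sample_rate / f))
        lo, hi = max(int(0.8 * lag), 2), min(int(1.2 * lag) + 1, win - 1)
        if hi <= lo:
            continue
        seg_r = rn[lo:hi] / np.maximum(rw[lo:hi], 0.1)
        pk = lo + int(np.argmax(seg_r))
        from .pitch import _parabolic
        _, rmax = _parabolic(rn / np.maximum(rw, 0.1), pk)
        rmax = float(np.clip(rmax, 1e-4, 1.0 - 1e-7))
        vals.append(10.0 * np.log10(rmax / (1.0 - rmax)))
    if not vals:
        raise IncompleteFeatures("no frames usable for harmonicity")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# spectral entropy
# ---------------------------------------------------------------------------

def spectral_entropy(samples: np.ndarray, sample_rate: int,
                     frame: int = 1024, smooth_bins: int = 9) -> float:
    """Mean frame-wise Wiener entropy (spectral flatness), in [0, 1].

    Each frame's power spectrum is lightly smoothed across frequency before
    taking geometric-mean / arithmetic-mean, so that the statistic approaches
    1 for broadband noise and stays near 0 for a pure tone.
    """
    x = np.asarray(samples, float)
    if len(x) < frame:
        frame = max(1 << int(np.log2(max(len(x), 16))), 16)
    if not np.any(x):
        raise ValueError("all-zero signal has no spectrum")
    hop = frame // 2
    w = np.hanning(frame)
    vals, energies = [], []
    for s0 in range(0, len(x) - frame + 1, hop):
        seg = x[s0:s0 + frame] * w
        p = np.abs(np.fft.rfft(seg)) ** 2
        p = np.convolve(p, np.ones(smooth_bins) / smooth_bins, mode="same")
        e = p.sum()
        energies.append(e)
        if e <= 0:
            vals.append(0.0)
            continue
        p = np.maximum(p, p.max() * 1e-10)
        flat = np.exp(np.mean(np.log(p))) / np.mean(p)
        vals.append(float(flat))
    vals = np.asarray(vals)
    energies = np.asarray(energies)
    keep = energies > energies.max() * 1e-4
    return float(np.clip(vals[keep].mean(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# nonlinear phenomena (annotation-driven)
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    iv = sorted(intervals)
    total, cur_s, cur_e = 0.0, iv[0][0], iv[0][1]
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def nlp_features(annotation: NLPAnnotation,
                 duration_s: float) -> dict[str, float]:
    """Percent of call duration per phenomenon + frequency-jump count."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    annotation.validate(duration_s)
    out = {}
    for ph, col in (("chaos", "chaos_pct"), ("subharmonics",
                    "subharmonics_pct"), ("sidebands", "sidebands_pct")):
        out[col] = min(100.0 * _union_length(annotation.intervals(ph))
                       / duration_s, 100.0)
    out["freq_jumps"] = float(len(annotation.intervals("jump")))
    return out


# ---------------------------------------------------------------------------
# whole-call extraction
# ---------------------------------------------------------------------------

def trim_silence(samples: np.ndarray, sample_rate: int,
                 threshold_db: float = TRIM_DB) -> tuple[int, int]:
    """First/last sample index whose amplitude exceeds threshold re peak."""
    x = np.abs(np.asarray(samples, float))
    peak = x.max()
    if peak <= 0:
        raise ValueError("silent signal")
    above = np.flatnonzero(x > peak * 10.0 ** (threshold_db / 20.0))
    return int(above[0]), int(above[-1]) + 1


def extract_features(call: CallRecording, floor: float = 150.0,
                     ceiling: float = 2500.0) -> dict[str, float]:
    """Measure the full 21-parameter vector for one call.

    The call is first trimmed at -40 dB re peak (this defines the measured
    duration); the same pitch floor/ceiling must be used for every call of a
    given individual across both valences.  Raises
    :class:`IncompleteFeatures` when any sub-extractor cannot measure — such
    calls are excluded listwise from statistics.
    """
    i0, i1 = trim_silence(call.samples, call.sample_rate)
    x = call.samples[i0:i1]
    duration = len(x) / call.sample_rate
    contour = extract_pitch(x, call.sample_rate, floor, ceiling)
    v = {"duration_s": duration}
    v.update(f0_features(contour, duration))
    v.update(amplitude_features(x, call.sample_rate, duration))
    v.update(periodicity_features(x, call.sample_rate, contour))
    v["entropy"] = spectral_entropy(x, call.sample_rate)
    ann = _shift_annotation(call.annotation, -i0 / call.sample_rate, duration)
    v.update(nlp_features(ann, duration))
    validate_feature_vector(v)
    return v


def _shift_annotation(ann: NLPAnnotation, offset_s: float,
                      duration_s: float) -> NLPAnnotation:
    events = []
    for ph, s, e in ann.events:
        s2 = float(np.clip(s + offset_s, 0.0, duration_s))
        e2 = float(np.clip(e + offset_s, 0.0, duration_s))
        if e2 > s2 or ph == "jump":
            events.append((ph, s2, e2 if ph != "jump" else s2))
    return NLPAnnotation(call_id=ann.call_id, events=events)


def extract_table(recordings: list[CallRecording],
                  pitch_bounds: dict[str, tuple[float, float]] | None = None,
                  floor: float = 150.0, ceiling: float = 2500.0,
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Extract features for a batch of calls; returns (table, excluded ids).

    ``pitch_bounds`` maps individual_id -> (floor, ceiling); individuals not
    listed fall back to the global defaults.
    """
    rows, excluded = [], []
    for rec in recordings:
        fl, ce = (pitch_bounds or {}).get(rec.individual_id,
                                          (floor, ceiling))
        try:
            v = extract_features(rec, fl, ce)
        except (IncompleteFeatures, ValueError) as err:
            log.warning("excluding %s: %s", rec.call_id, err)
            excluded.append(rec.call_id)
            continue
        row = {"call_id": rec.call_id, "individual_id": rec.individual_id,
               "context": rec.context, "valence": rec.valence}
        row.update(v)
        rows.append(row)
    return (pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS)),
            excluded)
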