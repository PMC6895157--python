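"""Autocorrelation pitch tracking with Viterbi path smoothing.

Frame-wise normalized autocorrelation (with a window-autocorrelation
correction) proposes up to four F0 candidates per frame plus an unvoiced
candidate; a dynamic-programming pass picks the contour that trades candidate
strength against octave-jump and voicing-transition costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRAME_STEP_S = 0.010          # fixed 10 ms hop
VOICING_THRESHOLD = 0.45      # corrected-autocorrelation strength
OCTAVE_COST = 0.35            # per octave of F0 movement between frames
OCTAVE_BIAS = 0.12            # strength penalty per octave below the ceiling
                              # (prefers the higher candidate when
                              # subharmonics make F0/2 look periodic too)
VOICED_UNVOICED_COST = 0.14
MAX_CANDIDATES = 4


@dataclass
class PitchContour:
    """Frame grid of F0 estimates with voicing decisions."""

    times: np.ndarray          # frame centers, seconds
    f0: np.ndarray             # Hz; NaN where unvoiced
    voiced: np.ndarray         # bool per frame
    floor: float
    ceiling: float

    def __post_init__(self) -> None:
        if not self.floor < self.ceiling:
            raise ValueError("pitch floor must be below ceiling")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    @property
    def voiced_times(self) -> np.ndarray:
        return self.times[self.voiced]

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a local maximum at index i by parabolic interpolation."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if abs(denom) < 1e-30:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    return i + d, b - 0.25 * (a - c) * d


def extract_pitch(samples: np.ndarray, sample_rate: int,
                  floor: float = 150.0, ceiling: float = 2500.0,
                  *, voicing_threshold: float = VOICING_THRESHOLD,
                  ) -> PitchContour:
    """Track F0 between ``floor`` and ``ceiling`` Hz.

    A fully unvoiced signal is a valid outcome (no voiced frames), not an
    error; downstream features flag themselves missing instead.
    """
    if floor < 30.0:
        raise ValueError("pitch floor must be >= 30 Hz")
    if ceiling > sample_rate / 4:
        raise ValueError("pitch ceiling must be <= sample_rate / 4")
    if floor >= ceiling:
        raise ValueError("pitch floor must be below ceiling")
    x = np.asarray(samples, float)
    win_s = max(0.040, 3.0 / floor)
    win = int(round(win_s * sample_rate))
    hop = int(round(FRAME_STEP_S * sample_rate))
    if len(x) < win:
        return PitchContour(times=np.array([len(x) / 2 / sample_rate]),
                            f0=np.array([np.nan]),
                            voiced=np.array([False]), floor=floor,
                            ceiling=ceiling)

    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    w = np.hanning(win)
    # window autocorrelation for Boersma-style normalization
    rw = np.fft.irfft(np.abs(np.fft.rfft(w, nfft)) ** 2)
    rw = rw[:win] / rw[0]

    lag_min = max(int(sample_rate / ceiling), 2)
    lag_max = min(int(np.ceil(sample_rate / floor)), win - 2)

    starts = np.arange(0, len(x) - win + 1, hop)
    times = (starts + win / 2) / sample_rate
    cand_f0: list[np.ndarray] = []
    cand_str: list[np.ndarray] = []
    for s0 in starts:
        seg = x[s0:s0 + win]
        seg = (seg - seg.mean()) * w
        spec = np.abs(np.fft.rfft(seg, nfft)) ** 2
        r = np.fft.irfft(spec)[:win]
        if r[0] <= 0:
            cand_f0.append(np.array([]))
            cand_str.append(np.array([]))
            continue
        rn = r / r[0]
        valid = rw > 0.1
        rc = np.where(valid, rn / np.where(valid, rw, 1.0), 0.0)
        seg_r = rc[lag_min:lag_max + 1]
        peaks = np.flatnonzero((seg_r[1:-1] > seg_r[:-2]) &
                               (seg_r[1:-1] >= seg_r[2:])) + 1 + lag_min
        f0s, sts = [], []
        for pk in peaks:
            lag, val = _parabolic(rc, pk)
            f = sample_rate / lag
            if floor <= f <= ceiling:
                f0s.append(f)
                sts.append(min(val, 1.0)
                           - OCTAVE_BIAS * np.log2(ceiling / f))
        if f0s:
            order = np.argsort(sts)[::-1][:MAX_CANDIDATES]
            cand_f0.append(np.array(f0s)[order])
            cand_str.append(np.array(sts)[order])
        else:
            cand_f0.append(np.array([]))
            cand_str.append(np.array([]))

    f0, voiced = _viterbi(cand_f0, cand_str, voicing_threshold)
    return PitchContour(times=times, f0=f0, voiced=voiced,
                        floor=floor, ceiling=ceiling)


def _viterbi(cand_f0: list[np.ndarray], cand_str: list[np.ndarray],
             thr: float) -> tuple[np.ndarray, np.ndarray]:
    """Best path through per-frame candidates (last candidate = unvoiced)."""
    n = len(cand_f0)
    f0 = np.full(n, np.nan)
    voiced = np.zeros(n, bool)
    if n == 0:
        return f0, voiced
    # states per frame: voiced candidates + one unvoiced state
    costs: list[np.ndarray] = []
    back: list[np.ndarray] = []
    prev_states: np.ndarray | None = None
    prev_cost: np.ndarray | None = None
    states_per_frame: list[np.ndarray] = []
    for i in range(n):
        fs_i = np.append(cand_f0[i], np.nan)
        st_i = np.append(cand_str[i], thr)    # unvoiced "strength" = threshold
        local = -st_i                          # reward strong candidates
        if prev_states is None:
            c = local.copy()
            b = np.full(len(fs_i), -1)
        else:
            trans = np.zeros((len(prev_states), len(fs_i)))
            for j, fp in enumerate(prev_states):
                for k, fc in enumerate(fs_i):
                    if np.isnan(fp) and np.isnan(fc):
                        trans[j, k] = 0.0
                    elif np.isnan(fp) or np.isnan(fc):
                        trans[j, k] = VOICED_UNVOICED_COST
                    else:
                        trans[j, k] = OCTAVE_COST * abs(np.log2(fc / fp))
            tot = prev_cost[:, None] + trans
            b = np.argmin(tot, axis=0)
            c = tot[b, np.arange(len(fs_i))] + local
        costs.append(c)
        back.append(b)
        states_per_frame.append(fs_i)
        prev_states, prev_cost = fs_i, c
    k = int(np.argmin(costs[-1]))
    for i in range(n - 1, -1, -1):
        f = states_per_frame[i][k]
        if not np.isnan(f):
            f0[i] = f
            voiced[i] = True
        k = back[i][k] if i > 0 else k
    return f0, voiced
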