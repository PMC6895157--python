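"""Synthetic herds of high-frequency cattle calls.

Two routes are provided:

* :func:`generate_dataset` — additive-harmonic waveform synthesis with
  injected nonlinear phenomena (subharmonics, biphonation sidebands,
  deterministic chaos, frequency jumps), each logged in a ground-truth
  annotation, so the acoustic extractor can be validated end to end.
* :func:`generate_feature_table` — draws the 21-parameter vectors directly
  from per-individual multivariate normals, bypassing audio, so the
  statistical machinery can be exercised in milliseconds.

Both routes share the same individual "signatures": per-individual parameter
means stable across emotional valence, with a configurable valence shift on
top.  This is the structure the discriminant analysis assumes — identity cues
that persist while context moves the calls around a little.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .params import (
    CONTEXT_VALENCE,
    COUNT_PARAMS,
    DEFAULT_POPULATION,
    NEGATIVE_CONTEXTS,
    NONNEG_PARAMS,
    PARAM_NAMES,
    PERCENT_PARAMS,
    POSITIVE_CONTEXTS,
    FEATURE_TABLE_COLUMNS,
    VALENCES,
)

PHENOMENA = ("chaos", "subharmonics", "sidebands")
_PHEN_PARAM = {"chaos": "chaos_pct", "subharmonics": "subharmonics_pct",
               "sidebands": "sidebands_pct"}


class ConfigurationError(ValueError):
    """Raised when a synthesis configuration violates its invariants."""


@dataclass
class IndividualSignature:
    """Per-individual acoustic identity: parameter means and spreads.

    ``phenomena_props`` are expected fractions of call duration occupied by
    each nonlinear phenomenon; ``jump_rate`` is the expected number of
    frequency jumps per call.
    """

    individual_id: str
    param_means: dict[str, float]
    param_sds: dict[str, float]
    phenomena_props: dict[str, float] = field(default_factory=dict)
    jump_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, sd in self.param_sds.items():
            if sd < 0:
                raise ConfigurationError(f"negative SD for {name!r}: {sd}")
        for ph, p in self.phenomena_props.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"phenomena proportion for {ph!r} outside [0,1]: {p}")
        if self.jump_rate < 0:
            raise ConfigurationError("jump_rate must be >= 0")
        m = self.param_means
        if {"f0_min_hz", "f0_mean_hz", "f0_max_hz"} <= m.keys():
            if not (m["f0_min_hz"] <= m["f0_mean_hz"] <= m["f0_max_hz"]):
                raise ConfigurationError(
                    f"{self.individual_id}: F0 means must satisfy "
                    "min <= mean <= max")
        if m.get("duration_s", 1.0) <= 0:
            raise ConfigurationError("duration mean must be > 0")


@dataclass
class ValenceShift:
    """Additive offsets + phenomena multiplier applied for one valence."""

    valence: str
    param_offsets: dict[str, float] = field(default_factory=dict)
    phenomena_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ConfigurationError(f"unknown valence {self.valence!r}")
        if self.phenomena_multiplier < 0:
            raise ConfigurationError("phenomena_multiplier must be >= 0")


def zero_shift(valence: str) -> ValenceShift:
    return ValenceShift(valence=valence)


def default_shifts() -> dict[str, ValenceShift]:
    """Moderate context-dependent shift: negative-context calls are slightly
    longer, higher, noisier and richer in nonlinear phenomena."""
    return {
        "positive": ValenceShift("positive"),
        "negative": ValenceShift(
            "negative",
            param_offsets={
                "duration_s": 0.12, "entropy": 0.025,
                "f0_mean_hz": 24.0, "f0_min_hz": 16.0, "f0_max_hz": 34.0,
                "f0_start_hz": 18.0, "f0_end_hz": 18.0,
                "f0_var_hz_per_s": 40.0, "am_var_per_s": 4.0,
                "harmonicity_db": -1.0,
            },
            phenomena_multiplier=1.55,
        ),
    }


@dataclass
class NLPAnnotation:
    """Ground-truth nonlinear-phenomena events for one call.

    Events are ``(phenomenon, start_s, end_s)`` with half-open intervals in
    seconds from call onset; frequency jumps are instantaneous
    (``start_s == end_s``).
    """

    call_id: str
    events: list[tuple[str, float, float]] = field(default_factory=list)

    def validate(self, duration_s: float) -> None:
        for ph, s, e in self.events:
            if not (0.0 <= s <= e <= duration_s + 1e-9):
                raise ValueError(
                    f"{self.call_id}: event {ph} [{s}, {e}) outside call "
                    f"of duration {duration_s}")
            if ph == "jump" and s != e:
                raise ValueError("jump events are instantaneous")

    def intervals(self, phenomenon: str) -> list[tuple[float, float]]:
        return [(s, e) for ph, s, e in self.events if ph == phenomenon]


@dataclass
class CallRecording:
    call_id: str
    individual_id: str
    context: str
    valence: str
    samples: np.ndarray
    sample_rate: int
    annotation: NLPAnnotation
    ground_truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if CONTEXT_VALENCE.get(self.context) != self.valence:
            raise ConfigurationError(
                f"context {self.context!r} is not a {self.valence} context")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("peak amplitude must be <= 1")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class SynthConfig:
    """Everything needed to deterministically synthesize a herd.

    ``calls_per_individual`` maps individual index -> {valence: n};  when
    ``None``, the per-valence totals are split unevenly across individuals
    (every individual keeps at least one call per valence, mirroring the
    unbalanced sampling typical of opportunistic field recording).
    """

    n_individuals: int = 13
    n_positive: int = 170
    n_negative: int = 163
    calls_per_individual: dict[str, dict[str, int]] | None = None
    population: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION))
    signatures: list[IndividualSignature] | None = None
    shifts: dict[str, ValenceShift] = field(default_factory=default_shifts)
    within_cov: np.ndarray | None = None   # full 21x21 within-individual cov
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("need at least 2 individuals")
        if self.calls_per_individual is None:
            if min(self.n_positive, self.n_negative) < self.n_individuals:
                raise ConfigurationError(
                    "each individual needs >= 1 call per valence")
        else:
            for ind, per in self.calls_per_individual.items():
                for v in VALENCES:
                    if per.get(v, 0) < 1:
                        raise ConfigurationError(
                            f"{ind} has no {v} calls; every individual needs "
                            ">= 1 call in each valence")
        if self.within_cov is not None:
            c = np.asarray(self.within_cov, float)
            if c.shape != (len(PARAM_NAMES), len(PARAM_NAMES)):
                raise ConfigurationError("within_cov must be 21 x 21")
            if np.linalg.eigvalsh((c + c.T) / 2).min() < -1e-8:
                raise ConfigurationError(
                    "within_cov is not positive semidefinite")


def study_preset(seed: int = 0, **overrides) -> SynthConfig:
    """The study-scale preset: 13 individuals, 170 positive + 163 negative."""
    return SynthConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# signatures and bookkeeping
# ---------------------------------------------------------------------------

def _child_rng(seed: int, *tags) -> np.random.Generator:
    """Independent child stream: hash the root seed with a tag tuple."""
    h = hashlib.sha256(("|".join(map(str, (seed,) + tags))).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "little"))


def draw_signatures(config: SynthConfig,
                    rng: np.random.Generator | None = None,
                    ) -> list[IndividualSignature]:
    """Draw per-individual signatures from the population hyperprior.

    Each parameter's per-individual mean is Normal(population mean,
    between-individual SD); the within-individual SD is shared.  Signatures
    violating the F0 ordering (min <= mean <= max) are redrawn, with a
    bounded retry budget.
    """
    if rng is None:
        rng = _child_rng(config.seed, "signatures")
    pop = config.population
    for name, (mu, bsd, wsd) in pop.items():
        if bsd < 0 or wsd < 0:
            raise ConfigurationError(f"negative SD in hyperprior for {name}")
        if not (np.isfinite(mu) and np.isfinite(bsd) and np.isfinite(wsd)):
            raise ConfigurationError(f"non-finite hyperprior for {name}")
    sigs: list[IndividualSignature] = []
    for i in range(config.n_individuals):
        ind = f"heifer{i + 1:02d}"
        for attempt in range(100):
            means = {n: rng.normal(mu, bsd) for n, (mu, bsd, _) in pop.items()}
            for n in NONNEG_PARAMS:
                if n in means:
                    means[n] = max(means[n], 0.0)
            if "entropy" in means:
                means["entropy"] = float(np.clip(means["entropy"], 0.0, 1.0))
            ok = means.get("f0_min_hz", 0) <= means.get("f0_mean_hz", 0) \
                <= means.get("f0_max_hz", np.inf)
            if ok and means.get("duration_s", 1.0) > 0:
                break
        else:
            raise ConfigurationError(
                f"could not draw a valid signature for {ind} in 100 tries")
        sds = {n: wsd for n, (_, _, wsd) in pop.items()}
        props = {ph: float(np.clip(means[_PHEN_PARAM[ph]] / 100.0, 0.0, 1.0))
                 for ph in PHENOMENA}
        sigs.append(IndividualSignature(
            individual_id=ind, param_means=means, param_sds=sds,
            phenomena_props=props, jump_rate=max(means["freq_jumps"], 0.0)))
    return sigs


def _allocate_counts(config: SynthConfig,
                     rng: np.random.Generator) -> dict[str, dict[str, int]]:
    """Uneven per-individual call counts with a >=1 floor in each valence."""
    if config.calls_per_individual is not None:
        return config.calls_per_individual
    ids = [f"heifer{i + 1:02d}" for i in range(config.n_individuals)]
    # shared gamma weights so prolific callers are prolific in both valences
    w = rng.gamma(shape=3.0, scale=1.0, size=config.n_individuals)
    w /= w.sum()
    out: dict[str, dict[str, int]] = {i: {} for i in ids}
    for valence, total in (("positive", config.n_positive),
                           ("negative", config.n_negative)):
        spare = total - config.n_individuals
        raw = w * spare
        base = np.floor(raw).astype(int)
        rem = spare - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        for ind, n in zip(ids, base + 1):
            out[ind][valence] = int(n)
    return out


def _assign_contexts(valence: str, n: int,
                     rng: np.random.Generator) -> list[str]:
    pool = POSITIVE_CONTEXTS if valence == "positive" else NEGATIVE_CONTEXTS
    return list(rng.choice(pool, size=n))


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _place_intervals(total: float, duration: float, n_pieces: int,
                     occupied: list[tuple[float, float]],
                     rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place non-overlapping intervals totalling ``total`` seconds."""
    if total <= 0.005:
        return []
    lengths = np.full(n_pieces, total / n_pieces)
    placed: list[tuple[float, float]] = []
    for ln in lengths:
        for _ in range(60):
            s = rng.uniform(0.0, max(duration - ln, 1e-6))
            cand = (s, s + ln)
            if all(cand[1] <= a or cand[0] >= b
                   for a, b in occupied + placed):
                placed.append(cand)
                break
    return placed


def _smooth_mask(n: int, fs: int, intervals: list[tuple[float, float]],
                 ramp_s: float = 0.005) -> np.ndarray:
    mask = np.zeros(n)
    for s, e in intervals:
        i0, i1 = int(s * fs), min(int(e * fs), n)
        mask[i0:i1] = 1.0
    ramp = max(int(ramp_s * fs), 1)
    kernel = np.hanning(2 * ramp + 1)
    kernel /= kernel.sum()
    return np.convolve(mask, kernel, mode="same")


def synthesize_call(sig: IndividualSignature, shift: ValenceShift,
                    rng: np.random.Generator, *, call_id: str = "call",
                    context: str | None = None,
                    sample_rate: int = 44100) -> CallRecording:
    """Additive-harmonic synthesis of one call with ground-truth annotation.

    The F0 contour rises from a start value to a peak (~35% into the call)
    and falls to an end value, carries sinusoidal frequency modulation and a
    slow jitter drift, and may be broken by instantaneous frequency jumps
    (>= 20% of F0, each followed by a 10 ms silent gap).  At least six
    harmonics with decaying amplitudes sit on the contour; sinusoidal
    amplitude modulation, fade-in/out and a broadband noise floor complete
    the source signal.  Subharmonic, sideband and chaos segments are injected
    per the signature's phenomena proportions and recorded in the annotation.
    """
    if context is None:
        context = (POSITIVE_CONTEXTS if shift.valence == "positive"
                   else NEGATIVE_CONTEXTS)[0]
    g = {n: sig.param_means.get(n, 0.0) + shift.param_offsets.get(n, 0.0)
         for n in PARAM_NAMES}
    sd = sig.param_sds
    fs = sample_rate

    duration = float(np.clip(rng.normal(g["duration_s"], sd["duration_s"]),
                             0.3, 3.0))
    if duration <= 0:
        raise ConfigurationError("call duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    mult = shift.phenomena_multiplier
    props = {}
    for ph in PHENOMENA:
        centre = sig.phenomena_props.get(ph, 0.0) * mult
        spread = sd.get(_PHEN_PARAM[ph], 0.0) / 100.0
        props[ph] = float(np.clip(rng.normal(centre, spread), 0.0, 1.0))
    if sum(props.values()) > 1.0:
        raise ConfigurationError(
            "phenomena proportions sum to more than the call duration")

    # --- F0 contour: start -> peak -> end + FM + slow drift + jumps
    f_start = max(rng.normal(g["f0_start_hz"], sd["f0_start_hz"]), 120.0)
    f_end = max(rng.normal(g["f0_end_hz"], sd["f0_end_hz"]), 120.0)
    f_peak = max(rng.normal(g["f0_max_hz"], sd["f0_max_hz"]),
                 f_start, f_end)
    t_peak = 0.35 * duration
    f0 = np.empty(n)
    up = t <= t_peak
    f0[up] = f_start + (f_peak - f_start) * 0.5 * (
        1 - np.cos(np.pi * t[up] / max(t_peak, 1e-6)))
    f0[~up] = f_end + (f_peak - f_end) * 0.5 * (
        1 + np.cos(np.pi * (t[~up] - t_peak) / max(duration - t_peak, 1e-6)))

    fm_rate = max(rng.normal(g["fm_rate_per_s"], sd["fm_rate_per_s"]), 0.0)
    fm_extent = max(rng.normal(g["fm_extent_hz"], sd["fm_extent_hz"]), 0.0)
    f0 = f0 + 0.5 * fm_extent * np.sin(2 * np.pi * fm_rate * t)

    jitter_target = max(rng.normal(g["jitter_pct"], sd["jitter_pct"]), 0.0)
    # slow multiplicative F0 drift from coarse smoothed noise knots
    knots = rng.standard_normal(max(int(duration * 40), 4))
    knots = np.convolve(knots, np.ones(3) / 3, mode="same")
    knots /= max(np.std(knots), 1e-12)
    drift = np.clip(np.interp(t, np.linspace(0, duration, len(knots)),
                              knots), -3.0, 3.0)
    f0 = f0 * (1.0 + 0.01 * jitter_target * drift)

    events: list[tuple[str, float, float]] = []
    n_jumps = int(rng.poisson(sig.jump_rate * mult))
    jump_times: list[float] = []
    if n_jumps:
        cand = np.sort(rng.uniform(0.12 * duration, 0.88 * duration,
                                   size=n_jumps))
        for jt in cand:
            if not jump_times or jt - jump_times[-1] > 0.08:
                jump_times.append(float(jt))
    jump_factor = np.ones(n)
    fac = 1.0
    for k, jt in enumerate(jump_times):
        fac *= 1.25 if k % 2 == 0 else 0.78
        jump_factor[int(jt * fs):] = fac
        events.append(("jump", jt, jt))
    f0 = f0 * jump_factor
    f0 = np.clip(f0, 80.0, fs / 8)

    # --- nonlinear-phenomena segments (non-overlapping across phenomena)
    occupied: list[tuple[float, float]] = []
    seg: dict[str, list[tuple[float, float]]] = {}
    for ph in PHENOMENA:
        pieces = 1 if props[ph] * duration < 0.25 else 2
        iv = _place_intervals(props[ph] * duration, duration, pieces,
                              occupied, rng)
        seg[ph] = iv
        occupied += iv
        for s, e in iv:
            events.append((ph, s, e))

    # --- harmonic stack
    phase = 2 * np.pi * np.cumsum(f0) / fs
    n_harm = int(min(8, np.floor(0.45 * fs / max(f0.max(), 1.0))))
    n_harm = max(n_harm, 6)
    amps = np.exp(-0.35 * np.arange(n_harm))
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        if h * f0.max() < 0.48 * fs:
            x += amps[h - 1] * np.sin(h * phase)

    if seg["subharmonics"]:
        m = _smooth_mask(n, fs, seg["subharmonics"])
        sub = np.zeros(n)
        for h in (0.5, 1.5, 2.5):
            if h * f0.max() < 0.48 * fs:
                sub += 0.35 * np.exp(-0.35 * h) * np.sin(h * phase)
        x = x + m * sub

    if seg["sidebands"]:
        m = _smooth_mask(n, fs, seg["sidebands"])
        f_mod = 110.0
        x = x * (1.0 + 0.55 * m * np.sin(2 * np.pi * f_mod * t))

    if seg["chaos"]:
        m = _smooth_mask(n, fs, seg["chaos"])
        lo = max(0.5 * float(np.median(f0)), 60.0)
        hi = min(4.5 * float(np.median(f0)), 0.45 * fs)
        b, a = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
        noise = sps.filtfilt(b, a, rng.standard_normal(n))
        noise *= np.std(x) / max(np.std(noise), 1e-12)
        x = x * (1.0 - m) + 1.2 * noise * m

    # --- amplitude envelope: AM, shimmer, fades, jump gaps, noise floor
    am_rate = max(rng.normal(g["am_rate_per_s"], sd["am_rate_per_s"]), 0.0)
    am_extent = max(rng.normal(g["am_extent_db"], sd["am_extent_db"]), 0.0)
    r = 10.0 ** (am_extent / 20.0)
    depth = (r - 1.0) / (r + 1.0)
    env = 1.0 + depth * np.sin(2 * np.pi * am_rate * t)
    shimmer_target = max(rng.normal(g["shimmer_pct"], sd["shimmer_pct"]), 0.0)
    env *= 1.0 + 0.01 * shimmer_target * drift[::-1]
    fade = min(int(0.02 * fs), n // 4)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
    env[:fade] *= ramp
    env[-fade:] *= ramp[::-1]
    gap = int(0.010 * fs)
    for jt in jump_times:
        j0 = int(jt * fs)
        env[j0:j0 + gap] = 0.0
    x = x * np.clip(env, 0.0, None)

    entropy_target = float(np.clip(
        rng.normal(g["entropy"], sd["entropy"]), 0.02, 0.9))
    noise = rng.standard_normal(n) * np.std(x) * 0.55 * entropy_target
    x = x + noise * np.clip(env, 0.0, None)

    x = 0.9 * x / max(np.abs(x).max(), 1e-12)

    ann = NLPAnnotation(call_id=call_id, events=sorted(events,
                                                       key=lambda e: e[1]))
    ann.validate(duration)

    # ground truth over frames outside chaos segments and jump gaps
    keep = np.ones(n, bool)
    for s, e in seg["chaos"]:
        keep[int(s * fs):int(e * fs)] = False
    for jt in jump_times:
        keep[int(jt * fs):int(jt * fs) + gap] = False
    f0k = f0[keep]
    phen_pct = {ph: 100.0 * sum(e - s for s, e in seg[ph]) / duration
                for ph in PHENOMENA}
    gt = {
        "duration_s": duration,
        "entropy": entropy_target,
        "f0_mean_hz": float(f0k.mean()),
        "f0_min_hz": float(f0k.min()),
        "f0_max_hz": float(f0k.max()),
        "f0_start_hz": float(f0k[0]),
        "f0_end_hz": float(f0k[-1]),
        "inflex": np.nan,
        "f0_var_hz_per_s": float(np.abs(np.diff(f0)).sum() * fs / fs
                                 / duration * 1.0) if n > 1 else 0.0,
        "fm_rate_per_s": fm_rate,
        "fm_extent_hz": fm_extent,
        "harmonicity_db": np.nan,
        "jitter_pct": jitter_target,
        "shimmer_pct": shimmer_target,
        "am_var_per_s": np.nan,
        "am_rate_per_s": am_rate,
        "am_extent_db": am_extent,
        "chaos_pct": phen_pct["chaos"],
        "subharmonics_pct": phen_pct["subharmonics"],
        "sidebands_pct": phen_pct["sidebands"],
        "freq_jumps": float(len(jump_times)),
    }
    return CallRecording(call_id=call_id, individual_id=sig.individual_id,
                         context=context, valence=shift.valence,
                         samples=x, sample_rate=fs, annotation=ann,
                         ground_truth=gt)


def suggested_pitch_bounds(sig: IndividualSignature) -> tuple[float, float]:
    """Per-individual pitch floor/ceiling adapted to the voice."""
    floor = max(100.0, 0.5 * sig.param_means["f0_min_hz"])
    ceiling = min(2.3 * sig.param_means["f0_max_hz"], 8000.0)
    return floor, ceiling


# ---------------------------------------------------------------------------
# dataset-level generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig,
                     ) -> tuple[list[CallRecording], pd.DataFrame]:
    """Synthesize the whole herd as waveforms + a ground-truth table."""
    sigs = config.signatures or draw_signatures(config)
    counts = _allocate_counts(config, _child_rng(config.seed, "counts"))
    recs: list[CallRecording] = []
    rows: list[dict] = []
    for sig in sigs:
        per = counts.get(sig.individual_id)
        if per is None or min(per.get(v, 0) for v in VALENCES) < 1:
            raise ConfigurationError(
                f"{sig.individual_id} has no calls in one valence")
        for valence in VALENCES:
            shift = config.shifts[valence]
            rng = _child_rng(config.seed, "calls", sig.individual_id, valence)
            ctxs = _assign_contexts(valence, per[valence], rng)
            for k in range(per[valence]):
                cid = f"{sig.individual_id}_{valence[:3]}_{k + 1:03d}"
                rec = synthesize_call(sig, shift, rng, call_id=cid,
                                      context=ctxs[k],
                                      sample_rate=config.sample_rate)
                recs.append(rec)
                row = {"call_id": cid, "individual_id": sig.individual_id,
                       "context": rec.context, "valence": valence}
                row.update(rec.ground_truth)
                rows.append(row)
    table = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    return recs, table


def generate_feature_table(config: SynthConfig) -> pd.DataFrame:
    """Draw 21-parameter vectors directly (no audio) — the fast route.

    Rows are Normal(signature mean + valence offset, within-individual SD)
    with a diagonal covariance by default (a full within-individual
    covariance may be supplied via ``config.within_cov``).  Percent-type
    parameters are clipped to [0, 100], the F0 order statistics are repaired
    to satisfy min <= mean <= max, and jump counts are rounded.
    """
    sigs = config.signatures or draw_signatures(config)
    counts = _allocate_counts(config, _child_rng(config.seed, "counts"))
    p = len(PARAM_NAMES)
    chol = None
    if config.within_cov is not None:
        c = np.asarray(config.within_cov, float)
        w, v = np.linalg.eigh((c + c.T) / 2)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rows = []
    for sig in sigs:
        per = counts[sig.individual_id]
        for valence in VALENCES:
            shift = config.shifts[valence]
            rng = _child_rng(config.seed, "table", sig.individual_id, valence)
            m = np.array([sig.param_means[nm] + shift.param_offsets.get(nm, 0)
                          for nm in PARAM_NAMES])
            for ph, col in _PHEN_PARAM.items():
                j = PARAM_NAMES.index(col)
                m[j] = sig.param_means[col] * shift.phenomena_multiplier
            j = PARAM_NAMES.index("freq_jumps")
            m[j] = sig.param_means["freq_jumps"] * shift.phenomena_multiplier
            s = np.array([sig.param_sds[nm] for nm in PARAM_NAMES])
            nv = per[valence]
            if chol is None:
                x = m + rng.standard_normal((nv, p)) * s
            else:
                x = m + rng.standard_normal((nv, p)) @ chol.T
            ctxs = _assign_contexts(valence, nv, rng)
            for k in range(nv):
                row = dict(zip(PARAM_NAMES, x[k]))
                _repair_row(row)
                row.update(call_id=f"{sig.individual_id}_{valence[:3]}"
                                   f"_{k + 1:03d}",
                           individual_id=sig.individual_id,
                           context=ctxs[k], valence=valence)
                rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def _repair_row(row: dict[str, float]) -> None:
    """Enforce the feature-vector invariants on one sampled row in place."""
    lo, mid, hi = sorted((row["f0_min_hz"], row["f0_mean_hz"],
                          row["f0_max_hz"]))
    row["f0_min_hz"], row["f0_mean_hz"], row["f0_max_hz"] = lo, mid, hi
    row["f0_start_hz"] = float(np.clip(row["f0_start_hz"], lo, hi))
    row["f0_end_hz"] = float(np.clip(row["f0_end_hz"], lo, hi))
    for nm in PERCENT_PARAMS:
        row[nm] = float(np.clip(row[nm], 0.0, 100.0))
    for nm in COUNT_PARAMS:
        row[nm] = float(max(round(row[nm]), 0))
    for nm in NONNEG_PARAMS:
        row[nm] = max(row[nm], 0.0)
    row["duration_s"] = max(row["duration_s"], 0.05)
    row["entropy"] = float(np.clip(row["entropy"], 0.0, 1.0))
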