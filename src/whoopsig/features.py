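"""Acoustic feature extraction for single whoops.

Implements the 16-feature set used for signature analysis: the 99%-energy
call duration, spectral peak/centroid, the fundamental-frequency contour and
its extremes, the constant-frequency (CF) plateau and upsweep segmentation,
subharmonic episodes and harmonic-to-subharmonic energy ratios, short-time
normalized spectral entropy, and cepstral peak prominence (CPP) statistics.

The fundamental contour is obtained by continuity-constrained spectrogram
ridge tracking inside a configurable search band (hand-traced contours can be
supplied instead and are passed through). All frequencies are reported in
kHz, durations in seconds, energy ratios in dB, entropy on a [0, 1] scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from fractions import Fraction

from .synth import WhoopRecord

__all__ = [
    "FeatureConfig",
    "FundamentalContour",
    "SegmentMarks",
    "WhoopFeatures",
    "FEATURE_NAMES",
    "resample_audio",
    "energy_window",
    "spectrum_summary",
    "trace_fundamental",
    "segment_cf",
    "segment_upsweep",
    "detect_subharmonics",
    "spectral_entropy_mean",
    "cpp_stats",
    "extract_features",
    "extract_table",
]

FEATURE_NAMES = [
    "dur", "dur_cf", "dur_upsweep", "dur_subharm",
    "endtime_cf", "endtime_upsweep",
    "freq_centroid", "freq_peak", "freq_min", "freq_max", "freq_mean_cf",
    "harmonic_ratio_total", "harmonic_ratio_cf",
    "mean_entropy", "cpp_mean", "cpp_sd",
]


@dataclass(frozen=True)
class FeatureConfig:
    """All tunables of the extraction pipeline.

    Spectrogram settings for ridge tracing, the f0 search band, subharmonic
    band widths, and the short-time block geometry for entropy and CPP are
    analysis parameters, not claims about the recordings; defaults suit a
    tonal call with a fundamental in the 0.2-2 kHz octave band.
    """

    analysis_rate: float = 32000.0   # Hz, common rate for spectral analysis
    lowband_rate: float = 8000.0     # Hz, rate for entropy / CPP analysis
    energy_fraction: float = 0.99    # energy criterion for call duration

    # ridge tracing
    trace_window: int = 1024         # samples at analysis_rate
    trace_hop: int = 256
    trace_nfft: int = 4096
    band_low: float = 200.0          # Hz, f0 search band
    band_high: float = 2000.0
    trace_floor_db: float = 35.0     # drop frames this far below the loudest
    max_jump_frac: float = 0.2       # max relative f0 step between frames

    # subharmonic detection
    n_harmonics: int = 6
    subharm_halfwidth_frac: float = 0.2  # band half-width as fraction of f0
    ratio_cap_db: float = 60.0

    # short-time entropy
    entropy_block_s: float = 0.004
    entropy_hop_s: float = 0.0005
    entropy_window: str = "hann"
    entropy_avg_halfwidth_s: float = 0.004  # Welch smoothing span (+/-)

    # cepstral peak prominence
    cpp_block_s: float = 0.004
    cpp_hop_s: float = 0.0005
    cpp_pad_factor: int = 2          # zero-padding of the block FFT
    cpp_f0_low: float = 100.0        # Hz, quefrency search band
    cpp_f0_high: float = 1200.0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class FundamentalContour:
    """Time-ordered trace of the fundamental frequency."""

    times: np.ndarray   # s, strictly increasing frame centres
    freqs: np.ndarray   # Hz
    frame_hop: float    # s

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.times.shape != self.freqs.shape:
            raise ValueError("times and freqs must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.freqs <= 0):
            raise ValueError("contour frequencies must be positive")


@dataclass
class SegmentMarks:
    """CF / upsweep / subharmonic segmentation of one call."""

    cf_start: float
    cf_end: float
    upsweep_end: float
    peak_time: float
    subharmonic_intervals: list = field(default_factory=list)
    cf_defined: bool = True


@dataclass
class WhoopFeatures:
    """The 16 per-call acoustic measures."""

    dur: float
    dur_cf: float
    dur_upsweep: float
    dur_subharm: float
    endtime_cf: float
    endtime_upsweep: float
    freq_centroid: float
    freq_peak: float
    freq_min: float
    freq_max: float
    freq_mean_cf: float
    harmonic_ratio_total: float
    harmonic_ratio_cf: float
    mean_entropy: float
    cpp_mean: float
    cpp_sd: float
    failed: bool = False
    failure_reason: str = ""
    config_hash: str = ""

    def validate(self) -> None:
        if self.failed:
            return
        if not self.dur > 0:
            raise ValueError("dur must be positive")
        for name in ("dur_cf", "dur_upsweep", "dur_subharm"):
            v = getattr(self, name)
            if not (0 <= v <= self.dur + 1e-9):
                raise ValueError(f"{name}={v} outside [0, dur]")
        if not (0 <= self.endtime_cf <= self.endtime_upsweep <= 1 + 1e-9):
            raise ValueError("endtime fractions must satisfy 0 <= cf <= upsweep <= 1")
        if not (self.freq_min <= self.freq_mean_cf <= self.freq_max):
            raise ValueError("need freq_min <= freq_mean_cf <= freq_max")
        if not (0 <= self.mean_entropy <= 1):
            raise ValueError("mean_entropy must lie in [0, 1]")


def resample_audio(record: WhoopRecord, target_rate: float) -> WhoopRecord:
    """Anti-aliased polyphase resampling to ``target_rate``."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == record.sample_rate:
        return record
    frac = Fraction(int(round(target_rate)), int(round(record.sample_rate))).limit_denominator(1000)
    y = resample_poly(record.waveform, frac.numerator, frac.denominator)
    return dataclasses.replace(record, waveform=y, sample_rate=float(target_rate))


def energy_window(
    waveform: np.ndarray, sample_rate: float, fraction: float = 0.99
) -> tuple[float, float]:
    """Symmetric-in-energy window containing ``fraction`` of squared energy.

    The cumulative energy crosses (1-fraction)/2 at the start and
    1-(1-fraction)/2 at the end; both times in seconds from waveform start.
    """
    e = np.asarray(waveform, dtype=float) ** 2
    total = e.sum()
    if total <= 0:
        raise ValueError("silent input: all-zero waveform")
    cum = np.cumsum(e) / total
    tail = (1.0 - fraction) / 2.0
    i0 = int(np.searchsorted(cum, tail, side="left"))
    i1 = int(np.searchsorted(cum, 1.0 - tail, side="left"))
    return i0 / sample_rate, (i1 + 1) / sample_rate


def spectrum_summary(
    waveform: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
    band: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """(peak frequency, centroid frequency) in kHz over the analysis window."""
    i0, i1 = int(round(window[0] * sample_rate)), int(round(window[1] * sample_rate))
    seg = np.asarray(waveform[i0:i1], dtype=float)
    if len(seg) < 2:
        raise ValueError("empty analysis window")
    spec = np.abs(np.fft.rfft(seg)) ** 2
    freqs = np.fft.rfftfreq(len(seg), 1.0 / sample_rate)
    if band is not None:
        m = (freqs >= band[0]) & (freqs <= band[1])
        spec, freqs = spec[m], freqs[m]
    peak = freqs[int(np.argmax(spec))]
    centroid = float(np.sum(freqs * spec) / np.sum(spec))
    return peak / 1000.0, centroid / 1000.0


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n = (len(x) - win) // hop + 1
    if n < 1:
        raise ValueError("signal shorter than one analysis frame")
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _stft_power(
    x: np.ndarray, fs: float, win: int, hop: int, nfft: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann power spectrogram; returns (frame centre times, freqs, P[frames, bins])."""
    frames = _frame(np.asarray(x, dtype=float), win, hop) * np.hanning(win)
    P = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2
    times = (np.arange(P.shape[0]) * hop + win / 2) / fs
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return times, freqs, P


def _parabolic_refine(P_log: np.ndarray, i: int, df: float, f: float) -> float:
    """Sub-bin quadratic interpolation of a spectral peak position."""
    if i <= 0 or i >= len(P_log) - 1:
        return f
    a, b, c = P_log[i - 1], P_log[i], P_log[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return f
    delta = 0.5 * (a - c) / denom
    return f + np.clip(delta, -0.5, 0.5) * df


def trace_fundamental(
    waveform: np.ndarray,
    sample_rate: float,
    config: FeatureConfig = FeatureConfig(),
    anchor: Optional[FundamentalContour] = None,
    _spec: Optional[tuple] = None,
) -> FundamentalContour:
    """Ridge-track the fundamental inside the configured search band.

    Starts at the highest-energy voiced frame and walks outward, constraining
    the inter-frame jump to ``max_jump_frac`` of the current f0; frames whose
    in-band energy falls ``trace_floor_db`` below the loudest frame are
    dropped. Peak positions are refined by parabolic interpolation. If an
    ``anchor`` contour is supplied it is resampled onto the frame grid and
    returned unchanged in value.
    """
    if config.band_high >= sample_rate / 2:
        raise ValueError("search band exceeds Nyquist")
    times, freqs, P = _spec if _spec is not None else _stft_power(
        waveform, sample_rate, config.trace_window, config.trace_hop, config.trace_nfft
    )
    hop_s = config.trace_hop / sample_rate
    if anchor is not None:
        m = (times >= anchor.times[0]) & (times <= anchor.times[-1])
        if not m.any():
            raise ValueError("anchor contour does not overlap the frame grid")
        f = np.interp(times[m], anchor.times, anchor.freqs)
        return FundamentalContour(times=times[m], freqs=f, frame_hop=hop_s)

    band = (freqs >= config.band_low) & (freqs <= config.band_high)
    if not band.any():
        raise ValueError("empty search band")
    bfreqs = freqs[band]
    BP = P[:, band]
    energy = BP.sum(axis=1)
    if energy.max() <= 0:
        raise ValueError("no voiced frames: zero in-band energy")
    keep = energy >= energy.max() * 10.0 ** (-config.trace_floor_db / 10.0)
    if not keep.any():
        raise ValueError("no voiced frames above the energy floor")
    df = bfreqs[1] - bfreqs[0]
    logBP = np.log(BP + 1e-300)

    n_frames = len(times)
    f0 = np.full(n_frames, np.nan)

    def peak_at(i: int, fmin: float, fmax: float) -> float:
        lo = int(np.searchsorted(bfreqs, fmin, side="left"))
        hi = int(np.searchsorted(bfreqs, fmax, side="right"))
        if hi <= lo:
            lo, hi = 0, len(bfreqs)
        j = lo + int(np.argmax(BP[i, lo:hi]))
        return _parabolic_refine(logBP[i], j, df, bfreqs[j])

    # Seed at the strongest frame whose unconstrained peak sits near the
    # median per-frame peak: subharmonic episodes can be the loudest part of
    # a call and would otherwise seed the tracker an octave low.
    kept_idx = np.flatnonzero(keep)
    raw_peaks = np.array([peak_at(int(i), config.band_low, config.band_high)
                          for i in kept_idx])
    med = float(np.median(raw_peaks))
    near = (raw_peaks >= 0.8 * med) & (raw_peaks <= 1.25 * med)
    cand = kept_idx[near] if near.any() else kept_idx
    seed = int(cand[np.argmax(energy[cand])])
    f0[seed] = peak_at(seed, config.band_low, config.band_high)
    for direction in (1, -1):
        prev = f0[seed]
        i = seed + direction
        while 0 <= i < n_frames:
            if keep[i]:
                f0[i] = peak_at(i, prev * (1 - config.max_jump_frac),
                                prev * (1 + config.max_jump_frac))
                prev = f0[i]
            i += direction
    voiced = keep & ~np.isnan(f0)
    return FundamentalContour(times=times[voiced], freqs=f0[voiced], frame_hop=hop_s)


def segment_cf(contour: FundamentalContour) -> tuple[SegmentMarks, float, float]:
    """Locate the CF plateau; returns (marks, dur_cf, freq_mean_cf [kHz]).

    The plateau is the longest contiguous run of frames, ending no later than
    the contour's peak frame, whose frequencies lie within +/-10% of the
    median contour frequency taken over frames strictly before the peak.
    Ties (equal-length runs, equal peak values) break to the earliest.
    """
    f = contour.freqs
    if len(f) < 3:
        raise ValueError("contour too short to segment (need >= 3 frames)")
    peak = int(np.argmax(f))  # argmax takes the earliest on ties
    hop = contour.frame_hop
    peak_time = contour.times[peak] + hop / 2
    if peak == 0:
        # no pre-peak frames: CF undefined
        marks = SegmentMarks(cf_start=contour.times[0], cf_end=contour.times[0],
                             upsweep_end=peak_time, peak_time=peak_time,
                             cf_defined=False)
        return marks, 0.0, float(f[peak]) / 1000.0
    m = np.median(f[:peak])
    ok = (f[: peak + 1] >= 0.9 * m) & (f[: peak + 1] <= 1.1 * m)
    if not ok.any():
        marks = SegmentMarks(cf_start=contour.times[0], cf_end=contour.times[0],
                             upsweep_end=peak_time, peak_time=peak_time,
                             cf_defined=False)
        return marks, 0.0, float(f[peak]) / 1000.0
    i0, i1 = _longest_true_run(ok)
    dur_cf = (i1 - i0 + 1) * hop
    cf_start = contour.times[i0] - hop / 2
    cf_end = cf_start + dur_cf
    marks = SegmentMarks(cf_start=cf_start, cf_end=cf_end,
                         upsweep_end=peak_time, peak_time=peak_time)
    return marks, dur_cf, float(np.mean(f[i0 : i1 + 1])) / 1000.0


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """Inclusive (start, end) of the longest True run, earliest on ties."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("no True entries")
    edges = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    lengths = ends - starts + 1
    k = int(np.argmax(lengths))  # earliest maximal run
    return int(starts[k]), int(ends[k])


def segment_upsweep(
    contour: FundamentalContour, marks: SegmentMarks
) -> tuple[float, float]:
    """(dur_upsweep, upsweep_end_time): CF end to the contour peak."""
    if marks.peak_time < marks.cf_end - contour.frame_hop:
        raise ValueError("inconsistent marks: contour peak precedes CF end")
    return max(marks.peak_time - marks.cf_end, 0.0), marks.peak_time


def detect_subharmonics(
    waveform: np.ndarray,
    sample_rate: float,
    contour: FundamentalContour,
    marks: SegmentMarks,
    config: FeatureConfig = FeatureConfig(),
    _spec: Optional[tuple] = None,
) -> tuple[list, float, float, float]:
    """Frame-wise harmonic vs subharmonic energy comparison.

    Harmonic energy sums spectrogram power in bands around k*f0 (k=1..K),
    subharmonic energy around (k-1/2)*f0, each band a +/-0.2*f0 half-width.
    A frame is subharmonic-dominated iff subharmonic energy strictly exceeds
    harmonic energy. Returns (intervals, dur_subharm, ratio_total_db,
    ratio_cf_db); ratios are capped at +/-ratio_cap_db via an energy floor.
    """
    if len(contour.freqs) == 0:
        raise ValueError("contour missing")
    times, freqs, P = _spec if _spec is not None else _stft_power(
        waveform, sample_rate, config.trace_window, config.trace_hop, config.trace_nfft
    )
    hop = contour.frame_hop
    m = (times >= contour.times[0] - hop) & (times <= contour.times[-1] + hop)
    times, P = times[m], P[m]
    f0 = np.interp(times, contour.times, contour.freqs)
    w = config.subharm_halfwidth_frac * f0
    nyq = sample_rate / 2

    def band_energy(centers: np.ndarray) -> np.ndarray:
        # centers: [frames, bands]
        lo = np.searchsorted(freqs, centers - w[:, None], side="left")
        hi = np.searchsorted(freqs, centers + w[:, None], side="right")
        csum = np.concatenate([np.zeros((P.shape[0], 1)), np.cumsum(P, axis=1)], axis=1)
        rows = np.arange(P.shape[0])[:, None]
        return (csum[rows, hi] - csum[rows, lo]).sum(axis=1)

    k = np.arange(1, config.n_harmonics + 1)
    harm_centers = f0[:, None] * k[None, :]
    sub_centers = f0[:, None] * (k[None, :] - 0.5)
    valid_h = harm_centers + w[:, None] < nyq
    valid_s = sub_centers + w[:, None] < nyq
    Eh = band_energy(np.where(valid_h, harm_centers, nyq * 2))
    Es = band_energy(np.where(valid_s, sub_centers, nyq * 2))

    dominated = Es > Eh
    intervals: list[tuple[float, float]] = []
    if dominated.any():
        d = dominated.view(np.int8)
        edges = np.diff(np.concatenate(([0], d, [0])))
        for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1) - 1):
            intervals.append((times[s] - hop / 2, times[e] + hop / 2))
    dur_sub = float(sum(e - s for s, e in intervals))

    def ratio(mask: np.ndarray) -> float:
        H, S = Eh[mask].sum(), Es[mask].sum()
        floor = max((H + S) * 1e-6, 1e-300)
        r = 10.0 * np.log10(max(H, floor) / max(S, floor))
        return float(np.clip(r, -config.ratio_cap_db, config.ratio_cap_db))

    all_mask = np.ones(len(times), dtype=bool)
    cf_mask = (times >= marks.cf_start) & (times <= marks.cf_end)
    if not cf_mask.any():
        cf_mask = all_mask
    return intervals, dur_sub, ratio(all_mask), ratio(cf_mask)


def _block_spectra(
    x: np.ndarray, fs: float, block_s: float, hop_s: float,
    window: str, nfft: int,
) -> tuple[np.ndarray, np.ndarray]:
    block = int(round(block_s * fs))
    hop = max(int(round(hop_s * fs)), 1)
    wfun = {"hann": np.hanning, "hamming": np.hamming, "rect": np.ones}[window]
    frames = _frame(np.asarray(x, dtype=float), block, hop) * wfun(block)
    P = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2
    centres = (np.arange(P.shape[0]) * hop + block / 2) / fs
    return centres, P


def spectral_entropy_mean(
    waveform: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Mean normalized Shannon spectral entropy over short blocks.

    Per block, the power spectrum is estimated as the Welch mean of the
    hann periodograms of the heavily-overlapped neighbouring blocks within
    +/-``entropy_avg_halfwidth_s`` (variance stabilisation; a stationary or
    slowly-modulated tone is unaffected), then H = -sum p log p / log N over
    the normalized spectrum, and the mean is taken over blocks whose centres
    lie inside the 99%-energy window. 0 ~ pure tone, 1 ~ white noise.
    """
    fs = sample_rate
    block = int(round(config.entropy_block_s * fs))
    centres, P = _block_spectra(
        waveform, fs, config.entropy_block_s, config.entropy_hop_s,
        config.entropy_window, nfft=block,
    )
    if config.entropy_avg_halfwidth_s > 0:
        hop = max(int(round(config.entropy_hop_s * fs)), 1)
        half = int(round(config.entropy_avg_halfwidth_s * fs / hop))
        if half > 0:
            # centred moving average along the time axis, edge-padded
            k = 2 * half + 1
            Ppad = np.pad(P, ((half, half), (0, 0)), mode="edge")
            c = np.cumsum(np.vstack([np.zeros((1, P.shape[1])), Ppad]), axis=0)
            P = (c[k:] - c[:-k]) / k
    m = (centres >= window[0]) & (centres <= window[1])
    if not m.any():
        raise ValueError("analysis window shorter than one block")
    P = P[m]
    p = P / P.sum(axis=1, keepdims=True)
    H = -(p * np.log(np.maximum(p, 1e-300))).sum(axis=1) / np.log(P.shape[1])
    return float(H.mean())


def cpp_stats(
    waveform: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float]:
    """(mean, s.d.) of cepstral peak prominence across short blocks.

    Per block: real cepstrum of the dB log-magnitude spectrum; a straight
    line is regressed on the cepstrum over the quefrency range spanned by the
    configured f0 band, and CPP is the cepstral peak height above that line.
    Scale-invariant by construction (an amplitude factor shifts the whole log
    spectrum, changing only the DC cepstral bin).
    """
    fs = sample_rate
    block = int(round(config.cpp_block_s * fs))
    nfft = block * config.cpp_pad_factor
    q_lo = max(1, int(np.ceil(fs / config.cpp_f0_high)))
    q_hi = min(nfft // 2, int(np.floor(fs / config.cpp_f0_low)))
    if q_hi <= q_lo:
        raise ValueError(
            "empty quefrency search range at this block size; "
            "increase cpp_block_s or cpp_pad_factor"
        )
    centres, P = _block_spectra(waveform, fs, config.cpp_block_s, config.cpp_hop_s,
                                "hann", nfft=nfft)
    m = (centres >= window[0]) & (centres <= window[1])
    if not m.any():
        raise ValueError("analysis window shorter than one block")
    logS = 10.0 * np.log10(np.maximum(P[m], 1e-300))
    cep = np.fft.irfft(logS, nfft, axis=1)
    q = np.arange(q_lo, q_hi + 1, dtype=float)
    c = cep[:, q_lo : q_hi + 1]
    qc = q - q.mean()
    slope = (c * qc).sum(axis=1) / (qc * qc).sum()
    fit = c.mean(axis=1)[:, None] + slope[:, None] * qc[None, :]
    cpp = (c - fit).max(axis=1)
    return float(cpp.mean()), float(cpp.std())


def extract_features(
    record: WhoopRecord,
    config: FeatureConfig = FeatureConfig(),
    anchor: Optional[FundamentalContour] = None,
) -> WhoopFeatures:
    """Run the full 16-feature pipeline on one whoop.

    A whoop that fails contour tracing (or any other stage) is returned with
    ``failed=True`` and the failure reason, never silently dropped.
    """
    try:
        rec = resample_audio(record, config.analysis_rate)
        fs = rec.sample_rate
        t0, t1 = energy_window(rec.waveform, fs, config.energy_fraction)
        dur = t1 - t0
        freq_peak, freq_centroid = spectrum_summary(rec.waveform, fs, (t0, t1))
        spec = _stft_power(rec.waveform, fs, config.trace_window,
                           config.trace_hop, config.trace_nfft)
        contour = trace_fundamental(rec.waveform, fs, config, anchor=anchor, _spec=spec)
        if len(contour.freqs) < 3:
            raise ValueError("no voiced frames: contour too short")
        marks, dur_cf, freq_mean_cf = segment_cf(contour)
        dur_upsweep, upsweep_end = segment_upsweep(contour, marks)
        intervals, dur_sub, ratio_total, ratio_cf = detect_subharmonics(
            rec.waveform, fs, contour, marks, config, _spec=spec
        )
        marks.subharmonic_intervals = intervals
        low = resample_audio(rec, config.lowband_rate)
        entropy = spectral_entropy_mean(low.waveform, low.sample_rate, (t0, t1), config)
        cpp_mean, cpp_sd = cpp_stats(low.waveform, low.sample_rate, (t0, t1), config)

        def frac(t: float) -> float:
            return float(np.clip((t - t0) / dur, 0.0, 1.0))

        feats = WhoopFeatures(
            dur=dur,
            dur_cf=min(dur_cf, dur),
            dur_upsweep=min(dur_upsweep, dur),
            dur_subharm=min(dur_sub, dur),
            endtime_cf=frac(marks.cf_end) if marks.cf_defined else 0.0,
            endtime_upsweep=max(frac(upsweep_end),
                                frac(marks.cf_end) if marks.cf_defined else 0.0),
            freq_centroid=freq_centroid,
            freq_peak=freq_peak,
            freq_min=float(contour.freqs.min()) / 1000.0,
            freq_max=float(contour.freqs.max()) / 1000.0,
            freq_mean_cf=freq_mean_cf,
            harmonic_ratio_total=ratio_total,
            harmonic_ratio_cf=ratio_cf,
            mean_entropy=entropy,
            cpp_mean=cpp_mean,
            cpp_sd=cpp_sd,
            config_hash=config.config_hash(),
        )
        feats.validate()
        return feats
    except (ValueError, FloatingPointError) as exc:
        return WhoopFeatures(
            **{name: np.nan for name in FEATURE_NAMES},
            failed=True, failure_reason=str(exc), config_hash=config.config_hash(),
        )


METADATA_FIELDS = [
    "whoop_id", "bout_id", "caller_id", "clan_id", "position_in_bout",
    "whoop_type", "age_months", "sex", "recording_method",
]


def extract_table(
    records: Sequence[WhoopRecord],
    config: FeatureConfig = FeatureConfig(),
    anchors: Optional[dict] = None,
) -> pd.DataFrame:
    """Feature table: one row per record (metadata + 16 features + flag)."""
    rows = []
    for rec in records:
        anchor = (anchors or {}).get(rec.whoop_id)
        feats = extract_features(rec, config, anchor=anchor)
        row = {name: getattr(rec, name) for name in METADATA_FIELDS}
        row.update({name: getattr(feats, name) for name in FEATURE_NAMES})
        row["failed"] = feats.failed
        row["failure_reason"] = feats.failure_reason
        rows.append(row)
    return pd.DataFrame(rows)
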