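"""Synthetic whoop-bout generator.

Emulates a population of clans and individuals producing harmonic,
frequency-modulated tonal long-distance calls ("whoops") in bouts, with
known ground truth. Each individual carries a vocal signature — a set of
mean contour parameters (plateau frequency, peak frequency, duration, CF
fraction) — drawn around population base values with separate clan-level
and individual-level offsets, so worlds with and without group signatures
can be simulated. Calls are rendered as phase-continuous harmonic stacks
over a piecewise-smooth fundamental contour (onset rise, constant-frequency
plateau, upsweep to peak, decay), optionally with a subharmonic episode at
half-integer multiples of the fundamental, and additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "PopulationSpec",
    "IndividualSignature",
    "BoutSpec",
    "SynthWhoopParams",
    "WhoopRecord",
    "sample_population",
    "generate_bout",
    "render_whoop",
    "contour_frequency",
    "truth_features",
    "write_dataset",
    "synthesize_dataset",
]

#: parameters that clan/individual offsets may act on
SIGNATURE_PARAMS = ("f0_cf", "f0_max", "dur", "cf_fraction")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of clans and individuals with known signature structure.

    Individual parameter means are ``base * (1 + clan_offset + indiv_offset)``
    with offsets drawn i.i.d. normal at s.d. ``clan_effect_scale`` and
    ``individual_effect_scale``. The default world has no clan signature
    (``clan_effect_scale = 0``) but a real individual signature.
    """

    n_clans: int = 4
    individuals_per_clan: int = 5
    clan_effect_scale: float = 0.0
    individual_effect_scale: float = 0.08
    within_individual_cv: float = 0.04
    f0_cf_base: float = 750.0      # Hz, plateau fundamental
    f0_max_base: float = 1000.0    # Hz, contour peak
    dur_base: float = 2.8          # s
    cf_fraction_base: float = 0.45  # fraction of call in the CF plateau
    seed: int = 0
    #: which signature parameters receive clan/individual offsets; restricting
    #: this (e.g. to frequency parameters only) builds worlds where the
    #: signature lives in a known feature subspace.
    effect_params: tuple = SIGNATURE_PARAMS

    def __post_init__(self):
        if self.n_clans < 1 or self.individuals_per_clan < 1:
            raise ValueError("population must contain at least one clan and one individual per clan")
        for name in ("clan_effect_scale", "individual_effect_scale", "within_individual_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.f0_max_base > self.f0_cf_base > 0):
            raise ValueError("need f0_max_base > f0_cf_base > 0")
        if not (0 < self.cf_fraction_base < 1):
            raise ValueError("cf_fraction_base must lie in (0, 1)")
        unknown = set(self.effect_params) - set(SIGNATURE_PARAMS)
        if unknown:
            raise ValueError(f"unknown effect_params: {sorted(unknown)}")


@dataclass(frozen=True)
class IndividualSignature:
    """Ground-truth per-individual call parameters."""

    individual_id: str
    clan_id: str
    sex: str
    age_months: int
    f0_cf_mean: float      # Hz
    f0_max_mean: float     # Hz
    dur_mean: float        # s
    cf_fraction_mean: float
    subharmonic_propensity: float
    amplitude_rolloff: float  # dB per harmonic step

    def __post_init__(self):
        if not (self.f0_max_mean >= self.f0_cf_mean > 0):
            raise ValueError("need f0_max_mean >= f0_cf_mean > 0")
        if not (0 <= self.subharmonic_propensity <= 1):
            raise ValueError("subharmonic_propensity must lie in [0, 1]")


@dataclass(frozen=True)
class BoutSpec:
    """Bout structure: length range and whoop-type sequence template.

    The default template is an optional leading preliminary (P) whoop, a body
    of asymmetric/symmetric (A/S) whoops, and an optional terminal (T) whoop.
    Edge probabilities and the A/S mix are assumptions: only the bout-length
    range (2-34 calls) is an observed constraint.
    """

    length_min: int = 2
    length_max: int = 34
    p_leading: float = 0.5     # probability the bout opens with a P whoop
    p_trailing: float = 0.5    # probability the bout closes with a T whoop
    p_asymmetric: float = 0.5  # P(A) vs P(S) for body whoops
    inter_whoop_interval: float = 4.0  # s, metadata only
    #: per-call jitter shared by all whoops of a bout (lognormal CV); models
    #: bout-level drift and induces correlated within-bout errors when > 0
    bout_level_cv: float = 0.0

    def __post_init__(self):
        if not (2 <= self.length_min <= self.length_max):
            raise ValueError("need 2 <= length_min <= length_max")
        for name in ("p_leading", "p_trailing", "p_asymmetric"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be a probability")
        if self.bout_level_cv < 0:
            raise ValueError("bout_level_cv must be >= 0")


@dataclass(frozen=True)
class SynthWhoopParams:
    """Ground-truth contour anatomy of one synthetic whoop."""

    whoop_type: str            # P, S, A or T
    f0_cf: float               # Hz, plateau frequency
    f0_max: float              # Hz, contour peak frequency
    dur: float                 # s
    cf_start: float            # s
    cf_end: float              # s
    upsweep_end: float         # s
    n_harmonics: int = 6
    amplitude_rolloff: float = 6.0       # dB per harmonic step
    subharmonic_start: Optional[float] = None  # s
    subharmonic_end: Optional[float] = None    # s
    subharmonic_level_db: float = -3.0   # dB re fundamental
    snr_db: Optional[float] = None       # None = noiseless

    def __post_init__(self):
        if self.whoop_type not in ("P", "S", "A", "T"):
            raise ValueError("whoop_type must be one of P, S, A, T")
        if not (0 <= self.cf_start < self.cf_end <= self.upsweep_end <= self.dur):
            raise ValueError("need 0 <= cf_start < cf_end <= upsweep_end <= dur")
        if self.f0_max < self.f0_cf:
            raise ValueError("need f0_max >= f0_cf")
        if (self.subharmonic_start is None) != (self.subharmonic_end is None):
            raise ValueError("subharmonic interval needs both start and end")
        if self.subharmonic_start is not None and not (
            0 <= self.subharmonic_start < self.subharmonic_end <= self.dur
        ):
            raise ValueError("subharmonic interval must lie within the call")


@dataclass
class WhoopRecord:
    """One call: waveform, sample rate and metadata."""

    waveform: np.ndarray
    sample_rate: float
    whoop_id: str
    bout_id: str
    caller_id: str
    clan_id: str
    position_in_bout: int
    whoop_type: str
    age_months: int
    sex: str
    recording_method: str = "synthetic"


def sample_population(spec: PopulationSpec) -> list[IndividualSignature]:
    """Draw a balanced population of individual vocal signatures.

    Deterministic given ``spec.seed``. Each of the four signature parameters
    gets an independent clan offset (shared within a clan) and an individual
    offset; parameters not in ``spec.effect_params`` receive neither.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    base = {
        "f0_cf": spec.f0_cf_base,
        "f0_max": spec.f0_max_base,
        "dur": spec.dur_base,
        "cf_fraction": spec.cf_fraction_base,
    }
    active = set(spec.effect_params)
    out: list[IndividualSignature] = []
    for c in range(spec.n_clans):
        clan_id = f"clan{c:02d}"
        clan_off = {p: rng.normal(0.0, spec.clan_effect_scale) if p in active else 0.0
                    for p in SIGNATURE_PARAMS}
        for i in range(spec.individuals_per_clan):
            ind_off = {p: rng.normal(0.0, spec.individual_effect_scale) if p in active else 0.0
                       for p in SIGNATURE_PARAMS}
            mean = {p: base[p] * (1.0 + clan_off[p] + ind_off[p]) for p in SIGNATURE_PARAMS}
            # keep the anatomy physical: positive plateau, peak above plateau,
            # CF fraction inside the call
            f0_cf = max(mean["f0_cf"], 50.0)
            f0_max = max(mean["f0_max"], 1.05 * f0_cf)
            cf_frac = float(np.clip(mean["cf_fraction"], 0.1, 0.8))
            out.append(
                IndividualSignature(
                    individual_id=f"{clan_id}_h{i:02d}",
                    clan_id=clan_id,
                    sex="f" if rng.random() < 0.5 else "m",
                    age_months=int(rng.integers(25, 180)),
                    f0_cf_mean=f0_cf,
                    f0_max_mean=f0_max,
                    dur_mean=max(mean["dur"], 0.5),
                    cf_fraction_mean=cf_frac,
                    subharmonic_propensity=float(rng.uniform(0.0, 0.3)),
                    amplitude_rolloff=float(rng.uniform(5.0, 7.0)),
                )
            )
    return out


def _lognormal_jitter(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal jitter with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def generate_bout(
    sig: IndividualSignature,
    bout: BoutSpec,
    rng: np.random.Generator,
    snr_db: Optional[float] = None,
    within_individual_cv: float = 0.04,
    n_harmonics: int = 6,
) -> list[SynthWhoopParams]:
    """Draw the ground-truth parameters of one bout of whoops.

    Bout length is uniform on [length_min, length_max]. Per-call parameters
    are the individual's means times mean-one lognormal jitter with CV
    ``within_individual_cv`` (plus an optional bout-level shared jitter).
    P whoops are short (duration multiplier < 0.5); T whoops are flat
    (peak ~ plateau) and lower in frequency.
    """
    n = int(rng.integers(bout.length_min, bout.length_max + 1))
    types = []
    lead = rng.random() < bout.p_leading
    trail = rng.random() < bout.p_trailing
    for k in range(n):
        if k == 0 and lead:
            types.append("P")
        elif k == n - 1 and trail and n > 1:
            types.append("T")
        else:
            types.append("A" if rng.random() < bout.p_asymmetric else "S")

    bout_jit = {p: _lognormal_jitter(rng, bout.bout_level_cv) for p in SIGNATURE_PARAMS}
    out = []
    for wtype in types:
        jit = {p: bout_jit[p] * _lognormal_jitter(rng, within_individual_cv)
               for p in SIGNATURE_PARAMS}
        f0_cf = sig.f0_cf_mean * jit["f0_cf"]
        f0_max = max(sig.f0_max_mean * jit["f0_max"], 1.02 * f0_cf)
        dur = sig.dur_mean * jit["dur"]
        cf_frac = float(np.clip(sig.cf_fraction_mean * jit["cf_fraction"], 0.08, 0.85))
        if wtype == "P":
            dur *= 0.35
            cf_start, cf_end, upsweep_end = 0.06 * dur, 0.30 * dur, 0.60 * dur
        elif wtype == "S":
            # bell-like: short plateau, peak near the call centre
            cf_start, cf_end, upsweep_end = 0.06 * dur, 0.25 * dur, 0.55 * dur
        elif wtype == "A":
            # long CF portion, late rise to peak
            cf_start = 0.06 * dur
            cf_end = max(cf_start + 0.05 * dur, cf_frac * dur)
            upsweep_end = max(0.88 * dur, cf_end)
        else:  # T: flat, low, no real upsweep
            dur *= 0.8
            f0_cf *= 0.8
            f0_max = 1.005 * f0_cf
            cf_start = 0.05 * dur
            cf_end = upsweep_end = 0.95 * dur
        sub_start = sub_end = None
        if rng.random() < sig.subharmonic_propensity and wtype in ("A", "S"):
            span = cf_end - cf_start
            sub_start = cf_start + 0.2 * span
            sub_end = sub_start + 0.4 * span
        out.append(
            SynthWhoopParams(
                whoop_type=wtype,
                f0_cf=float(f0_cf),
                f0_max=float(f0_max),
                dur=float(dur),
                cf_start=float(cf_start),
                cf_end=float(cf_end),
                upsweep_end=float(upsweep_end),
                n_harmonics=n_harmonics,
                amplitude_rolloff=sig.amplitude_rolloff,
                subharmonic_start=sub_start,
                subharmonic_end=sub_end,
                snr_db=snr_db,
            )
        )
    return out


# fraction of the plateau frequency at which the onset ramp starts, and of the
# peak frequency at which the final decay ends
_ONSET_RATIO = 0.92
_DECAY_RATIO = 0.75


def contour_frequency(params: SynthWhoopParams, times: np.ndarray) -> np.ndarray:
    """The true fundamental contour f0(t) in Hz, evaluated at ``times``.

    Piecewise smooth: cosine-ramp onset to the plateau, constant-frequency
    plateau, cubic-smoothstep upsweep to the peak, cosine decay to the end.
    """
    t = np.asarray(times, dtype=float)
    f = np.full(t.shape, params.f0_cf, dtype=float)
    if params.cf_start > 0:
        m = t < params.cf_start
        u = t[m] / params.cf_start
        lo = _ONSET_RATIO * params.f0_cf
        f[m] = lo + (params.f0_cf - lo) * 0.5 * (1 - np.cos(np.pi * u))
    if params.upsweep_end > params.cf_end:
        m = (t > params.cf_end) & (t <= params.upsweep_end)
        u = (t[m] - params.cf_end) / (params.upsweep_end - params.cf_end)
        s = u * u * (3 - 2 * u)
        f[m] = params.f0_cf + (params.f0_max - params.f0_cf) * s
    if params.dur > params.upsweep_end:
        m = t > params.upsweep_end
        u = np.clip((t[m] - params.upsweep_end) / (params.dur - params.upsweep_end), 0, 1)
        lo = _DECAY_RATIO * params.f0_max
        f[m] = params.f0_max - (params.f0_max - lo) * 0.5 * (1 - np.cos(np.pi * u))
    return f


def render_whoop(
    params: SynthWhoopParams,
    sample_rate: float = 32000.0,
    rng: Optional[np.random.Generator] = None,
    metadata: Optional[dict] = None,
) -> WhoopRecord:
    """Render a whoop as a phase-continuous harmonic stack plus noise.

    The waveform is the sum of harmonics k*f0(t) (k = 1..n_harmonics) with
    the given amplitude rolloff, phase-continuous via the integrated
    instantaneous frequency, with an optional subharmonic component at
    half-integer multiples of f0 on its interval, a raised-cosine (Tukey)
    amplitude envelope, and Gaussian noise at the stated SNR.
    """
    top = params.n_harmonics * params.f0_max
    if sample_rate < 4.0 * top:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low for {params.n_harmonics} harmonics "
            f"up to {top:.0f} Hz (need >= {4.0 * top:.0f} Hz)"
        )
    n = int(round(params.dur * sample_rate))
    t = np.arange(n) / sample_rate
    f0 = contour_frequency(params, t)
    phase = 2 * np.pi * np.cumsum(f0) / sample_rate
    amps = 10.0 ** (-params.amplitude_rolloff * np.arange(params.n_harmonics) / 20.0)
    wave = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        wave += amps[k - 1] * np.sin(k * phase)
    if params.subharmonic_start is not None:
        g = 10.0 ** (params.subharmonic_level_db / 20.0)
        mask = _smooth_gate(t, params.subharmonic_start, params.subharmonic_end, ramp=0.01)
        sub = np.zeros(n)
        for k in range(1, params.n_harmonics + 1):
            if (k - 0.5) * params.f0_max < 0.5 * sample_rate:
                sub += amps[k - 1] * np.sin((k - 0.5) * phase)
        wave += g * mask * sub
    from scipy.signal.windows import tukey

    # brief cosine on/offsets (1% of the call each side): keeps the rendered
    # 99%-energy duration close to the declared duration
    wave *= tukey(n, 0.02)
    if params.snr_db is not None:
        if rng is None:
            raise ValueError("noisy render (snr_db set) requires an rng")
        p_sig = np.mean(wave**2)
        sigma = np.sqrt(p_sig / 10.0 ** (params.snr_db / 10.0))
        wave = wave + rng.normal(0.0, sigma, size=n)
    meta = metadata or {}
    return WhoopRecord(
        waveform=wave,
        sample_rate=sample_rate,
        whoop_id=meta.get("whoop_id", "w0"),
        bout_id=meta.get("bout_id", "b0"),
        caller_id=meta.get("caller_id", "h0"),
        clan_id=meta.get("clan_id", "c0"),
        position_in_bout=meta.get("position_in_bout", 0),
        whoop_type=params.whoop_type,
        age_months=meta.get("age_months", 60),
        sex=meta.get("sex", "f"),
        recording_method=meta.get("recording_method", "synthetic"),
    )


def _smooth_gate(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Unit gate over [start, end] with cosine edges of width ``ramp`` seconds."""
    g = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    g[inside] = 1.0
    if ramp > 0:
        up = (t >= start - ramp) & (t < start)
        g[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start + ramp) / ramp))
        dn = (t > end) & (t <= end + ramp)
        g[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - end) / ramp))
    return g


def truth_features(params: SynthWhoopParams, grid_s: float = 0.001) -> dict:
    """Ground-truth values of the contour-derived features for one whoop.

    Duration and peak frequency come straight from the parameters; the CF
    plateau quantities are obtained by applying the CF definition (the longest
    pre-peak run of the contour within +/-10% of the pre-peak median) to the
    analytic contour on a fine time grid, so the generator's truth is stated
    in the same terms the extractor measures.
    """
    t = np.arange(0.0, params.dur, grid_s)
    f = contour_frequency(params, t)
    peak = int(np.argmax(f))
    if peak == 0:
        dur_cf, fmean_cf, cf_end = 0.0, float(f[0]), 0.0
    else:
        m = np.median(f[:peak])
        ok = (f[: peak + 1] >= 0.9 * m) & (f[: peak + 1] <= 1.1 * m)
        i0, i1 = _longest_run(ok)
        dur_cf = (i1 - i0 + 1) * grid_s
        fmean_cf = float(np.mean(f[i0 : i1 + 1]))
        cf_end = (i1 + 1) * grid_s
    return {
        "dur": params.dur,
        "dur_cf": dur_cf,
        "freq_mean_cf": fmean_cf / 1000.0,     # kHz
        "freq_max": float(f.max()) / 1000.0,   # kHz
        "freq_min": float(f.min()) / 1000.0,   # kHz
        "dur_upsweep": max(params.upsweep_end - cf_end, 0.0),
        "cf_end": cf_end,
    }


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, end) inclusive indices of the longest True run; earliest on ties."""
    best = (-1, -1)
    best_len = 0
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best_len == 0:
        raise ValueError("mask has no True run")
    return best


def synthesize_dataset(
    pop_spec: PopulationSpec,
    bout_spec: BoutSpec = BoutSpec(),
    n_bouts_per_individual: int = 4,
    snr_db: Optional[float] = 15.0,
    sample_rate: float = 32000.0,
    render: bool = True,
    individuals: Optional[list] = None,
) -> tuple[list[WhoopRecord], list[SynthWhoopParams], pd.DataFrame]:
    """Generate a full dataset: every individual calls in several bouts.

    Returns (records, params, truth table). With ``render=False`` the records
    list is empty (ground-truth parameters only). ``individuals`` overrides
    the population draw (e.g. hand-edited signatures). Fully deterministic
    given ``pop_spec.seed``.
    """
    if individuals is None:
        individuals = sample_population(pop_spec)
    ss = np.random.SeedSequence([pop_spec.seed, 0xB0071])
    rng = np.random.default_rng(ss)
    records: list[WhoopRecord] = []
    all_params: list[SynthWhoopParams] = []
    truth_rows = []
    wid = 0
    for sig in individuals:
        for b in range(n_bouts_per_individual):
            bout_id = f"{sig.individual_id}_b{b:02d}"
            plist = generate_bout(
                sig, bout_spec, rng, snr_db=snr_db,
                within_individual_cv=pop_spec.within_individual_cv,
            )
            for pos, p in enumerate(plist):
                meta = {
                    "whoop_id": f"w{wid:05d}",
                    "bout_id": bout_id,
                    "caller_id": sig.individual_id,
                    "clan_id": sig.clan_id,
                    "position_in_bout": pos,
                    "age_months": sig.age_months,
                    "sex": sig.sex,
                    "recording_method": "synthetic",
                }
                if render:
                    records.append(render_whoop(p, sample_rate, rng=rng, metadata=meta))
                all_params.append(p)
                truth_rows.append({**meta, "whoop_type": p.whoop_type,
                                   **{k: v for k, v in dataclasses.asdict(p).items()
                                      if k != "whoop_type"},
                                   **truth_features(p)})
                wid += 1
    return records, all_params, pd.DataFrame(truth_rows)


METADATA_COLUMNS = [
    "whoop_id", "bout_id", "caller_id", "clan_id", "position_in_bout",
    "whoop_type", "age_months", "sex", "recording_method", "wav_path",
]


def write_dataset(
    records: Sequence[WhoopRecord],
    out_dir: str | Path,
    params: Optional[Sequence[SynthWhoopParams]] = None,
) -> dict:
    """Write one mono float32 WAV per whoop plus metadata and truth CSVs."""
    if not records:
        raise ValueError("no records to write")
    out_dir = Path(out_dir)
    wav_dir = out_dir / "audio"
    wav_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        path = wav_dir / f"{rec.whoop_id}.wav"
        wavfile.write(path, int(rec.sample_rate), rec.waveform.astype(np.float32))
        rows.append({
            "whoop_id": rec.whoop_id, "bout_id": rec.bout_id,
            "caller_id": rec.caller_id, "clan_id": rec.clan_id,
            "position_in_bout": rec.position_in_bout, "whoop_type": rec.whoop_type,
            "age_months": rec.age_months, "sex": rec.sex,
            "recording_method": rec.recording_method, "wav_path": str(path),
        })
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    meta_path = out_dir / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    out = {"metadata": meta_path, "wav_dir": wav_dir, "n": len(records)}
    if params is not None:
        truth = pd.DataFrame([dataclasses.asdict(p) for p in params])
        truth.insert(0, "whoop_id", [r.whoop_id for r in records])
        truth_path = out_dir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        out["truth"] = truth_path
    return out


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV as float64 in [-1, 1] (int formats rescaled)."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(rate)
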