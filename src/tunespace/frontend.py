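"""Audio frontend: cochlear-style spectrograms and stimulus construction.

The model-facing half converts waveforms into 32-channel log-compressed
gammatone spectrograms at 100 Hz.  The stimulus-construction half
implements the natural-segment sequence design: excitation-pattern
based diversity selection of brief sound segments and crossfaded
assembly into fixed-duration sequences with random level roving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .data import Spectrogram

__all__ = [
    "FrontendParams",
    "ExcitationPattern",
    "SegmentRecord",
    "SequenceSpec",
    "SelectionRules",
    "erb_bandwidth",
    "gammatone_spectrogram",
    "excitation_pattern",
    "filter_segment_pool",
    "assemble_sequence",
]

#: allowed nominal segment durations (ms)
SEGMENT_DURATIONS_MS = (50, 110, 190, 420, 780)


@dataclass
class FrontendParams:
    """Parameters of the gammatone spectrogram frontend.

    ``erb_coefs = (c0, c1)`` parameterizes the filter bandwidth as
    ``ERB(f) = c0 * (c1 * f / 1000 + 1)``; the default is the standard
    human formula (24.7, 4.37).
    """

    n_channels: int = 32
    f_low: float = 200.0
    f_high: float = 20000.0
    frame_rate: float = 100.0
    gammatone_order: int = 2
    log_floor: float = 1e-4
    erb_coefs: tuple = (24.7, 4.37)

    def __post_init__(self):
        if self.f_low >= self.f_high:
            raise ValueError("f_low must be below f_high")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    @property
    def center_freqs(self) -> np.ndarray:
        """Log-spaced (strictly increasing) channel center frequencies in Hz."""
        return np.geomspace(self.f_low, self.f_high, self.n_channels)


def erb_bandwidth(freq, coefs=(24.7, 4.37)):
    """Equivalent rectangular bandwidth ERB(f) = c0 (c1 f/1000 + 1), in Hz."""
    c0, c1 = coefs
    return c0 * (c1 * np.asarray(freq, dtype=float) / 1000.0 + 1.0)


def _erb_number(freq, coefs=(24.7, 4.37)):
    """Warped frequency axis: integral of 1/ERB(f) df."""
    c0, c1 = coefs
    return (1000.0 / (c0 * c1)) * np.log1p(c1 * np.asarray(freq, dtype=float) / 1000.0)


def gammatone_spectrogram(wave: np.ndarray, rate: float,
                          params: FrontendParams | None = None) -> Spectrogram:
    """Log-compressed gammatone spectrogram of a waveform.

    Each channel is a cascade of ``gammatone_order`` complex one-pole
    resonators at the channel center frequency with bandwidth
    ``1.019 * ERB(f)``; the envelope is the magnitude of the complex
    output (the rectified analytic envelope), averaged over
    non-overlapping frames at ``frame_rate`` and compressed as
    ``log(x + log_floor)``.  A 2-s input at 100 Hz frame rate yields
    exactly 200 frames (``T = ceil(duration * frame_rate)``).
    """
    params = params or FrontendParams()
    wave = np.asarray(wave, dtype=float)
    if wave.ndim == 2:  # stereo: take the left channel
        wave = wave[:, 0]
    if not np.all(np.isfinite(wave)):
        raise ValueError("waveform must be finite")
    if rate < 2 * params.f_high:
        raise ValueError(
            f"sample rate {rate} Hz is below the Nyquist limit {2 * params.f_high} Hz "
            f"for f_high={params.f_high} Hz")
    freqs = params.center_freqs
    n = wave.shape[0]
    n_frames = math.ceil(n * params.frame_rate / rate)
    frame_idx = np.minimum((np.arange(n) * params.frame_rate / rate).astype(int),
                           n_frames - 1)
    counts = np.bincount(frame_idx, minlength=n_frames)
    out = np.empty((params.n_channels, n_frames))
    for ch, fc in enumerate(freqs):
        bw = 1.019 * erb_bandwidth(fc, params.erb_coefs)
        pole = np.exp((-2 * np.pi * bw + 2j * np.pi * fc) / rate)
        y = wave.astype(complex)
        for _ in range(params.gammatone_order):
            y = lfilter([1.0], [1.0, -pole], y)
        # normalize to unit gain at the center frequency
        gain = abs(1.0 - pole * np.exp(-2j * np.pi * fc / rate)) ** params.gammatone_order
        env = np.abs(y) * gain
        frames = np.bincount(frame_idx, weights=env, minlength=n_frames) / counts
        out[ch] = np.log(frames + params.log_floor)
    return Spectrogram(values=out, frame_rate=params.frame_rate, center_freqs=freqs)


@dataclass
class ExcitationPattern:
    """Compressed cochlear-filter energy profile of a segment."""

    values: np.ndarray
    compression_exponent: float = 0.3

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("excitation pattern entries must be non-negative")

    def correlation(self, other: "ExcitationPattern") -> float:
        a, b = self.values, other.values
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])


def _cosine_filters(freqs: np.ndarray, n_filters: int, f_low: float, f_high: float,
                    erb_coefs) -> np.ndarray:
    """Overlapping half-cosine magnitude profiles on the ERB-warped axis."""
    e = _erb_number(freqs, erb_coefs)
    lo, hi = _erb_number(f_low, erb_coefs), _erb_number(f_high, erb_coefs)
    centers = np.linspace(lo, hi, n_filters + 2)[1:-1]
    width = centers[1] - centers[0]
    filters = np.zeros((n_filters, len(freqs)))
    for k, c in enumerate(centers):
        arg = (e - c) / (2 * width)
        inside = np.abs(arg) < 0.5
        filters[k, inside] = np.cos(np.pi * arg[inside])
    return filters


def excitation_pattern(segment: np.ndarray, rate: float,
                       params: FrontendParams | None = None,
                       n_filters: int = 32,
                       compression: float = 0.3) -> ExcitationPattern:
    """Excitation pattern of a segment: cosine-filtered power spectrum,
    compressed by raising to the 0.3 power.

    Invariant to overall segment gain up to a common scale, so the
    Pearson correlation between two patterns ignores level.  An all-zero
    segment yields the zero vector.
    """
    params = params or FrontendParams()
    segment = np.asarray(segment, dtype=float)
    if segment.ndim == 2:
        segment = segment[:, 0]
    if segment.size == 0:
        raise ValueError("segment is empty")
    spec = np.abs(np.fft.rfft(segment)) ** 2
    freqs = np.fft.rfftfreq(segment.shape[0], d=1.0 / rate)
    filters = _cosine_filters(freqs, n_filters, params.f_low, params.f_high,
                              params.erb_coefs)
    return ExcitationPattern(values=(filters @ spec) ** compression,
                             compression_exponent=compression)


@dataclass(eq=False)  # identity equality: records carry waveform arrays
class SegmentRecord:
    """One candidate segment for sequence construction."""

    source_id: str
    category: str
    duration_ms: int
    waveform: np.ndarray
    excitation: ExcitationPattern | None = None

    def __post_init__(self):
        if self.duration_ms not in SEGMENT_DURATIONS_MS:
            raise ValueError(
                f"duration {self.duration_ms} ms not in {SEGMENT_DURATIONS_MS}")
        self.waveform = np.asarray(self.waveform, dtype=float)

    def power_db(self) -> float:
        p = float(np.mean(self.waveform ** 2))
        return 10.0 * np.log10(p) if p > 0 else -np.inf


@dataclass
class SelectionRules:
    """Diversity/selection rules applied to the candidate segment stream."""

    similarity_r: float = 0.8
    max_similar_frac: float = 0.05
    similarity_sample: int = 10000
    power_floor_db: float = 25.0
    category_cap: float = 0.20
    seed: int = 0


def filter_segment_pool(candidates: list, rules: SelectionRules | None = None):
    """Select diverse segments from an ordered candidate stream.

    Four rules, applied in order, each rejection logged with the rule
    that fired:

    * ``power-floor`` — the segment's power is more than
      ``power_floor_db`` below the maximum-power segment of the same
      recording (silent periods);
    * ``same-recording similarity`` — excitation pattern correlates
      ``r > similarity_r`` with an already-accepted segment from the
      same recording;
    * ``population similarity`` — correlates ``r > similarity_r`` with
      more than ``max_similar_frac`` of previously selected segments
      (checked against a seeded sample of up to ``similarity_sample``);
    * ``category cap`` — the candidate's category already makes up
      ``category_cap`` of the accepted set.

    Returns ``(accepted, rejection_log)`` where the log is a list of
    dicts with keys ``source_id, category, rule, r_value``.
    """
    rules = rules or SelectionRules()
    rng = np.random.default_rng(rules.seed)
    max_power = {}
    for c in candidates:
        p = c.power_db()
        max_power[c.source_id] = max(p, max_power.get(c.source_id, -np.inf))
    accepted: list[SegmentRecord] = []
    rejections: list[dict] = []
    cat_counts: dict[str, int] = {}

    def reject(c, rule, r=np.nan):
        rejections.append({"source_id": c.source_id, "category": c.category,
                           "rule": rule, "r_value": r})

    for c in candidates:
        if c.power_db() < max_power[c.source_id] - rules.power_floor_db:
            reject(c, "power-floor")
            continue
        if c.excitation is None:
            raise ValueError("candidates must carry excitation patterns")
        same = [a for a in accepted if a.source_id == c.source_id]
        r_same = max((c.excitation.correlation(a.excitation) for a in same),
                     default=-np.inf)
        if r_same > rules.similarity_r:
            reject(c, "same-recording similarity", r_same)
            continue
        if accepted:
            pool = accepted
            if len(accepted) > rules.similarity_sample:
                idx = rng.choice(len(accepted), rules.similarity_sample,
                                 replace=False)
                pool = [accepted[i] for i in idx]
            rs = np.array([c.excitation.correlation(a.excitation) for a in pool])
            frac = float(np.mean(rs > rules.similarity_r))
            if frac > rules.max_similar_frac:
                reject(c, "population similarity", float(rs.max()))
                continue
        if c.category and accepted:
            n_cat = cat_counts.get(c.category, 0)
            if (n_cat + 1) / (len(accepted) + 1) > rules.category_cap:
                reject(c, "category cap")
                continue
        accepted.append(c)
        if c.category:
            cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
    return accepted, rejections


@dataclass
class SequenceSpec:
    """Composition of one stimulus sequence."""

    composition: dict = field(default_factory=lambda: dict(
        zip(SEGMENT_DURATIONS_MS, (64, 32, 16, 8, 4))))
    silence_per_duration: int = 1
    level_rove_db: float = 20.0
    crossfade_ms: float = 10.0
    target_duration_s: float = 17.79

    def __post_init__(self):
        if any(v <= 0 for v in self.composition.values()):
            raise ValueError("composition counts must be positive")
        if self.crossfade_ms >= min(self.composition):
            raise ValueError("crossfade must be shorter than the shortest segment")


def assemble_sequence(segments: list, spec: SequenceSpec | None = None,
                      seed: int = 0, rate: float = 44100.0):
    """Assemble segments into one crossfaded sequence with level roving.

    Segments are placed at cumulative nominal offsets in seeded random
    order; consecutive segments overlap by ``crossfade_ms`` with
    complementary raised-cosine (Hanning) ramps that sum to unity at
    every overlap sample, so constant-amplitude material shows no dip.
    Each segment's gain is drawn uniformly from
    ``±level_rove_db / 2`` around the sequence reference.  One silent
    segment per duration is inserted.  Returns ``(waveform, manifest)``.
    """
    spec = spec or SequenceSpec()
    rng = np.random.default_rng(seed)
    by_dur: dict[int, list] = {d: [] for d in spec.composition}
    for seg in segments:
        if seg.duration_ms in by_dur:
            by_dur[seg.duration_ms].append(seg)
    shortfall = {d: n - len(by_dur[d]) for d, n in spec.composition.items()
                 if len(by_dur[d]) < n}
    if shortfall:
        raise ValueError(f"insufficient segments per duration (needed - have): "
                         f"{shortfall}")
    chosen: list = []
    for d, n in spec.composition.items():
        idx = rng.choice(len(by_dur[d]), n, replace=False)
        chosen.extend(by_dur[d][i] for i in idx)
    for d in spec.composition:  # silent segments
        for _ in range(spec.silence_per_duration):
            chosen.append(SegmentRecord(source_id="<silence>", category="",
                                        duration_ms=d,
                                        waveform=np.zeros(int(rate * d / 1000))))
    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]

    xf = int(round(rate * spec.crossfade_ms / 1000.0))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(xf) / max(xf - 1, 1)))
    nominal = [int(round(rate * c.duration_ms / 1000.0)) for c in chosen]
    total = sum(nominal) + xf
    out = np.zeros(total)
    manifest = []
    offset = 0
    for c, nom in zip(chosen, nominal):
        need = nom + xf
        w = c.waveform[:need]
        if len(w) < need:
            w = np.pad(w, (0, need - len(w)))
        gain_db = float(rng.uniform(-spec.level_rove_db / 2, spec.level_rove_db / 2))
        w = w * 10.0 ** (gain_db / 20.0)
        w = w.copy()
        if offset > 0:
            w[:xf] *= ramp
        w[-xf:] *= ramp[::-1]
        out[offset:offset + need] += w
        manifest.append({"source_id": c.source_id, "category": c.category,
                         "duration_ms": c.duration_ms, "offset_s": offset / rate,
                         "gain_db": gain_db})
        offset += nom
    return out, manifest
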