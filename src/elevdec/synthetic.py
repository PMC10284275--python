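"""Synthetic study generator with a known latent emotion trajectory.

Emulates the study's three input streams so every pipeline stage can be
verified by parameter recovery:

* a smooth per-second latent elevation trajectory (low-pass filtered
  Gaussian noise plus a few positive bumps, standardized over the full
  concatenation);
* Poisson comment streams whose word composition tracks the latent value
  through a softmax link (higher latent -> more high-score terms), drawn
  from a small synthetic vocabulary with negators and degree words;
* multi-participant EEG in which designated (channel, band) pairs carry a
  per-second amplitude envelope ``1 + g * sign * latent``, embedded in
  band-limited background noise, broadband sensor noise and 50-Hz line
  interference.  The envelope gain ``g`` of each coupling is solved
  numerically so the group-level univariate correlation between that
  band-power feature and the latent equals the requested ``effect_r``;
* sliding-bar self-report traces: the latent shifted by a reaction lag,
  scaled to the bar range and corrupted by rater noise.

Defaults reproduce the reference study's dimensions: 23 participants,
32 channels at 250 Hz, videos of 136/84/80 s (300 s total), and seven
negative beta/gamma couplings at frontal and temporo-parietal sites with
|r| between 0.22 and 0.28.  Everything is deterministic under the master
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from .dictionary import DEFAULT_DEGREE_WORDS, DEFAULT_NEGATORS, EmotionDictionary
from .eeg import DEFAULT_BANDS, DEFAULT_MONTAGE, BandDefinition, EEGRecording
from .scoring import Comment, CommentStream

__all__ = [
    "Coupling",
    "SimulationConfig",
    "LatentTrajectory",
    "SelfReportTraces",
    "default_dictionary",
    "DEFAULT_COUPLINGS",
    "gen_latent",
    "gen_comments",
    "gen_eeg",
    "gen_selfreport",
    "simulate_dataset",
    "SimulatedDataset",
]


class SimulationError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class Coupling:
    """A planted (channel, band) modulation with signed target correlation."""

    channel: str
    band: str
    effect_r: float  # signed group-level univariate correlation target

    def __post_init__(self) -> None:
        if not 0 < abs(self.effect_r) < 1:
            raise SimulationError(
                f"effect_r must have magnitude in (0, 1), got {self.effect_r}"
            )


#: Default planted couplings: negative beta/gamma modulation at frontal and
#: bilateral temporo-parietal sites, magnitudes in the 0.2-0.3 range.
DEFAULT_COUPLINGS: tuple[Coupling, ...] = (
    Coupling("F4", "beta", -0.23),
    Coupling("P7", "beta", -0.22),
    Coupling("Fz", "gamma", -0.27),
    Coupling("F4", "gamma", -0.26),
    Coupling("FC2", "gamma", -0.24),
    Coupling("P7", "gamma", -0.24),
    Coupling("P8", "gamma", -0.28),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults match the reference study."""

    n_participants: int = 23
    channel_names: tuple[str, ...] = DEFAULT_MONTAGE
    fs: int = 250
    video_durations_s: tuple[int, ...] = (136, 84, 80)
    comment_rate: float = 60.0       # mean comments per second
    comment_link_beta: float = 0.8   # softmax slope of score vs latent
    p_negator: float = 0.05
    p_degree: float = 0.10
    couplings: tuple[Coupling, ...] = DEFAULT_COUPLINGS
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_amplitudes: tuple[float, ...] = (4.0, 3.0, 2.0, 1.5)  # uV RMS per band
    broadband_sd: float = 1.0        # white sensor noise, uV
    line_amplitude: float = 2.0      # 50-Hz interference, uV
    line_hz: float = 50.0
    latent_smoothness_s: float = 4.0
    n_raters: int = 5
    selfreport_noise_sd: float = 0.1
    selfreport_lag_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationError("need at least one participant")
        if len(self.band_amplitudes) != len(self.bands):
            raise SimulationError("one amplitude per band required")
        if any(d < 1 for d in self.video_durations_s):
            raise SimulationError("video durations must be positive")
        band_names = {b.name for b in self.bands}
        for c in self.couplings:
            if c.channel not in self.channel_names:
                raise SimulationError(f"coupling channel {c.channel!r} not in montage")
            if c.band not in band_names:
                raise SimulationError(f"coupling band {c.band!r} not defined")

    @property
    def total_seconds(self) -> int:
        return int(sum(self.video_durations_s))

    @property
    def video_ids(self) -> tuple[str, ...]:
        return tuple(f"video{k + 1}" for k in range(len(self.video_durations_s)))

    def stage_rng(self, stage: str, *extra: int) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the master seed."""
        key = [self.seed, sum(ord(ch) for ch in stage), *extra]
        return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class LatentTrajectory:
    """Ground-truth per-second latent trajectory over the concatenated videos."""

    values: np.ndarray
    video_durations_s: tuple[int, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(values) != sum(self.video_durations_s):
            raise SimulationError("latent length does not match video durations")

    def __len__(self) -> int:
        return len(self.values)

    def per_video(self) -> list[np.ndarray]:
        out, offset = [], 0
        for d in self.video_durations_s:
            out.append(self.values[offset : offset + d])
            offset += d
        return out


# --- vocabulary --------------------------------------------------------------

_SCORE2_WORDS = (
    "touching", "inspiring", "heartwarming", "moving", "uplifting",
    "noble", "selfless", "heroic", "admirable", "virtuous", "salute",
    "respect", "tears", "goosebumps", "gratitude", "awe", "kindhearted",
    "humbling", "faith in humanity", "heart of gold",
)
_SCORE1_WORDS = (
    "nice", "kind", "sweet", "warm", "good", "gentle", "caring",
    "thoughtful", "pleasant", "helpful", "decent", "friendly",
    "generous", "supportive", "wholesome", "lovely", "heartfelt",
    "touched a bit", "well done", "bless",
)
_SCORE0_WORDS = (
    "first", "hello", "lol", "music", "camera", "editing", "subtitle",
    "volume", "anyone here", "watching again", "what song", "cold today",
    "random", "test", "ok", "hmm", "background", "quality", "buffering",
    "boring",
)


def default_dictionary() -> EmotionDictionary:
    """The synthetic ~60-term vocabulary with default modifier lexicons."""
    entries: dict[str, int] = {}
    for words, score in ((_SCORE0_WORDS, 0), (_SCORE1_WORDS, 1), (_SCORE2_WORDS, 2)):
        for w in words:
            entries[w] = score
    return EmotionDictionary(
        entries=entries,
        negators=DEFAULT_NEGATORS,
        degree_words=dict(DEFAULT_DEGREE_WORDS),
    )


# --- latent ------------------------------------------------------------------

def gen_latent(cfg: SimulationConfig) -> LatentTrajectory:
    """Smooth multi-bump latent trajectory, standardized over all videos.

    Each video gets low-pass filtered Gaussian noise (Gaussian kernel of
    ``latent_smoothness_s`` seconds) plus 2-4 positive Gaussian bumps with
    random centers, widths of 8-15 s and amplitudes of 1-3; the
    concatenation is z-scored (population SD).
    """
    rng = cfg.stage_rng("latent")
    parts = []
    for dur in cfg.video_durations_s:
        base = gaussian_filter1d(rng.normal(size=dur), cfg.latent_smoothness_s,
                                 mode="reflect")
        t = np.arange(dur, dtype=float)
        for _ in range(int(rng.integers(2, 5))):
            center = rng.uniform(0, dur)
            width = rng.uniform(8.0, 15.0)
            amp = rng.uniform(1.0, 3.0)
            base = base + amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        parts.append(base)
    values = np.concatenate(parts)
    values = (values - values.mean()) / values.std()
    return LatentTrajectory(values=values, video_durations_s=cfg.video_durations_s)


# --- comments ----------------------------------------------------------------

def _score_probs(latent_value: float, beta: float) -> np.ndarray:
    logits = np.array([0.0, 1.0, 2.0]) * beta * latent_value
    w = np.exp(logits - logits.max())
    return w / w.sum()


def gen_comments(
    latent: LatentTrajectory,
    dictionary: EmotionDictionary,
    cfg: SimulationConfig,
) -> list[CommentStream]:
    """Poisson comment streams whose term scores track the latent trajectory.

    Per second the comment count is Poisson(``comment_rate``); each comment
    holds 1-3 entry terms whose score s in {0, 1, 2} is drawn with
    probability proportional to exp(s * beta * latent), i.e. high-score
    terms become monotonically more likely as the latent rises.  Negators
    and degree words are prepended with small fixed probabilities.
    """
    by_score = {s: dictionary.terms_with_score(s) for s in (0, 1, 2)}
    if any(not terms for terms in by_score.values()):
        raise SimulationError("dictionary needs entries at every score level")
    negators = sorted(dictionary.negators)
    degree = sorted(dictionary.degree_words)
    rng = cfg.stage_rng("comments")
    streams = []
    for vid, dur, lat in zip(cfg.video_ids, cfg.video_durations_s,
                             latent.per_video()):
        comments: list[Comment] = []
        for i in range(dur):
            probs = _score_probs(lat[i], cfg.comment_link_beta)
            for _ in range(rng.poisson(cfg.comment_rate)):
                ts = i + rng.uniform(0.0, 1.0)
                words = []
                for _ in range(int(rng.integers(1, 4))):
                    s = int(rng.choice(3, p=probs))
                    term = by_score[s][int(rng.integers(len(by_score[s])))]
                    prefix = []
                    if negators and rng.uniform() < cfg.p_negator:
                        prefix.append(negators[int(rng.integers(len(negators)))])
                    if degree and rng.uniform() < cfg.p_degree:
                        prefix.append(degree[int(rng.integers(len(degree)))])
                    words.extend(prefix + [term])
                comments.append(Comment(min(ts, dur - 1e-9), " ".join(words)))
        comments.sort(key=lambda c: c.timestamp)
        streams.append(CommentStream(video_id=vid, duration_s=dur,
                                     comments=tuple(comments)))
    return streams


# --- EEG ---------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, lo: float, hi: float,
                n_rows: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance noise with a flat spectrum confined to [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros((n_rows, len(freqs)), dtype=complex)
    spec[:, mask] = rng.normal(size=(n_rows, mask.sum())) \
        + 1j * rng.normal(size=(n_rows, mask.sum()))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _calibrate_gain(powers: np.ndarray, latent: np.ndarray,
                    effect_r: float) -> float:
    """Solve the envelope gain hitting the target group-level correlation.

    ``powers`` is (participants, seconds): per-second power of the planted
    component before modulation.  The coupled group-mean power at gain g is
    mean_p((1 + g*sign*latent)^2 * powers); g is the root of its
    correlation with the latent minus the target.
    """
    sign = np.sign(effect_r)
    g_max = 0.95 / np.abs(latent).max()

    def gap(g: float) -> float:
        env2 = (1.0 + g * sign * latent) ** 2
        group = (env2[None, :] * powers).mean(axis=0)
        return float(np.corrcoef(group, latent)[0, 1]) - effect_r

    lo, hi = 1e-9, g_max
    if gap(lo) * gap(hi) > 0:
        if sign * gap(lo) > 0:
            # the unmodulated noise already correlates beyond the target in
            # the target's direction -- only possible at very small scales
            warnings.warn(
                f"baseline correlation already beyond effect_r={effect_r}; "
                "using zero gain", stacklevel=2)
            return 0.0
        raise SimulationError(
            f"effect_r={effect_r} unreachable with a positive amplitude "
            "envelope (|effect_r| too large for the noise level)"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def gen_eeg(
    latent: LatentTrajectory,
    cfg: SimulationConfig,
    channels: Sequence[str] | None = None,
) -> tuple[list[EEGRecording], dict[tuple[str, str], float]]:
    """Simulated recordings, one per participant per video.

    Each channel is a sum of band-limited noise components (one per band),
    broadband white noise and 50-Hz line interference with a random phase.
    For coupled (channel, band) pairs the band component carries the
    per-second amplitude envelope ``1 + g*sign*latent`` with ``g``
    calibrated per realization (see :func:`_calibrate_gain`); all other
    components are stationary.

    ``channels`` optionally restricts the synthesized montage to a subset
    of the default channel list (generation is per-channel independent, so
    a subset is bit-identical to slicing the full montage).  Returns the
    recordings and the calibrated gain per coupling.
    """
    if channels is None:
        channels = cfg.channel_names
    else:
        unknown = set(channels) - set(cfg.channel_names)
        if unknown:
            raise SimulationError(f"channels not in montage: {sorted(unknown)}")
    n_sec = cfg.total_seconds
    if len(latent) != n_sec:
        raise SimulationError("latent length does not match config durations")
    fs = cfg.fs
    n = n_sec * fs
    lat = latent.values
    band_amp = {b.name: a for b, a in zip(cfg.bands, cfg.band_amplitudes)}
    band_edges = {b.name: (b.low_hz, b.high_hz) for b in cfg.bands}
    coupled = {(c.channel, c.band): c for c in cfg.couplings}

    # planted components first (deterministic per coupling x participant),
    # so their realized powers drive the gain calibration
    comp: dict[tuple[str, str], np.ndarray] = {}
    gains: dict[tuple[str, str], float] = {}
    for (ch, band), c in coupled.items():
        rng = cfg.stage_rng("eeg-coupled", cfg.channel_names.index(ch),
                            [b.name for b in cfg.bands].index(band))
        comp[(ch, band)] = _band_noise(rng, *band_edges[band],
                                       cfg.n_participants, n, fs) * band_amp[band]
        powers = (comp[(ch, band)].reshape(cfg.n_participants, n_sec, fs) ** 2
                  ).sum(axis=2)
        gains[(ch, band)] = _calibrate_gain(powers, lat, c.effect_r)

    t = np.arange(n) / fs
    envelopes = {
        key: np.repeat(1.0 + g * np.sign(coupled[key].effect_r) * lat, fs)
        for key, g in gains.items()
    }
    recordings: list[EEGRecording] = []
    for p in range(cfg.n_participants):
        data = np.zeros((len(channels), n))
        # one random stream per (participant, channel): a channel subset is
        # then bit-identical to the matching rows of the full montage
        for i, ch in enumerate(channels):
            rng = cfg.stage_rng("eeg-background", p, cfg.channel_names.index(ch))
            row = data[i]
            for band in band_edges:
                if (ch, band) in coupled:
                    row += comp[(ch, band)][p] * envelopes[(ch, band)]
                else:
                    row += _band_noise(rng, *band_edges[band], 1, n, fs)[0] \
                        * band_amp[band]
            row += cfg.broadband_sd * rng.normal(size=n)
            row += cfg.line_amplitude * np.sin(
                2 * np.pi * cfg.line_hz * t + rng.uniform(0, 2 * np.pi))
        offset = 0
        for vid, dur in zip(cfg.video_ids, cfg.video_durations_s):
            recordings.append(EEGRecording(
                participant_id=f"sub{p + 1:02d}",
                video_id=vid,
                data=data[:, offset * fs : (offset + dur) * fs].copy(),
                channel_names=tuple(channels),
                fs=float(fs),
            ))
            offset += dur
    return recordings, gains


# --- self-report -------------------------------------------------------------

@dataclass(frozen=True)
class SelfReportTraces:
    """Per-rater sliding-bar traces (1 value/s) and their mean."""

    traces: np.ndarray  # (n_raters, n_seconds)
    mean_trace: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", np.asarray(self.traces, dtype=float))
        object.__setattr__(self, "mean_trace",
                           np.asarray(self.mean_trace, dtype=float))


def _lag_kernel(lag_s: float, width_s: float) -> np.ndarray:
    """Discrete 1-Hz kernel delaying a series by ``lag_s`` seconds."""
    if width_s <= 0:
        shift = int(round(lag_s))
        k = np.zeros(shift + 1)
        k[shift] = 1.0
        return k
    half = int(np.ceil(3 * width_s))
    taps = np.arange(0, lag_s + half + 1)
    k = np.exp(-0.5 * ((taps - lag_s) / width_s) ** 2)
    return k / k.sum()


def gen_selfreport(
    latent: LatentTrajectory,
    n_raters: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    lag_s: float = 2.0,
    kernel_width_s: float = 1.0,
    scale: float = 0.12,
    center: float = 0.5,
    bar_range: tuple[float, float] = (0.0, 1.0),
) -> SelfReportTraces:
    """Sliding-bar traces: lagged latent, scaled to the bar, plus noise.

    Each rater's trace is the latent convolved per video with a causal lag
    kernel (Gaussian of ``kernel_width_s`` centered ``lag_s`` seconds in
    the past), mapped to the bar as ``center + scale * value``, corrupted
    with white noise of ``noise_sd`` (bar units) and clipped to the bar
    range.  ``noise_sd=0, lag_s=0, kernel_width_s=0`` recovers the latent
    up to the affine bar mapping wherever the clip is inactive.
    """
    if n_raters < 1:
        raise SimulationError("need at least one rater")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    kernel = _lag_kernel(lag_s, kernel_width_s)
    lagged_parts = []
    for seg in latent.per_video():
        padded = np.concatenate([np.full(len(kernel) - 1, seg[0]), seg])
        lagged_parts.append(np.convolve(padded, kernel, mode="valid"))
    lagged = np.concatenate(lagged_parts)
    traces = center + scale * lagged[None, :] \
        + noise_sd * rng.normal(size=(n_raters, len(lagged)))
    traces = np.clip(traces, *bar_range)
    return SelfReportTraces(traces=traces, mean_trace=traces.mean(axis=0))


# --- full bundle -------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimulationConfig
    dictionary: EmotionDictionary
    latent: LatentTrajectory
    streams: list[CommentStream]
    recordings: list[EEGRecording]
    selfreport: SelfReportTraces
    gains: dict[tuple[str, str], float]


def simulate_dataset(
    cfg: SimulationConfig,
    dictionary: EmotionDictionary | None = None,
    with_eeg: bool = True,
) -> SimulatedDataset:
    """Generate a complete dataset (latent, comments, EEG, self-report)."""
    if dictionary is None:
        dictionary = default_dictionary()
    latent = gen_latent(cfg)
    streams = gen_comments(latent, dictionary, cfg)
    if with_eeg:
        recordings, gains = gen_eeg(latent, cfg)
    else:
        recordings, gains = [], {}
    selfreport = gen_selfreport(
        latent,
        n_raters=cfg.n_raters,
        noise_sd=cfg.selfreport_noise_sd,
        seed=cfg.seed,
        lag_s=cfg.selfreport_lag_s,
    )
    return SimulatedDataset(cfg, dictionary, latent, streams, recordings,
                            selfreport, gains)
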