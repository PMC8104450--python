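"""Synthetic multichannel speech-envelope generator with known ground truth.

Stands in for a speech corpus processed through a subcortical auditory model:
produces non-negative amplitude envelopes across auditory channels with
theta-band syllabic energy fluctuations, a channel-amplitude profile peaked
at mid ("vocalic") channels, and a paired phoneme/syllable transcription.
Because the generator controls syllable boundaries and phoneme intervals
exactly, entrainment and segmentation analyses can be validated against
ground truth without any external corpus.

Construction: a sentence is a sequence of syllables, each an (optional)
consonant interval followed by a vowel interval.  Each syllable contributes a
smooth high-amplitude envelope bump (the vocalic nucleus) centered at the
syllable midpoint, strongest at the designated mid-vocalic channel;
consonants contribute weaker, higher-channel transients.  Syllable durations
are lognormal around 1000/rate ms.  Speech onset occurs at 1 s; envelopes
are zero during the pre-speech baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SPEECH_ONSET = 1000.0  # ms of silence before the sentence starts

PHONEME_CLASSES = ("stop", "affricate", "fricative", "nasal",
                   "semivowel/glide", "vowel", "other")

# consonant classes cycled round-robin so class histograms are exercised
_CONSONANT_CYCLE = ("stop", "fricative", "nasal", "semivowel/glide",
                    "affricate")


def channel_center_frequencies() -> np.ndarray:
    """Center frequencies (kHz) of the 16 standard auditory channels."""
    return np.array([0.1, 0.13, 0.16, 0.21, 0.26, 0.33, 0.41, 0.55,
                     0.65, 0.82, 1.04, 1.31, 1.65, 2.07, 2.61, 3.29])


def full_channel_layout(n: int = 128, f_lo: float = 0.08,
                        f_hi: float = 8.0) -> np.ndarray:
    """A 128-channel cochlear-style layout (kHz, log-spaced)."""
    return np.geomspace(f_lo, f_hi, n)


def sub_bands(channels) -> list[np.ndarray]:
    """Partition a 128-channel layout into 8 contiguous 16-channel groups."""
    channels = np.asarray(channels)
    if channels.size % 16 != 0:
        raise ValueError("channel count must be divisible by 16")
    return [channels[i:i + 16] for i in range(0, channels.size, 16)]


@dataclass
class Transcription:
    """Phoneme intervals, syllable boundaries, and derived midpoints (ms).

    Phoneme intervals tile the sentence without overlap; midpoints are the
    averages of successive syllable boundaries.
    """

    phonemes: list            # (start, end, label, cls) tuples
    syllable_boundaries: np.ndarray

    @property
    def syllable_midpoints(self) -> np.ndarray:
        b = self.syllable_boundaries
        return 0.5 * (b[:-1] + b[1:])

    def phoneme_class_at(self, t: float) -> str:
        for start, end, _label, cls in self.phonemes:
            if start <= t < end:
                return cls
        return "other"

    # -- .PHN-style three-column text round trip ---------------------------

    def save_phn(self, path) -> None:
        with open(path, "w") as fh:
            for start, end, label, cls in self.phonemes:
                fh.write(f"{start:.3f} {end:.3f} {label}\n")

    def save_boundaries(self, path) -> None:
        np.savetxt(path, self.syllable_boundaries, fmt="%.3f")

    @classmethod
    def load_phn(cls, phn_path, boundaries_path) -> "Transcription":
        phonemes = []
        with open(phn_path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                start, end, label = float(parts[0]), float(parts[1]), parts[2]
                cls_name = label.split("_")[0]
                if cls_name not in PHONEME_CLASSES:
                    cls_name = "other"
                phonemes.append((start, end, label, cls_name))
        bounds = np.atleast_1d(np.loadtxt(boundaries_path, dtype=float))
        return cls(phonemes=phonemes, syllable_boundaries=bounds)


@dataclass
class SentenceEnvelopes:
    """Channel envelopes for one synthetic sentence."""

    envelopes: np.ndarray       # (n_channels, n_samples), non-negative
    channel_freqs: np.ndarray   # kHz labels
    dt: float                   # ms
    transcription: Transcription
    peak_channel: int
    seed: int

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.envelopes.shape[1]) * self.dt

    @property
    def duration(self) -> float:
        return self.envelopes.shape[1] * self.dt


def _channel_profile(n_channels: int, peak: int, width: float) -> np.ndarray:
    idx = np.arange(n_channels)
    return np.exp(-0.5 * ((idx - peak) / width) ** 2)


def generate_sentence(n_syllables: int, syllable_rate: float = 5.0,
                      channel_freqs=None, peak_channel: int = 5,
                      noise_level: float = 0.05, jitter_sigma: float = 0.3,
                      seed: int = 0, dt: float = 0.1,
                      consonant_fraction: float = 0.35,
                      consonant_level: float = 0.3,
                      profile_width: float = 2.0,
                      nucleus_width: float = 0.15,
                      tail: float = 300.0) -> SentenceEnvelopes:
    """Generate one synthetic sentence.

    ``syllable_rate`` (Hz, in [1, 13]) sets the median syllable duration
    1000/rate ms; ``jitter_sigma`` is the lognormal sigma of per-syllable
    duration jitter (0 = perfectly rhythmic).  ``peak_channel`` designates
    the mid-vocalic channel carrying the strongest nucleus energy.
    ``noise_level`` scales additive non-negative noise relative to the
    nucleus amplitude (1.0); ``nucleus_width`` is the Gaussian sigma of the
    vocalic bump as a fraction of the syllable duration.
    ``profile_width`` (channels) sets how sharply
    nucleus energy concentrates on the peak channel: ~2 emulates the full
    0.1-3.3 kHz channel spread, larger values a homogeneous mid-vocalic
    sub-band whose 16 adjacent channels all carry vocalic energy.
    """
    if n_syllables < 1:
        raise ValueError("need at least one syllable")
    if not 1.0 <= syllable_rate <= 13.0:
        raise ValueError("syllable rate must lie in [1, 13] Hz")
    if channel_freqs is None:
        channel_freqs = channel_center_frequencies()
    channel_freqs = np.asarray(channel_freqs, dtype=float)
    n_ch = channel_freqs.size
    if not 0 <= peak_channel < n_ch:
        raise ValueError("peak channel outside layout")
    rng = np.random.default_rng(seed)

    median_dur = 1000.0 / syllable_rate
    if jitter_sigma > 0:
        durs = median_dur * np.exp(rng.normal(0.0, jitter_sigma, n_syllables))
    else:
        durs = np.full(n_syllables, median_dur)
    if np.any(durs <= 0):
        raise ValueError("syllable durations must be positive")

    boundaries = SPEECH_ONSET + np.concatenate([[0.0], np.cumsum(durs)])
    duration = boundaries[-1] + tail
    n_samples = int(round(duration / dt))
    t = np.arange(n_samples) * dt

    vowel_profile = _channel_profile(n_ch, peak_channel, width=profile_width)
    cons_peak = min(n_ch - 1, peak_channel + 7)
    cons_profile = _channel_profile(n_ch, cons_peak, width=1.5 * profile_width)

    env = np.zeros((n_ch, n_samples))
    phonemes = []
    midpoints = 0.5 * (boundaries[:-1] + boundaries[1:])
    for i in range(n_syllables):
        start, end = boundaries[i], boundaries[i + 1]
        c_end = start + consonant_fraction * (end - start)
        cls = _CONSONANT_CYCLE[i % len(_CONSONANT_CYCLE)]
        phonemes.append((start, c_end, f"{cls}_{i}", cls))
        phonemes.append((c_end, end, f"vowel_{i}", "vowel"))
        # vocalic nucleus: Gaussian bump at the syllable midpoint
        sig_v = nucleus_width * (end - start)
        bump = np.exp(-0.5 * ((t - midpoints[i]) / sig_v) ** 2)
        env += vowel_profile[:, None] * bump[None, :]
        # consonant transient at the consonant-interval center
        c_mid = 0.5 * (start + c_end)
        sig_c = 0.10 * (c_end - start)
        cbump = np.exp(-0.5 * ((t - c_mid) / sig_c) ** 2)
        env += consonant_level * cons_profile[:, None] * cbump[None, :]

    if noise_level > 0:
        speech = t >= SPEECH_ONSET
        noise = np.abs(rng.normal(0.0, noise_level, (n_ch, n_samples)))
        env[:, speech] += noise[:, speech]
    env[:, t < SPEECH_ONSET] = 0.0

    # normalize as for pulse trains: the peak channel carries unit mean
    # input over the speech period (before gain); other channels scale
    # relative to it through the vocalic amplitude profile
    speech_mean = env[peak_channel, t >= SPEECH_ONSET].mean()
    if speech_mean > 0:
        env /= speech_mean

    trans = Transcription(phonemes=phonemes, syllable_boundaries=boundaries)
    return SentenceEnvelopes(envelopes=env, channel_freqs=channel_freqs,
                             dt=dt, transcription=trans,
                             peak_channel=peak_channel, seed=seed)


def save_envelopes(sentence: SentenceEnvelopes, path) -> None:
    """Delimited dump: first row channel labels (kHz), then one row per sample."""
    header = ",".join(f"{f:.4g}" for f in sentence.channel_freqs)
    np.savetxt(path, sentence.envelopes.T, delimiter=",", header=header,
               comments="# kHz: ")
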