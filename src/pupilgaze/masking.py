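"""Acoustic masker construction and SNR mixing for speech-in-noise stimuli.

Implements the two masker families used in listening-effort experiments:
multi-talker babble (averaging many random-order concatenations of the
sentence set) and envelope-modulated pink noise (the target sentence's
Hilbert amplitude envelope, 30 Hz low-pass Butterworth filtered, imposed on
1/f noise), plus RMS-based SNR mixing, lead/tail framing with short linear
ramps, and RMS normalization.

SNR here is the RMS power ratio 20*log10(RMS_target / RMS_masker), the
field's standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "Waveform",
    "MaskingConfig",
    "amplitude_envelope",
    "pink_noise",
    "make_env_pink_masker",
    "make_babble",
    "mix_at_snr",
    "frame_with_noise",
    "rms_normalize",
    "rms",
    "measure_snr_db",
    "read_wav",
    "write_wav",
]


@dataclass
class Waveform:
    """A mono waveform: sampling rate in Hz and float samples (nominal ±1)."""

    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class MaskingConfig:
    """Masker-construction parameters (study defaults)."""

    snr_db: float = 0.0
    env_lp_cutoff_hz: float = 30.0
    env_lp_order: int = 4
    lead_s: float = 3.0
    tail_s: float = 1.2
    ramp_s: float = 0.01
    babble_n: int = 30

    def validate(self) -> None:
        if not (self.ramp_s < self.lead_s and self.ramp_s < self.tail_s):
            raise ValueError("ramp_s must be shorter than lead_s and tail_s")
        if self.env_lp_cutoff_hz <= 0 or self.env_lp_order < 1:
            raise ValueError("invalid envelope filter parameters")


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def measure_snr_db(target: Waveform, masker: Waveform) -> float:
    """RMS-based SNR in dB over the common span of target and masker."""
    n = min(len(target), len(masker))
    rt = rms(target.samples[:n])
    rm = rms(masker.samples[:n])
    if rm == 0:
        raise ValueError("masker has zero RMS; SNR undefined")
    return 20.0 * np.log10(rt / rm)


def amplitude_envelope(w: Waveform, cfg: MaskingConfig | None = None) -> np.ndarray:
    """Low-pass-filtered Hilbert amplitude envelope of *w*.

    Magnitude of the analytic signal, zero-phase Butterworth low-pass
    filtered at ``cfg.env_lp_cutoff_hz``; negative excursions produced by
    filtering are clipped to 0.
    """
    cfg = cfg or MaskingConfig()
    if w.sampling_rate <= 2 * cfg.env_lp_cutoff_hz:
        raise ValueError(
            f"sampling rate {w.sampling_rate} Hz too low for a "
            f"{cfg.env_lp_cutoff_hz} Hz envelope cutoff")
    env = np.abs(hilbert(w.samples))
    sos = butter(cfg.env_lp_order, cfg.env_lp_cutoff_hz,
                 btype="low", fs=w.sampling_rate, output="sos")
    env = sosfiltfilt(sos, env)
    return np.clip(env, 0.0, None)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise via spectral shaping."""
    n_freq = n // 2 + 1
    mag = np.zeros(n_freq)
    mag[1:] = 1.0 / np.sqrt(np.arange(1, n_freq))
    phase = rng.uniform(0, 2 * np.pi, size=n_freq)
    spec = mag * np.exp(1j * phase)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    r = rms(x)
    return x / r if r > 0 else x


def make_env_pink_masker(target: Waveform, cfg: MaskingConfig | None = None,
                         seed: int | None = None) -> Waveform:
    """Pink noise carrying the target sentence's amplitude envelope.

    The masker is unique to the target (same length), so the instantaneous
    masking level tracks the sentence energy. Deterministic given *seed*.
    """
    if len(target) == 0:
        raise ValueError("target waveform is empty")
    cfg = cfg or MaskingConfig()
    env = amplitude_envelope(target, cfg)
    rng = np.random.default_rng(seed)
    pink = pink_noise(len(target), rng)
    return Waveform(target.sampling_rate, pink * env)


def make_babble(sentences: list[Waveform], n_streams: int = 30,
                seed: int | None = None) -> Waveform:
    """Multi-talker babble: average of random-order sentence concatenations.

    Each of *n_streams* streams concatenates the full sentence set in an
    independent random order; streams are truncated to the shortest and
    averaged samplewise. The result has the long-term spectrum of the
    sentence material and a relatively flat envelope.
    """
    if not sentences:
        raise ValueError("need at least one sentence")
    rates = {s.sampling_rate for s in sentences}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    rng = np.random.default_rng(seed)
    streams = []
    for _ in range(n_streams):
        order = rng.permutation(len(sentences))
        streams.append(np.concatenate([sentences[i].samples for i in order]))
    n = min(s.size for s in streams)
    babble = np.mean([s[:n] for s in streams], axis=0)
    return Waveform(rates.pop(), babble)


def mix_at_snr(target: Waveform, masker: Waveform, snr_db: float,
               mode: str = "scale_target") -> Waveform:
    """Mix target and masker at an exact RMS-based SNR.

    The designated component (``scale_target`` or ``scale_masker``) is
    rescaled so that 20*log10(RMS_target/RMS_masker) over the overlap equals
    *snr_db* exactly; the return value is the rescaled sum.
    """
    if len(target) != len(masker):
        raise ValueError("target and masker must have equal length")
    if target.sampling_rate != masker.sampling_rate:
        raise ValueError("target and masker must share a sampling rate")
    rm = rms(masker.samples)
    if rm == 0:
        raise ValueError("masker has zero RMS over the target span")
    rt = rms(target.samples)
    if rt == 0:
        raise ValueError("target has zero RMS; SNR undefined")
    current = 20.0 * np.log10(rt / rm)
    if mode == "scale_target":
        gain = 10.0 ** ((snr_db - current) / 20.0)
        mixed = target.samples * gain + masker.samples
    elif mode == "scale_masker":
        gain = 10.0 ** ((current - snr_db) / 20.0)
        mixed = target.samples + masker.samples * gain
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Waveform(target.sampling_rate, mixed)


def frame_with_noise(mix: Waveform, masker: Waveform,
                     cfg: MaskingConfig | None = None) -> Waveform:
    """Frame the sentence-span mixture with masker-only lead and tail.

    The output is ``lead_s`` of masker, then *mix* unchanged, then
    ``tail_s`` of masker, with the masker faded in over the first
    ``ramp_s`` and out over the last ``ramp_s`` (linear ramps). Sample
    counts: lead = round(lead_s*fs), tail = round(tail_s*fs); total length
    is exactly lead + len(mix) + tail.
    """
    cfg = cfg or MaskingConfig()
    cfg.validate()
    fs = mix.sampling_rate
    if masker.sampling_rate != fs:
        raise ValueError("mix and masker must share a sampling rate")
    lead = int(round(cfg.lead_s * fs))
    tail = int(round(cfg.tail_s * fs))
    total = lead + len(mix) + tail
    if len(masker) < total:
        raise ValueError(
            f"masker too short: {len(masker)} samples < {total} needed")
    out = np.empty(total)
    out[:lead] = masker.samples[:lead]
    out[lead:lead + len(mix)] = mix.samples
    out[lead + len(mix):] = masker.samples[lead + len(mix):total]
    n_ramp = int(round(cfg.ramp_s * fs))
    if n_ramp > 1:
        out[:n_ramp] *= np.linspace(0.0, 1.0, n_ramp)
        out[-n_ramp:] *= np.linspace(1.0, 0.0, n_ramp)
    return Waveform(fs, out)


def rms_normalize(w: Waveform, target_rms: float) -> Waveform:
    """Rescale so the output RMS equals *target_rms* (rel. tol. 1e-9)."""
    r = rms(w.samples)
    if r == 0:
        raise ValueError("cannot RMS-normalize a silent waveform")
    return Waveform(w.sampling_rate, w.samples * (target_rms / r))


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------


def read_wav(path) -> Waveform:
    fs, x = wavfile.read(path)
    x = np.asarray(x)
    if x.ndim == 2:  # average channels to mono
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(float) / float(np.iinfo(x.dtype).max)
    return Waveform(float(fs), x.astype(float))


def write_wav(w: Waveform, path) -> None:
    wavfile.write(path, int(round(w.sampling_rate)),
                  w.samples.astype(np.float32))
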