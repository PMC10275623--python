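"""Random binned-spectrum stimuli and their audio synthesis.

A stimulus is a random on/off pattern over the mel bins: the number of
"filled" bins is drawn uniformly from {min_filled, ..., max_filled}
(defaults 2..7 of 8), the filled subset uniformly without replacement.
Filled bins carry 0 dB power, unfilled bins -100 dB.  The waveform is
synthesized by assigning each positive FFT frequency the magnitude of its
bin, giving every component an i.i.d. uniform random phase, and taking the
real inverse transform, then peak-normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .binning import BinPartition, BinnedSpectrum

__all__ = [
    "StimulusSpec",
    "Waveform",
    "generate_stimulus",
    "generate_stimulus_batch",
    "synthesize_waveform",
    "export_stimulus_wav",
    "read_wav",
]

FILLED_DB = 0.0
UNFILLED_DB = -100.0


@dataclass
class StimulusSpec:
    """One random stimulus: the filled-bin mask and its dB pattern."""

    binned: BinnedSpectrum
    filled_mask: np.ndarray  # bool, length b
    stimulus_id: str
    seed_state: dict

    @property
    def mask_string(self) -> str:
        """The mask as a 0/1 string (manifest encoding)."""
        return "".join("1" if m else "0" for m in self.filled_mask)


@dataclass
class Waveform:
    """A finite, peak-bounded audio signal."""

    samples: np.ndarray
    sample_rate: float
    duration: float

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        n = int(round(self.sample_rate * self.duration))
        if x.shape != (n,):
            raise ValueError(
                f"expected {n} samples for {self.duration}s @ {self.sample_rate}Hz, "
                f"got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("waveform samples must be finite")
        if np.max(np.abs(x), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("waveform peak must not exceed 1")
        self.samples = x


def generate_stimulus_batch(
    partition: BinPartition,
    n: int,
    rng: np.random.Generator,
    min_filled: int = 2,
    max_filled: int = 7,
    filled_db: float = FILLED_DB,
    unfilled_db: float = UNFILLED_DB,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` stimuli at once; returns (power_db (n,b), masks (n,b) bool).

    Vectorized form of the stimulus model: per row, a filled count uniform
    on {min_filled..max_filled}, then a uniformly random subset of that
    size.  Rows are the Psi rows used by the estimator.
    """
    b = partition.b
    if not (1 <= min_filled <= max_filled <= b):
        raise ValueError(
            f"need 1 <= min_filled <= max_filled <= b, "
            f"got [{min_filled}, {max_filled}] with b={b}"
        )
    counts = rng.integers(min_filled, max_filled + 1, size=n)
    # Uniform random subset of each size: rank the bins by i.i.d. uniforms
    # and fill the `count` lowest-ranked ones.
    ranks = np.argsort(rng.random((n, b)), axis=1).argsort(axis=1)
    masks = ranks < counts[:, None]
    power = np.where(masks, filled_db, unfilled_db)
    return power, masks


def generate_stimulus(
    partition: BinPartition,
    rng: np.random.Generator,
    min_filled: int = 2,
    max_filled: int = 7,
    filled_db: float = FILLED_DB,
    unfilled_db: float = UNFILLED_DB,
    stimulus_id: str = "stim",
    seed_state: dict | None = None,
) -> StimulusSpec:
    """Draw one random stimulus (see module docstring for the model)."""
    power, masks = generate_stimulus_batch(
        partition, 1, rng, min_filled, max_filled, filled_db, unfilled_db
    )
    return StimulusSpec(
        binned=BinnedSpectrum(partition=partition, power_db=power[0]),
        filled_mask=masks[0],
        stimulus_id=stimulus_id,
        seed_state=seed_state or {},
    )


def _spectral_magnitudes(
    binned: BinnedSpectrum, sample_rate: float, n_samples: int
) -> np.ndarray:
    """One-sided magnitude spectrum on the rFFT grid of an n-sample frame.

    Positive frequencies inside [f_lo, f_hi] take 10^(dB/20) of their bin;
    frequencies outside the partition, DC, and Nyquist are zero.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    idx = binned.partition.bin_index(freqs)
    mag = np.where(idx >= 0, 10.0 ** (binned.power_db[np.maximum(idx, 0)] / 20.0), 0.0)
    mag[0] = 0.0  # DC
    mag[-1] = 0.0  # Nyquist (n even)
    return mag


def synthesize_waveform(
    spec: StimulusSpec | BinnedSpectrum,
    sample_rate: float = 44100.0,
    duration: float = 0.5,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Random-phase inverse-FFT synthesis of a binned spectrum.

    Builds the one-sided spectrum with per-bin magnitudes 10^(dB/20) and
    i.i.d. uniform [0, 2*pi) phases, inverse-transforms, and peak-normalizes.
    ``sample_rate * duration`` must be an even integer so the one-sided
    spectrum has a well-defined Nyquist sample.
    """
    binned = spec.binned if isinstance(spec, StimulusSpec) else spec
    n_float = sample_rate * duration
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n % 2 != 0:
        raise ValueError(
            f"sample_rate * duration must be an even integer, got {n_float}"
        )
    if rng is None:
        rng = np.random.default_rng()
    mag = _spectral_magnitudes(binned, sample_rate, n)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=mag.size)
    spectrum = mag * np.exp(1j * phase)
    spectrum[0] = 0.0
    spectrum[-1] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return Waveform(samples=x, sample_rate=sample_rate, duration=duration)


def export_stimulus_wav(
    wave: Waveform, path: str | Path, subtype: str = "float32"
) -> Path:
    """Write a mono WAV file (IEEE float32 by default, or PCM-16)."""
    path = Path(path)
    if subtype == "float32":
        data = wave.samples.astype(np.float32)
    elif subtype == "pcm16":
        data = np.clip(np.round(wave.samples * 32767.0), -32768, 32767).astype(np.int16)
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")
    wavfile.write(path, int(wave.sample_rate), data)
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float samples in [-1, 1] plus its sample rate.

    Integer PCM is rescaled to full-scale float; multi-channel audio is
    averaged to mono.
    """
    rate, data = wavfile.read(Path(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, float(rate)
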