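"""Generate one random mel-binned stimulus and synthesize its waveform.

Builds the default 8-bin mel partition of [100, 13000] Hz, draws a random
filled-bin pattern (2-7 bins at 0 dB, the rest at -100 dB), synthesizes
the 500 ms random-phase waveform, and verifies by analysis that the
waveform's binned periodogram reproduces the generating mask.
"""

import tempfile
from pathlib import Path

import numpy as np

from revcorr import (
    bin_dense_spectrum,
    export_stimulus_wav,
    generate_stimulus,
    make_mel_partition,
    periodogram_db,
    synthesize_waveform,
)

partition = make_mel_partition(100.0, 13000.0, 8)
print("bin edges (Hz):", np.round(partition.edges, 1))

rng = np.random.default_rng(0)
stim = generate_stimulus(partition, rng, stimulus_id="demo-000")
print("filled mask   :", stim.mask_string, f"({stim.filled_mask.sum()} bins at 0 dB)")

wave = synthesize_waveform(stim, sample_rate=44100, duration=0.5, rng=rng)
print("waveform      :", wave.samples.size, "samples, peak",
      round(float(np.max(np.abs(wave.samples))), 3))

with tempfile.TemporaryDirectory() as tmp:
    path = export_stimulus_wav(wave, Path(tmp) / "demo-000.wav")
    print("wrote         :", path.name)

# analysis-by-synthesis: the binned periodogram should separate filled
# from unfilled bins by far more than 60 dB
binned = bin_dense_spectrum(periodogram_db(wave.samples, 44100), partition)
contrast = (binned.power_db[stim.filled_mask].min()
            - binned.power_db[~stim.filled_mask].max())
print("fill contrast :", round(float(contrast), 1),
      "dB between quietest filled and loudest unfilled bin")
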