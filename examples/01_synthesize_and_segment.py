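"""Generate stylized cry audio, write it to WAV, and segment it into epochs.

The 5-s non-overlapping epoch is the unit everything downstream works on:
annotation, feature extraction, classification and the cry-sequence
biomarkers all live on this grid.
"""

import tempfile
from pathlib import Path

from crydetect import load_wav, segment_epochs, synth_cry, write_wav

cry = synth_cry(duration=17.0, seed=1)
print(f"synthesized {cry.duration:.1f}s of cry audio at {cry.sample_rate} Hz")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cry.wav"
    write_wav(cry, path)
    reloaded = load_wav(path)
    epochs = segment_epochs(reloaded)

print(f"{len(epochs)} whole 5-s epochs; the trailing "
      f"{reloaded.duration - 5 * len(epochs):.1f}s remainder is discarded")
for ep in epochs:
    print(f"  epoch {ep.index}: [{ep.start_time:.0f}, {ep.start_time + 5:.0f})s, "
          f"{ep.samples.size} samples")
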