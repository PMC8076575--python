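"""Robustness-based feature screening on perturbed re-recordings.

The same clips are re-"recorded" under attenuation (distance analogue),
low-pass filtering (barrier analogue) and added background noise, and any
feature whose mean or spread shifts under any condition is excluded.
Gain-sensitive features (raw energies) go; gain-invariant ones (voicing,
ZCR, MFCC shape) mostly survive.
"""

from crydetect.feature_screen import apply_screen
from crydetect.pipeline import extract_clip_features, make_corpus, screen_corpus

clips, labels = make_corpus(n_cry=25, n_noncry=30, seed=5)
matrix = extract_clip_features(clips)
report = screen_corpus(clips, matrix, seed=5)

total = len(report.retained) + len(report.excluded)
print(f"screened {total} features against 3 conditions: "
      f"{report.n_retained} retained, {len(report.excluded)} excluded")

by_family = {}
for name in report.retained:
    fam = name.split("_")[0].rstrip("0123456789")
    by_family[fam] = by_family.get(fam, 0) + 1
print("retained by LLD family:", dict(sorted(by_family.items())))

screened = apply_screen(matrix, report)
print(f"training matrix now {screened.shape[0]} epochs x "
      f"{screened.shape[1] - 1} features (plus epoch_index)")
example = report.excluded[0]
print(f"\nexample exclusion: {example} -> {report.details[example]['reason']}")
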