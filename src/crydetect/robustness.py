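"""Cumulative-cry-count robustness analysis.

Repeatability and robustness of the detector are judged by running it on
repeated or perturbed versions of the same session and comparing the
running total of cry-labeled epochs (the cumulative cry count curve)
against the reference curve from the ground-truth annotation. A purely
software pipeline is deterministic, so repeated runs on identical input
must coincide exactly; perturbation conditions (attenuation for distance,
low-pass for barriers, added background for ambient noise) probe how far
the final cry count drifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSignal
from .features import DEFAULT_REGISTRY, extract_features
from .synth import condition_label, perturb


@dataclass
class CumulativeCryCurve:
    label: str
    counts: np.ndarray  # prefix sums of the binary epoch labels

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        steps = np.diff(np.concatenate([[0], self.counts]))
        if self.counts.size and not np.isin(steps, (0, 1)).all():
            raise ValueError("cumulative curve must increase in unit steps")

    @property
    def final(self) -> int:
        return int(self.counts[-1]) if self.counts.size else 0

    def __len__(self) -> int:
        return self.counts.size


def cumulative_curve(labels, label: str = "") -> CumulativeCryCurve:
    """Prefix-sum curve of a binary epoch label series."""
    arr = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return CumulativeCryCurve(label=label, counts=np.cumsum(arr))


def compare_runs(reference: CumulativeCryCurve, runs) -> list[dict]:
    """Per-run deviation report against a reference curve."""
    out = []
    for run in runs:
        if len(run) != len(reference):
            raise ValueError(
                f"run '{run.label}' has {len(run)} epochs, reference {len(reference)}"
            )
        dev = run.counts - reference.counts
        abs_dev = np.abs(dev)
        argmax = int(np.argmax(abs_dev)) if abs_dev.size else 0
        out.append(
            {
                "label": run.label,
                "final_count": run.final,
                "final_delta": run.final - reference.final,
                "max_abs_deviation": int(abs_dev.max()) if abs_dev.size else 0,
                "epoch_of_max_deviation": argmax,
            }
        )
    return out


def run_conditions(
    session: AudioSignal,
    truth_labels,
    model,
    conditions,
    seed: int = 0,
    registry=DEFAULT_REGISTRY,
) -> list[CumulativeCryCurve]:
    """Detect crying under each perturbation condition of one session.

    Returns the ground-truth reference curve first, then one predicted
    curve per condition (an empty condition dict means the unperturbed
    session). Errors in any stage are re-raised with the condition named.
    """
    from .classify import predict_epochs

    curves = [cumulative_curve(truth_labels, label="reference")]
    for condition in conditions:
        label = condition_label(condition) if condition else "unperturbed"
        try:
            audio = perturb(session, condition, seed=seed) if condition else session
            matrix = extract_features(audio, registry)
            pred, _ = predict_epochs(model, matrix)
        except Exception as exc:
            raise RuntimeError(f"robustness condition '{label}' failed: {exc}") from exc
        curves.append(cumulative_curve(pred, label=label))
    return curves
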