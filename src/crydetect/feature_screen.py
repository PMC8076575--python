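"""Robustness-based feature screening.

The same audio re-recorded under different ambient conditions (distance,
barriers, background noise) should yield identical feature distributions;
features that shift are fragile and are excluded before training. The
screen makes that judgment explicit and reproducible: for every feature
and every condition it computes a standardized mean difference (SMD)
against the reference recording and the ratio of standard deviations, and
excludes the feature if, in ANY condition, |SMD| exceeds a threshold or
the SD ratio leaves a band. Worst-case (any-condition) exclusion matches
the intent that a feature must be robust under all conditions, not on
average.

SMD = |mean_c - mean_ref| / pooled_SD with
pooled_SD = sqrt((SD_ref^2 + SD_c^2) / 2), population SDs. A feature with
zero pooled SD is excluded iff the means differ (a constant that moves is
maximally fragile; a constant that stays put is harmless).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DEFAULT_REGISTRY, FeatureRegistry

DEFAULT_SMD_THRESHOLD = 0.5
DEFAULT_SD_RATIO_BOUNDS = (0.5, 2.0)
MIN_EPOCHS_WARN = 10


@dataclass
class ConditionFeatureSet:
    """A feature matrix extracted from one re-recording condition."""

    condition_label: str
    matrix: pd.DataFrame
    registry: FeatureRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)

    @property
    def features(self) -> pd.DataFrame:
        return self.matrix[list(self.registry.names)]


@dataclass
class ScreenReport:
    """Per-feature retention decision with per-condition evidence."""

    retained: list[str]
    excluded: list[str]
    details: dict[str, dict]
    smd_threshold: float
    sd_ratio_bounds: tuple[float, float]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "smd_threshold": self.smd_threshold,
            "sd_ratio_bounds": list(self.sd_ratio_bounds),
            "retained": self.retained,
            "excluded": self.excluded,
            "details": self.details,
        }

    def save(self, path: str | Path, **extra) -> None:
        payload = {**extra, **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScreenReport":
        d = json.loads(Path(path).read_text())
        return cls(
            retained=list(d["retained"]),
            excluded=list(d["excluded"]),
            details=d.get("details", {}),
            smd_threshold=d["smd_threshold"],
            sd_ratio_bounds=tuple(d["sd_ratio_bounds"]),
        )


def _check_compatible(reference: ConditionFeatureSet, conditions) -> None:
    ref_names = tuple(reference.registry.names)
    n_ref = len(reference.matrix)
    for cond in conditions:
        if tuple(cond.registry.names) != ref_names:
            raise ValueError(
                f"condition '{cond.condition_label}' uses a different feature registry"
            )
        if len(cond.matrix) != n_ref:
            raise ValueError(
                f"condition '{cond.condition_label}' has {len(cond.matrix)} epochs, "
                f"reference has {n_ref}; re-recordings must share the epoch grid"
            )


def screen_features(
    reference: ConditionFeatureSet,
    conditions,
    smd_threshold: float = DEFAULT_SMD_THRESHOLD,
    sd_ratio_bounds: tuple[float, float] = DEFAULT_SD_RATIO_BOUNDS,
) -> ScreenReport:
    """Screen every registry feature for distributional stability.

    A feature is excluded iff for ANY condition the standardized mean
    difference exceeds ``smd_threshold`` or SD_cond/SD_ref falls outside
    ``sd_ratio_bounds``.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("screening requires at least one condition set")
    _check_compatible(reference, conditions)
    if len(reference.matrix) < MIN_EPOCHS_WARN:
        import warnings

        warnings.warn(
            f"screening with only {len(reference.matrix)} epochs per set; "
            "mean/SD estimates will be unstable",
            stacklevel=2,
        )

    names = list(reference.registry.names)
    ref = reference.features.to_numpy(dtype=np.float64)
    ref_mean = ref.mean(axis=0)
    ref_sd = ref.std(axis=0)

    lo, hi = sd_ratio_bounds
    retained_mask = np.ones(len(names), dtype=bool)
    details: dict[str, dict] = {name: {"conditions": {}} for name in names}

    for cond in conditions:
        x = cond.features.to_numpy(dtype=np.float64)
        mean_c = x.mean(axis=0)
        sd_c = x.std(axis=0)
        pooled = np.sqrt((ref_sd**2 + sd_c**2) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            smd = np.abs(mean_c - ref_mean) / pooled
            ratio = sd_c / ref_sd
        # zero pooled SD: exclude iff means differ
        zero_pool = pooled == 0.0
        smd[zero_pool] = np.where(mean_c[zero_pool] == ref_mean[zero_pool], 0.0, np.inf)
        # SD ratio conventions: 0/0 -> 1 (both constant); >0/0 -> inf
        ratio[(ref_sd == 0.0) & (sd_c == 0.0)] = 1.0
        ratio[(ref_sd == 0.0) & (sd_c > 0.0)] = np.inf

        mean_bad = smd > smd_threshold
        sd_bad = (ratio < lo) | (ratio > hi)
        retained_mask &= ~(mean_bad | sd_bad)
        for j, name in enumerate(names):
            details[name]["conditions"][cond.condition_label] = {
                "smd": float(smd[j]) if np.isfinite(smd[j]) else None,
                "sd_ratio": float(ratio[j]) if np.isfinite(ratio[j]) else None,
                "mean_unstable": bool(mean_bad[j]),
                "sd_unstable": bool(sd_bad[j]),
            }

    retained, excluded = [], []
    for j, name in enumerate(names):
        if retained_mask[j]:
            retained.append(name)
            details[name]["retained"] = True
            details[name]["reason"] = "stable across all conditions"
        else:
            excluded.append(name)
            conds = details[name]["conditions"]
            bad = [
                f"{label} ({'mean' if info['mean_unstable'] else 'sd'})"
                for label, info in conds.items()
                if info["mean_unstable"] or info["sd_unstable"]
            ]
            details[name]["retained"] = False
            details[name]["reason"] = "unstable in: " + ", ".join(bad)
    return ScreenReport(
        retained=retained,
        excluded=excluded,
        details=details,
        smd_threshold=smd_threshold,
        sd_ratio_bounds=tuple(sd_ratio_bounds),
    )


def apply_screen(matrix: pd.DataFrame, report: ScreenReport) -> pd.DataFrame:
    """Restrict a feature matrix to the retained columns, order preserved."""
    missing = [n for n in report.retained + report.excluded if n not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks screened features: {missing[:5]}...")
    if not report.retained:
        raise ValueError("screen retained no features; refusing an empty feature set")
    meta = [c for c in ("epoch_index", "start_time_s") if c in matrix.columns]
    return matrix[meta + report.retained]
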