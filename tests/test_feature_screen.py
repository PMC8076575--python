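import numpy as np
import pandas as pd
import pytest

from crydetect.feature_screen import (
    ConditionFeatureSet,
    ScreenReport,
    apply_screen,
    screen_features,
)
from crydetect.features import FUNCTIONAL_NAMES, FeatureRegistry


def toy_registry(n_features):
    # one pseudo-LLD per feature with a single functional keeps names simple
    return FeatureRegistry(
        llds=tuple(f"f{i}" for i in range(n_features)), functionals=("mean",)
    )


def gaussian_set(label, registry, n_epochs, rng, shift=None, scale=None):
    names = list(registry.names)
    x = rng.standard_normal((n_epochs, len(names)))
    if shift is not None:
        x += shift
    if scale is not None:
        x *= scale
    return ConditionFeatureSet(label, pd.DataFrame(x, columns=names), registry)


def test_identical_conditions_retain_everything():
    rng = np.random.default_rng(0)
    reg = toy_registry(30)
    ref = gaussian_set("reference", reg, 100, np.random.default_rng(1))
    same = ConditionFeatureSet("same", ref.matrix.copy(), reg)
    report = screen_features(ref, [same])
    assert report.excluded == []
    assert report.retained == list(reg.names)


def test_single_shifted_feature_is_excluded():
    reg = toy_registry(20)
    rng = np.random.default_rng(2)
    ref = gaussian_set("reference", reg, 200, rng)
    cond_matrix = ref.matrix.copy()
    cond_matrix[reg.names[7]] += 3.0  # +3 SD shift on one feature
    cond = ConditionFeatureSet("shifted", cond_matrix, reg)
    report = screen_features(ref, [cond])
    assert report.excluded == [reg.names[7]]


def test_planted_instability_simulation():
    """100 features, 20 planted unstable: all caught, <=10% false exclusions."""
    reg = toy_registry(100)
    names = list(reg.names)
    planted_mean = names[:10]
    planted_sd = names[10:20]
    stable = names[20:]
    false_rates = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        ref = gaussian_set("reference", reg, 300, rng)
        cond_matrix = pd.DataFrame(
            rng.standard_normal((300, 100)), columns=names
        )
        cond_matrix[planted_mean] += 1.0  # 1 SD mean shift
        cond_matrix[planted_sd] *= 3.0  # SD ratio 3
        report = screen_features(ref, [ConditionFeatureSet("bad", cond_matrix, reg)])
        assert set(planted_mean + planted_sd) <= set(report.excluded)
        false_rates.append(
            len([n for n in stable if n in report.excluded]) / len(stable)
        )
    assert max(false_rates) <= 0.10


def test_zero_variance_features():
    reg = toy_registry(2)
    names = list(reg.names)
    ref = ConditionFeatureSet(
        "reference", pd.DataFrame({names[0]: [1.0] * 50, names[1]: [2.0] * 50}), reg
    )
    cond = ConditionFeatureSet(
        "cond", pd.DataFrame({names[0]: [1.0] * 50, names[1]: [5.0] * 50}), reg
    )
    report = screen_features(ref, [cond])
    assert names[0] in report.retained  # constant, identical: harmless
    assert names[1] in report.excluded  # constant that moved: fragile


def test_threshold_monotonicity():
    """A looser SMD threshold never excludes what a stricter one retained."""
    reg = toy_registry(50)
    rng = np.random.default_rng(3)
    ref = gaussian_set("reference", reg, 80, rng)
    cond = gaussian_set("cond", reg, 80, rng, shift=rng.uniform(0, 1, 50))
    strict = screen_features(ref, [cond], smd_threshold=0.3)
    loose = screen_features(ref, [cond], smd_threshold=0.8)
    assert set(strict.retained) <= set(loose.retained)


def test_contract_errors():
    reg = toy_registry(5)
    rng = np.random.default_rng(4)
    ref = gaussian_set("reference", reg, 50, rng)
    other_reg = toy_registry(6)
    with pytest.raises(ValueError, match="registry"):
        screen_features(ref, [gaussian_set("c", other_reg, 50, rng)])
    with pytest.raises(ValueError, match="epoch"):
        screen_features(ref, [gaussian_set("c", reg, 49, rng)])
    with pytest.raises(ValueError, match="at least one"):
        screen_features(ref, [])
    with pytest.warns(UserWarning, match="unstable"):
        small_ref = gaussian_set("reference", reg, 5, rng)
        screen_features(small_ref, [gaussian_set("c", reg, 5, rng)])


def test_apply_screen_identity_and_subset():
    reg = toy_registry(10)
    rng = np.random.default_rng(5)
    ref = gaussian_set("reference", reg, 60, rng)
    all_retained = screen_features(
        ref, [ConditionFeatureSet("same", ref.matrix.copy(), reg)]
    )
    out = apply_screen(ref.matrix, all_retained)
    pd.testing.assert_frame_equal(out, ref.matrix)

    none_retained = ScreenReport(
        retained=[], excluded=list(reg.names), details={},
        smd_threshold=0.5, sd_ratio_bounds=(0.5, 2.0),
    )
    with pytest.raises(ValueError, match="empty feature set"):
        apply_screen(ref.matrix, none_retained)
    with pytest.raises(ValueError, match="lacks"):
        apply_screen(ref.matrix.iloc[:, :3], all_retained)


def test_attenuation_only_screen_retains_gain_invariant_features():
    """Pure attenuation cannot unsettle gain-invariant LLD functionals."""
    from crydetect.features import DEFAULT_REGISTRY, FUNCTIONAL_NAMES
    from crydetect.pipeline import extract_clip_features
    from crydetect.synth import perturb, synth_cry, synth_noncry

    clips = [synth_cry(5.0, seed=s) for s in range(6)] + [
        synth_noncry("white_noise", 5.0, seed=s) for s in range(6)
    ]
    ref = ConditionFeatureSet(
        "reference", extract_clip_features(clips), DEFAULT_REGISTRY
    )
    att = ConditionFeatureSet(
        "attenuated",
        extract_clip_features([perturb(c, {"attenuate_db": 6.0}) for c in clips]),
        DEFAULT_REGISTRY,
    )
    report = screen_features(ref, [att])
    for lld in ("zcr", "voicing", "f0"):
        for fn in FUNCTIONAL_NAMES:
            assert f"{lld}_{fn}" in report.retained


def test_report_json_round_trip(tmp_path):
    reg = toy_registry(8)
    rng = np.random.default_rng(6)
    ref = gaussian_set("reference", reg, 60, rng)
    cond_matrix = ref.matrix.copy()
    cond_matrix[reg.names[2]] *= 5.0
    report = screen_features(ref, [ConditionFeatureSet("c", cond_matrix, reg)])
    path = tmp_path / "screen.json"
    report.save(path)
    loaded = ScreenReport.load(path)
    assert loaded.retained == report.retained
    assert loaded.excluded == report.excluded
    assert loaded.smd_threshold == report.smd_threshold
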