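"""Statistical feature extraction, fusion, and the feature table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painlab.core import Epoch, EpochSet, InputError
from painlab.features import (
    FEATURE_NAMES,
    build_feature_table,
    extract_feature_vector,
    fuse_features,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: direct loop translation of the formulas


def naive_features(h):
    import math

    n = len(h)
    d = [h[i + 1] - h[i] for i in range(n - 1)]
    m = len(d)
    f1 = sum(math.log(max(x * x, 1e-300)) for x in h)
    peak = max(abs(x) for x in h)
    rms = math.sqrt(sum(x * x for x in h) / n)
    am = sum(abs(x) for x in h) / n
    mean_h = sum(h) / n
    var_h = sum((x - mean_h) ** 2 for x in h) / n
    mean_d = sum(d) / m
    var_d = sum((x - mean_d) ** 2 for x in d) / m
    dd = [d[i + 1] - d[i] for i in range(m - 1)]
    mean_dd = sum(dd) / len(dd)
    var_dd = sum((x - mean_dd) ** 2 for x in dd) / len(dd)
    mob = math.sqrt(var_d / var_h)
    mob_d = math.sqrt(var_dd / var_d)
    return {
        "log_energy": f1,
        "crest_factor": peak / rms,
        "shape_factor": rms / am,
        "impulse_factor": peak / am,
        "margin_factor": peak / am**2,
        "mobility": mob,
        "complexity": mob_d / mob,
        "mad_first_derivative": sum(abs(x - mean_d) for x in d) / m,
        "range": max(h) - min(h),
        "variation_first_derivative": var_d,
    }


def test_matches_naive_oracle_on_random_epochs(rng):
    for _ in range(100):
        h = rng.normal(scale=rng.uniform(0.1, 10), size=rng.integers(10, 200))
        got = extract_feature_vector(h).values
        want = naive_features(h.tolist())
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-10), name


# ---------------------------------------------------------------------------


def test_ramp_epoch_derivative_features_vanish():
    v = extract_feature_vector([0.0, 1.0, 2.0, 3.0])
    assert v.values["range"] == pytest.approx(3.0)
    assert v.values["mad_first_derivative"] == pytest.approx(0.0)
    assert v.values["variation_first_derivative"] == pytest.approx(0.0)
    # constant derivative: complexity undefined (0/0), flagged
    assert "complexity" in v.undefined


def test_sine_analytic_limits():
    # peak 1, rms 1/sqrt(2), abs-mean 2/pi for a continuous sinusoid
    t = np.arange(1000) / 1000.0
    v = extract_feature_vector(np.sin(2 * np.pi * t)).values
    assert v["crest_factor"] == pytest.approx(np.sqrt(2), rel=0.01)
    assert v["shape_factor"] == pytest.approx(np.pi / (2 * np.sqrt(2)), rel=0.01)


def test_constant_epoch_flags_and_unit_ratios():
    v = extract_feature_vector([5.0, 5.0, 5.0, 5.0])
    assert v.values["crest_factor"] == pytest.approx(1.0)
    assert v.values["shape_factor"] == pytest.approx(1.0)
    assert v.values["impulse_factor"] == pytest.approx(1.0)
    assert v.values["range"] == 0.0
    assert {"mobility", "complexity"} <= set(v.undefined)
    assert not v.ok


def test_too_short_epoch_rejected():
    with pytest.raises(InputError):
        extract_feature_vector([1.0, 2.0])


@settings(max_examples=30, deadline=None)
@given(a=st.floats(min_value=0.01, max_value=1000))
def test_scaling_behaviour(a):
    rng = np.random.default_rng(7)
    h = rng.normal(size=100)
    base = extract_feature_vector(h).values
    scaled = extract_feature_vector(a * h).values
    for name in ("crest_factor", "shape_factor", "impulse_factor", "mobility", "complexity"):
        assert scaled[name] == pytest.approx(base[name], rel=1e-9), name
    assert scaled["margin_factor"] == pytest.approx(base["margin_factor"] / a, rel=1e-9)
    for name in ("mad_first_derivative", "range"):
        assert scaled[name] == pytest.approx(a * base[name], rel=1e-9), name
    assert scaled["variation_first_derivative"] == pytest.approx(
        a**2 * base["variation_first_derivative"], rel=1e-9
    )


def test_offset_behaviour(rng):
    h = rng.normal(size=100)
    base = extract_feature_vector(h).values
    shifted = extract_feature_vector(h + 50.0).values
    # derivative- and range-based features are offset-invariant
    for name in (
        "mobility",
        "complexity",
        "mad_first_derivative",
        "range",
        "variation_first_derivative",
    ):
        assert shifted[name] == pytest.approx(base[name], rel=1e-9), name
    # amplitude-ratio features are not
    for name in ("crest_factor", "shape_factor", "impulse_factor", "margin_factor"):
        assert shifted[name] != pytest.approx(base[name], rel=1e-6), name


def test_ratio_invariants(rng):
    for _ in range(20):
        v = extract_feature_vector(rng.normal(size=50)).values
        assert v["crest_factor"] >= 1.0
        assert v["shape_factor"] >= 1.0
        assert v["impulse_factor"] >= v["crest_factor"] - 1e-12
        assert v["range"] >= 0.0
        assert v["mobility"] >= 0.0


# ---------------------------------------------------------------------------
# fusion and table


def _vec(subject="S01", onset=60.0, values=None):
    from painlab.features import FeatureVector

    vals = values or {name: float(i) for i, name in enumerate(FEATURE_NAMES)}
    return FeatureVector(vals, subject_id=subject, class_label="LP", onset_s=onset)


def test_fusion_yields_20_named_values_hbo2_first():
    row = fuse_features(_vec(), _vec())
    assert len(row) == 20
    names = list(row)
    assert names[:10] == [f"{n}_hbo2" for n in FEATURE_NAMES]
    assert names[10:] == [f"{n}_hhb" for n in FEATURE_NAMES]


def test_fusing_a_vector_with_itself_duplicates_values():
    row = fuse_features(_vec(), _vec())
    for name in FEATURE_NAMES:
        assert row[f"{name}_hbo2"] == row[f"{name}_hhb"]


def test_fusion_errors(rng):
    with pytest.raises(InputError):
        fuse_features(_vec(), None)
    with pytest.raises(InputError, match="mismatched"):
        fuse_features(_vec(subject="S01"), _vec(subject="S02"))
    with pytest.raises(InputError, match="mismatched"):
        fuse_features(_vec(onset=60.0), _vec(onset=70.0))


def _epochset(n_epochs, subject="S01", rng=None, constant=False):
    rng = rng or np.random.default_rng(0)
    es = EpochSet(epoch_duration=10.0, sampling_rate=50.0)
    for i in range(n_epochs):
        series = np.full(500, 1.0) if constant else rng.normal(size=500)
        es.epochs.append(
            Epoch(series, "LP", "LA", subject, onset_s=60.0 + 10.0 * i)
        )
    return es


def test_table_shapes_per_mode(rng):
    a = _epochset(5, rng=np.random.default_rng(1))
    b = _epochset(5, rng=np.random.default_rng(2))
    fused = build_feature_table(a, b, mode="fused")
    assert fused.shape == (5, 22)
    single = build_feature_table(a, None, mode="hbo2")
    assert single.shape == (5, 12)
    assert list(single.columns[:2]) == ["subject", "class"]


def test_degenerate_epochs_dropped_not_propagated():
    a = _epochset(2, constant=True)
    table = build_feature_table(a, None, mode="hbo2")
    assert len(table) == 0
    assert list(table.columns) == ["subject", "class"] + list(FEATURE_NAMES)


def test_misaligned_epoch_sets_rejected():
    a = _epochset(3, subject="S01")
    b = _epochset(3, subject="S02")
    with pytest.raises(InputError, match="misaligned"):
        build_feature_table(a, b, mode="fused")


def test_empty_epoch_set_gives_header_only():
    empty = EpochSet()
    table = build_feature_table(empty, EpochSet(), mode="fused")
    assert len(table) == 0
    assert len(table.columns) == 22
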