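import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from branchsight.pvalues import AdjustmentConfig, adjust, bh_fdr, mass_at_one, robust_fdr

from _oracles import stepup_bh_reference


def test_mass_at_one_examples():
    assert mass_at_one([1, 1, 0.3, 1], tolerance=1e-12) == pytest.approx(0.75)
    assert mass_at_one([0.5] * 10) == 0.0
    with pytest.raises(ValueError):
        mass_at_one([])


def test_adjust_modes():
    p = np.array([1.0, 0.3, 1.0, 0.7])
    assert adjust(p, "halve")[0] == 0.5
    assert np.array_equal(adjust(p, "none"), p)
    with pytest.raises(ValueError):
        adjust(p, "bogus")


def test_scale_by_nonzero_fraction_worked_example():
    """With 33% of the p-values below 1, p = 0.3 scales to 0.099."""
    p = np.concatenate([np.full(67, 1.0), np.full(32, 0.6), [0.3]])
    assert np.mean(p < 1) == pytest.approx(0.33)
    scaled = adjust(p, "scale_by_nonzero_fraction")
    assert scaled[-1] == pytest.approx(0.099)


@given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_adjust_preserves_ranking(p):
    p = np.array(p)
    for mode in ("halve", "scale_by_nonzero_fraction"):
        a = adjust(p, mode)
        assert np.array_equal(np.argsort(p, kind="stable"), np.argsort(a, kind="stable"))


def test_bh_hand_enumeration():
    """Step-up on [0.01, 0.02, 0.03, 0.5] at 5%: thresholds are
    0.0125/0.025/0.0375/0.05, so the first three are rejected."""
    rejected, q = bh_fdr([0.01, 0.02, 0.03, 0.5], alpha=0.05)
    assert rejected.tolist() == [True, True, True, False]
    assert np.all(np.diff(q[np.argsort([0.01, 0.02, 0.03, 0.5])]) >= 0)
    none_rej, _ = bh_fdr([1.0, 1.0, 1.0], alpha=0.05)
    assert none_rej.sum() == 0


def test_bh_rejections_grow_with_alpha():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200) ** 2
    r1, _ = bh_fdr(p, 0.01)
    r2, _ = bh_fdr(p, 0.10)
    assert (r1 & ~r2).sum() == 0


def test_bh_agrees_with_stepup_reference():
    """1,000 random vectors against an independent step-up rule."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(1, 40)
        p = rng.uniform(size=n)
        if rng.random() < 0.3:
            p[: n // 2] **= 4  # inject signal
        alpha = rng.uniform(0.01, 0.2)
        got, _ = bh_fdr(p, alpha)
        assert np.array_equal(got, stepup_bh_reference(p, alpha))


def test_robust_fdr_null_behavior():
    """On uniform p-values the smallest decile's estimates exceed the
    raw p-values: no signal means no enrichment."""
    rng = np.random.default_rng(1)
    p = rng.uniform(size=1000)
    out = robust_fdr(p, cutoff=1.0)
    decile = p <= np.quantile(p, 0.1)
    assert (out.rfdr[decile] > p[decile]).all()


def test_robust_fdr_strong_signal():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(size=900), np.full(100, 1e-6)])
    out = robust_fdr(p)
    assert (out.rfdr[900:] < 0.05).all()
    # not grossly more conservative than BH on the same pool
    _, q = bh_fdr(p, 0.05)
    assert (out.rfdr[900:] <= 5 * q[900:] + 1e-12).all()


def test_robust_fdr_monotone_and_exclusions():
    rng = np.random.default_rng(3)
    p = np.concatenate([rng.uniform(size=300), [0.985, 0.999, 1.0]])
    out = robust_fdr(p, cutoff=0.98)
    assert out.excluded.sum() == (p >= 0.98).sum() >= 3
    assert np.isnan(out.rfdr[out.excluded]).all()
    included = out[~out.excluded].sort_values("p")
    assert np.all(np.diff(included.rfdr) >= -1e-12)
    with pytest.raises(ValueError):
        robust_fdr([0.99, 1.0], cutoff=0.98)


def test_adjustment_config_validation():
    with pytest.raises(ValueError):
        AdjustmentConfig(alpha=1.5)
    with pytest.raises(ValueError):
        AdjustmentConfig(truncation_cutoff=0.0)
    cfg = AdjustmentConfig(truncation_cutoff=0.5)
    out = robust_fdr(np.linspace(0.01, 0.99, 50), config=cfg)
    assert out.excluded.sum() == (np.linspace(0.01, 0.99, 50) >= 0.5).sum()


def test_adjustment_table_schema_and_consistency():
    from branchsight.pvalues import adjustment_table

    p = np.array([0.01, 0.5, 1.0, 0.99])
    table = adjustment_table(["g1", "g2", "g3", "g4"], ["A"] * 4, p)
    assert list(table.columns) == [
        "gene_id", "branch", "p_raw", "p_halved", "p_scaled", "bh_q", "rfdr",
        "excluded_flag",
    ]
    assert np.array_equal(table.p_halved, p / 2)
    assert table.excluded_flag.tolist() == [False, False, True, True]
    assert np.isnan(table.rfdr[2])
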