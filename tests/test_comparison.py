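import itertools

import numpy as np
import pytest
from scipy import stats

import germeval as ge
from germeval.errors import ValidationError

from conftest import make_table


def _two_groups(a, b):
    values = np.concatenate([a, b])
    groups = np.array(["g1"] * len(a) + ["g2"] * len(b), dtype=object)
    return values, groups


# -- ANOVA --------------------------------------------------------------


def test_identical_groups_f_zero():
    v, g = _two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    f, p = ge.one_way_anova(v, g)
    assert f == 0.0
    assert p == 1.0


def test_constant_equal_groups_defined_as_zero():
    v, g = _two_groups([5.0, 5.0], [5.0, 5.0])
    assert ge.one_way_anova(v, g) == (0.0, 1.0)


def test_large_shift_detected():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, 40)
    b = rng.normal(10.0, 1.0, 40)  # 10-SD shift
    _, p = ge.one_way_anova(*_two_groups(a, b))
    assert p < 1e-4


def test_f_equals_t_squared_for_two_groups():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 25)
    b = rng.normal(0.5, 1, 25)
    f, p_f = ge.one_way_anova(*_two_groups(a, b))
    t, p_t = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-10)


def test_anova_affine_invariance():
    rng = np.random.default_rng(4)
    v = rng.normal(size=60)
    g = np.array(["a", "b", "c"] * 20, dtype=object)
    f0, _ = ge.one_way_anova(v, g)
    f1, _ = ge.one_way_anova(3.5 * v + 100.0, g)
    assert f1 == pytest.approx(f0, rel=1e-9)


def test_small_group_rejected():
    v = np.array([1.0, 2.0, 3.0])
    g = np.array(["a", "a", "b"], dtype=object)
    with pytest.raises(ValidationError, match="'b'"):
        ge.one_way_anova(v, g)
    with pytest.raises(ValidationError, match="2 groups"):
        ge.one_way_anova(np.array([1.0, 2.0]), np.array(["a", "a"], dtype=object))


# -- Tukey HSD ----------------------------------------------------------


def test_tukey_identical_groups_p_one():
    v, g = _two_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    _, p = ge.tukey_hsd(v, g)
    assert p[0, 1] >= 0.999
    assert np.array_equal(np.diag(p), np.ones(2))


def test_tukey_two_groups_reduces_to_t_test():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 18)
    b = rng.normal(0.8, 1, 12)  # unbalanced on purpose
    _, pmat = ge.tukey_hsd(*_two_groups(a, b))
    _, p_t = stats.ttest_ind(a, b)
    assert pmat[0, 1] == pytest.approx(p_t, abs=1e-6)


def test_tukey_three_group_pattern():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        v = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(5, 1, 30)]
        )
        g = np.array(["g1"] * 30 + ["g2"] * 30 + ["g3"] * 30, dtype=object)
        _, p = ge.tukey_hsd(v, g)
        if p[0, 2] < 0.05 and p[1, 2] < 0.05 and p[0, 1] >= 0.05:
            hits += 1
    assert hits >= 19


def test_tukey_matches_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(6)
    sizes = (12, 25, 8)
    v = np.concatenate([rng.normal(m, 1.2, n) for m, n in zip((0, 0.7, 1.5), sizes)])
    g = np.concatenate([[f"g{i}"] * n for i, n in enumerate(sizes)]).astype(object)
    levels, p = ge.tukey_hsd(v, g)
    sm = pairwise_tukeyhsd(v, g)
    sm_p = {}
    for row in sm.summary().data[1:]:
        sm_p[(str(row[0]), str(row[1]))] = float(row[3])
    for (i, a), (j, b) in itertools.combinations(enumerate(levels), 2):
        assert p[i, j] == pytest.approx(sm_p[(a, b)], abs=2e-3)


def test_tukey_p_monotone_in_mean_difference():
    rng = np.random.default_rng(7)
    base = rng.normal(0, 1, 30)
    other = rng.normal(0, 1, 30)
    last_p = 1.1
    for shift in (0.0, 0.5, 1.0, 1.5, 2.0):
        _, p = ge.tukey_hsd(*_two_groups(base, other + shift))
        assert p[0, 1] <= last_p + 1e-12
        last_p = p[0, 1]


# -- compact letter display --------------------------------------------


def _sig(pairs, k):
    m = np.zeros((k, k), dtype=bool)
    for i, j in pairs:
        m[i, j] = m[j, i] = True
    return m


def test_cld_trivial_cases():
    lv = ("x", "y", "z")
    means = [3.0, 2.0, 1.0]
    assert ge.compact_letter_display(_sig([], 3), lv, means) == ("a", "a", "a")
    assert ge.compact_letter_display(
        _sig([(0, 1), (0, 2), (1, 2)], 3), lv, means
    ) == ("a", "b", "c")
    assert ge.compact_letter_display(_sig([(0, 2)], 3), lv, means) == ("a", "ab", "b")


@pytest.mark.parametrize("k", [3, 4])
def test_cld_letter_sharing_matches_matrix_exhaustively(k):
    """Levels share a letter iff they are not significantly different,
    for every possible significance pattern."""
    pairs = list(itertools.combinations(range(k), 2))
    levels = tuple(f"l{i}" for i in range(k))
    means = list(range(k, 0, -1))
    for bits in itertools.product([False, True], repeat=len(pairs)):
        sig = _sig([p for p, b in zip(pairs, bits) if b], k)
        letters = ge.compact_letter_display(sig, levels, means)
        for i, j in pairs:
            share = bool(set(letters[i]) & set(letters[j]))
            assert share != sig[i, j], (bits, letters)


def test_cld_rejects_bad_matrix():
    m = np.zeros((3, 3), dtype=bool)
    m[0, 1] = True  # asymmetric
    with pytest.raises(ValidationError):
        ge.compact_letter_display(m, ("a", "b", "c"))


def test_anova_with_letters_consistency():
    rng = np.random.default_rng(8)
    v = np.concatenate([rng.normal(m, 1, 25) for m in (0.0, 0.2, 4.0)])
    g = np.array(["g1"] * 25 + ["g2"] * 25 + ["g3"] * 25, dtype=object)
    res = ge.anova_with_letters(v, g, trait_code="protein", alpha=0.05)
    assert res.p_value < 0.001
    by_level = dict(zip(res.levels, res.letters))
    assert set(by_level["g1"]) & set(by_level["g2"])
    assert not set(by_level["g1"]) & set(by_level["g3"])
    # best mean carries letter 'a'
    best = res.levels[int(np.argmax(res.group_means))]
    assert "a" in by_level[best]


# -- per-trait counts ---------------------------------------------------


def test_count_significant_traits_recovers_planted_23():
    """Origin shifts of >= 1 SD planted on exactly 23 of the 26
    nutritional traits are all detected (fixed seed)."""
    cfg = ge.default_config(seed=42)
    cfg.origin_effects[:] = 0.0
    cfg.period_effects[:] = 0.0
    reg = cfg.registry
    nutritional = reg.nutritional_codes
    planted = nutritional[:23]
    null = nutritional[23:]
    sds = cfg.trait_sds
    for code in planted:
        j = reg.index(code)
        cfg.origin_effects[3, j] = 1.2 * sds[j]   # NIR up
        cfg.origin_effects[5, j] = -1.2 * sds[j]  # FOR down
    table, _ = ge.generate(cfg)
    count, flags = ge.count_significant_traits(table, "origin", alpha=0.05)
    assert all(flags[c] for c in planted)
    assert count == 23  # no false positive on the 3 null traits this seed
    assert [c for c in null if flags[c]] == []


def test_count_significant_null_calibration():
    """With no planted effects the per-trait false-positive rate sits
    near alpha (uncorrected by design)."""
    total = 0
    n_seeds = 40
    for seed in range(n_seeds):
        cfg = ge.default_config(seed=1000 + seed)
        cfg.origin_effects[:] = 0.0
        cfg.period_effects[:] = 0.0
        table, _ = ge.generate(cfg)
        count, _ = ge.count_significant_traits(table, "origin", alpha=0.05)
        total += count
    rate = total / (n_seeds * 26)
    assert 0.02 <= rate <= 0.09


def test_count_requires_valid_grouping(small_table):
    with pytest.raises(ValidationError):
        ge.count_significant_traits(small_table, grouping="species")


def test_count_single_level_errors():
    table = make_table(n=8)
    table.origin[:] = "YZR"
    with pytest.raises(ValidationError):
        ge.count_significant_traits(table, "origin")
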