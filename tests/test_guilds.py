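from itertools import chain, combinations

import numpy as np
import pytest

from chipsip.errors import InsufficientDataError
from chipsip.guilds import (GUILD_COPIOTROPH, GUILD_INTERMEDIATE, GUILD_NULL,
                            GUILD_OTHER, GUILDS, ancova_concentration_effect,
                            assign_guild, classify_guild, posthoc_pairs,
                            rank_activity)
from chipsip.isotope import HceEstimate

from conftest import make_table, taxon_spots


def make_est(taxon, slope):
    return HceEstimate(taxon_id=taxon, treatment="H", slope=slope,
                       slope_se=0.1, intercept=0.0, n_spots=10,
                       r_squared=0.9, enriched=True, mean_delta=slope * 30)


class TestRankActivity:
    def test_half_max_threshold(self):
        classes, report = rank_activity([make_est(t, v) for t, v in
                                         [("a", 10.0), ("b", 6.0), ("c", 1.0)]])
        by = {c.taxon_id: c.activity for c in classes}
        assert by == {"a": "HIGH", "b": "HIGH", "c": "LOW"}
        assert report.attrs["cutoff"] == pytest.approx(5.0)
        # percent-change series: 40% from 10 to 6, 83.3% from 6 to 1
        assert report["pct_change"].tolist()[1:] == pytest.approx([40.0, 250 / 3])

    def test_all_equal_all_high(self):
        classes, _ = rank_activity([make_est(t, 4.0) for t in "abcd"])
        assert all(c.activity == "HIGH" for c in classes)

    def test_empty_input(self):
        classes, report = rank_activity([])
        assert classes == [] and report.empty

    def test_lognormal_counts_match_threshold_scan(self, rng):
        values = rng.lognormal(0.0, 1.0, 107)
        classes, _ = rank_activity([make_est(f"t{i}", v)
                                    for i, v in enumerate(values)])
        n_high = sum(c.activity == "HIGH" for c in classes)
        assert n_high == int(np.sum(values >= 0.5 * values.max()))


class TestAncova:
    def test_identical_groups_no_effect(self):
        rows = [(f"p{j}", "A", t, float(j + 1), 10.0 * (j + 1))
                for t in "HML" for j in range(5)]
        res = ancova_concentration_effect(make_table(rows))
        assert res.p_value == pytest.approx(1.0)
        assert not res.partial

    def test_separated_slopes_detected(self, rng):
        hits = 0
        reps = 500
        for _ in range(reps):
            spots = taxon_spots(rng, (10.0, 5.0, 1.0), n_spots=20, noise_sd=1.0)
            hits += ancova_concentration_effect(spots).p_value < 0.05
        assert hits / reps >= 0.99

    def test_two_treatments_flagged_partial(self, rng):
        spots = taxon_spots(rng, (10.0, 5.0, 1.0), n_spots=10)
        spots = spots[spots["treatment"] != "M"]
        res = ancova_concentration_effect(spots)
        assert res.partial
        assert res.levels == ("H", "L")

    def test_single_treatment_raises(self, rng):
        spots = taxon_spots(rng, (10.0, 5.0, 1.0), n_spots=10)
        with pytest.raises(InsufficientDataError):
            ancova_concentration_effect(spots[spots["treatment"] == "H"])

    def test_intercept_only_model_detects_offset(self, rng):
        spots = taxon_spots(rng, (5.0, 5.0, 5.0), n_spots=20, noise_sd=1.0)
        shifted = spots.copy()
        shifted.loc[shifted["treatment"] == "L", "delta_permil"] -= 100.0
        res = ancova_concentration_effect(shifted, model="intercept")
        assert res.p_value < 0.05


class TestPosthocPairs:
    def test_clearly_separated_all_pairs(self, rng):
        spots = taxon_spots(rng, (10.0, 5.0, 1.0), n_spots=20, noise_sd=1.0)
        pairs = posthoc_pairs(spots, overall_p=0.001)
        assert pairs == {("H", "M"), ("H", "L"), ("M", "L")}

    def test_equal_high_medium(self, rng):
        # H and M identical by construction, both far above L
        hits_hm = 0
        for _ in range(50):
            spots = taxon_spots(rng, (10.0, 10.0, 1.0), n_spots=20, noise_sd=1.0)
            pairs = posthoc_pairs(spots, overall_p=0.001)
            assert ("H", "L") in pairs and ("M", "L") in pairs
            hits_hm += ("H", "M") in pairs
        assert hits_hm <= 10  # (H,M) false-positive rate stays near alpha

    def test_gate_on_overall_p(self, rng):
        spots = taxon_spots(rng, (10.0, 5.0, 1.0), n_spots=20, noise_sd=1.0)
        assert posthoc_pairs(spots, overall_p=0.2) == frozenset()

    def test_reversed_direction_never_significant(self, rng):
        # incorporation increasing toward LOW concentration: inadmissible
        spots = taxon_spots(rng, (1.0, 5.0, 10.0), n_spots=20, noise_sd=1.0)
        assert posthoc_pairs(spots, overall_p=0.001) == frozenset()

    def test_holm_is_more_conservative(self, rng):
        for _ in range(20):
            spots = taxon_spots(rng, (10.0, 8.0, 6.0), n_spots=10, noise_sd=30.0)
            plain = posthoc_pairs(spots, overall_p=0.001, correction="none")
            holm = posthoc_pairs(spots, overall_p=0.001, correction="holm")
            assert holm <= plain


def powerset(items):
    return chain.from_iterable(combinations(items, r)
                               for r in range(len(items) + 1))


class TestClassifyGuild:
    def test_nonsignificant_is_null(self):
        assert classify_guild("t", 0.2, frozenset()).guild == GUILD_NULL

    def test_full_separation_is_copiotroph(self):
        pairs = frozenset({("H", "M"), ("H", "L"), ("M", "L")})
        assert classify_guild("t", 0.001, pairs).guild == GUILD_COPIOTROPH

    def test_saturating_at_high_is_intermediate(self):
        pairs = frozenset({("H", "L"), ("M", "L")})
        assert classify_guild("t", 0.001, pairs).guild == GUILD_INTERMEDIATE

    @pytest.mark.parametrize("pairs,expected", [
        (frozenset(), GUILD_OTHER),                       # significant, no pair
        ({("H", "M")}, GUILD_OTHER),                      # H>M≈L pattern
        ({("H", "M"), ("H", "L")}, GUILD_OTHER),
        ({("M", "L")}, GUILD_INTERMEDIATE),
        ({("H", "L")}, GUILD_INTERMEDIATE),
        ({("H", "M"), ("M", "L")}, GUILD_COPIOTROPH),
    ])
    def test_decision_table(self, pairs, expected):
        assert classify_guild("t", 0.001, frozenset(pairs)).guild == expected

    def test_total_and_deterministic(self):
        """Every (p, pairs) combination maps to exactly one valid label."""
        all_pairs = [("H", "M"), ("H", "L"), ("M", "L")]
        for p in (0.001, 0.04999, 0.05, 0.9):
            for subset in powerset(all_pairs):
                a = classify_guild("t", p, frozenset(subset))
                b = classify_guild("t", p, frozenset(subset))
                assert a.guild == b.guild
                assert a.guild in GUILDS
                if p >= 0.05:
                    assert a.guild == GUILD_NULL


class TestAssignGuild:
    @pytest.mark.parametrize("slopes,expected", [
        ((10.0, 10.0, 10.0), GUILD_NULL),
        ((10.0, 10.0, 2.0), GUILD_INTERMEDIATE),
        ((10.0, 5.0, 1.0), GUILD_COPIOTROPH),
        ((10.0, 2.0, 2.0), GUILD_OTHER),
    ])
    def test_recovers_constructed_pattern(self, slopes, expected):
        rng = np.random.default_rng(hash(slopes) % 2**31)
        spots = taxon_spots(rng, slopes, n_spots=20, noise_sd=1.0)
        assert assign_guild(spots).guild == expected
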