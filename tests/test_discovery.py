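"""The three detectors: worked examples, symmetries, oracle equivalence."""
from __future__ import annotations

import numpy as np
import pytest

from _oracle import calls_by_loop, hwe_false_positive_probs
from conftest import A, H, N, R, build_catalog, make_sex_map, random_catalog
from gbsex.discovery import (
    DiscoveryConfig,
    Method,
    Pattern,
    Verdict,
    aggregate_tags,
    detect_freq,
    detect_het,
    detect_pa,
    snp_method_overlap,
)
from gbsex.model import ValidationError
from gbsex.sexstats import SexCounts, SiteSexStats, compute_site_stats

CFG = DiscoveryConfig()


def counts(n_hom_ref, n_het, n_hom_alt):
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return SexCounts(0, 0, 0, 0, None, None)
    fr = (2 * n_hom_ref + n_het) / (2 * n)
    return SexCounts(n, n_hom_ref, n_het, n_hom_alt, fr, 1 - fr)


def site(female, male):
    return SiteSexStats("t:0", "t", "A", "G", female, male)


class TestDetectFreq:
    def test_canonical_xy_site_is_called(self):
        st = site(female=counts(10, 0, 0), male=counts(0, 10, 0))
        (call,) = detect_freq([st], CFG)
        assert call.pattern is Pattern.XY and call.method is Method.FREQ
        assert call.stats["divergence"] == pytest.approx(0.5)
        assert call.stats["sex_specific_allele"] == "G"

    def test_divergence_below_threshold_is_not_called(self):
        # female REF freq 19/20 = 0.95; male REF freq 28/50 = 0.56 -> 0.39
        st = site(female=counts(9, 1, 0), male=counts(14, 0, 11))
        assert detect_freq([st], CFG) == []

    def test_divergence_exactly_at_threshold_is_called(self):
        # male REF freq 11/20 = 0.55 -> divergence exactly 0.40 (inclusive)
        st = site(female=counts(9, 1, 0), male=counts(5, 1, 4))
        (call,) = detect_freq([st], CFG)
        assert call.pattern is Pattern.XY

    def test_zw_mirror(self):
        st = site(female=counts(0, 10, 0), male=counts(10, 0, 0))
        (call,) = detect_freq([st], CFG)
        assert call.pattern is Pattern.ZW

    def test_sites_below_min_called_are_skipped(self):
        st = site(female=counts(1, 0, 0), male=counts(0, 10, 0))
        assert detect_freq([st], CFG) == []

    def test_tied_sex_cannot_anchor_fixation(self):
        # the female 50:50 tie blocks the XY clause; the male-side fixation
        # still legitimately satisfies the ZW mirror
        st = site(female=counts(5, 0, 5), male=counts(10, 0, 0))
        calls = detect_freq([st], CFG)
        assert [c.pattern for c in calls] == [Pattern.ZW]

    def test_both_patterns_fire_on_opposite_fixation(self):
        # near-fixation of different alleles in the two sexes satisfies both
        # clauses; the tag resolves to AMBIGUOUS downstream
        st = site(female=counts(10, 0, 0), male=counts(0, 0, 10))
        calls = detect_freq([st], CFG)
        assert {c.pattern for c in calls} == {Pattern.XY, Pattern.ZW}


class TestDetectHet:
    def test_canonical_xy_pattern(self):
        st = site(female=counts(10, 0, 0), male=counts(0, 10, 0))
        (call,) = detect_het([st], CFG)
        assert call.pattern is Pattern.XY
        assert call.stats["hom_prop"] == 1.0 and call.stats["het_prop"] == 1.0

    def test_fifty_fifty_boundary_emits_both_patterns(self):
        st = site(female=counts(5, 5, 0), male=counts(5, 5, 0))
        calls = detect_het([st], CFG)
        assert {c.pattern for c in calls} == {Pattern.XY, Pattern.ZW}

    def test_zw_mirror(self):
        st = site(female=counts(0, 10, 0), male=counts(10, 0, 0))
        (call,) = detect_het([st], CFG)
        assert call.pattern is Pattern.ZW

    def test_hom_alt_counts_as_homozygous(self):
        st = site(female=counts(4, 0, 6), male=counts(0, 10, 0))
        (call,) = detect_het([st], CFG)
        assert call.pattern is Pattern.XY


class TestDetectPA:
    def pa_catalog(self, male_present, female_present):
        sm = make_sex_map(10, 10)
        geno = [R if i < male_present else N for i in range(10)]
        geno += [R if i < female_present else N for i in range(10)]
        return build_catalog({"t": [(0, "A", "G", geno)]}, sm), sm

    def test_male_limited_tag_called_xy(self):
        cat, sm = self.pa_catalog(male_present=6, female_present=0)
        (call,) = detect_pa(cat, sm, CFG)
        assert call.pattern is Pattern.XY and call.site_id is None

    def test_single_female_recovery_vetoes_call(self):
        cat, sm = self.pa_catalog(male_present=5, female_present=1)
        assert detect_pa(cat, sm, CFG) == []

    def test_female_limited_tag_called_zw(self):
        cat, sm = self.pa_catalog(male_present=0, female_present=5)
        (call,) = detect_pa(cat, sm, CFG)
        assert call.pattern is Pattern.ZW

    def test_presence_below_half_not_called(self):
        cat, sm = self.pa_catalog(male_present=4, female_present=0)
        assert detect_pa(cat, sm, CFG) == []


class TestAggregate:
    def test_two_methods_one_tag_union(self):
        sm = make_sex_map(10, 10)
        geno = [H] * 10 + [R] * 10
        cat = build_catalog(
            {"t": [(0, "A", "G", list(geno)), (7, "C", "T", list(geno))]}, sm
        )
        stats = compute_site_stats(cat, sm)
        calls = detect_freq(stats, CFG) + detect_het(stats, CFG)
        (tc,) = aggregate_tags(calls, cat)
        assert tc.verdict is Verdict.XY
        assert tc.methods_found == {Method.FREQ, Method.HET}
        assert snp_method_overlap(calls)["n_shared_snps"] == 2

    def test_conflicting_patterns_make_ambiguous(self):
        sm = make_sex_map(10, 10)
        xy = [H] * 10 + [R] * 10
        zw = [R] * 10 + [H] * 10
        cat = build_catalog({"t": [(0, "A", "G", xy), (5, "C", "T", zw)]}, sm)
        stats = compute_site_stats(cat, sm)
        calls = detect_freq(stats, CFG)
        (tc,) = aggregate_tags(calls, cat)
        assert tc.verdict is Verdict.AMBIGUOUS

    def test_no_calls_empty(self):
        assert aggregate_tags([], None) == []


def all_calls(cat, sm, cfg=CFG):
    stats = compute_site_stats(cat, sm)
    return detect_freq(stats, cfg) + detect_het(stats, cfg) + detect_pa(cat, sm, cfg)


def as_tuples(calls):
    return {
        (c.tag_id, c.site_id, c.method.value, c.pattern.value) for c in calls
    }


def test_sex_swap_maps_every_call_to_its_mirror():
    rng = np.random.default_rng(23)
    for _ in range(5):
        cat, sm = random_catalog(rng, n_tags=30, n_males=6, n_females=6)
        direct = as_tuples(all_calls(cat, sm))
        flip = {"XY": "ZW", "ZW": "XY"}
        mirrored = {
            (t, s, m, flip[p]) for (t, s, m, p) in as_tuples(all_calls(cat, sm.swapped()))
        }
        assert direct == mirrored


def test_brute_force_oracle_agrees_on_random_catalogs():
    rng = np.random.default_rng(29)
    for _ in range(5):
        cat, sm = random_catalog(rng, n_tags=40, n_males=5, n_females=7)
        assert as_tuples(all_calls(cat, sm)) == calls_by_loop(cat, sm, CFG)


def test_raising_thresholds_never_adds_calls():
    rng = np.random.default_rng(31)
    cat, sm = random_catalog(rng, n_tags=60)
    stats = compute_site_stats(cat, sm)
    base_freq = as_tuples(detect_freq(stats, CFG))
    base_pa = as_tuples(detect_pa(cat, sm, CFG))
    for cfg in (
        DiscoveryConfig(divergence_min=0.6),
        DiscoveryConfig(fixation_min=0.99),
        DiscoveryConfig(fixation_min=1.0, divergence_min=0.9),
    ):
        assert as_tuples(detect_freq(stats, cfg)) <= base_freq
    for cfg in (
        DiscoveryConfig(presence_prop_min=0.8),
        DiscoveryConfig(presence_prop_min=1.0),
    ):
        assert as_tuples(detect_pa(cat, sm, cfg)) <= base_pa


def test_one_sex_all_missing_skipped_by_snp_methods_but_pa_eligible():
    sm = make_sex_map(10, 10)
    geno = [R] * 6 + [N] * 4 + [N] * 10  # called in 6 males, no females
    cat = build_catalog({"t": [(0, "A", "G", geno)]}, sm)
    stats = compute_site_stats(cat, sm)
    assert detect_freq(stats, CFG) == [] and detect_het(stats, CFG) == []
    (call,) = detect_pa(cat, sm, CFG)
    assert call.pattern is Pattern.XY


def test_config_validation_rejects_out_of_range():
    with pytest.raises(ValidationError):
        DiscoveryConfig(fixation_min=1.01)
    with pytest.raises(ValidationError):
        DiscoveryConfig(presence_prop_min=0.0)
    with pytest.raises(ValidationError):
        DiscoveryConfig(min_called_per_sex=0)


def test_autosomal_false_positive_rate_within_exact_hwe_bound():
    """On clean HWE autosomal data the per-pattern false-positive count must
    stay within the exactly enumerated binomial expectation."""
    from gbsex.simulate import SimConfig, TagClass, simulate_catalog

    cfg = SimConfig(
        seed=101, n_auto_tags=300, n_sexlinked_tags=0, n_sexlimited_tags=0,
        n_opposite_noise_tags=0, genotype_error=0.0, missing_rate=0.0,
    )
    res = simulate_catalog(cfg)
    stats = compute_site_stats(res.catalog, res.sex_map)
    calls = detect_freq(stats, CFG) + detect_het(stats, CFG)
    observed: dict = {}
    for c in calls:
        observed[(c.method.value, c.pattern.value)] = (
            observed.get((c.method.value, c.pattern.value), 0) + 1
        )
    mean = {k: 0.0 for k in (("FREQ", "XY"), ("FREQ", "ZW"), ("HET", "XY"), ("HET", "ZW"))}
    var = dict(mean)
    for truth in res.truth.tags.values():
        for q in truth.mafs.values():
            probs = hwe_false_positive_probs(q, cfg.n_females, cfg.n_males, CFG)
            for k, p in probs.items():
                mean[k] += p
                var[k] += p * (1 - p)
    for k in mean:
        bound = mean[k] + 4 * np.sqrt(var[k]) + 2
        assert observed.get(k, 0) <= bound, (k, observed.get(k, 0), bound)
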