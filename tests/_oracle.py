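"""Independent brute-force oracles for the detection criteria.

Everything here re-derives expected results from raw genotypes with plain
Python loops and first-principles enumeration, deliberately avoiding the
package's own statistics/discovery code paths.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

from gbsex.model import Genotype, Sex


def site_stats_by_loop(genotypes, sexes):
    """Recount one site by direct enumeration.

    genotypes: iterable of Genotype codes; sexes: matching iterable of Sex.
    Returns {sex: dict} with counts and ref frequency (None if no calls).
    """
    out = {}
    for sex in (Sex.FEMALE, Sex.MALE):
        hom_ref = het = hom_alt = 0
        for g, s in zip(genotypes, sexes):
            if s is not sex:
                continue
            if g == Genotype.HOM_REF:
                hom_ref += 1
            elif g == Genotype.HET:
                het += 1
            elif g == Genotype.HOM_ALT:
                hom_alt += 1
        called = hom_ref + het + hom_alt
        freq_ref = None if called == 0 else (2 * hom_ref + het) / (2 * called)
        out[sex] = {
            "n_called": called,
            "n_hom_ref": hom_ref,
            "n_het": het,
            "n_hom_alt": hom_alt,
            "freq_ref": freq_ref,
        }
    return out


def _exact_freq_ref(side):
    return Fraction(2 * side["n_hom_ref"] + side["n_het"], 2 * side["n_called"])


def _freq_fires(fixed, other, fixation_min, divergence_min):
    """FREQ clause on one (fixed-sex, other-sex) count pair.

    All comparisons in exact rationals; thresholds interpreted with their
    decimal meaning (0.4 == 4/10), matching the documented inclusive
    boundary semantics.
    """
    if fixed["n_called"] == 0 or other["n_called"] == 0:
        return False
    fr = _exact_freq_ref(fixed)
    if fr > Fraction(1, 2):
        f, o = fr, _exact_freq_ref(other)
    elif fr < Fraction(1, 2):
        f, o = 1 - fr, 1 - _exact_freq_ref(other)
    else:
        return False  # tie: no majority allele
    return f >= Fraction(str(fixation_min)) and (f - o) >= Fraction(str(divergence_min))


def _het_fires(hom_side, het_side, hom_prop_min, het_prop_min):
    if hom_side["n_called"] == 0 or het_side["n_called"] == 0:
        return False
    hom_prop = Fraction(
        hom_side["n_hom_ref"] + hom_side["n_hom_alt"], hom_side["n_called"]
    )
    het_prop = Fraction(het_side["n_het"], het_side["n_called"])
    return hom_prop >= Fraction(str(hom_prop_min)) and het_prop >= Fraction(
        str(het_prop_min)
    )


def calls_by_loop(catalog, sex_map, cfg):
    """Re-evaluate all three criteria from raw genotypes.

    Returns a set of (tag_id, site_id-or-None, method, pattern) tuples with
    method/pattern as plain strings.
    """
    sexes = [sex_map.as_dict()[s] for s in catalog.samples]
    found = set()
    for tag in catalog.tags:
        for site in tag.sites:
            st = site_stats_by_loop([Genotype(int(g)) for g in site.genotypes], sexes)
            f, m = st[Sex.FEMALE], st[Sex.MALE]
            if f["n_called"] < cfg.min_called_per_sex or m["n_called"] < cfg.min_called_per_sex:
                continue
            if _freq_fires(f, m, cfg.fixation_min, cfg.divergence_min):
                found.add((tag.tag_id, site.site_id, "FREQ", "XY"))
            if _freq_fires(m, f, cfg.fixation_min, cfg.divergence_min):
                found.add((tag.tag_id, site.site_id, "FREQ", "ZW"))
            if _het_fires(f, m, cfg.hom_prop_min, cfg.het_prop_min):
                found.add((tag.tag_id, site.site_id, "HET", "XY"))
            if _het_fires(m, f, cfg.hom_prop_min, cfg.het_prop_min):
                found.add((tag.tag_id, site.site_id, "HET", "ZW"))
        # presence/absence at tag level
        present_m = present_f = 0
        n_m = n_f = 0
        for col, sex in enumerate(sexes):
            called = any(
                int(site.genotypes[col]) != int(Genotype.MISSING) for site in tag.sites
            )
            if sex is Sex.MALE:
                n_m += 1
                present_m += called
            else:
                n_f += 1
                present_f += called
        thr = Fraction(str(cfg.presence_prop_min))
        if present_f == 0 and Fraction(present_m, n_m) >= thr:
            found.add((tag.tag_id, None, "PA", "XY"))
        if present_m == 0 and Fraction(present_f, n_f) >= thr:
            found.add((tag.tag_id, None, "PA", "ZW"))
    return found


def binom_minlike_pvalue(k, n):
    """Two-sided exact binomial p (p0 = 0.5) by direct PMF summation."""
    from scipy.stats import binom

    pmf = binom.pmf(range(n + 1), n, 0.5)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


def _compositions(n):
    """All (hom_ref, het, hom_alt) with sum n."""
    return [
        (a, b, n - a - b) for a in range(n + 1) for b in range(n - a + 1)
    ]


def _multinomial_pmf(counts, probs, n):
    a, b, c = counts
    return (
        comb(n, a) * comb(n - a, b)
        * probs[0] ** a * probs[1] ** b * probs[2] ** c
    )


def hwe_false_positive_probs(q, n_f, n_m, cfg):
    """Exact per-site probability that an autosomal HWE site (ALT freq q,
    fully called) fires each criterion/pattern, by enumerating joint
    genotype-count distributions in the two sexes.

    Returns dict with keys ("FREQ","XY"), ("FREQ","ZW"), ("HET","XY"),
    ("HET","ZW").
    """
    p = 1 - q
    probs = (p * p, 2 * p * q, q * q)
    per_sex = {}
    for n in {n_f, n_m}:
        per_sex[n] = [
            (counts, _multinomial_pmf(counts, probs, n)) for counts in _compositions(n)
        ]
    out = {("FREQ", "XY"): 0.0, ("FREQ", "ZW"): 0.0,
           ("HET", "XY"): 0.0, ("HET", "ZW"): 0.0}
    for fc, fp in per_sex[n_f]:
        fstat = {
            "n_called": n_f, "n_hom_ref": fc[0], "n_het": fc[1], "n_hom_alt": fc[2],
            "freq_ref": (2 * fc[0] + fc[1]) / (2 * n_f),
        }
        for mc, mp in per_sex[n_m]:
            mstat = {
                "n_called": n_m, "n_hom_ref": mc[0], "n_het": mc[1], "n_hom_alt": mc[2],
                "freq_ref": (2 * mc[0] + mc[1]) / (2 * n_m),
            }
            w = fp * mp
            if _freq_fires(fstat, mstat, cfg.fixation_min, cfg.divergence_min):
                out[("FREQ", "XY")] += w
            if _freq_fires(mstat, fstat, cfg.fixation_min, cfg.divergence_min):
                out[("FREQ", "ZW")] += w
            if _het_fires(fstat, mstat, cfg.hom_prop_min, cfg.het_prop_min):
                out[("HET", "XY")] += w
            if _het_fires(mstat, fstat, cfg.hom_prop_min, cfg.het_prop_min):
                out[("HET", "ZW")] += w
    return out
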