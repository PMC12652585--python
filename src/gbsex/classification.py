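"""Sex-determination-system verdict and tag accounting.

Given tag-level XY and ZW tallies, an exact two-sided binomial test asks
whether the majority pattern exceeds what a 50:50 split would produce; the
system is declared only when the p-value clears alpha.  Union accounting
reproduces the per-method / union / percentage bookkeeping used to report
a marker screen (how many tags each detector found, their overlap, and the
fraction showing the majority pattern).
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum

from scipy.stats import binomtest

from .model import ValidationError


class SystemCall(str, Enum):
    XY = "XY"
    ZW = "ZW"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class SystemVerdict:
    n_xy_tags: int
    n_zw_tags: int
    n_ambiguous: int
    prop_major: float
    p_value: float
    alpha: float
    system: SystemCall

    @property
    def n_total_informative(self) -> int:
        return self.n_xy_tags + self.n_zw_tags

    def as_dict(self) -> dict:
        return {
            "n_xy_tags": self.n_xy_tags,
            "n_zw_tags": self.n_zw_tags,
            "n_ambiguous": self.n_ambiguous,
            "n_total_informative": self.n_total_informative,
            "prop_major": self.prop_major,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "system": self.system.value,
        }


def binomial_system_test(
    n_xy: int, n_zw: int, alpha: float = 0.01, n_ambiguous: int = 0
) -> SystemVerdict:
    """Exact two-sided binomial test of the XY:ZW tag split against 0.5.

    k = max(n_xy, n_zw) successes in n = n_xy + n_zw trials; the two-sided
    p-value sums every binomial PMF term no larger than PMF(k) (the
    "minlike" definition).  The majority pattern is declared the system
    when p <= alpha, otherwise UNDETERMINED.
    """
    if n_xy < 0 or n_zw < 0:
        raise ValidationError("tag counts must be non-negative")
    n = n_xy + n_zw
    if n == 0:
        raise ValidationError("no informative tags")
    k = max(n_xy, n_zw)
    p_value = float(binomtest(k, n, p=0.5, alternative="two-sided").pvalue)
    if p_value <= alpha:
        system = SystemCall.XY if n_xy >= n_zw else SystemCall.ZW
    else:
        system = SystemCall.UNDETERMINED
    return SystemVerdict(
        n_xy_tags=n_xy,
        n_zw_tags=n_zw,
        n_ambiguous=n_ambiguous,
        prop_major=k / n,
        p_value=p_value,
        alpha=alpha,
        system=system,
    )


def round_half_even_pct(numerator: int, denominator: int, ndigits: int) -> float:
    """Percentage 100*num/den rounded half-even to ndigits, computed in
    decimal so binary float artefacts cannot flip a boundary case."""
    if denominator == 0:
        return 0.0
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(quantum, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class UnionSummary:
    n_freq: int
    n_het: int
    n_freq_and_het: int
    n_pa_male: int
    n_pa_female: int
    n_total: int
    n_male_pattern: int
    pct_male_pattern: float

    def as_dict(self) -> dict:
        return {
            "n_freq": self.n_freq,
            "n_het": self.n_het,
            "n_freq_and_het": self.n_freq_and_het,
            "n_pa_male": self.n_pa_male,
            "n_pa_female": self.n_pa_female,
            "n_total": self.n_total,
            "n_male_pattern": self.n_male_pattern,
            "pct_male_pattern": self.pct_male_pattern,
        }


def union_accounting(
    freq_tags: set[str],
    het_tags: set[str],
    pa_male_tags: set[str],
    pa_female_tags: set[str],
) -> UnionSummary:
    """Per-method counts, union total, and male-pattern percentage.

    The male-pattern group is the union of the FREQ, HET and male-limited
    PA tag sets; the total adds the female-limited PA set.  The percentage
    is reported to two decimals, round-half-even.
    """
    total = freq_tags | het_tags | pa_male_tags | pa_female_tags
    male_pattern = freq_tags | het_tags | pa_male_tags
    return UnionSummary(
        n_freq=len(freq_tags),
        n_het=len(het_tags),
        n_freq_and_het=len(freq_tags & het_tags),
        n_pa_male=len(pa_male_tags),
        n_pa_female=len(pa_female_tags),
        n_total=len(total),
        n_male_pattern=len(male_pattern),
        pct_male_pattern=round_half_even_pct(len(male_pattern), len(total), 2),
    )


def tally_verdicts(classifications) -> tuple[int, int, int]:
    """(n_xy, n_zw, n_ambiguous) from a list of TagClassification."""
    from .discovery import Verdict

    n_xy = sum(1 for c in classifications if c.verdict is Verdict.XY)
    n_zw = sum(1 for c in classifications if c.verdict is Verdict.ZW)
    n_amb = sum(1 for c in classifications if c.verdict is Verdict.AMBIGUOUS)
    return n_xy, n_zw, n_amb
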