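"""Cohort-level allele-aggregation statistics.

Given a recurrent variant observed k times among the cohort's n alleles and
a reference-population allele frequency p (gnomAD), the headline statistic
is the binomial point probability

    Pr(K = k) = C(n, k) p^k (1 - p)^(n - k),

matching the source analysis (its printed 0.2184 for 2/22 alleles at
p = 0.053 is the point mass, not a tail).  The upper tail Pr(K >= k) is
always computed alongside: it is the calibrated "k or more carriers by
chance" p-value, and the proper quantity for significance statements.

Sex differences in allele frequency are tested with the two-sided Fisher
exact test under the probability-ordering convention (sum of hypergeometric
probabilities of all tables with the same margins that are no more likely
than the observed one).

Both the binomial pmf and the Fisher p are computed here in log space /
from hypergeometric masses directly, so that library routines
(scipy.stats.binom, scipy.stats.fisher_exact) remain available as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

from .errors import ValidationError
from .models import AggregationResult, Cohort, SexContingency, VariantRecord
from .triage import allele_count

#: Relative tolerance for the probability-ordering comparison in the
#: two-sided Fisher test (tables whose probability exceeds the observed
#: one by less than this are still counted, guarding against round-off).
FISHER_RELATIVE_TOL = 1e-7


def _check_binomial_domain(k: int, n: int, p: float) -> None:
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValidationError("k and n must be integers")
    if k < 0 or n < 0 or k > n:
        raise ValidationError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p={p} outside [0, 1]")


def binomial_point_prob(k: int, n: int, p: float) -> float:
    """Binomial point mass Pr(K = k | n, p), evaluated in log space."""
    _check_binomial_domain(k, n, p)
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    log_coeff = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    log_pmf = log_coeff + k * math.log(p) + (n - k) * math.log1p(-p)
    return float(math.exp(log_pmf))


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Upper tail Pr(K >= k | n, p), the "k or more alleles" probability."""
    _check_binomial_domain(k, n, p)
    total = math.fsum(binomial_point_prob(j, n, p) for j in range(k, n + 1))
    return min(1.0, total)


def aggregate_variant(
    records: Sequence[VariantRecord],
    cohort: Cohort,
    p_ref: Optional[float] = None,
    mode: str = "point",
) -> AggregationResult:
    """Aggregate one variant's carriers against a reference frequency.

    *p_ref* defaults to the (consistent) reference allele frequency carried
    by the records themselves.  A novel variant has no reference frequency:
    the result is returned with ``computable=False`` and a reason, with the
    observed (k, n) still filled in.
    """
    if mode not in {"point", "upper_tail"}:
        raise ValidationError(f"mode={mode!r}")
    k, n = allele_count(records, cohort)
    first = records[0]
    novel = any(r.is_novel for r in records)
    x_linked = first.chromosome_class == "X"
    scope = first.freq_scope

    if p_ref is None:
        freqs = {r.allele_freq for r in records}
        if freqs == {None}:
            reason = (
                "novel variant: no reference allele frequency"
                if novel
                else "reference allele frequency not found (NF)"
            )
            return AggregationResult(
                gene=first.gene,
                nt_change=first.nt_change,
                k=k,
                n=n,
                p_ref=None,
                freq_scope=None,
                point_prob=None,
                tail_prob=None,
                mode_used=mode,
                computable=False,
                reason=reason,
                novel=novel,
                x_linked=x_linked,
            )
        freqs.discard(None)
        if len(freqs) != 1:
            raise ValidationError(
                f"{first.gene} {first.nt_change}: inconsistent reference "
                f"frequencies across carriers: {sorted(freqs)}"
            )
        p_ref = freqs.pop()

    return AggregationResult(
        gene=first.gene,
        nt_change=first.nt_change,
        k=k,
        n=n,
        p_ref=p_ref,
        freq_scope=scope,
        point_prob=binomial_point_prob(k, n, p_ref),
        tail_prob=binomial_upper_tail(k, n, p_ref),
        mode_used=mode,
        novel=novel,
        x_linked=x_linked,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by probability ordering.

    *table* is [[a, b], [c, d]] of nonnegative integer counts.  All tables
    with the observed margins whose hypergeometric probability does not
    exceed the observed table's (within relative tolerance 1e-7) contribute
    to the p-value.  Degenerate margins (an empty row or column) give 1.0.
    """
    ((a, b), (c, d)) = table
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValidationError("table entries must be nonnegative integers")
    n1 = a + b  # first row margin
    n2 = c + d
    m1 = a + c  # first column margin
    total = n1 + n2
    if n1 == 0 or n2 == 0 or m1 == 0 or m1 == total:
        return 1.0
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, total, m1, n1)
    p_obs = hypergeom.pmf(a, total, m1, n1)
    p_value = float(probs[probs <= p_obs * (1.0 + FISHER_RELATIVE_TOL)].sum())
    return min(1.0, p_value)


def sex_frequency_test(
    alt_male: int, ref_male: int, alt_female: int, ref_female: int
) -> SexContingency:
    """Exact test of allele-frequency difference between sexes."""
    p = fisher_exact_2x2([[alt_male, alt_female], [ref_male, ref_female]])
    return SexContingency(
        alt_male=alt_male,
        ref_male=ref_male,
        alt_female=alt_female,
        ref_female=ref_female,
        p_value=p,
    )
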