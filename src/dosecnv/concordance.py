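"""Callset matching, detection sensitivity and Wilson confidence intervals.

Two callsets (e.g. exome-depth calls vs an orthogonal array callset, or
calls vs a simulated truth set) are matched greedily one-to-one by
reciprocal overlap within (sample, type) strata. Sensitivity is the
fraction of reference calls matched, reported with a Wilson score
interval — the binomial CI obtained by inverting the score test, which
stays well-behaved at extreme proportions and small n.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .caller import CnvCall
from .filters import reciprocal_overlap


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion k/n with its Wilson score interval."""

    k: int
    n: int
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95

    def __str__(self) -> str:
        # mirrors the usual "X% [95% CI, a–b%]" reporting style
        pct = 100.0 * self.estimate
        return (
            f"{self.k}/{self.n} = {pct:.1f}% "
            f"[{self.confidence * 100:.0f}% CI, "
            f"{100 * self.lower:.1f}–{100 * self.upper:.1f}%]"
        )


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval for k successes in n trials.

    With p-hat = k/n and z the normal quantile at (1 + confidence)/2:

        center     = (p-hat + z^2 / 2n) / (1 + z^2 / n)
        half-width = z * sqrt(p-hat (1 - p-hat)/n + z^2 / 4n^2) / (1 + z^2 / n)

    No continuity correction. The interval always contains k/n, and its
    bounds hit 0 and 1 exactly at k = 0 and k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    p_hat = k / n
    denom = 1.0 + z * z / n
    center = (p_hat + z * z / (2.0 * n)) / denom
    half = z * ((p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n)) ** 0.5) / denom
    # the algebra gives exactly 0/1 at the boundary counts; avoid float drift
    lower = 0.0 if k == 0 else max(0.0, center - half)
    upper = 1.0 if k == n else min(1.0, center + half)
    return ProportionCI(
        k=k, n=n, estimate=p_hat, lower=lower, upper=upper, confidence=confidence
    )


def match_callsets(
    test_calls: list[CnvCall],
    reference_calls: list[CnvCall],
    match_overlap: float = 0.5,
    require_same_sample: bool = True,
    require_same_type: bool = True,
) -> tuple[list[tuple[CnvCall, CnvCall]], list[CnvCall], list[CnvCall]]:
    """Greedy one-to-one matching by descending reciprocal overlap.

    Candidate pairs within a (sample, type) stratum with reciprocal
    overlap >= ``match_overlap`` are taken best-first (ties broken by
    leftmost reference then test start), each call matched at most once.
    Returns (matched (test, reference) pairs, unmatched reference,
    unmatched test).
    """
    candidates = []
    for ti, t in enumerate(test_calls):
        for ri, r in enumerate(reference_calls):
            if require_same_sample and t.sample != r.sample:
                continue
            if require_same_type and t.type != r.type:
                continue
            if t.chrom != r.chrom:
                continue
            ro = reciprocal_overlap((t.chrom, t.start, t.end), (r.chrom, r.start, r.end))
            if ro >= match_overlap:
                candidates.append((-ro, r.start, t.start, ti, ri))
    candidates.sort()
    used_test: set[int] = set()
    used_ref: set[int] = set()
    matched: list[tuple[CnvCall, CnvCall]] = []
    for _, _, _, ti, ri in candidates:
        if ti in used_test or ri in used_ref:
            continue
        used_test.add(ti)
        used_ref.add(ri)
        matched.append((test_calls[ti], reference_calls[ri]))
    unmatched_ref = [r for i, r in enumerate(reference_calls) if i not in used_ref]
    unmatched_test = [t for i, t in enumerate(test_calls) if i not in used_test]
    return matched, unmatched_ref, unmatched_test


def sensitivity_with_ci(
    test_calls: list[CnvCall],
    reference_calls: list[CnvCall],
    match_overlap: float = 0.5,
    confidence: float = 0.95,
    require_same_sample: bool = True,
    require_same_type: bool = True,
) -> ProportionCI:
    """Detected / total reference calls, with a Wilson interval attached."""
    if not reference_calls:
        raise ValueError("reference callset is empty")
    matched, _, _ = match_callsets(
        test_calls,
        reference_calls,
        match_overlap=match_overlap,
        require_same_sample=require_same_sample,
        require_same_type=require_same_type,
    )
    return wilson_ci(len(matched), len(reference_calls), confidence)
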