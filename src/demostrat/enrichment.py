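"""Enrichment of significant associations over chance expectation.

A scan of n independent tests at level alpha is expected to produce
n * alpha significant results by chance alone; a scan of 60 sex x
generation tests at alpha = 0.05 expects three.  The fold excess is the
observed count over that expectation, and the attached test asks how
likely a count at least as large is under the null.  Two p-values are
reported: an exact binomial upper tail and a one-sided normal
approximation on the observed proportion (variance taken at the observed
proportion).  The tests-independent assumption mirrors the scan design —
disjoint demographic cells — and is noted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import InputError

__all__ = ["EnrichmentResult", "expected_by_chance", "fold_excess",
           "enrichment_test", "enrichment_summary"]


@dataclass
class EnrichmentResult:
    n_tests: int
    alpha: float
    observed: int
    expected: float
    fold: float
    p_exact: float
    p_normal: float


def _validate(n_tests: int, alpha: float, observed: int | None = None):
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must be in (0, 1)")
    if observed is not None and not 0 <= observed <= n_tests:
        raise InputError("observed count must be in [0, n_tests]")


def expected_by_chance(n_tests: int, alpha: float) -> float:
    """Expected number of significant tests under the global null."""
    _validate(n_tests, alpha)
    return n_tests * alpha


def fold_excess(observed: int, n_tests: int, alpha: float) -> float:
    """Observed significant count over the chance expectation."""
    _validate(n_tests, alpha, observed)
    return observed / (n_tests * alpha)


def enrichment_test(observed: int, n_tests: int, alpha: float
                    ) -> tuple[float, float]:
    """(exact binomial tail, normal-approximation tail), both one-sided.

    The exact tail is P(X >= observed) for X ~ Binomial(n_tests, alpha).
    The normal approximation uses z = (phat - alpha) / sqrt(phat(1-phat)/n)
    with phat the observed proportion; degenerate proportions (0 or 1) give
    tail probabilities 1 and ~0 respectively.
    """
    _validate(n_tests, alpha, observed)
    # binom.sf(k-1) is the inclusive upper tail P(X >= k)
    p_exact = float(stats.binom.sf(observed - 1, n_tests, alpha))
    phat = observed / n_tests
    if phat in (0.0, 1.0):
        p_normal = 1.0 if phat == 0.0 else float(stats.norm.sf(37.0))
    else:
        z = (phat - alpha) / (phat * (1.0 - phat) / n_tests) ** 0.5
        p_normal = float(stats.norm.sf(z))
    return p_exact, p_normal


def enrichment_summary(observed: int, n_tests: int,
                       alpha: float = 0.05) -> EnrichmentResult:
    """Full enrichment report for a scan's significant-test count."""
    p_exact, p_normal = enrichment_test(observed, n_tests, alpha)
    return EnrichmentResult(
        n_tests=n_tests, alpha=alpha, observed=observed,
        expected=expected_by_chance(n_tests, alpha),
        fold=fold_excess(observed, n_tests, alpha),
        p_exact=p_exact, p_normal=p_normal)
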