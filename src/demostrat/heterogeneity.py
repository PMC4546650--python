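"""Between-cell effect heterogeneity and the strong/weak subsample split.

Heterogeneity among per-cell effect estimates is quantified with Cochran's
Q and the I² statistic, I² = 100 * max(0, (Q - df) / Q), read as the
percentage of total variability in the effects due to true between-cell
heterogeneity.  Pooling uses inverse-variance fixed-effect weights.

The S/W partition splits the demographic cells, for one SNP, into an
S-subsample — the cells whose effects are mutually homogeneous (within-group
I² minimal, zero when attainable) and whose pooled effect carries the sign
of a reference estimate (e.g. a published meta-analytic effect) — and the
complementary W-subsample, which provides the weakest support.  Among
sign-concordant homogeneous groups the partition chosen maximises the
between-group I² computed on the two pooled estimates (df = 1), i.e. it
minimises heterogeneity within the subsamples while maximising it between
them.  Selection is exhaustive over all bipartitions, so it is exact for
the cell counts that arise here (six to eight cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import InputError

__all__ = ["HeterogeneityResult", "SWPartition", "cochran_q", "i_squared",
           "pool_fixed", "heterogeneity", "partition_sw"]


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    i2: float                   # percent in [0, 100]
    pooled_beta: float
    pooled_se: float


@dataclass
class SWPartition:
    """The S (strong-support) / W (weak-support) split of cells for one SNP."""

    s_cells: list
    w_cells: list
    i2_s: float
    i2_w: float
    i2_between: float
    s_pooled: tuple[float, float]       # (beta, se)
    w_pooled: tuple[float, float] | None
    degenerate: bool = False            # homogeneous limit: no real split
    no_support: bool = False            # no sign-concordant group existed
    candidates: list = field(default_factory=list)  # audit trail


def pool_fixed(betas, ses) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooled estimate and its SE."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size == 0:
        raise InputError("cannot pool an empty set of effects")
    if np.any(ses <= 0):
        raise InputError("standard errors must be positive")
    w = 1.0 / ses ** 2
    pooled = float(np.sum(w * betas) / np.sum(w))
    return pooled, float(np.sum(w) ** -0.5)


def cochran_q(betas, ses) -> tuple[float, int]:
    """Cochran's Q = sum_i w_i (beta_i - pooled)^2 with w_i = 1/se_i^2."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size < 2:
        raise InputError("Q needs at least 2 effects")
    pooled, _ = pool_fixed(betas, ses)
    w = 1.0 / ses ** 2
    q = float(np.sum(w * (betas - pooled) ** 2))
    return q, int(betas.size - 1)


def i_squared(q: float, df: int) -> float:
    """I² in percent: 100 * max(0, (Q - df) / Q); zero when Q = 0."""
    if q < 0:
        raise InputError("Q must be non-negative")
    if df < 1:
        raise InputError("df must be >= 1")
    if q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (q - df) / q)


def heterogeneity(betas, ses) -> HeterogeneityResult:
    """Q, I² and the fixed-effect pool for a set of effects."""
    q, df = cochran_q(betas, ses)
    pooled, pooled_se = pool_fixed(betas, ses)
    return HeterogeneityResult(q, df, i_squared(q, df), pooled, pooled_se)


def _within_i2(betas, ses) -> float:
    if len(betas) < 2:
        return 0.0          # a single effect has no internal heterogeneity
    q, df = cochran_q(betas, ses)
    return i_squared(q, df)


def _between_i2(pool_a, pool_b) -> float:
    betas = [pool_a[0], pool_b[0]]
    ses = [pool_a[1], pool_b[1]]
    q, df = cochran_q(betas, ses)
    return i_squared(q, df)


def partition_sw(cell_results, reference_beta: float,
                 *, i2_tol: float = 1e-9) -> SWPartition:
    """Exhaustive S/W bipartition of per-cell results for one SNP.

    ``cell_results`` are objects with ``beta``, ``se`` and ``cell``
    attributes (AssocResult works); ``reference_beta`` is the signed
    reference effect the S-subsample must support.  Feasible S candidates
    are the cell subsets with minimal within-group I² (0 when attainable)
    whose pooled effect matches the reference sign; among them the subset
    maximising the between-group I² against its complement wins.  Ties are
    broken by the larger |pooled z| of S, then by lexicographic cell order.
    If no subset pools to the reference sign, the partition is returned
    flagged ``no_support`` with S set to the least-contradicting singleton
    (the cell whose reference-signed z is largest).
    """
    if reference_beta == 0:
        raise InputError("reference effect must be non-zero")
    k = len(cell_results)
    if k < 3:
        raise InputError("partition needs at least 3 cells")
    order = sorted(range(k), key=lambda i: str(cell_results[i].cell))
    betas = np.array([cell_results[i].beta for i in order])
    ses = np.array([cell_results[i].se for i in order])
    labels = [str(cell_results[i].cell) for i in order]
    sign = np.sign(reference_beta)

    entries = []                # (i2_s, candidate record)
    for size in range(1, k):
        for subset in combinations(range(k), size):
            s = list(subset)
            pooled = pool_fixed(betas[s], ses[s])
            if np.sign(pooled[0]) != sign:
                continue
            w = [i for i in range(k) if i not in subset]
            w_pooled = pool_fixed(betas[w], ses[w])
            rec = {
                "s": s, "w": w,
                "i2_s": _within_i2(betas[s], ses[s]),
                "i2_w": _within_i2(betas[w], ses[w]),
                "i2_between": _between_i2(pooled, w_pooled),
                "s_pooled": pooled, "w_pooled": w_pooled,
                "abs_z": abs(pooled[0] / pooled[1]),
            }
            entries.append(rec)

    if not entries:
        # No subset pools to the reference sign: flag and return the
        # least-contradicting singleton (largest reference-signed z).
        zs = sign * betas / ses
        best = int(np.argmax(zs))
        w = [i for i in range(k) if i != best]
        w_pooled = pool_fixed(betas[w], ses[w])
        s_pooled = (float(betas[best]), float(ses[best]))
        return SWPartition(
            s_cells=[labels[best]], w_cells=[labels[i] for i in w],
            i2_s=0.0, i2_w=_within_i2(betas[w], ses[w]),
            i2_between=_between_i2(s_pooled, w_pooled),
            s_pooled=s_pooled, w_pooled=w_pooled, no_support=True)

    min_i2 = min(e["i2_s"] for e in entries)
    feasible = [e for e in entries if e["i2_s"] <= min_i2 + i2_tol]
    # max between-group I2; ties: larger |z_S|, then lexicographic cells.
    best = sorted(feasible,
                  key=lambda e: (-e["i2_between"], -e["abs_z"],
                                 tuple(labels[i] for i in e["s"])))[0]
    return SWPartition(
        s_cells=[labels[i] for i in best["s"]],
        w_cells=[labels[i] for i in best["w"]],
        i2_s=best["i2_s"], i2_w=best["i2_w"],
        i2_between=best["i2_between"],
        s_pooled=best["s_pooled"], w_pooled=best["w_pooled"],
        degenerate=best["i2_between"] == 0.0,
        candidates=feasible)
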