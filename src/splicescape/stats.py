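"""Statistical machinery: the excess-AS randomization test and standard tests.

The randomization test asks, per AS gene, whether its event count is
unusually high: the observed count is compared against ``n_reps`` genes
drawn uniformly (with replacement) from the *other* AS genes, and the
empirical p-value is the fraction of draws whose count reaches the observed
value.  Two tie rules are offered: ``"ge"`` (draw >= observed; the default,
which cannot declare a fully tied population significant) and ``"gt"``
(draw strictly greater than observed, the literal wording of the original
procedure).  :func:`exact_excess_p` is the n_reps -> infinity limit used as
the oracle.

The remaining operations are validated fronts over scipy/statsmodels:
Fisher's one-tailed exact test, the Mann-Whitney U test (exact for small
tie-free samples, tie-corrected normal approximation otherwise), the
Kruskal-Wallis rank-sum test, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_models import ValidationError

__all__ = [
    "GeneASCount",
    "RandomizationResult",
    "randomization_excess_as",
    "exact_excess_p",
    "fisher_one_tailed",
    "mann_whitney_u",
    "kruskal_wallis",
    "bh_adjust",
]


class GeneASCount(NamedTuple):
    """A gene and its total AS event count (all five types, within + among)."""

    gene_id: str
    n_events: int


@dataclass
class RandomizationResult:
    gene_id: str
    observed: int
    p_empirical: float
    significant: bool
    n_reps: int
    seed: int


def _validate_counts(counts: Sequence[GeneASCount]) -> list[GeneASCount]:
    counts = list(counts)
    if len(counts) < 2:
        raise ValidationError("randomization needs at least two AS genes")
    ids = [c.gene_id for c in counts]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene_id in counts")
    for c in counts:
        if c.n_events < 0:
            raise ValidationError(f"negative event count for {c.gene_id}")
    return counts


def randomization_excess_as(
    counts: Sequence[GeneASCount],
    n_reps: int = 1000,
    seed: int = 0,
    tie_rule: str = "ge",
    alpha: float = 0.05,
) -> list[RandomizationResult]:
    """Empirical excess-AS p-value for every gene.

    For each focal gene, ``n_reps`` genes are drawn uniformly with
    replacement from the other genes; p is the fraction of draws whose
    count is >= (tie_rule "ge") or > (tie_rule "gt") the observed count.
    A gene is significant iff p < alpha.  Per-gene random substreams are
    derived from ``seed`` by sorted gene id, so results do not depend on
    the iteration order of the input.
    """
    counts = _validate_counts(counts)
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if tie_rule not in ("ge", "gt"):
        raise ValidationError(f"tie_rule must be 'ge' or 'gt', got {tie_rule!r}")
    # work in sorted-gene order so draws are independent of input order
    by_id = sorted(counts, key=lambda c: c.gene_id)
    vals = np.array([c.n_events for c in by_id], dtype=int)
    children = np.random.SeedSequence(seed).spawn(len(by_id))
    results: dict[str, RandomizationResult] = {}
    for rank, c in enumerate(by_id):
        rng = np.random.default_rng(children[rank])
        idx = rng.integers(0, len(by_id) - 1, size=n_reps)
        idx = idx + (idx >= rank)  # skip the focal gene
        draws = vals[idx]
        hits = int((draws >= vals[rank]).sum() if tie_rule == "ge" else (draws > vals[rank]).sum())
        p = hits / n_reps
        results[c.gene_id] = RandomizationResult(
            gene_id=c.gene_id,
            observed=int(vals[rank]),
            p_empirical=p,
            significant=p < alpha,
            n_reps=n_reps,
            seed=seed,
        )
    return [results[c.gene_id] for c in counts]


def exact_excess_p(
    counts: Sequence[GeneASCount], focal: str, tie_rule: str = "ge"
) -> float:
    """Exact limit of the randomization p: fraction of other genes reaching focal."""
    counts = _validate_counts(counts)
    if tie_rule not in ("ge", "gt"):
        raise ValidationError(f"tie_rule must be 'ge' or 'gt', got {tie_rule!r}")
    by_id = {c.gene_id: c.n_events for c in counts}
    if focal not in by_id:
        raise ValidationError(f"unknown focal gene {focal!r}")
    obs = by_id[focal]
    others = [c.n_events for c in counts if c.gene_id != focal]
    if tie_rule == "ge":
        hits = sum(1 for v in others if v >= obs)
    else:
        hits = sum(1 for v in others if v > obs)
    return hits / len(others)


def fisher_one_tailed(
    table: Sequence[Sequence[int]], direction: str = "greater"
) -> float:
    """Exact one-tailed Fisher p for a 2x2 table of non-negative integers."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("Fisher test needs a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("table entries must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("table margins must be positive")
    if direction not in ("greater", "less"):
        raise ValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    return float(sps.fisher_exact(arr, alternative=direction)[1])


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Rank-sum U statistic and p-value.

    Exact enumeration when both samples are tie-free with n <= 20, the
    tie-corrected normal approximation otherwise.  With fully tied data the
    tie-corrected variance is zero and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (not has_ties and x.size <= 20 and y.size <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H against chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("all groups must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, df, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), df, float(p)


def bh_adjust(pvals: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(arr, method="fdr_bh")[1]]
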