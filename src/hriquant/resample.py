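"""Bootstrap-by-gene and permutation inference.

Confidence intervals for f_HRi and Ka+ come from resampling genes with
replacement and rerunning the whole pipeline (binning, per-bin estimation,
local regression, the loss totals) on each replicate; category contrasts use
the paired per-replicate differences (the Z statistic); the immune/testes
enrichment test permutes gene labels without replacement and recomputes the
class difference of pooled Ka+ under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "ZComparison",
    "bootstrap_pipeline",
    "z_category_test",
    "permutation_test_groups",
]


@dataclass
class BootstrapResult:
    """Point estimate + replicate distribution of one statistic.

    The CI endpoints are order statistics of the replicate vector (percentile
    interval: 2.5% from below, 97.5% from above).
    """

    statistic: str
    point: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, float)
        if len(self.replicates) != self.B:
            raise ValueError("replicate count does not equal B")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low exceeds ci_high")


@dataclass
class ZComparison:
    """Paired per-replicate difference between two category statistics."""

    pair: tuple
    z_values: np.ndarray
    p_one_tailed: float


def percentile_ci(replicates, level=0.95):
    """Percentile interval whose endpoints are order statistics."""
    reps = np.sort(np.asarray(replicates, float))
    alpha = (1.0 - level) / 2.0
    lo = reps[int(np.floor(alpha * (len(reps) - 1)))]
    hi = reps[int(np.ceil((1.0 - alpha) * (len(reps) - 1)))]
    return float(lo), float(hi)


def bootstrap_pipeline(genes, pipeline_fn, B, seed, statistic="statistic",
                       max_retries=3):
    """Bootstrap a pipeline statistic by resampling genes with replacement.

    ``pipeline_fn(genes, rng) -> float`` maps a gene list to the statistic
    (typically: split K4, bin, estimate per-bin Ka+, fit the LOESS curve and
    apply the loss equations).  Each replicate resamples to the original
    gene count and reruns the pipeline with a child seed derived from the
    master seed, so identical master seeds give bit-identical replicates.
    Replicate-level failures are logged and redrawn up to ``max_retries``
    times, never silently dropped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    genes = list(genes)
    n = len(genes)
    ss = np.random.SeedSequence(seed)
    point_rng = np.random.default_rng(ss.spawn(1)[0])
    point = float(pipeline_fn(genes, point_rng))
    reps = np.empty(B)
    children = ss.spawn(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sample = [genes[i] for i in idx]
            try:
                reps[b] = float(pipeline_fn(sample, rng))
                break
            except Exception as exc:
                logger.warning("bootstrap replicate %d attempt %d failed: %s",
                               b, attempt + 1, exc)
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap replicate {b} failed after "
                        f"{max_retries + 1} attempts") from exc
    lo, hi = percentile_ci(reps)
    return BootstrapResult(statistic=statistic, point=point, replicates=reps,
                           ci_low=lo, ci_high=hi, B=B, seed=seed)


def z_category_test(reps_a, reps_b, pair=("A", "B"), direction="greater"):
    """Paired bootstrap contrast Z = statistic(A) - statistic(B).

    One-tailed p: with ``direction='greater'`` (is A larger?) the p value is
    the fraction of replicate differences on the null side, z <= 0; ties at
    zero count conservatively toward the null.
    """
    a = np.asarray(reps_a, float)
    b = np.asarray(reps_b, float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length (paired)")
    z = a - b
    if direction == "greater":
        p = float(np.mean(z <= 0.0))
    elif direction == "less":
        p = float(np.mean(z >= 0.0))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return ZComparison(pair=tuple(pair), z_values=z, p_one_tailed=p)


def all_pairwise_z(category_reps, direction="greater"):
    """All pairwise Z comparisons among category replicate vectors (six for
    the 2x2 gene-density x mutation-rate design)."""
    names = sorted(category_reps)
    out = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            out.append(z_category_test(category_reps[na], category_reps[nb],
                                       pair=(na, nb), direction=direction))
    return out


def permutation_test_groups(genes, focal_mask, statistic_fn, B, seed,
                            include_observed=False):
    """Label-permutation test of a class difference in a pooled statistic.

    ``focal_mask`` marks the focal class (e.g. immune/testes genes);
    ``statistic_fn(genes) -> float`` computes the pooled statistic for a gene
    subset.  Each replicate shuffles the labels without replacement (class
    sizes preserved) and records control - focal.  The one-tailed p value is
    the fraction of null replicates below the observed difference; with
    ``include_observed`` the observed value is added to the null (the +1
    convention).

    Returns (null_differences, observed_difference, p_one_tailed).
    """
    genes = list(genes)
    mask = np.asarray(focal_mask, bool)
    if mask.shape != (len(genes),):
        raise ValueError("focal_mask must align with genes")
    n_focal = int(mask.sum())
    if n_focal == 0 or n_focal == len(genes):
        raise ValueError("both label classes must be non-empty")

    def diff(m):
        focal = [g for g, f in zip(genes, m) if f]
        control = [g for g, f in zip(genes, m) if not f]
        return float(statistic_fn(control)) - float(statistic_fn(focal))

    observed = diff(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = diff(rng.permutation(mask))
    n_below = int(np.sum(null < observed))
    if include_observed:
        p = (n_below + 1) / (B + 1)
    else:
        p = n_below / B
    return null, observed, float(p)
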