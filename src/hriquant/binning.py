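"""Gene binning and hypergeometric splitting of synonymous divergence.

Adaptive-rate estimates are too noisy for single genes, so genes are pooled
into equal-size rank bins (e.g. 45 bins of 136 genes ranked by recombination
rate).  When the binning key itself derives from 4-fold divergence, K4 is
first split into statistically independent variates by multivariate
hypergeometric sampling - one variate ranks the genes, another feeds the
adaptive-rate estimate, a third reads out the mutation rate - so that
sampling error cannot induce a spurious correlation between the key and the
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .counts import FoldedSFS, GeneCovariates, GeneSiteCounts

logger = logging.getLogger(__name__)

__all__ = [
    "SplitK4",
    "GeneRecord",
    "GeneBin",
    "split_k4_three",
    "split_k4_two",
    "rank_bin",
    "nested_partition",
    "pool_bin",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitK4:
    """Hypergeometric partition of a gene's 4-fold divergence.

    ``d4_parts`` sum exactly to D4; ``shares`` are the integer site totals of
    each partition block; ``k4_parts`` are the per-site rates d4/share.
    """

    gene_id: str
    d4_parts: tuple
    shares: tuple
    k4_parts: tuple

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.d4_parts):
            raise ValueError("negative divergence part")
        if any(d > s for d, s in zip(self.d4_parts, self.shares)):
            raise ValueError("divergence part exceeds its site-share capacity")


def _split_k4(gene_id, D4, L4, fractions, rng):
    if not 0 <= D4 <= L4:
        raise ValueError(f"{gene_id}: D4={D4} outside [0, L4={L4}]")
    parts = []
    shares = []
    remaining_sites = L4
    remaining_hits = D4
    for frac in fractions:
        n_draw = _round_half_up(frac * L4)
        n_draw = min(n_draw, remaining_sites)
        d = int(rng.hypergeometric(remaining_hits, remaining_sites - remaining_hits,
                                   n_draw)) if n_draw > 0 else 0
        parts.append(d)
        shares.append(n_draw)
        remaining_sites -= n_draw
        remaining_hits -= d
    parts.append(remaining_hits)
    shares.append(remaining_sites)
    k4 = tuple(d / s if s > 0 else float("nan") for d, s in zip(parts, shares))
    return SplitK4(gene_id, tuple(parts), tuple(shares), k4)


def split_k4_three(gene_id, D4, L4, rng):
    """Three-way split: K4,1 ranks genes, K4,2 estimates the adaptive rate,
    K4,3 reads out the mutation rate.  Draw sizes round(0.33 L4) twice, the
    third block takes the remainder; closure D4,1+D4,2+D4,3 = D4 is exact."""
    return _split_k4(gene_id, D4, L4, (0.33, 0.33), rng)


def split_k4_two(gene_id, D4, L4, rng):
    """Two-way split (draws round(0.5 L4)): K4,1 ranks, K4,2 estimates."""
    return _split_k4(gene_id, D4, L4, (0.5,), rng)


# ---------------------------------------------------------------------------
# gene records and bins
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One gene's counts + covariates (+ optional K4 split) as a binning unit."""

    counts: GeneSiteCounts
    covariates: GeneCovariates
    split: SplitK4 | None = None

    @property
    def gene_id(self) -> str:
        return self.counts.gene_id


@dataclass
class GeneBin:
    """A pooled bin of genes: element-wise summed SFS and count totals plus
    mean covariates.  ``D4``/``L4`` here are whatever 4-fold variate the
    caller designated for estimation (full divergence, or the K4,2 block)."""

    bin_id: str
    gene_ids: list
    sfs0: FoldedSFS
    sfs4: FoldedSFS
    D0: int
    L0: int
    D4: int
    L4: int
    D4_ts: int
    D4_tv: int
    gc4: float
    mean_rr: float
    mean_density: float
    mean_fop: float
    mean_k4_rank: float = float("nan")
    mean_k4_mut: float = float("nan")
    category: str = ""


def pool_bin(genes, bin_id, estimation="full", category=""):
    """Pool a list of GeneRecord into a GeneBin.

    ``estimation`` selects the 4-fold divergence fed to the adaptive-rate
    stage: ``"full"`` uses each gene's complete (D4, L4); ``"k4_2"`` uses the
    second block of the hypergeometric split (divergence part and its site
    share).  Transition/transversion counts are allocated to the block
    proportionally to the gene's overall ts fraction, since the split
    partitions total divergent sites only.
    """
    if not genes:
        raise ValueError("cannot pool an empty bin")
    sfs0 = genes[0].counts.sfs0
    sfs4 = genes[0].counts.sfs4
    for g in genes[1:]:
        sfs0 = sfs0 + g.counts.sfs0
        sfs4 = sfs4 + g.counts.sfs4
    D0 = sum(g.counts.D0 for g in genes)
    L0 = sum(g.counts.L0 for g in genes)
    if estimation == "full":
        D4 = sum(g.counts.D4 for g in genes)
        L4 = sum(g.counts.L4 for g in genes)
        D4_ts = sum(g.counts.D4_ts for g in genes)
        D4_tv = D4 - D4_ts
    elif estimation == "k4_2":
        D4 = L4 = 0
        ts_exact = 0.0
        for g in genes:
            if g.split is None:
                raise ValueError(f"{g.gene_id}: estimation='k4_2' requires a K4 split")
            d = g.split.d4_parts[1]
            D4 += d
            L4 += g.split.shares[1]
            if g.counts.D4 > 0:
                ts_exact += d * g.counts.D4_ts / g.counts.D4
        D4_ts = min(int(round(ts_exact)), D4)
        D4_tv = D4 - D4_ts
    else:
        raise ValueError(f"unknown estimation source {estimation!r}")
    tot_L4 = sum(g.counts.L4 for g in genes)
    gc4 = (sum(g.counts.gc4 * g.counts.L4 for g in genes) / tot_L4
           if tot_L4 > 0 else float("nan"))
    k4_rank = [g.split.k4_parts[0] for g in genes if g.split is not None]
    k4_mut = [g.split.k4_parts[-1] for g in genes
              if g.split is not None and len(g.split.k4_parts) == 3]
    return GeneBin(
        bin_id=bin_id,
        gene_ids=[g.gene_id for g in genes],
        sfs0=sfs0, sfs4=sfs4,
        D0=D0, L0=L0, D4=D4, L4=L4, D4_ts=D4_ts, D4_tv=D4_tv, gc4=gc4,
        mean_rr=float(np.mean([g.covariates.rr for g in genes])),
        mean_density=float(np.mean([g.covariates.density for g in genes])),
        mean_fop=float(np.mean([g.covariates.fop for g in genes])),
        mean_k4_rank=float(np.mean(k4_rank)) if k4_rank else float("nan"),
        mean_k4_mut=float(np.mean(k4_mut)) if k4_mut else float("nan"),
        category=category,
    )


def rank_bin(genes, key, n_bins):
    """Sort genes ascending by ``key`` and chunk into ``n_bins`` equal bins.

    Bin size is floor(N / n_bins); the N mod n_bins leftover genes with the
    highest key values are discarded (and logged).  Ties are broken by
    gene_id so the assignment is deterministic under permuted input.
    Returns a list of lists of GeneRecord.
    """
    n = len(genes)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({n})")
    size = n // n_bins
    ordered = sorted(genes, key=lambda g: (key(g), g.gene_id))
    n_discard = n - size * n_bins
    if n_discard:
        dropped = [g.gene_id for g in ordered[size * n_bins:]]
        logger.info("rank_bin discarded %d highest-key genes: %s%s",
                    n_discard, ",".join(dropped[:5]), "..." if n_discard > 5 else "")
    ordered = ordered[:size * n_bins]
    return [ordered[i * size:(i + 1) * size] for i in range(n_bins)]


def _level_label(name, level, n_levels):
    if n_levels == 2 and name in ("density", "gene_density"):
        return "GenL" if level == 0 else "GenH"
    if n_levels == 2 and name in ("k4_1", "k4", "mutation"):
        return "MutL" if level == 0 else "MutH"
    return f"{name}Q{level + 1}"


_KEY_FUNCS = {
    "rr": lambda g: g.covariates.rr,
    "density": lambda g: g.covariates.density,
    "gene_density": lambda g: g.covariates.density,
    "fop": lambda g: g.covariates.fop,
    "k4_1": lambda g: g.split.k4_parts[0],
    "k4": lambda g: g.counts.D4 / g.counts.L4 if g.counts.L4 else 0.0,
    "mutation": lambda g: g.split.k4_parts[0],
}


def nested_partition(genes, spec):
    """Nested factor grouping, e.g. density halves x K4,1 halves x 12 RR bins.

    ``spec`` is an ordered list of (covariate_name, n_levels); every factor
    but the last splits its group into n_levels nearly equal rank groups, and
    the final factor rank-bins each group (discarding remainders).  Covariate
    names: rr, density, fop, k4_1 (requires a prior K4 split), k4.

    Returns ``{category_label: [bin, ...]}`` where each bin is a list of
    GeneRecord.  For the 2 density x 2 mutation layout the labels are
    GenH-MutH / GenH-MutL / GenL-MutH / GenL-MutL.
    """
    if not spec:
        raise ValueError("empty partition spec")
    *outer, (last_name, last_bins) = spec

    def recurse(subset, labels, factors):
        if not factors:
            label = "-".join(labels) if labels else "all"
            if last_bins > len(subset):
                raise ValueError(
                    f"level {label!r} has {len(subset)} genes, fewer than "
                    f"{last_bins} bins")
            return {label: rank_bin(subset, _KEY_FUNCS[last_name], last_bins)}
        (name, n_levels), *rest = factors
        ordered = sorted(subset, key=lambda g: (_KEY_FUNCS[name](g), g.gene_id))
        out = {}
        for lvl, chunk in enumerate(np.array_split(np.array(ordered, dtype=object),
                                                   n_levels)):
            out.update(recurse(list(chunk), labels + [_level_label(name, lvl, n_levels)],
                               rest))
        return out

    return recurse(list(genes), [], outer)
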