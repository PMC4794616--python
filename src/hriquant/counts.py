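"""Per-gene polymorphism/divergence summaries and covariates.

Builds folded site-frequency spectra, counts raw differences to the outgroup,
applies multiple-hit corrections (Jukes-Cantor for 0-fold sites, Tamura 1992
for 4-fold sites, which allows unequal GC content and a ts/tv bias), and
computes the per-gene covariates used to stratify the analysis: codon-usage
bias (Fop), local gene density, and the crossover rate of the 100-kb window
overlapping the gene midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FoldedSFS",
    "GeneSiteCounts",
    "GeneCovariates",
    "build_folded_sfs",
    "count_substitutions",
    "jc_correct",
    "jc_uncorrect",
    "tamura_correct",
    "compute_fop",
    "gene_density",
    "assign_rr",
    "read_recombination_map",
    "DMEL_OPTIMAL_CODONS",
]


class SaturationError(ValueError):
    """Observed divergence too high for the multiple-hit correction."""


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum for a fixed sample size.

    ``counts[i-1]`` is the number of sites whose minor allele is carried by
    exactly ``i`` of the ``n`` chromosomes, for i = 1 .. floor(n/2).
    """

    n_chromosomes: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.n_chromosomes // 2
        if self.counts.shape != (expected,):
            raise ValueError(
                f"folded SFS for n={self.n_chromosomes} must have length "
                f"{expected}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative SFS entry")

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "FoldedSFS") -> "FoldedSFS":
        if other.n_chromosomes != self.n_chromosomes:
            raise ValueError("cannot pool SFS with different sample sizes")
        return FoldedSFS(self.n_chromosomes, self.counts + other.counts)

    @classmethod
    def zeros(cls, n_chromosomes: int) -> "FoldedSFS":
        return cls(n_chromosomes, np.zeros(n_chromosomes // 2, dtype=np.int64))


@dataclass
class GeneSiteCounts:
    """Site inventories, folded SFS and raw divergence for one gene.

    D values are raw difference counts (multiple-hit corrections are applied
    downstream on the pooled proportions).  ``p4_ts``/``p4_tv`` are observed
    transition/transversion difference counts at 4-fold sites (kept as counts
    so they pool exactly).
    """

    gene_id: str
    L0: int
    L4: int
    Li: int
    D0: int
    D4: int
    Di: int
    sfs0: FoldedSFS
    sfs4: FoldedSFS
    sfsi: FoldedSFS
    gc4: float
    D4_ts: int
    D4_tv: int

    def __post_init__(self) -> None:
        for d, l, name in ((self.D0, self.L0, "0-fold"), (self.D4, self.L4, "4-fold"),
                           (self.Di, self.Li, "intron")):
            if not 0 <= d <= l:
                raise ValueError(f"{self.gene_id}: {name} divergence {d} outside [0, {l}]")
        if self.D4_ts + self.D4_tv != self.D4:
            raise ValueError(f"{self.gene_id}: ts+tv parts must sum to D4")


@dataclass
class GeneCovariates:
    """Recombination rate, gene density, codon bias and gene-class label."""

    gene_id: str
    rr: float
    density: float
    fop: float
    immune_testes: bool = False

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise ValueError("recombination rate must be >= 0")
        if not 0.0 <= self.density <= 100_000.0:
            raise ValueError("gene density must lie in [0, 100000] per 100 kb")
        if not 0.0 <= self.fop <= 1.0:
            raise ValueError("Fop must lie in [0, 1]")


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

def build_folded_sfs(columns, n_chromosomes, strict=False):
    """Fold allele-count columns into a minor-allele-frequency spectrum.

    Parameters
    ----------
    columns : iterable of dict
        One ``{allele: count}`` mapping per site; counts must sum to
        ``n_chromosomes`` at every site.
    n_chromosomes : int
        Post-downsampling sample size n.
    strict : bool
        If True, a site with more than two alleles raises; otherwise such
        sites are excluded and tallied.

    Returns
    -------
    (FoldedSFS, n_monomorphic, n_excluded_multiallelic)
    """
    half = n_chromosomes // 2
    counts = np.zeros(half, dtype=np.int64)
    n_mono = 0
    n_multi = 0
    for col in columns:
        alleles = {a: c for a, c in col.items() if c > 0}
        total = sum(alleles.values())
        if total != n_chromosomes:
            raise ValueError(
                f"column allele counts sum to {total}, expected {n_chromosomes}"
            )
        if len(alleles) == 1:
            n_mono += 1
        elif len(alleles) == 2:
            minor = min(alleles.values())
            counts[min(minor, n_chromosomes - minor) - 1] += 1
        else:
            if strict:
                raise ValueError(f"column with {len(alleles)} alleles in strict mode")
            n_multi += 1
    return FoldedSFS(n_chromosomes, counts), n_mono, n_multi


def count_substitutions(hap_seq, outgroup_seq, columns):
    """Raw differences between one ingroup haplotype and the outgroup.

    Returns ``(D, L)``: D differences over L comparable columns (both bases
    called, i.e. in ACGT).  ``columns`` restricts the comparison to one site
    class.
    """
    called = set("ACGT")
    D = 0
    L = 0
    for c in columns:
        a, b = hap_seq[c].upper(), outgroup_seq[c].upper()
        if a in called and b in called:
            L += 1
            if a != b:
                D += 1
    return D, L


# ---------------------------------------------------------------------------
# multiple-hit corrections
# ---------------------------------------------------------------------------

def jc_correct(p: float) -> float:
    """Jukes-Cantor correction K = -(3/4) ln(1 - 4p/3) of a raw difference
    proportion p.  Used for 0-fold (and short-intron) divergence."""
    if p < 0:
        raise ValueError("difference proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p={p} >= 0.75: Jukes-Cantor correction saturated")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_uncorrect(k: float) -> float:
    """Inverse of :func:`jc_correct`: the raw difference proportion that a
    true per-site substitution rate ``k`` produces under the JC model."""
    if k < 0:
        raise ValueError("substitution rate must be >= 0")
    return 0.75 * -np.expm1(-4.0 * k / 3.0)


def tamura_correct(P: float, Q: float, theta_gc: float) -> float:
    """Tamura (1992) distance from transition (P) and transversion (Q)
    difference proportions, allowing for GC content ``theta_gc`` != 0.5.

    K = -h ln(1 - P/h - Q) - (1/2)(1-h) ln(1 - 2Q), h = 2 theta_gc (1-theta_gc).
    Reduces to Kimura's two-parameter distance at theta_gc = 0.5.
    """
    if P < 0 or Q < 0:
        raise ValueError("difference proportions must be >= 0")
    if not 0.0 < theta_gc < 1.0:
        raise ValueError("theta_gc must lie strictly between 0 and 1")
    h = 2.0 * theta_gc * (1.0 - theta_gc)
    arg1 = 1.0 - P / h - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0:
        raise SaturationError(f"Tamura correction saturated: 1 - P/h - Q = {arg1:.4g} <= 0")
    if arg2 <= 0.0:
        raise SaturationError(f"Tamura correction saturated: 1 - 2Q = {arg2:.4g} <= 0")
    return -h * np.log(arg1) - 0.5 * (1.0 - h) * np.log(arg2)


#: Transition partners (A<->G, C<->T).
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_ts_tv(base_a: str, base_b: str) -> str:
    """'ts' if the pair is a transition, 'tv' if a transversion."""
    if base_a == base_b:
        raise ValueError("bases are identical")
    return "ts" if (base_a.upper(), base_b.upper()) in _TRANSITIONS else "tv"


# ---------------------------------------------------------------------------
# codon usage bias
# ---------------------------------------------------------------------------

#: Default optimal-codon set for D. melanogaster (one preferred codon per
#: degenerate amino acid, the C/G-ending codons favoured in this species).
#: Configurable; any study should supply the table appropriate to its taxon.
DMEL_OPTIMAL_CODONS = frozenset({
    "GCC", "CGC", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC", "ATC",
    "CTG", "AAG", "TTC", "CCC", "TCC", "ACC", "TAC", "GTG",
})

_STOPS = {"TAA", "TAG", "TGA"}
_SINGLE_CODON = {"ATG", "TGG"}  # Met, Trp: no synonymous alternative


def compute_fop(coding_seq: str, optimal_codons=DMEL_OPTIMAL_CODONS) -> float:
    """Frequency of optimal codons.

    fop = (# codons in the optimal set) / (# codons of amino acids with
    synonymous alternatives).  Met, Trp and stop codons are excluded from the
    denominator.  Raises ValueError when the denominator is empty (gene is
    flagged upstream).
    """
    seq = coding_seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    n_opt = 0
    n_degenerate = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in _STOPS or codon in _SINGLE_CODON or not set(codon) <= set("ACGT"):
            continue
        n_degenerate += 1
        if codon in optimal_codons:
            n_opt += 1
    if n_degenerate == 0:
        raise ValueError("no codons with synonymous alternatives: Fop undefined")
    return n_opt / n_degenerate


# ---------------------------------------------------------------------------
# gene density and recombination rate
# ---------------------------------------------------------------------------

def _interval_union_length(intervals, lo, hi):
    """Total length covered by the union of [start, end) intervals clipped
    to [lo, hi).  Sweep-line over sorted starts."""
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def gene_density(coding_intervals, midpoint, chrom_length=None, half_window=50_000):
    """Coding-site density around a gene midpoint, per 100,000 sites.

    Counts positions within [midpoint - half_window, midpoint + half_window)
    covered by at least one coding exon of *any* annotated gene (interval
    union, each site once).  At chromosome ends the window is truncated and
    the count rescaled to the surveyed length so the units stay per 100 kb.
    """
    lo = midpoint - half_window
    hi = midpoint + half_window
    if chrom_length is not None:
        if not 0 <= midpoint < chrom_length:
            raise ValueError(f"midpoint {midpoint} outside chromosome [0, {chrom_length})")
        lo = max(lo, 0)
        hi = min(hi, chrom_length)
    surveyed = hi - lo
    if surveyed <= 0:
        raise ValueError("empty survey window")
    covered = _interval_union_length(coding_intervals, lo, hi)
    return covered / surveyed * 100_000.0


def read_recombination_map(path) -> pd.DataFrame:
    """Read a TSV recombination map: arm, start, end, cM_per_Mb.

    Coordinates are 0-based half-open 100-kb tiles; windows must tile each
    arm without overlap.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["arm", "start", "end", "cM_per_Mb"], header=0)
    for arm, sub in df.groupby("arm"):
        s = sub.sort_values("start")
        if (s["end"].values[:-1] > s["start"].values[1:]).any():
            raise ValueError(f"overlapping recombination windows on arm {arm}")
    return df


def assign_rr(recmap: pd.DataFrame, arm: str, midpoint: int):
    """Crossover rate (cM/Mb) of the window containing the gene midpoint.

    Half-open windows: a midpoint exactly at a boundary belongs to the window
    starting there.  Returns None when the midpoint is not covered (the gene
    is then flagged and excluded upstream); no smoothing is applied.
    """
    sub = recmap[recmap["arm"] == arm]
    hit = sub[(sub["start"] <= midpoint) & (midpoint < sub["end"])]
    if hit.empty:
        return None
    return float(hit["cM_per_Mb"].iloc[0])
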