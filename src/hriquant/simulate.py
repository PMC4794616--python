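"""Synthetic gene-level data with known ground truth.

Generates per-gene site counts, folded spectra, divergence and covariates
with the statistical structure the analysis assumes: 4-fold (and
short-intron) spectra are neutral under a two-epoch demography; 0-fold
spectra follow a gamma DFE; divergence has a nonadaptive component (the
DFE-averaged relative fixation rate times the local mutation rate) plus an
adaptive component whose per-site rate follows an imposed curvilinear law

    Ka+(rr) = a + b * exp(-c * rr)

in the local recombination rate.  Counts are drawn at the spectrum level
(Poisson random field) - the analysis consumes only spectra and divergence,
so no forward simulation of linkage is needed; interference enters purely
through the imposed Ka+(rr) curve, making the generator an oracle for
estimator-recovery tests rather than a model of the mechanism.

Raw difference counts are drawn at the *observed* scale: true substitution
rates are pushed through the inverse Jukes-Cantor / Tamura maps so that the
analysis-side multiple-hit corrections recover the generating rates.

`emit_fixtures` additionally materializes genes as FASTA alignments + GFF3
annotation + a recombination map, so the full I/O path can be exercised and
round-tripped against the directly simulated counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._wf import SFSEngine
from .counts import (FoldedSFS, GeneCovariates, GeneSiteCounts, jc_uncorrect,
                     tamura_correct)
from .binning import GeneRecord
from .dfe import Demography, GammaDFE, SelectionGrid, fixation_factor

__all__ = ["SimParams", "SimTruth", "simulate_gene_counts", "true_fhri",
           "emit_fixtures"]


@dataclass
class SimParams:
    """Generator settings; defaults emulate an autosomal Drosophila-like
    coding genome surveyed in 128 lines with a yakuba-distance outgroup.

    theta4 is the scaled per-site mutation rate at neutral sites (pairwise
    diversity scale, ~0.02 at 4-fold sites in D. melanogaster); k4_mean the
    true 4-fold substitution rate to the outgroup (~0.19); the DFE and the
    adaptive-curve asymptote are in the range inferred for this system.  The
    adaptive curve must be non-negative over the recombination support, so
    the default keeps the published-scale asymptote (0.0126) with a slightly
    shallower amplitude than the negative-at-zero fitted values.
    """

    n_genes: int = 6120
    n_chromosomes: int = 128
    theta4: float = 0.02
    theta0_scale: float = 1.0
    dfe: GammaDFE = field(default_factory=lambda: GammaDFE(2000.0, 0.3))
    demography: Demography = field(default_factory=lambda: Demography(1.5, 0.1))
    adaptive_curve: tuple = (0.0126, -0.0121, 2.0)
    # recombination: point mass near zero + a broad positive component, so
    # both sides of the 2 cM/Mb threshold are populated
    rr_zero_frac: float = 0.25
    rr_low_max: float = 0.5
    rr_gamma_shape: float = 2.0
    rr_gamma_scale: float = 1.5
    rr_max: float = 10.0
    density_range: tuple = (5_000.0, 40_000.0)
    mean_L0: float = 1000.0
    sigma_L0: float = 0.5
    l4_ratio: float = 0.35
    mut_sigma: float = 0.3       # lognormal spread of the per-gene theta multiplier
    k4_mean: float = 0.19
    ts_fraction: float = 0.65    # transition share of 4-fold differences
    gc4: float = 0.5
    intron_frac: float = 0.55    # genes with two qualifying short introns
    li_sites: int = 46           # 2 introns x positions 8-30
    fop_mean: float = 0.5
    fop_sd: float = 0.15
    fop_rr_slope: float = 0.0
    n_pop_grid: int = 200
    rr_threshold: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        a, b, c = self.adaptive_curve
        rr = np.linspace(0.0, self.rr_max, 512)
        if np.any(a + b * np.exp(-c * rr) < -1e-12):
            raise ValueError("adaptive_curve is negative inside the rr support")

    def ka_plus_at(self, rr):
        a, b, c = self.adaptive_curve
        return a + b * np.exp(-c * np.asarray(rr, float))


@dataclass
class SimTruth:
    """Per-gene generating values plus the global truth they imply."""

    gene_ids: list
    rr: np.ndarray
    density: np.ndarray
    theta_multiplier: np.ndarray
    L0: np.ndarray
    expected_D4: np.ndarray
    expected_adaptive_D0: np.ndarray
    ka_plus_true: np.ndarray
    fixation_factor: float
    f_hri: float
    rr_threshold: float


def true_fhri(params: SimParams, rr, L0, rr_threshold=None) -> float:
    """Ground-truth f_HRi implied by the generating curve and site totals.

    The no-interference rate is the curve's asymptote ``a``; the lost total
    integrates (a - Ka+(rr)) * L0 over genes below the recombination
    threshold; the no-interference total runs over all genes.
    """
    a, b, c = params.adaptive_curve
    if rr_threshold is None:
        rr_threshold = params.rr_threshold
    rr = np.asarray(rr, float)
    L0 = np.asarray(L0, float)
    total_no = float(np.sum(L0 * a))
    if total_no == 0:
        return 0.0
    below = rr < rr_threshold
    lost = float(np.sum(L0[below] * (a - params.ka_plus_at(rr[below]))))
    return lost / total_no


def _draw_rr(params, rng, n):
    low = rng.uniform(0.0, params.rr_low_max, size=n)
    broad = rng.gamma(params.rr_gamma_shape, params.rr_gamma_scale, size=n)
    broad = np.clip(broad, 0.0, params.rr_max)
    use_low = rng.random(n) < params.rr_zero_frac
    return np.where(use_low, low, broad)


def _invert_tamura(k_target, ts_fraction, gc):
    """Observed total difference proportion p whose (P, Q) = (fr p, (1-fr) p)
    Tamura-corrects back to ``k_target``."""
    if k_target <= 0:
        return 0.0
    fr = ts_fraction
    h = 2.0 * gc * (1.0 - gc)
    p_hi = min(1.0 / (fr / h + (1.0 - fr)), 0.5 / (1.0 - fr)) * (1 - 1e-9)

    def f(p):
        return tamura_correct(fr * p, (1.0 - fr) * p, gc) - k_target

    if f(p_hi) < 0:
        raise ValueError(f"k4 target {k_target} beyond Tamura saturation")
    return brentq(f, 0.0, p_hi, xtol=1e-12)


def _expected_class_sfs(engine, params, grid):
    """Unit-inflow folded intensity vectors and the per-site calibration.

    Returns (neutral_vec, selected_vec, per_site_unit) where expected folded
    counts for a class are L * theta_class * per_site_unit * vec:
    calibrated so a neutral constant-size class has E[#segregating] =
    L * theta * a_n (Watterson).
    """
    n = params.n_chromosomes
    d = params.demography
    f_const = engine.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=n, normalize=False)
    a_n = np.sum(1.0 / np.arange(1, n))
    unit = a_n / f_const.sum()
    f_neu = engine.expected_folded_sfs(0.0, d.size_ratio, d.t2, n_sample=n,
                                       normalize=False)
    w = grid.weights(params.dfe)
    f_sel = np.zeros_like(f_neu)
    for wj, S in zip(w, grid.S):
        if wj <= 0:
            continue
        f_sel += wj * engine.expected_folded_sfs(
            S, d.size_ratio, d.t2, n_sample=n, normalize=False)
    return f_neu, f_sel, unit


def _simulate_one_gene(params, rng, gene_id, rr, L0, L4, m_theta,
                       f_neu, f_sel, unit, e_r, has_introns):
    n = params.n_chromosomes
    th4 = params.theta4 * m_theta
    th0 = th4 * params.theta0_scale

    sfs4 = FoldedSFS(n, rng.poisson(L4 * th4 * unit * f_neu))
    sfs0 = FoldedSFS(n, rng.poisson(L0 * th0 * unit * f_sel))

    k4_true = params.k4_mean * m_theta
    p4 = _invert_tamura(k4_true, params.ts_fraction, params.gc4)
    P, Q = params.ts_fraction * p4, (1.0 - params.ts_fraction) * p4
    d4_ts, d4_tv, _ = rng.multinomial(L4, [P, Q, 1.0 - P - Q])

    ka_plus = float(params.ka_plus_at(rr))
    k0_total = k4_true * params.theta0_scale * e_r + ka_plus
    D0 = int(rng.binomial(L0, jc_uncorrect(k0_total)))

    if has_introns:
        Li = params.li_sites
        sfsi = FoldedSFS(n, rng.poisson(Li * th4 * unit * f_neu))
        Di = int(rng.binomial(Li, jc_uncorrect(k4_true)))
    else:
        Li, Di, sfsi = 0, 0, FoldedSFS.zeros(n)

    counts = GeneSiteCounts(
        gene_id=gene_id, L0=int(L0), L4=int(L4), Li=Li,
        D0=D0, D4=int(d4_ts + d4_tv), Di=Di,
        sfs0=sfs0, sfs4=sfs4, sfsi=sfsi,
        gc4=params.gc4, D4_ts=int(d4_ts), D4_tv=int(d4_tv))
    return counts, ka_plus, k4_true


def simulate_gene_counts(params: SimParams, seed=None, engine=None):
    """Draw a full synthetic gene set.

    Returns (genes, truth): a list of GeneRecord (counts + covariates, no
    K4 split yet) and the SimTruth holding every generating value plus the
    implied global f_HRi.
    """
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = SFSEngine(n_grid=params.n_pop_grid)
    elif engine.n_grid != params.n_pop_grid:
        raise ValueError("engine grid does not match params.n_pop_grid")
    grid = SelectionGrid()
    f_neu, f_sel, unit = _expected_class_sfs(engine, params, grid)
    e_r = fixation_factor(params.dfe, grid)

    n = params.n_genes
    rr = _draw_rr(params, rng, n)
    density = rng.uniform(*params.density_range, size=n)
    m_theta = (rng.lognormal(-params.mut_sigma ** 2 / 2.0, params.mut_sigma, size=n)
               if params.mut_sigma > 0 else np.ones(n))
    L0 = np.maximum(30, rng.lognormal(
        np.log(params.mean_L0) - params.sigma_L0 ** 2 / 2.0, params.sigma_L0,
        size=n)).astype(int)
    L4 = np.maximum(10, np.round(params.l4_ratio * L0)).astype(int)
    fop = np.clip(rng.normal(params.fop_mean, params.fop_sd, size=n)
                  + params.fop_rr_slope * rr, 0.0, 1.0)
    has_introns = rng.random(n) < params.intron_frac

    width = len(str(n))
    genes = []
    ka_true = np.empty(n)
    exp_d4 = np.empty(n)
    for i in range(n):
        gid = f"g{i:0{width}d}"
        counts, kap, k4t = _simulate_one_gene(
            params, rng, gid, rr[i], L0[i], L4[i], m_theta[i],
            f_neu, f_sel, unit, e_r, has_introns[i])
        ka_true[i] = kap
        exp_d4[i] = L4[i] * k4t
        cov = GeneCovariates(gene_id=gid, rr=float(rr[i]),
                             density=float(density[i]), fop=float(fop[i]))
        genes.append(GeneRecord(counts=counts, covariates=cov))

    truth = SimTruth(
        gene_ids=[g.gene_id for g in genes],
        rr=rr, density=density, theta_multiplier=m_theta,
        L0=L0.astype(float), expected_D4=exp_d4,
        expected_adaptive_D0=L0 * ka_true, ka_plus_true=ka_true,
        fixation_factor=e_r,
        f_hri=true_fhri(params, rr, L0),
        rr_threshold=params.rr_threshold)
    return genes, truth


# ---------------------------------------------------------------------------
# fixture emission (FASTA + GFF3 + recombination map)
# ---------------------------------------------------------------------------

_CORE_MARGIN = 8  # codons; matches the reader's default exon-core margin


def _place_variants(rng, capacity_cols, needs):
    """Assign disjoint column indices for each (label, count) need."""
    total = sum(c for _, c in needs)
    if total > len(capacity_cols):
        raise ValueError(
            f"fixture gene needs {total} variant columns but only "
            f"{len(capacity_cols)} are available; lower theta or divergence")
    chosen = rng.choice(len(capacity_cols), size=total, replace=False)
    out = {}
    pos = 0
    for label, cnt in needs:
        out[label] = [capacity_cols[i] for i in chosen[pos:pos + cnt]]
        pos += cnt
    return out


def emit_fixtures(params: SimParams, seed, out_dir, engine=None):
    """Materialize a small synthetic gene set as FASTA + GFF3 + map files.

    Genes are built from GGN codons (two 0-fold sites + one conserved 4-fold
    site each) and ATG filler codons (three 0-fold sites), flanked by
    exon-core margin codons, with two 60-bp introns appended.  Each gene's
    drawn L0 is snapped to the nearest composition-realizable value
    (L0 = 2 L4 + 3 m); haplotype 0 carries no minor alleles so it can serve
    as a pinned divergence line for exact round-trip comparisons.

    Returns (genes, truth) for the *realized* counts; files land in
    ``out_dir``: alignments/<gene>.fasta, annotation.gff3, recmap.tsv,
    truth.json.
    """
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = SFSEngine(n_grid=params.n_pop_grid)
    grid = SelectionGrid()
    f_neu, f_sel, unit = _expected_class_sfs(engine, params, grid)
    e_r = fixation_factor(params.dfe, grid)
    n_hap = params.n_chromosomes

    ngenes = params.n_genes
    rr_all = _draw_rr(params, rng, ngenes)
    density_all = rng.uniform(*params.density_range, size=ngenes)
    m_all = (rng.lognormal(-params.mut_sigma ** 2 / 2, params.mut_sigma, ngenes)
             if params.mut_sigma > 0 else np.ones(ngenes))

    gff_lines = ["##gff-version 3"]
    recmap_lines = ["arm\tstart\tend\tcM_per_Mb"]
    genes = []
    width = len(str(ngenes))
    for i in range(ngenes):
        gid = f"g{i:0{width}d}"
        L0_draw = max(60, int(rng.lognormal(
            np.log(params.mean_L0) - params.sigma_L0 ** 2 / 2, params.sigma_L0)))
        L4 = max(10, int(round(params.l4_ratio * L0_draw)))
        m_fill = max(4, int(round((L0_draw - 2 * L4) / 3.0)))
        L0 = 2 * L4 + 3 * m_fill

        counts, _, _ = _simulate_one_gene(
            params, rng, gid, rr_all[i], L0, L4, m_all[i],
            f_neu, f_sel, unit, e_r, has_introns=True)
        # every 0-fold variant column sits at pos 1 of an ATG filler codon;
        # widen the filler block if the draw needs more columns than planned
        need0 = int(counts.sfs0.counts.sum()) + counts.D0
        if need0 > m_fill:
            m_fill = need0
            L0 = 2 * L4 + 3 * m_fill
            counts = replace(counts, L0=L0)
        need4 = int(counts.sfs4.counts.sum()) + counts.D4
        if need4 > L4:
            raise ValueError(
                f"{gid}: 4-fold variant draw ({need4}) exceeds L4={L4}; "
                "use a smaller theta4/k4_mean for fixtures")

        # --- build the exon: margins + GGG block + ATG block + margins
        margin = ["ATG"] * _CORE_MARGIN
        core = ["GGG"] * L4 + ["ATG"] * m_fill
        codons = margin + core + margin
        exon_len = 3 * len(codons)
        # columns usable for variation: pos3 of each GGG, pos1 of each ATG
        g_cols = [3 * (_CORE_MARGIN + j) + 2 for j in range(L4)]
        a_cols = [3 * (_CORE_MARGIN + L4 + j) for j in range(m_fill)]

        sfs4 = counts.sfs4.counts
        needs4 = [(f"seg4_{k + 1}", int(c)) for k, c in enumerate(sfs4) if c > 0]
        needs4 += [("div4_ts", counts.D4_ts), ("div4_tv", counts.D4_tv)]
        placed4 = _place_variants(rng, g_cols, needs4)
        sfs0 = counts.sfs0.counts
        needs0 = [(f"seg0_{k + 1}", int(c)) for k, c in enumerate(sfs0) if c > 0]
        needs0 += [("div0", counts.D0)]
        placed0 = _place_variants(rng, a_cols, needs0)

        exon = "".join(codons)
        haps = [list(exon) for _ in range(n_hap)]
        outg = list(exon)
        for label, cols in placed4.items():
            for col in cols:
                if label == "div4_ts":
                    outg[col] = "A"     # GGG -> GGA, transition, same aa
                elif label == "div4_tv":
                    outg[col] = "T"     # GGG -> GGT, transversion, same aa
                else:
                    k = int(label.split("_")[1])
                    for h in range(1, k + 1):   # haplotype 0 stays reference
                        haps[h][col] = "A"
        for label, cols in placed0.items():
            for col in cols:
                if label == "div0":
                    outg[col] = "G"     # ATG -> GTG: amino acid change
                else:
                    k = int(label.split("_")[1])
                    for h in range(1, k + 1):
                        haps[h][col] = "G"

        # --- two 60-bp introns; neutral sites at positions 8..30
        intron_cols_per = list(range(7, 30))  # 0-based within the intron
        intr_seqs = []
        intron_blocks = []
        icols_abs = []
        for it in range(2):
            body = ["C"] * 60
            body[0:2] = ["G", "T"]
            body[-2:] = ["A", "G"]
            start = exon_len + it * 60
            intron_blocks.append((start, start + 60))
            icols_abs.extend(start + c for c in intron_cols_per)
            intr_seqs.append(body)
        cap_i = list(range(len(icols_abs)))
        sfsi = counts.sfsi.counts
        needsi = [(f"segi_{k + 1}", int(c)) for k, c in enumerate(sfsi) if c > 0]
        needsi += [("divi", counts.Di)]
        placedi = _place_variants(rng, cap_i, needsi)
        intron_concat = "".join("".join(b) for b in intr_seqs)
        ihaps = [list(intron_concat) for _ in range(n_hap)]
        ioutg = list(intron_concat)
        rel0 = exon_len
        for label, idxs in placedi.items():
            for idx in idxs:
                col = icols_abs[idx] - rel0
                if label == "divi":
                    ioutg[col] = "T"
                else:
                    k = int(label.split("_")[1])
                    for h in range(1, k + 1):
                        ihaps[h][col] = "T"

        full_haps = ["".join(h) + "".join(ih) for h, ih in zip(haps, ihaps)]
        full_outg = "".join(outg) + "".join(ioutg)

        fasta = out / "alignments" / f"{gid}.fasta"
        with open(fasta, "w") as fh:
            for h, seq in enumerate(full_haps):
                fh.write(f">line{h:03d}\n{seq}\n")
            fh.write(f">outgroup|yak\n{full_outg}\n")
        gff_lines.append(
            f"{gid}\tsim\texon\t1\t{exon_len}\t.\t+\t.\tID={gid}.e1")
        for j, (s, e) in enumerate(intron_blocks):
            gff_lines.append(
                f"{gid}\tsim\tintron\t{s + 1}\t{e}\t.\t+\t.\tID={gid}.i{j + 1}")
        recmap_lines.append(f"{gid}\t0\t100000\t{rr_all[i]:.6f}")

        # realized gc4 as the reader computes it: mean GC over the divergence
        # haplotype (0) and the outgroup at 4-fold columns
        gc_hap = np.mean([full_haps[0][c] in "GC" for c in g_cols])
        gc_out = np.mean([full_outg[c] in "GC" for c in g_cols])
        counts.gc4 = float((gc_hap + gc_out) / 2.0)
        cov = GeneCovariates(gene_id=gid, rr=float(rr_all[i]),
                             density=float(density_all[i]),
                             fop=float(np.clip(rng.normal(params.fop_mean,
                                                          params.fop_sd), 0, 1)))
        genes.append(GeneRecord(counts=counts, covariates=cov))

    (out / "annotation.gff3").write_text("\n".join(gff_lines) + "\n")
    (out / "recmap.tsv").write_text("\n".join(recmap_lines) + "\n")
    truth = SimTruth(
        gene_ids=[g.gene_id for g in genes],
        rr=rr_all, density=density_all, theta_multiplier=m_all,
        L0=np.array([g.counts.L0 for g in genes], float),
        expected_D4=np.array([g.counts.D4 for g in genes], float),
        expected_adaptive_D0=np.array(
            [g.counts.L0 * params.ka_plus_at(r) for g, r in zip(genes, rr_all)]),
        ka_plus_true=params.ka_plus_at(rr_all),
        fixation_factor=e_r,
        f_hri=true_fhri(params, rr_all,
                        np.array([g.counts.L0 for g in genes], float)),
        rr_threshold=params.rr_threshold)
    with open(out / "truth.json", "w") as fh:
        json.dump({"f_hri": truth.f_hri,
                   "fixation_factor": truth.fixation_factor,
                   "gene_ids": truth.gene_ids,
                   "rr": truth.rr.tolist(),
                   "ka_plus_true": truth.ka_plus_true.tolist()}, fh, indent=1)
    return genes, truth
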