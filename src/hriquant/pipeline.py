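"""End-to-end orchestration: alignments -> counts -> bins -> f_HRi report.

The stages are importable on their own (see the stage modules); this module
wires them together behind a single config, adds the bookkeeping a full run
needs (drop tallies, seeds, manifest) and validates the conservation
invariants of a finished output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .sites import (GeneAlignment, classify_coding_sites, downsample_column,
                    extract_short_intron_sites, filter_and_trim_exons,
                    pick_divergence_haplotype, read_gene_alignments)
from .counts import (DMEL_OPTIMAL_CODONS, FoldedSFS, GeneCovariates,
                     GeneSiteCounts, assign_rr, build_folded_sfs,
                     classify_ts_tv, compute_fop, count_substitutions,
                     gene_density, read_recombination_map)
from .binning import GeneRecord, pool_bin, rank_bin, split_k4_three, split_k4_two
from .dfe import SFSEngine, SelectionGrid, estimate_alpha_ka_plus, fit_bin
from .hri import asymptotic_ka, estimate_fhri, loess_predict

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "process_alignment", "fhri_from_genes",
           "fhri_fast", "run_all", "validate_tables"]


# ---------------------------------------------------------------------------
# per-gene processing
# ---------------------------------------------------------------------------

def process_alignment(aln: GeneAlignment, n_chromosomes, rng,
                      core_margin_codons=8, divergence_haplotype=None,
                      optimal_codons=DMEL_OPTIMAL_CODONS):
    """Turn one gene alignment into (GeneSiteCounts, fop) or (None, reason).

    Applies the exon filters, classifies sites, downsamples every column to
    ``n_chromosomes`` alleles, folds the spectra, and counts raw divergence
    on one randomly chosen ingroup chromosome (pass ``divergence_haplotype``
    to pin it).  Columns where the outgroup is uncalled are excluded from
    every class.
    """
    retained = filter_and_trim_exons(aln.exons, aln.ingroup_seqs, aln.outgroup_seq)
    if not retained:
        return None, "no_exon_passed_filters"
    s0, s4 = classify_coding_sites(retained, aln.ingroup_seqs, aln.outgroup_seq,
                                   core_margin_codons)
    si = extract_short_intron_sites(aln.introns, aln.ingroup_seqs, aln.outgroup_seq)
    if not s0 and not s4:
        return None, "no_classified_sites"
    if divergence_haplotype is None:
        div_hap = pick_divergence_haplotype(aln.n_ingroup, rng)
    else:
        div_hap = int(divergence_haplotype)
    hap = aln.ingroup_seqs[div_hap]
    outg = aln.outgroup_seq

    def usable(cols):
        kept, dicts = [], []
        for c in cols:
            if outg[c].upper() not in "ACGT":
                continue  # divergence undefined: drop from all classes
            d = downsample_column([s[c] for s in aln.ingroup_seqs],
                                  n_chromosomes, rng)
            if d is None:
                continue
            kept.append(c)
            dicts.append(d)
        return kept, dicts

    k0, d0 = usable(s0)
    k4, d4 = usable(s4)
    ki, di = usable(si)
    sfs0, _, _ = build_folded_sfs(d0, n_chromosomes)
    sfs4, _, _ = build_folded_sfs(d4, n_chromosomes)
    sfsi, _, _ = build_folded_sfs(di, n_chromosomes)
    D0, _ = count_substitutions(hap, outg, k0)
    D4, _ = count_substitutions(hap, outg, k4)
    Di, _ = count_substitutions(hap, outg, ki)
    ts = sum(1 for c in k4
             if hap[c] != outg[c] and {hap[c], outg[c]} <= set("ACGT")
             and classify_ts_tv(hap[c], outg[c]) == "ts")
    if k4:
        gc_vals = [b in "GCgc" for c in k4 for b in (hap[c], outg[c])]
        gc4 = float(np.mean(gc_vals))
    else:
        gc4 = 0.5
    counts = GeneSiteCounts(
        gene_id=aln.gene_id, L0=len(k0), L4=len(k4), Li=len(ki),
        D0=D0, D4=D4, Di=Di, sfs0=sfs0, sfs4=sfs4, sfsi=sfsi,
        gc4=gc4, D4_ts=ts, D4_tv=D4 - ts)
    cds = "".join(hap[s:e] for s, e in retained)
    try:
        fop = compute_fop(cds, optimal_codons)
    except ValueError:
        fop = float("nan")
    return counts, fop


# ---------------------------------------------------------------------------
# the core analysis: genes -> bins -> Ka+ -> f_HRi
# ---------------------------------------------------------------------------

def fhri_from_genes(genes, rng, n_bins=45, engine=None, grid=None,
                    rr_threshold=2.0, clamp=False, span=1.0,
                    fixation=None, split=False):
    """Recombination-bin analysis of a gene list, through to f_HRi.

    Genes are rank-binned by recombination rate; each bin's Ka+ is estimated
    either by the full DFE stage (demography + gamma fit per bin) or, when
    ``fixation`` (a known DFE-averaged relative fixation rate) is supplied,
    by the closed-form shortcut d_exp = k4 * fixation.  A LOESS curve
    (span 1) of bin Ka+ against bin mean recombination rate supplies the
    per-bin predictions, the mean Ka+ above ``rr_threshold`` the asymptote,
    and the loss equations the f_HRi.

    With ``split=True`` each gene's K4 is first split two ways and the
    second block is used for estimation (required whenever the bins, or a
    surrounding grouping, were keyed on 4-fold divergence).

    Returns (HRiResult, bins_dataframe).
    """
    genes = list(genes)
    if split:
        genes = [GeneRecord(g.counts, g.covariates,
                            split_k4_two(g.gene_id, g.counts.D4, g.counts.L4, rng))
                 for g in genes]
    bins = rank_bin(genes, lambda g: g.covariates.rr, n_bins)
    pooled = [pool_bin(b, f"rr{j:03d}", estimation="k4_2" if split else "full")
              for j, b in enumerate(bins)]
    rows = []
    if fixation is None and engine is None:
        engine = SFSEngine()
    if grid is None:
        grid = SelectionGrid()
    for pb in pooled:
        if fixation is not None:
            fit = estimate_alpha_ka_plus(
                None, None, pb.D0, pb.L0, pb.D4, pb.L4, pb.gc4,
                pb.D4_ts / pb.L4, pb.D4_tv / pb.L4, fixation=fixation)
        else:
            fit = fit_bin(pb, engine, grid)
        rows.append({"bin_id": pb.bin_id, "n_genes": len(pb.gene_ids),
                     "mean_rr": pb.mean_rr, "mean_density": pb.mean_density,
                     "mean_fop": pb.mean_fop, "L0": pb.L0, "L4": pb.L4,
                     "D0": pb.D0, "D4": pb.D4, "alpha": fit.alpha,
                     "omega_a": fit.omega_a, "ka": fit.ka, "k4": fit.k4,
                     "ka_plus": fit.ka_plus, "loglik": fit.loglik,
                     "size_ratio": fit.demography.size_ratio if fit.demography else np.nan,
                     "t2": fit.demography.t2 if fit.demography else np.nan,
                     "gamma_mean": fit.dfe.gamma_mean if fit.dfe else np.nan,
                     "shape_beta": fit.dfe.shape_beta if fit.dfe else np.nan})
    df = pd.DataFrame(rows)
    preds = loess_predict(df["mean_rr"].values, df["ka_plus"].values, span=span)
    ka_no = asymptotic_ka(list(zip(df["mean_rr"], df["ka_plus"])), rr_threshold)
    result = estimate_fhri(df["mean_rr"].values, df["L0"].values, preds,
                           ka_no, rr_threshold=rr_threshold, clamp=clamp)
    df["loess_pred"] = result.per_bin_predictions
    return result, df


def fhri_fast(genes, rng, n_bins, fixation, rr_threshold=2.0, clamp=False,
              span=1.0, split=False):
    """Vectorized counts-only f_HRi, for nested resampling studies.

    Identical analysis logic to :func:`fhri_from_genes` with a *known*
    DFE-averaged relative fixation rate (so no spectra are needed and no
    per-bin likelihood fit runs): per-bin Ka+ = ka - k4 * fixation with the
    same multiple-hit corrections, then LOESS, asymptote and the loss
    equations.  Fast enough for bootstrap-inside-simulation calibration
    studies (thousands of full pipeline replicates).

    Returns the HRiResult only.
    """
    genes = list(genes)
    ids = np.array([g.gene_id for g in genes])
    rr = np.array([g.covariates.rr for g in genes])
    L0 = np.array([g.counts.L0 for g in genes], float)
    D0 = np.array([g.counts.D0 for g in genes], float)
    L4 = np.array([g.counts.L4 for g in genes], float)
    D4 = np.array([g.counts.D4 for g in genes], float)
    ts = np.array([g.counts.D4_ts for g in genes], float)
    tv = np.array([g.counts.D4_tv for g in genes], float)
    gc4 = np.array([g.counts.gc4 for g in genes], float)
    if split:
        n_draw = np.floor(0.5 * L4 + 0.5).astype(int)
        d41 = rng.hypergeometric(D4.astype(int), (L4 - D4).astype(int), n_draw)
        frac_ts = np.divide(ts, D4, out=np.zeros_like(ts), where=D4 > 0)
        D4 = D4 - d41
        L4 = L4 - n_draw
        ts = D4 * frac_ts
        tv = D4 - ts

    order = np.lexsort((ids, rr))
    size = len(genes) // n_bins
    if size < 1:
        raise ValueError("more bins than genes")
    keep = order[: size * n_bins]
    edges = np.arange(0, size * n_bins, size)

    def bsum(v):
        return np.add.reduceat(v[keep], edges)

    bL0, bD0, bL4, bts, btv = (bsum(v) for v in (L0, D0, L4, ts, tv))
    brr = bsum(rr) / size
    bgc = bsum(gc4 * L4) / np.maximum(bsum(L4), 1e-12)
    ka = -0.75 * np.log1p(-4.0 * (bD0 / bL0) / 3.0)
    h = 2.0 * bgc * (1.0 - bgc)
    P, Q = bts / bL4, btv / bL4
    k4 = -h * np.log(1.0 - P / h - Q) - 0.5 * (1.0 - h) * np.log(1.0 - 2.0 * Q)
    ka_plus = ka - k4 * fixation
    preds = loess_predict(brr, ka_plus, span=span)
    ka_no = asymptotic_ka(list(zip(brr, ka_plus)), rr_threshold)
    return estimate_fhri(brr, bL0, preds, ka_no, rr_threshold=rr_threshold,
                         clamp=clamp)


# ---------------------------------------------------------------------------
# config and full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    alignments_dir: str
    gff: str
    recmap: str
    out_dir: str
    labels: str | None = None        # optional TSV: gene_id <tab> immune_testes
    n_chromosomes: int = 128
    n_bins: int = 45
    rr_threshold: float = 2.0
    rr_threshold_high: float = 5.0   # for categories without an asymptote
    clamp_negative_predictions: bool = False
    core_margin_codons: int = 8
    engine_grid: int = 200
    master_seed: int = 1
    divergence_haplotype: int | None = None  # None = random per gene
    min_bins_for_hri: int = 5
    loess_span: float = 1.0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("alignments_dir", "gff", "recmap"):
            if not Path(getattr(cfg, key)).exists():
                raise FileNotFoundError(f"config path {key}={getattr(cfg, key)!r} "
                                        "does not exist")
        if cfg.rr_threshold <= 0 or cfg.rr_threshold_high <= 0:
            raise ValueError("recombination thresholds must be > 0")
        return cfg


def _sfs_str(sfs: FoldedSFS) -> str:
    return ",".join(str(int(c)) for c in sfs.counts)


def run_all(config: PipelineConfig):
    """Run every stage from a config; writes TSV/JSON outputs + manifest.

    Deterministic for a fixed config: all randomness flows from the master
    seed.  Returns the output directory path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.master_seed)
    recmap = read_recombination_map(config.recmap)
    labels = {}
    if config.labels:
        lab = pd.read_csv(config.labels, sep="\t")
        labels = dict(zip(lab["gene_id"], lab["immune_testes"].astype(bool)))

    # gene density needs the coding intervals of *all* annotated genes
    import gffutils
    db = gffutils.create_db(str(config.gff), ":memory:", force=True,
                            merge_strategy="create_unique")
    exons_by_arm = {}
    span_by_gene = {}
    for f in db.features_of_type("exon"):
        exons_by_arm.setdefault(f.seqid, []).append((f.start - 1, f.end))
        s, e = span_by_gene.get(f.seqid, (f.start - 1, f.end))
        span_by_gene[f.seqid] = (min(s, f.start - 1), max(e, f.end))

    tallies = {"input": 0, "no_exon_passed_filters": 0, "no_classified_sites": 0,
               "no_recombination_rate": 0, "kept": 0}
    genes = []
    count_rows = []
    cov_rows = []
    split_rows = []
    for aln in read_gene_alignments(config.alignments_dir, config.gff):
        tallies["input"] += 1
        counts, fop = process_alignment(
            aln, config.n_chromosomes, rng, config.core_margin_codons,
            config.divergence_haplotype)
        if counts is None:
            tallies[fop if isinstance(fop, str) else "no_classified_sites"] += 1
            logger.info("gene_dropped gene=%s reason=%s", aln.gene_id, fop)
            continue
        s, e = span_by_gene[aln.gene_id]
        midpoint = (s + e) // 2
        rr = assign_rr(recmap, aln.gene_id, midpoint)
        if rr is None:
            tallies["no_recombination_rate"] += 1
            logger.info("gene_dropped gene=%s reason=no_recombination_rate",
                        aln.gene_id)
            continue
        density = gene_density(exons_by_arm[aln.gene_id], midpoint)
        cov = GeneCovariates(gene_id=aln.gene_id, rr=rr, density=density,
                             fop=0.0 if np.isnan(fop) else fop,
                             immune_testes=labels.get(aln.gene_id, False))
        split = split_k4_three(aln.gene_id, counts.D4, counts.L4, rng)
        genes.append(GeneRecord(counts, cov, split))
        tallies["kept"] += 1
        count_rows.append({
            "gene_id": counts.gene_id, "L0": counts.L0, "L4": counts.L4,
            "Li": counts.Li, "D0": counts.D0, "D4": counts.D4, "Di": counts.Di,
            "D4_ts": counts.D4_ts, "D4_tv": counts.D4_tv, "gc4": counts.gc4,
            "sfs0": _sfs_str(counts.sfs0), "sfs4": _sfs_str(counts.sfs4),
            "sfsi": _sfs_str(counts.sfsi)})
        cov_rows.append({"gene_id": cov.gene_id, "rr": cov.rr,
                         "density": cov.density, "fop": cov.fop,
                         "immune_testes": cov.immune_testes})
        split_rows.append({"gene_id": split.gene_id,
                           "D4_1": split.d4_parts[0], "D4_2": split.d4_parts[1],
                           "D4_3": split.d4_parts[2], "D4": counts.D4,
                           "share_1": split.shares[0], "share_2": split.shares[1],
                           "share_3": split.shares[2]})

    pd.DataFrame(count_rows).to_csv(out / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(cov_rows).to_csv(out / "covariates.tsv", sep="\t", index=False)
    pd.DataFrame(split_rows).to_csv(out / "splits.tsv", sep="\t", index=False)

    report = {"status": "ok", "rr_threshold": config.rr_threshold,
              "clamp": config.clamp_negative_predictions}
    n_bins = min(config.n_bins, max(1, len(genes)))
    if len(genes) >= n_bins and n_bins >= config.min_bins_for_hri:
        engine = SFSEngine(n_grid=config.engine_grid)
        result, df = fhri_from_genes(
            genes, rng, n_bins=n_bins, engine=engine,
            rr_threshold=config.rr_threshold,
            clamp=config.clamp_negative_predictions, span=config.loess_span)
        df.to_csv(out / "bins.tsv", sep="\t", index=False)
        report.update({
            "ka_no_hri": result.ka_no_hri, "total_no_hri": result.total_no_hri,
            "total_lost": result.total_lost, "f_hri": result.f_hri,
            "clamped": result.clamped,
            "per_bin_predictions": result.per_bin_predictions.tolist()})
    else:
        report["status"] = (f"hri_skipped: {len(genes)} genes support fewer than "
                            f"{config.min_bins_for_hri} bins")
        # still write an (empty) bins table so the schema is stable
        pd.DataFrame(columns=["bin_id", "n_genes", "mean_rr", "ka_plus"]).to_csv(
            out / "bins.tsv", sep="\t", index=False)
    with open(out / "hri_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    manifest = {"version": __version__, "master_seed": config.master_seed,
                "config": asdict(config), "gene_tallies": tallies}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


# ---------------------------------------------------------------------------
# output validation
# ---------------------------------------------------------------------------

def validate_tables(out_dir):
    """Check conservation invariants across a finished output directory.

    Verifies per-gene closure of the hypergeometric split (the parts sum to
    D4), 0 <= D <= L for every class, and the loss-equation identity
    f_hri = total_lost / total_no_hri in the report.  Returns (ok, messages).
    """
    out = Path(out_dir)
    msgs = []
    required = ["counts.tsv", "splits.tsv", "hri_report.json", "manifest.json"]
    for name in required:
        if not (out / name).exists():
            return False, [f"missing output file: {name}"]
    counts = pd.read_csv(out / "counts.tsv", sep="\t")
    splits = pd.read_csv(out / "splits.tsv", sep="\t")
    for _, row in counts.iterrows():
        for c in ("0", "4", "i"):
            if not 0 <= row[f"D{c}"] <= row[f"L{c}"]:
                msgs.append(f"gene {row['gene_id']}: D{c} outside [0, L{c}]")
    merged = splits.merge(counts[["gene_id", "D4"]], on="gene_id",
                          suffixes=("", "_counts"))
    bad = merged[merged["D4_1"] + merged["D4_2"] + merged["D4_3"]
                 != merged["D4_counts"]]
    for _, row in bad.iterrows():
        msgs.append(f"gene {row['gene_id']}: split parts do not sum to D4")
    with open(out / "hri_report.json") as fh:
        report = json.load(fh)
    if report.get("status") == "ok" and "f_hri" in report:
        lhs = report["f_hri"]
        rhs = report["total_lost"] / report["total_no_hri"]
        if abs(lhs - rhs) > 1e-12 * max(1.0, abs(rhs)):
            msgs.append("report: f_hri != total_lost / total_no_hri")
    return (len(msgs) == 0), msgs
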