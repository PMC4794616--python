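"""Site classification from per-gene multiple alignments.

Each gene record holds n aligned ingroup haplotypes plus one outgroup
sequence, with exon and intron intervals in alignment coordinates (0-based,
half-open; GFF3 input is converted from 1-based inclusive at load).  This
module applies the exon quality filters (overlap resolution, codon trimming,
gap/frameshift/premature-stop exclusion), classifies alignment columns into
0-fold, 4-fold (exon-core, amino acid conserved between the species) and
short-intron (positions 8-30 of introns <= 65 bp) classes, and downsamples
every column to a fixed chromosome number so all sites share one sample size.

Minus-strand genes are reverse-complemented once at load, so everything
downstream works on the coding strand in a single reading-frame convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAlignment",
    "ClassifiedSites",
    "filter_and_trim_exons",
    "classify_coding_sites",
    "extract_short_intron_sites",
    "downsample_column",
    "pick_divergence_haplotype",
    "codon_degeneracy",
    "read_gene_alignments",
]

_CALLED = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN-acgtn-", "TGCAN-tgcan-")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    """Amino acid for a codon ('*' for stop); codon must be unambiguous."""
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def codon_degeneracy(codon: str, pos: int) -> int:
    """Number of the three alternative bases at ``pos`` that preserve the
    amino acid.  0 => 0-fold site, 3 => 4-fold site."""
    codon = codon.upper()
    aa = _translate(codon)
    n_syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if _translate(alt) == aa:
            n_syn += 1
    return n_syn


@dataclass
class GeneAlignment:
    """Aligned haplotypes of one gene: n ingroup sequences + 1 outgroup."""

    gene_id: str
    arm: str
    strand: str
    ingroup_seqs: list
    outgroup_seq: str
    exons: list  # [start, end) in alignment coordinates, coding strand
    introns: list

    def __post_init__(self) -> None:
        if len(self.ingroup_seqs) < 2:
            raise ValueError(f"{self.gene_id}: need >= 2 ingroup sequences")
        length = len(self.outgroup_seq)
        if any(len(s) != length for s in self.ingroup_seqs):
            raise ValueError(f"{self.gene_id}: sequences have unequal lengths")
        for s, e in list(self.exons) + list(self.introns):
            if not 0 <= s < e <= length:
                raise ValueError(f"{self.gene_id}: interval [{s},{e}) out of bounds")

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup_seqs)

    @property
    def length(self) -> int:
        return len(self.outgroup_seq)


@dataclass
class ClassifiedSites:
    """Alignment columns per site class, after downsampling to a fixed n."""

    gene_id: str
    sites_0fold: list
    sites_4fold: list
    sites_intron: list
    n_chromosomes: int

    def __post_init__(self) -> None:
        classes = [set(self.sites_0fold), set(self.sites_4fold), set(self.sites_intron)]
        total = sum(len(c) for c in classes)
        if len(set().union(*classes)) != total:
            raise ValueError(f"{self.gene_id}: site classes are not disjoint")


# ---------------------------------------------------------------------------
# exon filtering
# ---------------------------------------------------------------------------

def _has_gap(seqs, start, end):
    return any("-" in s[start:end] for s in seqs)


def _exon_has_early_stop(seqs, start, end, terminal_ok):
    """True if any sequence carries a stop codon before the exon's last
    codon, or in the last codon unless ``terminal_ok``.  Codons containing
    ambiguous bases are ignored here (they are skipped at classification)."""
    n_codons = (end - start) // 3
    for s in seqs:
        for ci in range(n_codons):
            codon = s[start + 3 * ci:start + 3 * ci + 3].upper()
            if not set(codon) <= _CALLED:
                continue
            if codon in _STANDARD_TABLE.stop_codons:
                if ci == n_codons - 1 and terminal_ok:
                    continue
                return True
    return False


def filter_and_trim_exons(exons, ingroup_seqs, outgroup_seq):
    """Apply the exon quality filters; returns retained [start, end) intervals.

    Overlapping exons are resolved first (the largest wins); survivors are
    trimmed to full codons, then dropped if they contain an alignment gap in
    any haplotype or the outgroup, or a premature stop codon.  A stop in the
    last codon of the gene's final exon is treated as the terminal stop.  An
    empty result means the gene is dropped (logged, not an exception).
    """
    all_seqs = list(ingroup_seqs) + [outgroup_seq]
    # overlap resolution: largest first, keep if disjoint from kept set
    kept = []
    for s, e in sorted(exons, key=lambda iv: (-(iv[1] - iv[0]), iv[0])):
        if all(e <= ks or s >= ke for ks, ke in kept):
            kept.append((s, e))
    kept.sort()
    last_exon_start = kept[-1][0] if kept else None

    retained = []
    for s, e in kept:
        e = s + ((e - s) // 3) * 3  # trim to full codons
        if e <= s:
            logger.info("exon_dropped gene_exon=[%d,%d) reason=shorter_than_codon", s, e)
            continue
        if _has_gap(all_seqs, s, e):
            logger.info("exon_dropped gene_exon=[%d,%d) reason=gap", s, e)
            continue
        if _exon_has_early_stop(all_seqs, s, e, terminal_ok=(s == last_exon_start)):
            logger.info("exon_dropped gene_exon=[%d,%d) reason=early_stop", s, e)
            continue
        retained.append((s, e))
    return retained


# ---------------------------------------------------------------------------
# coding-site classification
# ---------------------------------------------------------------------------

def _majority_codon(codons):
    """Most frequent codon; ties broken lexicographically for determinism."""
    counts = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    top = max(counts.values())
    return min(c for c, k in counts.items() if k == top)


def classify_coding_sites(retained_exons, ingroup_seqs, outgroup_seq,
                          core_margin_codons=8):
    """Classify exon-core columns into 0-fold and 4-fold degenerate sites.

    Degeneracy is read off the ingroup majority codon in the reference frame.
    A column is 0-fold iff every base change there is nonsynonymous, 4-fold
    iff all four bases are synonymous; 4-fold columns are kept only when the
    codon encodes the same amino acid in every ingroup haplotype and in the
    outgroup (codons segregating or diverged for the amino acid keep their
    0-fold sites - the conservation filter applies to the synonymous-rate
    sites only).  Codons within ``core_margin_codons`` of either exon
    boundary, or containing an ambiguous base in any sequence, are skipped.
    """
    sites_0fold = []
    sites_4fold = []
    for s, e in retained_exons:
        n_codons = (e - s) // 3
        for ci in range(core_margin_codons, n_codons - core_margin_codons):
            c0 = s + 3 * ci
            cols = (c0, c0 + 1, c0 + 2)
            in_codons = [seq[c0:c0 + 3].upper() for seq in ingroup_seqs]
            out_codon = outgroup_seq[c0:c0 + 3].upper()
            if any(not set(c) <= _CALLED for c in in_codons + [out_codon]):
                continue
            maj = _majority_codon(in_codons)
            aas = {_translate(c) for c in in_codons}
            same_aa = len(aas) == 1 and _translate(out_codon) in aas
            for pos in range(3):
                deg = codon_degeneracy(maj, pos)
                if deg == 0:
                    sites_0fold.append(cols[pos])
                elif deg == 3 and same_aa:
                    sites_4fold.append(cols[pos])
    return sites_0fold, sites_4fold


# ---------------------------------------------------------------------------
# short-intron sites
# ---------------------------------------------------------------------------

def extract_short_intron_sites(introns, ingroup_seqs, outgroup_seq, max_len=65,
                               pos_range=(8, 30), min_introns=2,
                               max_gap_frac=0.10):
    """Columns at positions 8-30 (1-based, 5' end, coding strand) of introns
    <= ``max_len`` bp - the near-neutral reference class.

    The invariant GT/AG splice dinucleotides never contribute (positions 1-2
    are below the range; the last two positions of the intron are excluded
    explicitly for introns short enough that the range reaches them).  The
    gene yields an empty list unless at least ``min_introns`` introns qualify
    and the gap fraction across their aligned columns is below
    ``max_gap_frac``.
    """
    all_seqs = list(ingroup_seqs) + [outgroup_seq]
    qualifying = [(s, e) for s, e in introns if (e - s) <= max_len]
    if len(qualifying) < min_introns:
        return []
    n_chars = sum((e - s) * len(all_seqs) for s, e in qualifying)
    n_gaps = sum(seq[s:e].count("-") for s, e in qualifying for seq in all_seqs)
    if n_chars == 0 or n_gaps / n_chars >= max_gap_frac:
        return []
    lo, hi = pos_range
    sites = []
    for s, e in qualifying:
        length = e - s
        # exclude the 3' AG: last usable position is length - 2
        for pos in range(lo, min(hi, length - 2) + 1):  # 1-based positions
            sites.append(s + pos - 1)
    return sites


# ---------------------------------------------------------------------------
# downsampling and divergence haplotype
# ---------------------------------------------------------------------------

def downsample_column(alleles, n_target, rng):
    """Draw ``n_target`` alleles uniformly without replacement from the
    called (ACGT) alleles of one column.

    Returns an ``{allele: count}`` dict, or None when fewer than ``n_target``
    alleles are called (the column is then unusable and excluded from all
    site classes).  Mirrors reducing a panel to a fixed number of lines by
    sampling the polymorphisms at each site without replacement.
    """
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    called = [a for a in (b.upper() for b in alleles) if a in _CALLED]
    if len(called) < n_target:
        return None
    if len(called) == n_target:
        chosen = called
    else:
        idx = rng.choice(len(called), size=n_target, replace=False)
        chosen = [called[i] for i in idx]
    out = {}
    for a in chosen:
        out[a] = out.get(a, 0) + 1
    return out


def pick_divergence_haplotype(n_haplotypes, rng):
    """Uniformly choose the single ingroup chromosome used for divergence."""
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    return int(rng.integers(n_haplotypes))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_features(gff_path):
    """Exon/intron intervals and strand per gene from a GFF3 file.

    Features of type ``exon``/``intron`` with the gene id in the seqid column
    (per-gene alignment coordinates, 1-based inclusive -> converted to
    0-based half-open here).
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique")
    feats = {}
    for kind in ("exon", "intron"):
        for f in db.features_of_type(kind):
            entry = feats.setdefault(f.seqid, {"exon": [], "intron": [], "strand": f.strand})
            entry[kind].append((f.start - 1, f.end))
            entry["strand"] = f.strand
    return feats


def read_gene_alignments(alignment_dir, gff_path, arm_of=None):
    """Load per-gene FASTA alignments plus GFF3 exon/intron annotation.

    ``alignment_dir`` holds one ``<gene_id>.fasta`` per gene with ingroup
    records named by line id and the outgroup record id prefixed
    ``outgroup|``.  Minus-strand genes are reverse-complemented to the coding
    strand at load (intervals flipped accordingly).  Yields GeneAlignment
    objects; genes with a missing outgroup record are logged and skipped.
    """
    feats = _load_features(gff_path)
    for gene_id in sorted(feats):
        fasta = Path(alignment_dir) / f"{gene_id}.fasta"
        if not fasta.exists():
            logger.warning("gene_skipped gene=%s reason=no_fasta", gene_id)
            continue
        ingroup, outgroup = [], None
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id.startswith("outgroup|"):
                outgroup = str(rec.seq).upper()
            else:
                ingroup.append(str(rec.seq).upper())
        if outgroup is None:
            logger.warning("gene_skipped gene=%s reason=no_outgroup", gene_id)
            continue
        exons = feats[gene_id]["exon"]
        introns = feats[gene_id]["intron"]
        strand = feats[gene_id]["strand"]
        if strand == "-":
            L = len(outgroup)
            ingroup = [_revcomp(s) for s in ingroup]
            outgroup = _revcomp(outgroup)
            exons = [(L - e, L - s) for s, e in exons]
            introns = [(L - e, L - s) for s, e in introns]
        yield GeneAlignment(
            gene_id=gene_id,
            arm=arm_of(gene_id) if arm_of else "synthetic",
            strand="+",
            ingroup_seqs=ingroup,
            outgroup_seq=outgroup,
            exons=sorted(exons),
            introns=sorted(introns),
        )
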