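"""Per-bin inference of the DFE and the adaptive substitution rate.

The estimation follows the two-step logic of McDonald-Kreitman-derived
methods that correct for slightly deleterious segregating mutations: a
two-epoch demography is fitted to the folded SFS of the neutral reference
class (4-fold sites), a gamma distribution of deleterious fitness effects is
then fitted to the folded SFS of the selected class (0-fold sites)
conditional on that demography, and the fitted DFE predicts the expected
nonadaptive nonsynonymous divergence

    d_exp = K4 * E_f[ r(S) ],   r(S) = S / (1 - e^-S),

where r is a deleterious mutation's fixation probability relative to a
neutral one and the expectation runs over the fitted DFE (S = 4 N s).  Any
observed nonsynonymous divergence above d_exp is attributed to positive
selection:

    alpha = (Ka - d_exp) / Ka,   Ka+ = alpha * Ka,   omega_A = Ka+ / K4.

Spectra are fitted by multinomial maximum likelihood over folded bins
(folded mode only: no ancestral-state polarization is needed).  All fits are
deterministic: the simplex optimizer uses fixed multi-starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from ._wf import SFSEngine
from .counts import FoldedSFS, jc_correct, tamura_correct

logger = logging.getLogger(__name__)

__all__ = [
    "Demography",
    "GammaDFE",
    "DFEFit",
    "SelectionGrid",
    "expected_folded_sfs",
    "fit_neutral_demography",
    "fit_gamma_dfe",
    "fixation_factor",
    "relative_fixation_rate",
    "estimate_alpha_ka_plus",
    "fit_bin",
]


@dataclass
class Demography:
    """Single instantaneous size change N1 -> N2 = size_ratio * N1, t2
    (units of N2 generations) ago.  size_ratio = 1 or t2 = 0 is a constant
    population."""

    size_ratio: float
    t2: float

    def __post_init__(self) -> None:
        if self.size_ratio <= 0:
            raise ValueError("size_ratio must be > 0")
        if self.t2 < 0:
            raise ValueError("t2 must be >= 0")


@dataclass
class GammaDFE:
    """Gamma DFE over deleterious effects: mean strength gamma_mean = -N_e s
    (deleterious-positive), shape beta (small = leptokurtic)."""

    gamma_mean: float
    shape_beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma_mean) or self.gamma_mean < 0:
            raise ValueError("gamma_mean must be finite and >= 0")
        if not np.isfinite(self.shape_beta) or self.shape_beta <= 0:
            raise ValueError("shape_beta must be finite and > 0")


@dataclass
class DFEFit:
    """Fitted demography + DFE and the derived adaptation statistics for one
    pooled bin.  Identities: ka_plus = alpha * ka; omega_a = ka_plus / k4."""

    demography: Demography
    dfe: GammaDFE
    alpha: float
    omega_a: float
    ka: float
    k4: float
    ka_plus: float
    loglik: float
    converged: bool = True


# ---------------------------------------------------------------------------
# selection quadrature
# ---------------------------------------------------------------------------

class SelectionGrid:
    """Fixed quadrature over scaled selection strength for DFE integrals.

    64 mass points log-spaced in |S| over [1e-4, 1e4] (S = 4 N s, negative =
    deleterious) plus a point at S = 0.  A gamma DFE is discretized onto the
    grid by assigning each point the gamma probability mass of the
    surrounding log-space cell; mass below the smallest |S| goes to the
    neutral point and mass above the largest |S| to the last point.
    """

    def __init__(self, n_points=64, s_min=1e-4, s_max=1e4):
        mag = np.geomspace(s_min, s_max, n_points)
        self.S = np.concatenate(([0.0], -mag))  # index 0 = neutral point
        step = mag[1] / mag[0]
        inner = np.sqrt(mag[:-1] * mag[1:])
        self._edges = np.concatenate(([mag[0] / np.sqrt(step)], inner, [np.inf]))

    def weights(self, dfe: GammaDFE) -> np.ndarray:
        """Probability mass at each S point under ``dfe`` (gamma over
        gamma = |S|/4 with mean gamma_mean and shape beta)."""
        if dfe.gamma_mean == 0:
            w = np.zeros(len(self.S))
            w[0] = 1.0
            return w
        scale = dfe.gamma_mean / dfe.shape_beta
        cdf = gamma_dist.cdf(self._edges / 4.0, a=dfe.shape_beta, scale=scale)
        w = np.empty(len(self.S))
        w[0] = cdf[0]
        w[1:] = np.diff(cdf)
        return w


def relative_fixation_rate(S):
    """Fixation probability of a new semidominant mutation relative to a
    neutral one: r(S) = S / (1 - e^-S), r(0) = 1; -> 0 as S -> -inf."""
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    nz = np.abs(S) > 1e-12
    with np.errstate(over="ignore"):
        denom = -np.expm1(-S[nz])
    out[nz] = np.where(np.isinf(denom), 0.0, S[nz] / denom)
    # far-negative S underflows the ratio to 0 via the inf denominator above;
    # far-positive S gives r ~ S
    return out if out.shape else float(out)


def fixation_factor(dfe: GammaDFE, grid: SelectionGrid) -> float:
    """E_f[r(S)]: the DFE-averaged fixation rate of new mutations relative
    to neutral - the factor converting neutral divergence into the expected
    nonadaptive divergence at selected sites."""
    return float(np.sum(grid.weights(dfe) * relative_fixation_rate(grid.S)))


# ---------------------------------------------------------------------------
# expected spectra and likelihoods
# ---------------------------------------------------------------------------

def expected_folded_sfs(S, demography, n_chromosomes, engine=None, n_pop_grid=200):
    """Expected folded-SFS proportions at scaled selection S under a
    two-epoch demography (probability vector of length floor(n/2))."""
    if engine is None:
        engine = SFSEngine(n_grid=n_pop_grid)
    return engine.expected_folded_sfs(S, demography.size_ratio, demography.t2,
                                      n_sample=n_chromosomes)


def _multinomial_loglik(counts, props):
    props = np.clip(props, 1e-300, None)
    props = props / props.sum()
    return float(np.sum(counts * np.log(props)))


def fit_neutral_demography(neutral_sfs: FoldedSFS, engine: SFSEngine,
                           max_iter=200) -> tuple:
    """Maximum-likelihood two-epoch demography from a neutral folded SFS.

    Multinomial likelihood over folded bins; deterministic fixed multi-start
    Nelder-Mead on (log size_ratio, log t2), with the constant-size model as
    an always-evaluated candidate.  Returns (Demography, loglik).
    """
    counts = neutral_sfs.counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("monomorphic neutral SFS: demography likelihood is flat")
    n = neutral_sfs.n_chromosomes

    def negll(x):
        ratio = float(np.exp(np.clip(x[0], np.log(0.1), np.log(engine.max_ratio))))
        t2 = float(np.exp(np.clip(x[1], np.log(1e-3), np.log(engine.max_t2))))
        props = engine.expected_folded_sfs(0.0, ratio, t2, n_sample=n)
        return -_multinomial_loglik(counts, props)

    const_ll = _multinomial_loglik(
        counts, engine.expected_folded_sfs(0.0, 1.0, 0.0, n_sample=n))

    starts = [(1.0, 0.02), (2.0, 0.1), (0.5, 0.1), (1.5, 0.5)]
    best = None
    for r0, t0 in starts:
        res = minimize(negll, np.log([r0, t0]), method="Nelder-Mead",
                       options={"maxiter": max_iter, "fatol": 1e-8, "xatol": 1e-5})
        if best is None or res.fun < best.fun:
            best = res
    if -best.fun <= const_ll + 1e-9:
        return Demography(1.0, 0.0), const_ll
    ratio = float(np.exp(np.clip(best.x[0], np.log(0.1), np.log(engine.max_ratio))))
    t2 = float(np.exp(np.clip(best.x[1], np.log(1e-3), np.log(engine.max_t2))))
    return Demography(ratio, t2), -best.fun


def _mixture_components(engine, demography, n_sample, grid):
    """Unnormalized folded spectra for every S on the quadrature grid (rows),
    proportional to expected segregating sites per unit inflow."""
    comps = np.empty((len(grid.S), n_sample // 2))
    for j, S in enumerate(grid.S):
        comps[j] = engine.expected_folded_sfs(
            S, demography.size_ratio, demography.t2, n_sample=n_sample,
            normalize=False)
    return comps


def fit_gamma_dfe(selected_sfs: FoldedSFS, demography: Demography,
                  engine: SFSEngine, grid: SelectionGrid | None = None,
                  max_iter=300) -> tuple:
    """ML gamma-DFE parameters from the selected-class folded SFS given an
    already-fitted demography (two-step procedure, neutral class first).

    The expected spectrum is the quadrature mixture of per-S spectra
    weighted by both the gamma mass and the relative segregating intensity
    at each S.  Five fixed starts; returns (GammaDFE, loglik).
    """
    if grid is None:
        grid = SelectionGrid()
    counts = selected_sfs.counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("monomorphic selected SFS: DFE likelihood is flat")
    comps = _mixture_components(engine, demography, selected_sfs.n_chromosomes, grid)

    def negll(x):
        mean = float(np.exp(np.clip(x[0], np.log(1e-3), np.log(1e6))))
        beta = float(np.exp(np.clip(x[1], np.log(0.05), np.log(5.0))))
        w = SelectionGrid.weights(grid, GammaDFE(mean, beta))
        mix = w @ comps
        return -_multinomial_loglik(counts, mix)

    starts = [(10.0, 0.3), (100.0, 0.5), (1000.0, 0.2), (1000.0, 1.0), (1.0, 0.5)]
    best = None
    n_fail = 0
    for m0, b0 in starts:
        res = minimize(negll, np.log([m0, b0]), method="Nelder-Mead",
                       options={"maxiter": max_iter, "fatol": 1e-8, "xatol": 1e-5})
        if not res.success:
            n_fail += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("gamma-DFE optimization failed from every start")
    if n_fail == len(starts):
        logger.warning("gamma-DFE fit: no start formally converged; "
                       "returning best point found")
    mean = float(np.exp(np.clip(best.x[0], np.log(1e-3), np.log(1e6))))
    beta = float(np.exp(np.clip(best.x[1], np.log(0.05), np.log(5.0))))
    return GammaDFE(mean, beta), -best.fun


# ---------------------------------------------------------------------------
# adaptation statistics
# ---------------------------------------------------------------------------

def estimate_alpha_ka_plus(dfe, demography, D0, L0, D4, L4, gc4, P4_ts, P4_tv,
                           grid: SelectionGrid | None = None, loglik=float("nan"),
                           fixation=None) -> DFEFit:
    """Derive alpha, Ka+ and omega_A from a fitted DFE and the divergence.

    ka is the Jukes-Cantor-corrected 0-fold divergence D0/L0; k4 the Tamura
    (1992)-corrected 4-fold divergence from transition/transversion
    proportions and GC content; d_exp = k4 * E_f[r(S)] is the nonadaptive
    expectation.  ``fixation`` overrides E_f[r(S)] when it is known
    externally (used by fast resampling paths).
    """
    if L0 <= 0 or L4 <= 0:
        raise ValueError("need L0 > 0 and L4 > 0")
    ka = jc_correct(D0 / L0)
    k4 = tamura_correct(P4_ts, P4_tv, gc4)
    if ka == 0:
        raise ValueError("ka = 0: alpha undefined for this bin")
    if fixation is None:
        fixation = fixation_factor(dfe, grid if grid is not None else SelectionGrid())
    d_exp = k4 * fixation
    alpha = (ka - d_exp) / ka
    ka_plus = alpha * ka
    omega_a = ka_plus / k4 if k4 > 0 else float("nan")
    return DFEFit(demography=demography, dfe=dfe, alpha=alpha, omega_a=omega_a,
                  ka=ka, k4=k4, ka_plus=ka_plus, loglik=loglik)


def fit_bin(gene_bin, engine: SFSEngine, grid: SelectionGrid | None = None) -> DFEFit:
    """Full per-bin estimate: demography from the pooled 4-fold SFS, gamma
    DFE from the pooled 0-fold SFS, adaptation statistics from the pooled
    divergence counts."""
    if grid is None:
        grid = SelectionGrid()
    demog, ll_neu = fit_neutral_demography(gene_bin.sfs4, engine)
    dfe_, ll_sel = fit_gamma_dfe(gene_bin.sfs0, demog, engine, grid)
    return estimate_alpha_ka_plus(
        dfe_, demog,
        D0=gene_bin.D0, L0=gene_bin.L0, D4=gene_bin.D4, L4=gene_bin.L4,
        gc4=gene_bin.gc4,
        P4_ts=gene_bin.D4_ts / gene_bin.L4, P4_tv=gene_bin.D4_tv / gene_bin.L4,
        grid=grid, loglik=ll_neu + ll_sel)
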