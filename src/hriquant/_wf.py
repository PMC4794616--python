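"""Discretized Wright-Fisher machinery for expected site-frequency spectra.

The expected folded SFS under selection and a two-epoch size history is
computed by iterating a mutation-inflow recursion on a finite haploid grid:
each generation, allele frequencies are updated deterministically by genic
selection (Delta p = sigma p(1-p), sigma = S / (2 n_grid), so that the
diffusion-scale selection strength S = 4 N s is grid-independent) and then
resampled binomially; new mutations enter at frequency 1/n_grid at a rate
proportional to the population size.  The ancestral epoch is solved to exact
equilibrium with a linear solve; the present epoch is iterated for
t2 * N2 generations after the size change; finally n chromosomes are sampled
binomially from the population frequencies and the spectrum is folded.

All spectra are *relative*: vectors are proportional to the expected number
of segregating sites per unit mutational inflow, which is what multinomial
SFS likelihoods and mixture weights need.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

__all__ = ["SFSEngine"]

_MAX_CACHE = 96  # transition matrices can reach ~8 MB each


class SFSEngine:
    """Expected-SFS calculator on a fixed haploid grid.

    Parameters
    ----------
    n_grid : int
        Haploid population grid size 2N for the ancestral epoch.  Must be at
        least the sample size of any SFS computed from it.
    max_ratio, max_t2 : float
        Bounds on the two-epoch parameters (N2/N1 and time since the change
        in units of N2 generations) honoured by the fitting routines.
    max_generations : int
        Hard cap on the number of epoch-2 iterations.
    """

    def __init__(self, n_grid=200, max_ratio=5.0, max_t2=2.0, max_generations=600):
        if n_grid < 4:
            raise ValueError("n_grid must be >= 4")
        self.n_grid = int(n_grid)
        self.max_ratio = float(max_ratio)
        self.max_t2 = float(max_t2)
        self.max_generations = int(max_generations)
        self._trans = {}   # (n_hap, S) -> interior transition matrix
        self._equil = {}   # S -> ancestral equilibrium occupancy (interior)
        self._sample = {}  # (n_hap, n_sample) -> binomial sampling matrix
        self._proj = {}    # (n2, S) -> ancestral-grid -> epoch-2-grid projection
        # the model depends on (size_ratio, t2) only through the integer
        # epoch-2 grid size and generation count, so folded spectra memoize
        # exactly on (S, n2, g, n_sample)
        self._folded = {}

    # -- building blocks ----------------------------------------------------

    @staticmethod
    def _post_selection(p, S, n_hap):
        sigma = S / (2.0 * n_hap)
        return np.clip(p + sigma * p * (1.0 - p), 0.0, 1.0)

    def _transition(self, n_hap, S):
        """Interior-to-interior WF transition matrix on an n_hap grid."""
        key = (n_hap, round(float(S), 10))
        T = self._trans.get(key)
        if T is None:
            p = np.arange(1, n_hap) / n_hap
            pstar = self._post_selection(p, S, n_hap)
            j = np.arange(1, n_hap)
            T = binom.pmf(j[None, :], n_hap, pstar[:, None])
            if len(self._trans) >= _MAX_CACHE:
                self._trans.pop(next(iter(self._trans)))
            self._trans[key] = T
        return T

    def _equilibrium(self, S):
        """Ancestral-epoch equilibrium occupancy under unit inflow per
        generation at frequency 1/n_grid: u = (I - T')^-1 e_1."""
        key = round(float(S), 10)
        u = self._equil.get(key)
        if u is None:
            T = self._transition(self.n_grid, S)
            m = self.n_grid - 1
            v = np.zeros(m)
            v[0] = 1.0
            u = np.linalg.solve(np.eye(m) - T.T, v)
            if np.any(u < -1e-9):
                raise RuntimeError(
                    f"equilibrium solve produced negative occupancy at S={S}")
            u = np.clip(u, 0.0, None)
            self._equil[key] = u
        return u

    def _sampling_matrix(self, n_hap, n_sample):
        key = (n_hap, n_sample)
        B = self._sample.get(key)
        if B is None:
            p = np.arange(1, n_hap) / n_hap
            k = np.arange(1, n_sample)
            B = binom.pmf(k[:, None], n_sample, p[None, :])
            if len(self._sample) >= _MAX_CACHE:
                self._sample.pop(next(iter(self._sample)))
            self._sample[key] = B
        return B

    # -- public API ----------------------------------------------------------

    def _epoch_params(self, size_ratio, t2):
        if size_ratio <= 0:
            raise ValueError("size_ratio must be > 0")
        if t2 < 0:
            raise ValueError("t2 must be >= 0")
        n2 = max(4, int(round(size_ratio * self.n_grid)))
        g = min(int(round(t2 * n2 / 2.0)), self.max_generations)
        return n2, g

    def population_occupancy(self, S, size_ratio=1.0, t2=0.0):
        """Occupancy vector over interior frequencies of the present-day
        grid, and that grid's haploid size.

        With ``t2 = 0`` (or ratio 1 and t2 arbitrary small) this is the
        ancestral equilibrium.  Otherwise the equilibrium is projected onto
        the epoch-2 grid and iterated for round(t2 * n2 / 2) generations with
        inflow scaled by N2/N1 (mutational input is proportional to
        population size).
        """
        n1 = self.n_grid
        n2, g = self._epoch_params(size_ratio, t2)
        if g == 0:
            return self._equilibrium(S), n1
        u1 = self._equilibrium(S)
        # projection of epoch-1 frequencies through one epoch-2 reproduction
        pkey = (n2, round(float(S), 10))
        P = self._proj.get(pkey)
        if P is None:
            p1 = np.arange(1, n1) / n1
            pstar = self._post_selection(p1, S, n2)
            j = np.arange(1, n2)
            P = binom.pmf(j[None, :], n2, pstar[:, None])
            if len(self._proj) >= _MAX_CACHE:
                self._proj.pop(next(iter(self._proj)))
            self._proj[pkey] = P
        inflow = np.zeros(n2 - 1)
        inflow[0] = n2 / n1  # mutational input scales with N2/N1
        u = P.T @ u1 + inflow
        T2 = self._transition(n2, S)
        for _ in range(g - 1):
            u = T2.T @ u + inflow
        return u, n2

    def expected_folded_sfs(self, S, size_ratio=1.0, t2=0.0, n_sample=None,
                            normalize=True):
        """Expected folded sample SFS (length floor(n/2)).

        Returns proportions over segregating minor-allele bins when
        ``normalize`` is True, otherwise the relative intensity vector whose
        sum is proportional to the expected number of segregating sites.
        """
        if n_sample is None or n_sample < 2:
            raise ValueError("n_sample must be >= 2")
        if n_sample > self.n_grid:
            raise ValueError(
                f"n_sample={n_sample} exceeds the population grid {self.n_grid}")
        n2, g = self._epoch_params(size_ratio, t2)
        fkey = (round(float(S), 10), n2, g, n_sample)
        folded = self._folded.get(fkey)
        if folded is None:
            u, n_hap = self.population_occupancy(S, size_ratio, t2)
            B = self._sampling_matrix(n_hap, n_sample)
            s = B @ u  # expected counts for k = 1 .. n_sample-1
            half = n_sample // 2
            folded = np.empty(half)
            for kk in range(1, half + 1):
                if kk == n_sample - kk:
                    folded[kk - 1] = s[kk - 1]
                else:
                    folded[kk - 1] = s[kk - 1] + s[n_sample - kk - 1]
            if len(self._folded) >= 200_000:
                self._folded.clear()
            self._folded[fkey] = folded
        if normalize:
            total = folded.sum()
            if total <= 0:
                raise RuntimeError(f"no segregating mass at S={S}")
            return folded / total
        return folded
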