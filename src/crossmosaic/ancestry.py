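"""Global and local ancestry inference.

Global ancestry is estimated two ways, matching the two families of tools
used for admixed livestock:

* :func:`supervised_global_ancestry` - per-individual maximum-likelihood
  breed proportions given fixed ancestral-pool allele frequencies (the
  supervised-admixture model family: Hardy-Weinberg within the mixture,
  binomial site likelihoods, EM on the simplex).
* :func:`infer_local_ancestry` followed by :func:`global_from_local` - a
  windowed haplotype-copying hidden Markov model that labels the pool of
  origin of every haplotype segment; averaging the labels over the genome
  gives a second, independent global estimate.

Population structure is visualised through the genomic relationship
matrix, GRM = ZZ'/d with Z the centered genotype matrix and
d = 2 * sum_i p_i (1 - p_i) (VanRaden's first method), and its
eigendecomposition (:func:`pca_from_grm`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AncestryTrack, GeneticMap, GenotypeMatrix, HaplotypePanel

__all__ = [
    "GRM",
    "LocalAncestryModel",
    "compute_grm",
    "pca_from_grm",
    "supervised_global_ancestry",
    "infer_local_ancestry",
    "global_from_local",
]


@dataclass
class GRM:
    """Genomic relationship matrix with its scaling metadata.

    ``matrix`` is n x n symmetric; ``d = 2 * sum p_i (1 - p_i)`` is the
    scaling denominator; ``freqs`` are the allele frequencies used for
    centering.
    """

    matrix: np.ndarray
    d: float
    freqs: np.ndarray
    samples: list[str]

    def offdiagonal(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major order."""
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


def compute_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """GRM = ZZ'/d from complete genotypes (VanRaden method 1).

    Genotypes in {0, 1, 2} are recoded to M in {-1, 0, 1}; the column
    means under Hardy-Weinberg, P = 2 (p_i - 0.5), are subtracted to give
    Z = M - P, and the product is scaled by d = 2 * sum p_i (1 - p_i).
    If ``freqs`` is omitted, p_i is estimated from ``g`` itself.

    Raises
    ------
    ValueError
        If missing genotypes are present (fill them first) or all sites
        are monomorphic (d = 0).
    """
    if g.has_missing():
        raise ValueError("GRM requires complete genotypes; fill sporadic missingness first")
    p = np.asarray(freqs, dtype=np.float64) if freqs is not None else g.allele_freqs()
    if p.shape != (g.n_sites,):
        raise ValueError("freqs must have one entry per site")
    d = float(2.0 * np.sum(p * (1.0 - p)))
    if d <= 0:
        raise ValueError("all sites monomorphic: scaling denominator d = 0")
    m = g.genotypes.astype(np.float64) - 1.0
    z = m - 2.0 * (p - 0.5)[None, :]
    return GRM(z @ z.T / d, d, p, list(g.samples))


def pca_from_grm(grm: GRM, n_pcs: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of a GRM.

    Returns per-individual PC scores (eigenvectors scaled by the square
    root of their eigenvalues) and the fraction of variance explained by
    each component (eigenvalue over the sum of positive eigenvalues).
    The sign of each PC is fixed so its largest-magnitude loading is
    positive.
    """
    n = grm.matrix.shape[0]
    if n_pcs > n:
        raise ValueError(f"n_pcs = {n_pcs} exceeds matrix dimension {n}")
    if not np.allclose(grm.matrix, grm.matrix.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[vals > 0].sum()
    varexp = np.maximum(vals[:n_pcs], 0.0) / pos if pos > 0 else np.zeros(n_pcs)
    scores = vecs[:, :n_pcs] * np.sqrt(np.maximum(vals[:n_pcs], 0.0))[None, :]
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_pcs)]
    return pd.DataFrame(scores, index=grm.samples, columns=cols), varexp


def supervised_global_ancestry(
    g: GenotypeMatrix,
    pool_freqs: pd.DataFrame | dict[str, np.ndarray],
    max_iter: int = 1000,
    tol: float = 1e-8,
    clip: float | None = 1e-3,
) -> pd.DataFrame:
    """Maximum-likelihood breed proportions with fixed pool frequencies.

    For each individual the mixture weights q over the K ancestral pools
    maximise ``sum_j [ g_j log(q.f_j) + (2 - g_j) log(1 - q.f_j) ]`` - the
    binomial likelihood of the genotype under Hardy-Weinberg at the mixed
    frequency.  Optimisation is by EM on the simplex, vectorised across
    individuals; convergence when the log-likelihood change drops below
    ``tol`` (or ``max_iter`` iterations).

    Parameters
    ----------
    pool_freqs
        Mapping (or DataFrame with one column per pool) of per-site
        alternate-allele frequencies for each ancestral pool.
    clip
        Pool frequencies are clipped to ``[clip, 1 - clip]``; pass ``None``
        to use them as given (frequencies at exactly 0/1 then raise on the
        resulting non-finite likelihood).

    Returns
    -------
    DataFrame of shape (n_individuals, K); rows sum to 1.
    """
    if g.has_missing():
        raise ValueError("supervised ancestry requires complete genotypes")
    if isinstance(pool_freqs, pd.DataFrame):
        names = list(pool_freqs.columns)
        F = pool_freqs.to_numpy(dtype=np.float64).T
    else:
        names = list(pool_freqs.keys())
        F = np.stack([np.asarray(pool_freqs[k], dtype=np.float64) for k in names])
    if F.shape[1] != g.n_sites:
        raise ValueError("pool frequencies must cover the matrix's site list")
    if clip is not None:
        F = np.clip(F, clip, 1.0 - clip)
    K, J = F.shape
    gt = g.genotypes.astype(np.float64)
    N = g.n_individuals

    q = np.full((N, K), 1.0 / K)
    if K == 1:
        return pd.DataFrame(q, index=g.samples, columns=names)

    ll_old = np.full(N, -np.inf)
    active = np.ones(N, dtype=bool)
    for _ in range(max_iter):
        fa = q @ F  # (N, J) mixed alt frequency
        fb = 1.0 - fa
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (gt * np.log(fa) + (2.0 - gt) * np.log(fb)).sum(axis=1)
        if not np.isfinite(ll).all():
            raise ValueError(
                "non-finite likelihood: pool frequencies must be clipped away from 0 and 1"
            )
        # EM: expected pool origin of each allele copy, then renormalise.
        q = q * ((gt / fa) @ F.T + ((2.0 - gt) / fb) @ (1.0 - F).T) / (2.0 * J)
        q /= q.sum(axis=1, keepdims=True)
        active = np.abs(ll - ll_old) > tol
        ll_old = ll
        if not active.any():
            break
    return pd.DataFrame(q, index=g.samples, columns=names)


@dataclass
class LocalAncestryModel:
    """Tuning parameters of the windowed haplotype-copying HMM.

    window_size
        SNPs per window; the hidden state is constant within a window.
    n_states
        Founder haplotypes retained per pool (the copying states).
    switch_rate
        Between-pool ancestry-switch rate per cM.
    mismatch_rate
        Per-site probability that the target allele differs from the
        copied founder allele.  This must absorb within-pool haplotype
        diversity relative to the retained founders, not just genotyping
        error, so it sits well above a pure error rate.
    """

    window_size: int = 12
    n_states: int = 15
    switch_rate: float = 0.01
    mismatch_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.n_states < 1:
            raise ValueError("window_size and n_states must be >= 1")
        for r in (self.switch_rate, self.mismatch_rate):
            if not 0 < r < 1:
                raise ValueError("rates must lie in (0, 1)")


def _window_bounds(n_sites: int, window: int) -> list[tuple[int, int]]:
    return [(s, min(s + window, n_sites)) for s in range(0, n_sites, window)]


def infer_local_ancestry(
    target_haplotypes: np.ndarray,
    pools: Sequence[HaplotypePanel],
    model: LocalAncestryModel | None = None,
    gmap: GeneticMap | None = None,
) -> AncestryTrack:
    """Label the ancestral pool of origin along each target haplotype.

    A simplified two-level analogue of window-based local-ancestry HMMs.
    The outer hidden chain runs over ancestral pools, one state per
    window of ``window_size`` SNPs, switching pools with probability
    ``1 - exp(-switch_rate * d_cM)`` between consecutive windows.  Within
    a window, the emission for pool k is the haplotype-copying likelihood
    of the window's alleles marginalised over the pool's first
    ``n_states`` founder haplotypes (uniform founder prior, per-site
    ``mismatch_rate``).  Decoding is by Viterbi per chromosome; window
    states expand to per-site pool labels.

    Parameters
    ----------
    target_haplotypes
        Array (n_ind, 2, n_sites) of phased 0/1 haplotypes.
    pools
        Reference panels; the first ``n_states`` haplotypes of each pool
        serve as founders.
    """
    from scipy.special import logsumexp

    model = model or LocalAncestryModel()
    if gmap is None:
        gmap = pools[0].gmap
    H = np.asarray(target_haplotypes)
    if H.ndim != 3 or H.shape[1] != 2:
        raise ValueError("target_haplotypes must have shape (n_ind, 2, n_sites)")
    n_ind, _, n_sites = H.shape
    if n_sites != gmap.n_sites:
        raise ValueError("target and pool site lists must be identical")
    for p in pools:
        if p.n_sites != n_sites:
            raise ValueError("target and pool site lists must be identical")

    founders = [p.haplotypes[: min(model.n_states, p.n_haplotypes)] for p in pools]
    K = len(pools)
    flat = H.reshape(n_ind * 2, n_sites)
    n_hap = flat.shape[0]
    out = np.empty((n_hap, n_sites), dtype=np.int16)
    log_match = np.log1p(-model.mismatch_rate)
    log_mis = np.log(model.mismatch_rate)

    for _, sl in gmap.chrom_slices():
        sites = np.arange(sl.start, sl.stop)
        cm = gmap.cm[sl]
        bounds = _window_bounds(len(sites), model.window_size)
        W = len(bounds)
        # Window emissions: founder-marginal copying likelihood per pool.
        emis = np.empty((W, n_hap, K))
        for w, (a, b) in enumerate(bounds):
            seg = sites[a:b]
            for k, F in enumerate(founders):
                mism = (flat[:, seg, None] != F[:, seg].T[None, :, :]).sum(axis=1)
                emis[w, :, k] = logsumexp(
                    mism * log_mis + (b - a - mism) * log_match, axis=1
                ) - np.log(F.shape[0])

        delta = emis[0] - np.log(K)
        backptr = np.empty((W, n_hap, K), dtype=np.int16)
        eye = np.eye(K, dtype=bool)
        for w in range(1, W):
            d_cm = cm[bounds[w][0]] - cm[bounds[w - 1][0]]
            p_switch = -np.expm1(-model.switch_rate * d_cm)
            with np.errstate(divide="ignore"):
                logT = np.log(np.where(eye, 1.0 - p_switch, p_switch / max(K - 1, 1)))
            cand = delta[:, :, None] + logT[None, :, :]
            backptr[w] = np.argmax(cand, axis=1)
            delta = np.max(cand, axis=1) + emis[w]

        path = np.empty((n_hap, W), dtype=np.int16)
        path[:, W - 1] = np.argmax(delta, axis=1)
        for w in range(W - 1, 0, -1):
            path[:, w - 1] = np.take_along_axis(
                backptr[w], path[:, w][:, None], axis=1
            ).squeeze(1)
        for w, (a, b) in enumerate(bounds):
            out[:, sites[a]:sites[b - 1] + 1] = path[:, w][:, None]

    labels = out.reshape(n_ind, 2, n_sites)
    samples = [f"ind{i:04d}" for i in range(n_ind)]
    return AncestryTrack(labels, [p.name for p in pools], samples)


def global_from_local(track: AncestryTrack) -> pd.DataFrame:
    """Global breed proportions as genome-wide label fractions.

    The proportion assigned to pool k is the fraction of
    (site, haplotype) slots labelled k; requires a complete track.
    """
    if not track.is_complete():
        raise ValueError("incomplete ancestry track: missing labels present")
    return track.proportions()
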