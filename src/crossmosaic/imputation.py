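"""Genotype imputation stand-ins and accuracy evaluation.

The imputer is a single-layer Li-Stephens haplotype-copying model: each
target haplotype is an imperfect mosaic of reference haplotypes, with
copying switches at rate ``recomb_scale`` per cM and a per-site allele
mismatch probability.  Posterior reference-allele expectations at untyped
sites give haplotype dosages in [0, 1]; the two haplotype dosages sum to
the individual dosage in [0, 2].  A trivial frequency imputer (dosage =
2 x reference frequency) is included as the chance-concordance baseline.

Accuracy is reported the way the imputation literature does: per-site
Pearson correlation of dosage against the true allele count (robust to
allele frequency), allele-level concordance (inflated at low MAF by
chance agreement), MAF-stratified versions of both, and the correlation
of genomic-relationship-matrix off-diagonals built from imputed versus
true genotypes (the quantity that matters for genomic evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .ancestry import compute_grm
from .containers import GeneticMap, GenotypeMatrix, HaplotypePanel
from .simulate import CrossbredCohort, PanelDef, mask_to_panel

__all__ = [
    "ImputationResult",
    "ScenarioSpec",
    "AccuracyReport",
    "fill_sporadic_missing",
    "impute",
    "frequency_impute",
    "best_guess_genotypes",
    "allelic_correlation",
    "concordance_rate",
    "maf_stratified_accuracy",
    "grm_offdiagonal_correlation",
    "run_scenarios",
]

DEFAULT_MAF_EDGES = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def fill_sporadic_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the site's most frequent genotype.

    Ties are broken toward the heterozygote, then toward the lower allele
    count.  A crude stand-in for pedigree/LD-aware sporadic-missingness
    imputation, adequate for low missing rates.
    """
    out = g.copy()
    gt = out.genotypes
    miss_sites = np.flatnonzero((gt == -1).any(axis=0))
    for j in miss_sites:
        col = gt[:, j]
        obs = col[col != -1]
        if obs.size == 0:
            raise ValueError(f"site {j} has no non-missing genotype")
        counts = np.bincount(obs, minlength=3)
        best = np.flatnonzero(counts == counts.max())
        # any tie resolves to the heterozygote (a {0,2} tie averages to 1);
        # a unique mode stands
        fill = int(best[0]) if len(best) == 1 else 1
        col[col == -1] = fill
    return out


@dataclass
class ImputationResult:
    """Dosages and best-guess genotypes over the full site list.

    ``typed`` flags the sites that were observed (dosage = observed
    genotype there); ``imputed_sites`` are the remaining indices, the ones
    accuracy metrics evaluate.
    """

    dosages: np.ndarray
    best_guess: np.ndarray
    typed: np.ndarray
    samples: list[str]
    sites: pd.DataFrame = field(repr=False)
    reference: str = ""

    def __post_init__(self) -> None:
        if np.any((self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def imputed_sites(self) -> np.ndarray:
        return np.flatnonzero(~self.typed)


def best_guess_genotypes(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to {0,1,2}; half-integer ties go to the heterozygote."""
    bg = np.rint(dosages)
    ties = np.abs(dosages - np.floor(dosages) - 0.5) < 1e-12
    bg[ties] = 1.0
    return bg.astype(np.int8)


def _ls_haplotype_dosages(
    X: np.ndarray,
    ref: np.ndarray,
    typed_idx: np.ndarray,
    cm: np.ndarray,
    mismatch_rate: float,
    recomb_scale: float,
) -> np.ndarray:
    """Li-Stephens posterior allele dosages for one chromosome.

    ``X`` (n_hap, n_sites) target haplotypes (only typed columns are
    read), ``ref`` (n_ref, n_sites) reference haplotypes, ``typed_idx``
    positions of typed sites, ``cm`` genetic positions.  Returns dosages
    in [0, 1] at every site (typed sites get their posterior too; the
    caller overwrites them with observations).

    Forward-backward runs over typed sites only; posteriors at untyped
    sites follow from the exact interpolation of the copying chain, whose
    messages relax toward uniform as ``exp(-recomb_scale * d_cM / 100)``
    across an emission-free gap.
    """
    H, n_sites = X.shape
    R = ref.shape[0]
    out = np.empty((H, n_sites))
    m = len(typed_idx)
    refT = ref.T.astype(np.float64)

    if m == 0:
        out[:] = ref.mean(axis=0)[None, :]
        return out

    # Emissions at typed sites: (m, H, R)
    match = 1.0 - mismatch_rate
    emis = np.where(
        X[:, typed_idx][:, :, None] == ref[:, typed_idx].T[None, :, :], match, mismatch_rate
    ).transpose(1, 0, 2)

    gaps = np.diff(cm[typed_idx])
    rho = -np.expm1(-recomb_scale * gaps / 100.0)

    fwd = np.empty((m, H, R))
    a = emis[0] / emis[0].sum(axis=1, keepdims=True)
    fwd[0] = a
    for j in range(1, m):
        pred = (1.0 - rho[j - 1]) * a + rho[j - 1] / R
        a = pred * emis[j]
        a /= a.sum(axis=1, keepdims=True)
        fwd[j] = a

    # bwd[j] = normalised E_j * B_j (emission-inclusive backward message).
    bwd = np.empty((m, H, R))
    c = emis[m - 1]
    bwd[m - 1] = c / c.sum(axis=1, keepdims=True)
    for j in range(m - 2, -1, -1):
        nxt = bwd[j + 1]
        b = (1.0 - rho[j]) * nxt + rho[j] / R  # rowsum(nxt) = 1
        c = emis[j] * b
        bwd[j] = c / c.sum(axis=1, keepdims=True)

    # Typed-site posteriors: fwd_j combined with downstream half of bwd.
    for j in range(m):
        if j == m - 1:
            post = fwd[j]
        else:
            b = (1.0 - rho[j]) * bwd[j + 1] + rho[j] / R
            post = fwd[j] * b
            post /= post.sum(axis=1, keepdims=True)
        out[:, typed_idx[j]] = post @ refT[typed_idx[j]]

    # Untyped sites, interval by interval (position order; cm is monotone
    # with position so the chain factorises at the flanking anchors).
    anchors_cm = cm[typed_idx]
    untyped = np.setdiff1d(np.arange(n_sites), typed_idx)
    if untyped.size == 0:
        return out
    interval = np.searchsorted(typed_idx, untyped)
    for iv in np.unique(interval):
        us = untyped[interval == iv]
        Rb = refT[us]  # (U, R) -> careful: refT is (n_sites, R)
        colmean = Rb.mean(axis=1)  # (U,)
        if iv == 0:
            dR = anchors_cm[0] - cm[us]
            cR = np.exp(-recomb_scale * dR / 100.0)
            t3 = bwd[0] @ Rb.T  # (H, U)
            out[:, us] = cR[None, :] * t3 + (1.0 - cR)[None, :] * colmean[None, :]
        elif iv == m:
            dL = cm[us] - anchors_cm[m - 1]
            cL = np.exp(-recomb_scale * dL / 100.0)
            t2 = fwd[m - 1] @ Rb.T
            out[:, us] = cL[None, :] * t2 + (1.0 - cL)[None, :] * colmean[None, :]
        else:
            A, D = fwd[iv - 1], bwd[iv]
            dL = cm[us] - anchors_cm[iv - 1]
            dR = anchors_cm[iv] - cm[us]
            cL = np.exp(-recomb_scale * dL / 100.0)
            cR = np.exp(-recomb_scale * dR / 100.0)
            t1 = (A * D) @ Rb.T
            t2 = A @ Rb.T
            t3 = D @ Rb.T
            sAD = (A * D).sum(axis=1)  # (H,)
            num = (
                (cL * cR)[None, :] * t1
                + (cL * (1.0 - cR) / R)[None, :] * t2
                + ((1.0 - cL) * cR / R)[None, :] * t3
                + ((1.0 - cL) * (1.0 - cR) / R)[None, :] * colmean[None, :]
            )
            den = (
                (cL * cR)[None, :] * sAD[:, None]
                + (cL * (1.0 - cR) / R)[None, :]
                + ((1.0 - cL) * cR / R)[None, :]
                + ((1.0 - cL) * (1.0 - cR) / R)[None, :]
            )
            out[:, us] = num / den
    return out


def impute(
    target_haplotypes: np.ndarray,
    typed: np.ndarray,
    reference: HaplotypePanel | np.ndarray,
    gmap: GeneticMap,
    samples: Sequence[str] | None = None,
    mismatch_rate: float = 0.001,
    recomb_scale: float = 1.0,
    reference_label: str = "",
) -> ImputationResult:
    """Impute untyped sites by haplotype copying from a reference panel.

    Parameters
    ----------
    target_haplotypes
        (n_ind, 2, n_sites) phased target haplotypes; only typed columns
        are read (targets must be phased at typed sites).
    typed
        Boolean mask over the full site list; False marks sites to impute.
    reference
        Reference haplotypes covering the full site list.
    recomb_scale
        Copying-switch rate per cM (1.0 = one expected switch per Morgan).
    """
    ref = reference.haplotypes if isinstance(reference, HaplotypePanel) else np.asarray(reference)
    typed = np.asarray(typed, dtype=bool)
    H3 = np.asarray(target_haplotypes)
    if H3.ndim != 3 or H3.shape[1] != 2:
        raise ValueError("target_haplotypes must have shape (n_ind, 2, n_sites)")
    n_ind, _, n_sites = H3.shape
    if ref.ndim != 2 or ref.shape[0] == 0:
        raise ValueError("reference panel is empty")
    if ref.shape[1] != n_sites or typed.shape != (n_sites,):
        raise ValueError("typed sites absent from reference: site lists must match")
    if gmap.n_sites != n_sites:
        raise ValueError("map does not cover the site list")

    X = H3.reshape(n_ind * 2, n_sites).astype(np.int8)
    hap_dos = np.empty((n_ind * 2, n_sites))
    for _, sl in gmap.chrom_slices():
        t_local = np.flatnonzero(typed[sl])
        hap_dos[:, sl] = _ls_haplotype_dosages(
            X[:, sl], ref[:, sl], t_local, gmap.cm[sl], mismatch_rate, recomb_scale
        )
    dosages = hap_dos.reshape(n_ind, 2, n_sites).sum(axis=1)
    np.clip(dosages, 0.0, 2.0, out=dosages)  # guard float roundoff
    # Observed genotypes stand at typed sites.
    obs = H3.sum(axis=1).astype(np.float64)
    dosages[:, typed] = obs[:, typed]
    bg = best_guess_genotypes(dosages)
    if samples is None:
        samples = [f"ind{i:04d}" for i in range(n_ind)]
    return ImputationResult(
        dosages, bg, typed, list(samples), gmap.site_table(), reference_label
    )


def frequency_impute(
    target: GenotypeMatrix, typed: np.ndarray, ref_freqs: np.ndarray
) -> ImputationResult:
    """Baseline imputer: dosage = 2 x reference allele frequency.

    Carries no individual information; its best guess is the major-allele
    homozygote at sites with MAF < 0.25.  Used to demonstrate the
    chance-concordance inflation at low MAF.
    """
    typed = np.asarray(typed, dtype=bool)
    f = np.asarray(ref_freqs, dtype=np.float64)
    dosages = np.tile(2.0 * f, (target.n_individuals, 1))
    obs = target.genotypes.astype(np.float64)
    dosages[:, typed] = obs[:, typed]
    return ImputationResult(
        dosages,
        best_guess_genotypes(dosages),
        typed,
        list(target.samples),
        target.sites,
        "frequency",
    )


def _per_site_pearson(dos: np.ndarray, tru: np.ndarray) -> tuple[np.ndarray, int]:
    """Columnwise Pearson r; NaN where truth is monomorphic (excluded)."""
    x = dos - dos.mean(axis=0, keepdims=True)
    y = tru - tru.mean(axis=0, keepdims=True)
    sx = np.sqrt((x * x).sum(axis=0))
    sy = np.sqrt((y * y).sum(axis=0))
    mono = sy == 0
    r = np.full(dos.shape[1], np.nan)
    ok = ~mono
    with np.errstate(invalid="ignore", divide="ignore"):
        r[ok] = np.where(sx[ok] > 0, (x * y).sum(axis=0)[ok] / (sx[ok] * sy[ok]), 0.0)
    return r, int(mono.sum())


@dataclass
class CorrelationSummary:
    per_site: np.ndarray  # NaN at monomorphic-truth sites
    mean_r: float
    pooled_r: float
    n_excluded_monomorphic: int


def allelic_correlation(
    imputed: ImputationResult, truth: GenotypeMatrix
) -> CorrelationSummary:
    """Allelic correlation of imputed dosage vs true genotype.

    Per imputed site, the Pearson correlation across individuals; sites
    monomorphic in the validation truth are excluded and counted.  A
    polymorphic site with zero dosage variance scores r = 0.  The summary
    is the unweighted mean over included sites; the pooled correlation
    over all (individual, site) entries is reported alongside.
    """
    if truth.n_individuals < 2:
        raise ValueError("allelic correlation needs at least 2 individuals")
    idx = imputed.imputed_sites
    dos = imputed.dosages[:, idx]
    tru = truth.genotypes[:, idx].astype(np.float64)
    r, n_mono = _per_site_pearson(dos, tru)
    mean_r = float(np.nanmean(r)) if np.isfinite(r).any() else float("nan")
    dflat, tflat = dos.ravel(), tru.ravel()
    if dflat.std() > 0 and tflat.std() > 0:
        pooled = float(np.corrcoef(dflat, tflat)[0, 1])
    else:
        pooled = 0.0
    return CorrelationSummary(r, mean_r, pooled, n_mono)


@dataclass
class ConcordanceSummary:
    per_site: np.ndarray
    allele_rate: float
    genotype_rate: float


def concordance_rate(imputed: ImputationResult, truth: GenotypeMatrix) -> ConcordanceSummary:
    """Correctly imputed alleles over total imputed alleles.

    Per (individual, site) pair the matched-allele count is
    ``2 - |best_guess - truth|``; the rate is total matched over
    ``2 x comparisons``.  Genotype-level concordance (exact genotype
    match) is reported alongside.
    """
    if truth.n_individuals < 2:
        raise ValueError("concordance needs at least 2 individuals")
    idx = imputed.imputed_sites
    bg = imputed.best_guess[:, idx].astype(np.int16)
    tru = truth.genotypes[:, idx].astype(np.int16)
    matched = 2 - np.abs(bg - tru)
    per_site = matched.mean(axis=0) / 2.0
    return ConcordanceSummary(
        per_site, float(matched.mean() / 2.0), float((bg == tru).mean())
    )


def maf_stratified_accuracy(
    imputed: ImputationResult,
    truth: GenotypeMatrix,
    bin_edges: Sequence[float] = DEFAULT_MAF_EDGES,
) -> pd.DataFrame:
    """Mean correlation and concordance per truth-MAF bin.

    Sites are binned by their minor allele frequency in the validation
    truth; bins are half-open [lo, hi) with the last bin closed.  Empty
    bins are omitted.  Monomorphic sites contribute to concordance but
    not to the correlation mean.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0) or edges[0] < 0 or edges[-1] > 0.5:
        raise ValueError("bin edges must be ascending within [0, 0.5]")
    idx = imputed.imputed_sites
    tru = truth.take_sites(idx)
    maf = tru.minor_allele_freqs()
    corr = allelic_correlation(imputed, truth)
    conc = concordance_rate(imputed, truth)
    which = np.digitize(maf, edges[1:-1], right=False)  # 0..len-2
    last = len(edges) - 2
    rows = []
    for b in range(last + 1):
        sel = which == b
        if not sel.any():
            continue
        r_vals = corr.per_site[sel]
        rows.append(
            {
                "maf_lo": edges[b],
                "maf_hi": edges[b + 1],
                "n_sites": int(sel.sum()),
                "mean_r": float(np.nanmean(r_vals)) if np.isfinite(r_vals).any() else np.nan,
                "concordance": float(conc.per_site[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def grm_offdiagonal_correlation(
    g_real: GenotypeMatrix, g_imputed: GenotypeMatrix
) -> float:
    """Pearson correlation of GRM strict-upper-triangle entries, real vs imputed."""
    if g_real.n_individuals < 3:
        raise ValueError("GRM off-diagonal correlation needs at least 3 individuals")
    if g_real.n_individuals != g_imputed.n_individuals or g_real.n_sites != g_imputed.n_sites:
        raise ValueError("matrices must cover the same individuals and sites")
    a = compute_grm(g_real).offdiagonal()
    b = compute_grm(g_imputed).offdiagonal()
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ScenarioSpec:
    """One imputation scenario: who imputes whom, between which panels.

    ``cv_folds = 1`` means direct imputation from the named external
    reference cohorts; ``k > 1`` runs k-fold cross-validation where each
    target fold is imputed with the remaining target individuals (plus any
    external reference cohorts) as reference.
    """

    name: str
    reference: list[str]
    target: str
    from_panel: str = "low"
    to_panel: str = "high"
    cv_folds: int = 1

    def __post_init__(self) -> None:
        if self.cv_folds < 1:
            raise ValueError("cv_folds must be >= 1")
        if self.cv_folds == 1 and not self.reference:
            raise ValueError("direct imputation needs at least one reference cohort")


@dataclass
class AccuracyReport:
    """Imputation accuracy for one scenario."""

    scenario: str
    mean_r: float
    pooled_r: float
    concordance: float
    genotype_concordance: float
    grm_offdiag_r: float
    n_sites_imputed: int
    n_excluded_monomorphic: int
    n_reference_haplotypes: int
    cv_folds: int
    maf_table: pd.DataFrame = field(repr=False)
    per_site: pd.DataFrame = field(repr=False)

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "mean_r": self.mean_r,
            "pooled_r": self.pooled_r,
            "concordance": self.concordance,
            "genotype_concordance": self.genotype_concordance,
            "grm_offdiag_r": self.grm_offdiag_r,
            "n_sites_imputed": self.n_sites_imputed,
            "n_excluded_monomorphic": self.n_excluded_monomorphic,
            "n_reference_haplotypes": self.n_reference_haplotypes,
            "cv_folds": self.cv_folds,
        }


def run_scenarios(
    specs: Sequence[ScenarioSpec],
    cohorts: Mapping[str, CrossbredCohort],
    panels: Mapping[str, PanelDef],
    seed: int = 0,
    mismatch_rate: float = 0.001,
    recomb_scale: float = 1.0,
) -> list[AccuracyReport]:
    """Run imputation scenarios and score them against simulated truth.

    For each scenario the target cohort is restricted to the ``to_panel``
    site universe, its typed sites are those of ``from_panel`` (panels are
    nested), and accuracy is measured at the remaining sites.  Fold
    assignment is reproducible from ``seed``.
    """
    reports = []
    for spec in specs:
        for label in [spec.target, *spec.reference]:
            if label not in cohorts:
                raise KeyError(f"scenario {spec.name!r} references unknown cohort {label!r}")
        for pname in (spec.from_panel, spec.to_panel):
            if pname not in panels:
                raise KeyError(f"scenario {spec.name!r} references unknown panel {pname!r}")
        target = cohorts[spec.target]
        universe = panels[spec.to_panel].site_subset
        typed = np.isin(universe, panels[spec.from_panel].site_subset)
        gmap_u = _subset_map(target.gmap, universe)
        tgt_haps = target.haplotypes[:, :, universe]
        truth = target.genotypes.take_sites(universe)
        ext_ref = (
            np.concatenate(
                [
                    cohorts[r].haplotypes[:, :, universe].reshape(-1, len(universe))
                    for r in spec.reference
                ],
                axis=0,
            )
            if spec.reference
            else np.empty((0, len(universe)), dtype=np.uint8)
        )

        n = target.n_individuals
        dosages = np.empty((n, len(universe)))
        if spec.cv_folds == 1:
            fold_assign = [np.arange(n)]
        else:
            perm = substream(seed, "folds", spec.name).permutation(n)
            fold_assign = [perm[f :: spec.cv_folds] for f in range(spec.cv_folds)]
        n_ref_haps = 0
        for fold in fold_assign:
            if len(fold) < 2:
                raise ValueError(f"scenario {spec.name!r}: fold with fewer than 2 individuals")
            rest = np.setdiff1d(np.arange(n), fold)
            parts = [ext_ref]
            if spec.cv_folds > 1 and len(rest):
                parts.append(tgt_haps[rest].reshape(-1, len(universe)))
            ref = np.concatenate(parts, axis=0)
            n_ref_haps = ref.shape[0]
            res = impute(
                tgt_haps[fold],
                typed,
                ref,
                gmap_u,
                samples=[target.samples[i] for i in fold],
                mismatch_rate=mismatch_rate,
                recomb_scale=recomb_scale,
                reference_label="+".join(spec.reference) or "cv",
            )
            dosages[fold] = res.dosages

        result = ImputationResult(
            dosages,
            best_guess_genotypes(dosages),
            typed,
            list(target.samples),
            truth.sites,
            "+".join(spec.reference) or "cv",
        )
        corr = allelic_correlation(result, truth)
        conc = concordance_rate(result, truth)
        maf_tab = maf_stratified_accuracy(result, truth)
        g_imp = GenotypeMatrix(result.best_guess, list(truth.samples), truth.sites)
        grm_r = grm_offdiagonal_correlation(truth, g_imp)
        idx = result.imputed_sites
        per_site = pd.DataFrame(
            {
                "site": universe[idx],
                "maf": truth.take_sites(idx).minor_allele_freqs(),
                "r": corr.per_site,
                "concordance": conc.per_site,
            }
        )
        reports.append(
            AccuracyReport(
                scenario=spec.name,
                mean_r=corr.mean_r,
                pooled_r=corr.pooled_r,
                concordance=conc.allele_rate,
                genotype_concordance=conc.genotype_rate,
                grm_offdiag_r=grm_r,
                n_sites_imputed=len(idx),
                n_excluded_monomorphic=corr.n_excluded_monomorphic,
                n_reference_haplotypes=n_ref_haps,
                cv_folds=spec.cv_folds,
                maf_table=maf_tab,
                per_site=per_site,
            )
        )
    return reports


def _subset_map(gmap: GeneticMap, idx: np.ndarray) -> GeneticMap:
    return GeneticMap(gmap.chrom[idx], gmap.pos[idx], gmap.cm[idx])
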