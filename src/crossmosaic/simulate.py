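"""Forward simulation of divergent ancestral pools and pedigreed crosses.

The generator emulates the structure of admixed cattle populations: a few
ancestral pools with divergent allele frequencies (Balding-Nichols model),
phased haplotypes on a genetic map, pedigreed crosses produced by explicit
gamete sampling with Haldane recombination (Poisson crossovers, no
interference), and nested SNP density panels with optional sporadic
missingness.  Every offspring carries its true per-site, per-haplotype
ancestry track, so downstream inference can always be scored against truth.

Ancestral pools
---------------
Per site a shared base frequency is drawn uniformly on
``[maf_floor, 1 - maf_floor]``; each pool's frequency is then drawn from a
beta distribution with mean equal to the base frequency and variance
``F * p * (1 - p)`` where ``F`` is the pool's divergence parameter.  Under
this model the expected Hudson Fst between two pools with the same ``F``
equals ``F``, and a pool's expected heterozygosity is ``(1 - F)`` times the
base-frequency heterozygosity - so higher divergence yields a lower-MAF
spectrum and a less heterozygous pool, mimicking the ascertainment-bias
driven ordering seen across real cattle reference populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import (
    AncestryTrack,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    uniform_map,
)

__all__ = [
    "AncestralPool",
    "Gamete",
    "Individual",
    "CrossSpec",
    "CrossbredCohort",
    "PanelDef",
    "make_ancestral_pools",
    "sample_gamete",
    "make_cross",
    "concat_cohorts",
    "define_panels",
    "mask_to_panel",
    "maf_filter",
]


@dataclass
class AncestralPool(HaplotypePanel):
    """A reference population: phased haplotypes plus its frequency model."""

    allele_freqs: np.ndarray = None
    base_freq: np.ndarray = None
    divergence: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("a pool needs an even number of haplotypes, at least 2")
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=np.float64)
        if np.any((self.allele_freqs < 0) | (self.allele_freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


def make_ancestral_pools(
    n_pools: int,
    n_hap: int,
    n_sites: int,
    divergence: float | Sequence[float] = 0.25,
    maf_floor: float = 0.05,
    map_length_cm: float = 100.0,
    n_chrom: int = 1,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> tuple[list[AncestralPool], GeneticMap]:
    """Generate divergent ancestral haplotype pools on a uniform map.

    Parameters
    ----------
    divergence
        Balding-Nichols drift parameter in (0, 1), scalar or one value per
        pool.  Expected pairwise Hudson Fst between two pools both at
        divergence ``F`` is ``F``.
    maf_floor
        The shared base frequency is drawn uniformly on
        ``[maf_floor, 1 - maf_floor]``.

    Returns
    -------
    (pools, gmap)
        Pools named ``pool1..poolK`` (or ``names``) and the map they share.
    """
    if n_pools < 2:
        raise ValueError("n_pools must be >= 2")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_hap < 2 or n_hap % 2:
        raise ValueError("n_hap must be even and >= 2")
    div = np.broadcast_to(np.asarray(divergence, dtype=float), (n_pools,)).copy()
    if np.any((div <= 0) | (div >= 1)):
        raise ValueError("divergence values must lie in (0, 1)")
    if not 0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must lie in [0, 0.5)")
    if names is None:
        names = [f"pool{k + 1}" for k in range(n_pools)]
    elif len(names) != n_pools:
        raise ValueError("names length must equal n_pools")

    rng = substream(seed, "pools")
    gmap = uniform_map(n_sites, map_length_cm, n_chrom=n_chrom)
    base = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_sites)
    pools = []
    for k in range(n_pools):
        F = div[k]
        a = base * (1.0 - F) / F
        b = (1.0 - base) * (1.0 - F) / F
        freqs = rng.beta(a, b)
        haps = (rng.random((n_hap, n_sites)) < freqs).astype(np.uint8)
        pools.append(
            AncestralPool(
                name=str(names[k]),
                haplotypes=haps,
                gmap=gmap,
                allele_freqs=freqs,
                base_freq=base,
                divergence=float(F),
            )
        )
    return pools, gmap


@dataclass
class Gamete:
    """One transmitted haplotype with its ancestry labels.

    ``breakpoints`` maps chromosome name to the sorted cM positions of the
    simulated crossovers; ``start`` maps chromosome name to the parental
    haplotype (0/1) copied before the first crossover.
    """

    haplotype: np.ndarray
    labels: np.ndarray
    breakpoints: dict[str, np.ndarray]
    start: dict[str, int]


def sample_gamete(
    parent_haplotypes: np.ndarray,
    parent_labels: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator | int,
) -> Gamete:
    """Sample one recombinant gamete from a phased parent.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans (Haldane model, no interference); crossover positions
    are uniform on the cM axis.  Between crossovers the gamete copies one
    parental haplotype, and its ancestry labels, contiguously; the starting
    haplotype is chosen uniformly per chromosome.
    """
    if isinstance(rng, (int, np.integer)):
        rng = substream(int(rng), "gamete")
    parent_haplotypes = np.asarray(parent_haplotypes)
    parent_labels = np.asarray(parent_labels)
    if parent_haplotypes.shape != (2, gmap.n_sites) or parent_labels.shape != (2, gmap.n_sites):
        raise ValueError("parent haplotypes/labels must cover the map's site list (2 x n_sites)")

    hap = np.empty(gmap.n_sites, dtype=parent_haplotypes.dtype)
    lab = np.empty(gmap.n_sites, dtype=parent_labels.dtype)
    breakpoints: dict[str, np.ndarray] = {}
    start: dict[str, int] = {}
    for name, sl in gmap.chrom_slices():
        cm = gmap.cm[sl]
        lo, hi = float(cm.min()), float(cm.max())
        length_morgans = (hi - lo) / 100.0
        n_x = rng.poisson(length_morgans) if length_morgans > 0 else 0
        bp = np.sort(rng.uniform(lo, hi, size=n_x)) if n_x else np.empty(0)
        s = int(rng.integers(2))
        # Which parental haplotype each site copies: parity of crossovers
        # to the left of the site.
        src = (s + np.searchsorted(bp, cm, side="right")) % 2
        idx = np.arange(sl.start, sl.stop)
        hap[sl] = parent_haplotypes[src, idx]
        lab[sl] = parent_labels[src, idx]
        breakpoints[name] = bp
        start[name] = s
    return Gamete(hap, lab, breakpoints, start)


@dataclass
class Individual:
    """A diploid: two phased haplotypes and their true ancestry labels."""

    haplotypes: np.ndarray  # (2, n_sites)
    labels: np.ndarray  # (2, n_sites)


def _split_recipe(recipe: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """Split a breed-proportion recipe into two parental recipes.

    Returns recipes u, v with (u + v) / 2 equal to the input; each is the
    breed composition of one parent.  Works for any recipe whose entries
    have finite binary expansions (pure, F1, BC1, three-way, ...).
    """
    u: dict[str, float] = {}
    v: dict[str, float] = {}
    c = 0.0
    for pool, w in recipe.items():
        w2 = 2.0 * w
        to_u = min(max(1.0 - c, 0.0), w2)
        if to_u > 1e-12:
            u[pool] = to_u
        if w2 - to_u > 1e-12:
            v[pool] = w2 - to_u
        c += w2
    return u, v


def _individual_from_recipe(
    recipe: Mapping[str, float],
    pools: dict[str, AncestralPool],
    pool_codes: dict[str, int],
    gmap: GeneticMap,
    rng: np.random.Generator,
    _depth: int = 0,
) -> Individual:
    """Realize a parent of the requested breed composition, recursively.

    A recipe with one pool at proportion 1 is a purebred drawn from that
    pool; anything else is built as the offspring of two parents whose
    recipes average to the requested one (e.g. a 3/4:1/4 parent is the
    offspring of a purebred and an F1).
    """
    if _depth > 20:
        raise ValueError(f"breed-proportion recipe is not dyadic-resolvable: {dict(recipe)}")
    items = {k: float(w) for k, w in recipe.items() if float(w) > 1e-12}
    total = sum(items.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"breed proportions must sum to 1, got {total} in {dict(recipe)}")
    for name in items:
        if name not in pools:
            raise KeyError(f"unknown pool name in recipe: {name!r}")
    if len(items) == 1:
        (name,) = items
        pool = pools[name]
        i, j = rng.choice(pool.n_haplotypes, size=2, replace=False)
        haps = pool.haplotypes[[i, j]].copy()
        labs = np.full((2, gmap.n_sites), pool_codes[name], dtype=np.int16)
        return Individual(haps, labs)
    u, v = _split_recipe(items)
    sire = _individual_from_recipe(u, pools, pool_codes, gmap, rng, _depth + 1)
    dam = _individual_from_recipe(v, pools, pool_codes, gmap, rng, _depth + 1)
    g1 = sample_gamete(sire.haplotypes, sire.labels, gmap, rng)
    g2 = sample_gamete(dam.haplotypes, dam.labels, gmap, rng)
    return Individual(
        np.stack([g1.haplotype, g2.haplotype]), np.stack([g1.labels, g2.labels])
    )


@dataclass
class CrossSpec:
    """A pedigreed cross: parental breed-proportion recipes and a count.

    ``sire``/``dam`` map pool names to breed proportions (each sums to 1).
    Standard crosses are available as classmethod constructors.
    """

    label: str
    sire: dict[str, float]
    dam: dict[str, float]
    n_offspring: int
    seed: int = 0

    def __post_init__(self) -> None:
        for side, recipe in (("sire", self.sire), ("dam", self.dam)):
            s = sum(recipe.values())
            if abs(s - 1.0) > 1e-8:
                raise ValueError(f"{side} breed proportions sum to {s}, expected 1")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")

    @classmethod
    def pure(cls, pool: str, n: int, seed: int = 0) -> "CrossSpec":
        return cls(f"pure_{pool}", {pool: 1.0}, {pool: 1.0}, n, seed)

    @classmethod
    def f1(cls, a: str, b: str, n: int, seed: int = 0) -> "CrossSpec":
        return cls(f"F1_{a}x{b}", {a: 1.0}, {b: 1.0}, n, seed)

    @classmethod
    def f2(cls, a: str, b: str, n: int, seed: int = 0) -> "CrossSpec":
        half = {a: 0.5, b: 0.5}
        return cls(f"F2_{a}x{b}", dict(half), dict(half), n, seed)

    @classmethod
    def bc1(cls, a: str, b: str, n: int, seed: int = 0, recurrent: str | None = None) -> "CrossSpec":
        """Backcross: F1(a, b) mated to the recurrent purebred (default a)."""
        rec = a if recurrent is None else recurrent
        return cls(f"BC1_{a}x{b}_to_{rec}", {a: 0.5, b: 0.5}, {rec: 1.0}, n, seed)

    @classmethod
    def inter_se(cls, recipe: Mapping[str, float], n: int, seed: int = 0) -> "CrossSpec":
        """Mating of two crossbred parents with identical breed composition."""
        r = dict(recipe)
        label = "interse_" + "_".join(f"{k}{v:g}" for k, v in r.items())
        return cls(label, dict(r), dict(r), n, seed)

    @classmethod
    def three_way(cls, a: str, b: str, c: str, n: int, seed: int = 0) -> "CrossSpec":
        """F1(a, b) mated to purebred c."""
        return cls(f"3way_{a}x{b}x{c}", {a: 0.5, b: 0.5}, {c: 1.0}, n, seed)


@dataclass
class CrossbredCohort:
    """A simulated cohort: genotypes, phased haplotypes, truth and pedigree."""

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # (n_ind, 2, n_sites) uint8
    truth: AncestryTrack
    pedigree: pd.DataFrame
    pools: list[str]
    gmap: GeneticMap = field(repr=False)

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    @property
    def true_breed_proportion(self) -> pd.DataFrame:
        """Per-individual pool fractions over all (site, haplotype) slots."""
        return self.truth.proportions()

    def take_individuals(self, idx: np.ndarray) -> "CrossbredCohort":
        idx = np.asarray(idx)
        return CrossbredCohort(
            self.genotypes.take_individuals(idx),
            self.haplotypes[idx],
            self.truth.take_individuals(idx),
            self.pedigree.iloc[idx].reset_index(drop=True),
            list(self.pools),
            self.gmap,
        )


def make_cross(
    spec: CrossSpec, pools: Sequence[AncestralPool], gmap: GeneticMap
) -> CrossbredCohort:
    """Simulate a pedigreed cross.

    For each offspring, fresh parents matching the sire and dam recipes are
    realized (recursively, from the pools) and one gamete is sampled from
    each; the offspring's truth track records the transmitted ancestry
    labels site by site.
    """
    pool_map = {p.name: p for p in pools}
    pool_names = [p.name for p in pools]
    pool_codes = {n: k for k, n in enumerate(pool_names)}
    rng = substream(spec.seed, "cross", spec.label)

    n = spec.n_offspring
    haps = np.empty((n, 2, gmap.n_sites), dtype=np.uint8)
    labs = np.empty((n, 2, gmap.n_sites), dtype=np.int16)
    for i in range(n):
        sire = _individual_from_recipe(spec.sire, pool_map, pool_codes, gmap, rng)
        dam = _individual_from_recipe(spec.dam, pool_map, pool_codes, gmap, rng)
        g1 = sample_gamete(sire.haplotypes, sire.labels, gmap, rng)
        g2 = sample_gamete(dam.haplotypes, dam.labels, gmap, rng)
        haps[i, 0], haps[i, 1] = g1.haplotype, g2.haplotype
        labs[i, 0], labs[i, 1] = g1.labels, g2.labels

    samples = [f"{spec.label}_{i:04d}" for i in range(n)]
    truth = AncestryTrack(labs, pool_names, samples)
    genotypes = GenotypeMatrix.from_haplotypes(haps, samples, gmap)
    pedigree = pd.DataFrame(
        {
            "id": samples,
            "cross": spec.label,
            "sire_recipe": [repr(spec.sire)] * n,
            "dam_recipe": [repr(spec.dam)] * n,
        }
    )
    return CrossbredCohort(genotypes, haps, truth, pedigree, pool_names, gmap)


def concat_cohorts(cohorts: Sequence[CrossbredCohort]) -> CrossbredCohort:
    """Stack cohorts simulated on the same map and pool list."""
    first = cohorts[0]
    for c in cohorts[1:]:
        if c.pools != first.pools:
            raise ValueError("cohorts must share the same pool list")
        if c.gmap.n_sites != first.gmap.n_sites:
            raise ValueError("cohorts must share the same site list")
    haps = np.concatenate([c.haplotypes for c in cohorts], axis=0)
    labs = np.concatenate([c.truth.labels for c in cohorts], axis=0)
    samples = [s for c in cohorts for s in c.samples]
    truth = AncestryTrack(labs, list(first.pools), samples)
    genotypes = GenotypeMatrix.from_haplotypes(haps, samples, first.gmap)
    pedigree = pd.concat([c.pedigree for c in cohorts], ignore_index=True)
    return CrossbredCohort(genotypes, haps, truth, pedigree, list(first.pools), first.gmap)


@dataclass
class PanelDef:
    """A nested SNP density panel: indices into a master site list."""

    name: str
    site_subset: np.ndarray
    n_total: int
    sporadic_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.site_subset = np.asarray(np.sort(self.site_subset), dtype=np.int64)
        if len(self.site_subset) and (
            self.site_subset[0] < 0 or self.site_subset[-1] >= self.n_total
        ):
            raise ValueError("panel site indices out of range")
        if not 0 <= self.sporadic_missing_rate < 1:
            raise ValueError("sporadic_missing_rate must lie in [0, 1)")

    @property
    def n_sites(self) -> int:
        return len(self.site_subset)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_total, dtype=bool)
        m[self.site_subset] = True
        return m


def define_panels(
    n_sites: int,
    fractions: Sequence[float] = (0.02, 0.1, 1.0),
    seed: int = 0,
    missing_rates: Sequence[float] = (0.0, 0.0, 0.0),
) -> list[PanelDef]:
    """Nested random low/medium/high density panels.

    ``fractions`` must be strictly increasing with the last equal to 1;
    the low panel is a random subset of the medium panel, which is a
    random subset of the full (high) site list - mirroring density panels
    defined by keeping the SNPs in common with sparser arrays.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or len(missing_rates) != 3:
        raise ValueError("exactly three panels (low, medium, high) are defined")
    if not (0 < fractions[0] < fractions[1] < fractions[2] or fractions == (1.0, 1.0, 1.0)):
        if not all(f == 1.0 for f in fractions):
            raise ValueError("fractions must be strictly increasing")
    if fractions[2] != 1.0:
        raise ValueError("the high-density panel must contain all sites (last fraction = 1)")
    rng = substream(seed, "panels")
    order = rng.permutation(n_sites)
    names = ("low", "medium", "high")
    panels = []
    for name, frac, miss in zip(names, fractions, missing_rates):
        k = int(round(frac * n_sites))
        panels.append(PanelDef(name, order[:k], n_sites, float(miss)))
    return panels


def mask_to_panel(g: GenotypeMatrix, panel: PanelDef, seed: int = 0) -> GenotypeMatrix:
    """Mask a genotype matrix down to a density panel.

    Sites outside the panel become missing; each retained call is
    additionally set missing with the panel's sporadic rate.  The input is
    left unmodified; the output keeps the full site list (density is a
    missingness pattern, so nested panels remain comparable).
    """
    if g.n_sites != panel.n_total:
        raise ValueError(
            f"panel indexes {panel.n_total} sites but the matrix has {g.n_sites}; "
            "panel sites must all be present in the matrix"
        )
    out = g.copy()
    keep = panel.mask()
    out.genotypes[:, ~keep] = -1
    if panel.sporadic_missing_rate > 0:
        rng = substream(seed, "sporadic", panel.name)
        drop = rng.random(out.genotypes.shape) < panel.sporadic_missing_rate
        out.genotypes[drop & keep[None, :]] = -1
    return out


def maf_filter(
    g: GenotypeMatrix, threshold: float = 0.01
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Remove sites with minor allele frequency strictly below ``threshold``.

    MAF is computed on non-missing genotypes; a site whose MAF equals the
    threshold exactly is retained ("lower than" is strict).  Returns the
    filtered matrix and the removed site indices.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    maf = g.minor_allele_freqs()
    with np.errstate(invalid="ignore"):
        removed = np.flatnonzero(maf < threshold)  # strict; NaN (all-missing) retained
    keep = np.setdiff1d(np.arange(g.n_sites), removed)
    return g.take_sites(keep), removed
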