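"""Core in-memory containers shared across the package.

Conventions
-----------
* Genotypes are alternate-allele counts in {0, 1, 2}; ``-1`` marks a
  missing call.
* Haplotypes are binary alternate-allele indicators, one row per
  haplotype.
* Site order is the master site order of the genetic map; sites are
  grouped contiguously by chromosome with non-decreasing genetic (cM)
  positions within each chromosome.
* Physical positions are 1-based (VCF convention); all array indices are
  0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "AncestryTrack",
    "HaplotypePanel",
    "uniform_map",
]

MISSING = -1


@dataclass
class GeneticMap:
    """Per-site physical and genetic coordinates.

    Attributes
    ----------
    chrom : array of str, one entry per site
    pos : array of int, 1-based physical coordinate (bp)
    cm : array of float, genetic position, non-decreasing within chromosome
    """

    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if not (len(self.chrom) == len(self.pos) == len(self.cm)):
            raise ValueError("chrom, pos and cM arrays must have equal length")
        if np.any(self.pos < 1):
            raise ValueError("physical positions are 1-based and must be >= 1")
        for _, sl in self.chrom_slices():
            c = self.cm[sl]
            if np.any(np.diff(c) < 0):
                raise ValueError("cM positions must be non-decreasing within a chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome name, slice) pairs in site order."""
        out: list[tuple[str, slice]] = []
        n = len(self.chrom)
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        names = [c for c, _ in out]
        if len(set(names)) != len(names):
            raise ValueError("sites of one chromosome must be contiguous")
        return out

    def length_cm(self) -> dict[str, float]:
        """Map length per chromosome (max cM minus min cM)."""
        return {
            name: float(self.cm[sl].max() - self.cm[sl].min()) if sl.stop > sl.start else 0.0
            for name, sl in self.chrom_slices()
        }

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom.astype(str), "pos": self.pos, "cm": self.cm})


def uniform_map(
    n_sites: int,
    length_cm: float = 100.0,
    n_chrom: int = 1,
    bp_per_site: int = 1000,
) -> GeneticMap:
    """Evenly spaced sites on ``n_chrom`` chromosomes of equal cM length.

    Sites are split as evenly as possible across chromosomes; cM runs
    linearly from 0 to ``length_cm`` on each chromosome (uniform
    recombination rate, a stated simplification relative to real maps).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if length_cm < 0:
        raise ValueError("length_cm must be >= 0")
    counts = np.full(n_chrom, n_sites // n_chrom, dtype=int)
    counts[: n_sites % n_chrom] += 1
    chroms, pos, cm = [], [], []
    for k, c in enumerate(counts):
        if c == 0:
            continue
        chroms.extend([str(k + 1)] * c)
        pos.extend(range(bp_per_site, bp_per_site * (c + 1), bp_per_site))
        cm.extend(np.linspace(0.0, length_cm, c) if c > 1 else [0.0])
    return GeneticMap(np.array(chroms, dtype=object), np.array(pos), np.array(cm))


@dataclass
class GenotypeMatrix:
    """Individuals x sites alternate-allele counts with missingness.

    ``genotypes`` is int8 with entries in {0, 1, 2} and -1 for missing.
    ``sites`` carries at least columns chrom, pos, cm.
    """

    genotypes: np.ndarray
    samples: list[str]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals x sites array")
        if self.genotypes.shape[0] != len(self.samples):
            raise ValueError("sample list length does not match genotype rows")
        if self.genotypes.shape[1] != len(self.sites):
            raise ValueError("site table length does not match genotype columns")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")

    @classmethod
    def from_haplotypes(
        cls, haplotypes: np.ndarray, samples: list[str], gmap: GeneticMap
    ) -> "GenotypeMatrix":
        """Build from a (n_ind, 2, n_sites) phased haplotype array."""
        haplotypes = np.asarray(haplotypes)
        if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_ind, 2, n_sites)")
        g = haplotypes.sum(axis=1).astype(np.int8)
        return cls(g, list(samples), gmap.site_table())

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_missing(self) -> np.ndarray:
        return self.genotypes == MISSING

    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def allele_freqs(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing calls.

        Sites with no non-missing call get frequency NaN.
        """
        g = self.genotypes.astype(np.float64)
        obs = g != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, g, 0.0).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, f, np.nan)

    def minor_allele_freqs(self) -> np.ndarray:
        f = self.allele_freqs()
        return np.minimum(f, 1.0 - f)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes.copy(), list(self.samples), self.sites.reset_index(drop=True).copy()
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.samples),
            self.sites.iloc[idx].reset_index(drop=True),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[idx],
            [self.samples[i] for i in idx],
            self.sites.reset_index(drop=True).copy(),
        )


@dataclass
class AncestryTrack:
    """Per-individual, per-haplotype, per-site ancestral-population labels.

    ``labels`` has shape (n_ind, 2, n_sites); entries are indices into
    ``pools`` (-1 marks a missing call, which truth tracks never contain).
    """

    labels: np.ndarray
    pools: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3 or self.labels.shape[1] != 2:
            raise ValueError("labels must have shape (n_ind, 2, n_sites)")
        if self.labels.shape[0] != len(self.samples):
            raise ValueError("sample list length does not match label rows")
        if self.labels.max(initial=-1) >= len(self.pools):
            raise ValueError("label code outside the declared pool list")
        if self.labels.min(initial=0) < -1:
            raise ValueError("label codes must be >= -1")

    @property
    def n_individuals(self) -> int:
        return self.labels.shape[0]

    @property
    def n_sites(self) -> int:
        return self.labels.shape[2]

    def is_complete(self) -> bool:
        return bool((self.labels >= 0).all())

    def proportions(self) -> pd.DataFrame:
        """Per-individual pool proportions over all (site, haplotype) slots."""
        if not self.is_complete():
            raise ValueError("track has missing ancestry calls; proportions undefined")
        n_slots = 2 * self.n_sites
        counts = np.stack(
            [(self.labels == k).sum(axis=(1, 2)) for k in range(len(self.pools))], axis=1
        )
        return pd.DataFrame(counts / n_slots, columns=self.pools, index=self.samples)

    def take_individuals(self, idx: np.ndarray) -> "AncestryTrack":
        idx = np.asarray(idx)
        return AncestryTrack(self.labels[idx], list(self.pools), [self.samples[i] for i in idx])


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one named population on a genetic map."""

    name: str
    haplotypes: np.ndarray
    gmap: GeneticMap = field(repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D n_hap x n_sites array")
        if self.haplotypes.shape[1] != self.gmap.n_sites:
            raise ValueError("haplotype site count does not match the map")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]
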