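"""Individual and ancestral-origin heterozygosity, with expectation bounds.

Ancestral-origin heterozygosity - the fraction of loci at which an
individual's two haplotypes descend from *different* ancestral
populations - is the genomic driver of heterosis: an F1 between two pure
populations has ancestral heterozygosity exactly 1, twice that expected
for an F2, even though the two have identical breed composition.

For an individual with breed-2 proportion ``p``:

* upper bound ``2p`` for ``p <= 0.5`` else ``2(1-p)`` - the triangle
  through the purebreds (0 and 1, heterozygosity 0) and the F1
  (p = 0.5, heterozygosity 1); attained by crosses with at least one
  purebred parent;
* lower bound ``2p(1-p)`` - the expectation under inter-se mating of
  crossbred parents of identical composition, where the two transmitted
  gamete ancestries are independent (0.5 at p = 0.5, the F2 value).

Both are expectations given parental composition; realized genome
averages of inter-se offspring scatter around the lower curve (the upper
bound, by contrast, holds pointwise for every track).

Individual (observed) heterozygosity admits analogous straight-line
bounds via ``expected_individual_heterozygosity``:
``H_i = H1 + p (H2 - H1) + a x`` with ``x = H_F1 - H1`` for ``p < 0.5``
and ``x = H_F1 - H2`` for ``p > 0.5``; evaluating at the upper/lower
ancestral-heterozygosity bound traces the outer/inter-se envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AncestryTrack, GenotypeMatrix

__all__ = [
    "BoundsModel",
    "individual_heterozygosity",
    "ancestral_origin_heterozygosity",
    "ancestral_het_bounds",
    "expected_individual_heterozygosity",
    "classify_cross",
    "het_table",
]


def individual_heterozygosity(g: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing sites at which each individual is heterozygous.

    Missing sites are excluded from both numerator and denominator; an
    individual with no non-missing site raises.
    """
    obs = ~g.is_missing
    n = obs.sum(axis=1)
    if np.any(n == 0):
        bad = [g.samples[i] for i in np.flatnonzero(n == 0)]
        raise ValueError(f"individual(s) with zero non-missing sites: {bad}")
    het = (g.genotypes == 1).sum(axis=1) / n
    return pd.Series(het, index=g.samples, name="individual_het")


def ancestral_origin_heterozygosity(
    track: AncestryTrack,
    scheme: str = "two_way",
    european_pool: str | None = None,
) -> pd.Series:
    """Per-individual ancestral-origin heterozygosity from an ancestry track.

    Scoring per site:

    * ``two_way`` - 1 iff the two haplotype labels differ;
    * ``three_way`` - 1 iff exactly one haplotype is the European pool and
      the other is one of the non-European pools (heterozygosity between
      the two non-European pools scores 0, as it carries no
      European-by-indigenous heterosis).

    ``european_pool`` names the European pool for the three-way rule.
    """
    if not track.is_complete():
        raise ValueError("track has missing ancestry labels")
    a, b = track.labels[:, 0, :], track.labels[:, 1, :]
    if scheme == "two_way":
        score = a != b
    elif scheme == "three_way":
        if european_pool is None:
            raise ValueError("three_way scoring needs european_pool")
        if european_pool not in track.pools:
            raise ValueError(f"label {european_pool!r} outside the track's pool set")
        eu = track.pools.index(european_pool)
        score = (a == eu) ^ (b == eu)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.Series(score.mean(axis=1), index=track.samples, name="ancestral_het")


def ancestral_het_bounds(p):
    """(lower, upper) ancestral-heterozygosity bounds at breed proportion p.

    ``upper = 2 min(p, 1 - p)`` (boundary crosses: one purebred parent);
    ``lower = 2 p (1 - p)`` (inter-se expectation).  Vectorised over p.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("breed proportion p must lie in [0, 1]")
    upper = 2.0 * np.minimum(p, 1.0 - p)
    lower = 2.0 * p * (1.0 - p)
    if p.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


@dataclass
class BoundsModel:
    """Parental and F1 mean individual heterozygosities.

    H1/H2 are the mean individual heterozygosities of parent breeds 1 and
    2 (breed proportion p refers to breed 2); H_F1 is the mean individual
    heterozygosity of F1 animals.
    """

    H1: float
    H2: float
    HF1: float

    def __post_init__(self) -> None:
        for v in (self.H1, self.H2, self.HF1):
            if not 0 <= v <= 1:
                raise ValueError("heterozygosities must lie in [0, 1]")


def expected_individual_heterozygosity(p, a, bounds: BoundsModel):
    """Expected individual heterozygosity of a cross: H1 + p(H2 - H1) + a*x.

    ``x = H_F1 - H1`` if ``p < 0.5``, ``x = H_F1 - H2`` if ``p > 0.5``;
    at exactly ``p = 0.5`` the midparent form ``x = H_F1 - (H1 + H2)/2``
    is used so the envelope passes through (0.5, a=1) -> H_F1 (the
    strictly piecewise rule would miss the F1 point whenever H1 != H2).
    Evaluating ``a`` at the upper/lower ancestral bound traces the outer
    and inter-se envelopes.  Vectorised over p and a.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if np.any((p < 0) | (p > 1)) or np.any((a < 0) | (a > 1)):
        raise ValueError("p and a must lie in [0, 1]")
    x = np.where(
        p < 0.5,
        bounds.HF1 - bounds.H1,
        np.where(p > 0.5, bounds.HF1 - bounds.H2, bounds.HF1 - (bounds.H1 + bounds.H2) / 2.0),
    )
    h = bounds.H1 + p * (bounds.H2 - bounds.H1) + a * x
    return float(h) if h.ndim == 0 else h


def classify_cross(p: float, a: float, tol: float = 0.02) -> str:
    """Classify an individual from (breed proportion, ancestral het).

    Labels: ``purebred`` (corner), ``F1`` (apex), ``boundary_cross`` (on
    the outer envelope: at least one purebred parent), ``below_lower``
    (anomalously under the inter-se curve, e.g. unmodelled ancestry or
    close inbreeding), else ``interior_cross`` (both parents crossbred).
    """
    if not (0 <= p <= 1 and 0 <= a <= 1):
        raise ValueError("p and a must lie in [0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    lower, upper = ancestral_het_bounds(p)
    if a <= tol and (p <= tol or p >= 1 - tol):
        return "purebred"
    if abs(a - 1.0) <= tol and abs(p - 0.5) <= tol:
        return "F1"
    if abs(a - upper) <= tol:
        return "boundary_cross"
    if a < lower - tol:
        return "below_lower"
    return "interior_cross"


def het_table(
    g: GenotypeMatrix,
    track: AncestryTrack,
    scheme: str = "two_way",
    european_pool: str | None = None,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Per-individual summary: p, individual het, ancestral het, class.

    ``p`` is the proportion of the European pool (three-way) or of the
    second pool in the track's pool list (two-way).
    """
    props = track.proportions()
    if scheme == "three_way":
        if european_pool is None:
            raise ValueError("three_way needs european_pool")
        p = props[european_pool]
    else:
        p = props[track.pools[1]] if len(track.pools) > 1 else props[track.pools[0]]
    ihet = individual_heterozygosity(g)
    ahet = ancestral_origin_heterozygosity(track, scheme, european_pool)
    cls = [classify_cross(pi, ai, tol) for pi, ai in zip(p.to_numpy(), ahet.to_numpy())]
    return pd.DataFrame(
        {
            "id": list(track.samples),
            "p": p.to_numpy(),
            "individual_het": ihet.to_numpy(),
            "ancestral_het": ahet.to_numpy(),
            "scheme": scheme,
            "class": cls,
        }
    )
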