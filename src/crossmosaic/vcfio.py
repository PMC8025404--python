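"""File formats: VCF genotypes and the ancestry-track TSV sidecar.

VCF 4.2 is used for genotypes (biallelic SNPs, GT field, phased entries
written with ``|``).  Ancestry tracks travel in a TSV sidecar with columns
``chrom, pos, individual, hap_index, ancestry_label`` and 1-based
positions matching the VCF.  Reading uses cyvcf2; multi-allelic records
are rejected with a clear message.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AncestryTrack, GeneticMap, GenotypeMatrix

__all__ = ["read_vcf", "write_vcf", "read_tracks", "write_tracks"]


def read_vcf(path: str) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Read a biallelic-SNP VCF.

    Returns
    -------
    (genotypes, phased, haplotypes)
        ``genotypes`` - alternate-allele counts with ``-1`` for missing;
        ``phased`` - per-entry bool ("|" separator);
        ``haplotypes`` - (n_ind, 2, n_sites) int8 with the written allele
        order (meaningful where phased), -1 for missing alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, poss, cms = [], [], [], []
    phased_cols, hap_cols = [], []
    for v in vcf:
        if len(v.ALT) > 1:
            raise ValueError(
                f"multi-allelic site at {v.CHROM}:{v.POS} not supported; split or filter it first"
            )
        a = np.array([[row[0], row[1]] for row in v.genotypes], dtype=np.int8)
        ph = np.array([bool(row[2]) for row in v.genotypes])
        g = np.where((a < 0).any(axis=1), -1, a.clip(min=0).sum(axis=1)).astype(np.int8)
        rows.append(g)
        phased_cols.append(ph)
        hap_cols.append(a)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        cms.append(np.nan)
    if not rows:
        raise ValueError(f"no records in {path}")
    genotypes = np.stack(rows, axis=1)
    phased = np.stack(phased_cols, axis=1)
    haps = np.stack(hap_cols, axis=2)  # (n_ind, 2, n_sites)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "cm": cms})
    return GenotypeMatrix(genotypes, samples, sites), phased, haps


def write_vcf(
    g: GenotypeMatrix,
    path: str,
    haplotypes: np.ndarray | None = None,
    phased: np.ndarray | bool = True,
) -> None:
    """Write genotypes as VCF 4.2 (REF=A, ALT=G placeholder alleles).

    If ``haplotypes`` (n_ind, 2, n_sites) is given, entries are written
    allele-by-allele with phase taken from ``phased`` (bool scalar or
    per-entry array); otherwise unphased genotypes 0/0, 0/1, 1/1 are
    emitted, with ./. for missing.
    """
    n_ind, n_sites = g.genotypes.shape
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes)
        if haplotypes.shape != (n_ind, 2, n_sites):
            raise ValueError("haplotypes shape must be (n_ind, 2, n_sites)")
    if isinstance(phased, (bool, np.bool_)):
        phased = np.full((n_ind, n_sites), bool(phased))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossmosaic\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = g.sites["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j in range(n_sites):
            chrom = g.sites["chrom"].iloc[j]
            pos = int(g.sites["pos"].iloc[j])
            fields = [str(chrom), str(pos), f"snp{j + 1}", "A", "G", ".", "PASS", ".", "GT"]
            for i in range(n_ind):
                sep = "|" if phased[i, j] else "/"
                if haplotypes is not None:
                    a0, a1 = haplotypes[i, :, j]
                    entry = "./." if (a0 < 0 or a1 < 0) else f"{a0}{sep}{a1}"
                else:
                    gt = g.genotypes[i, j]
                    entry = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}.get(int(gt), "./.")
                fields.append(entry)
            fh.write("\t".join(fields) + "\n")


def write_tracks(track: AncestryTrack, gmap: GeneticMap, path: str) -> None:
    """Write an ancestry track as the TSV sidecar (1-based positions)."""
    n_ind, _, n_sites = track.labels.shape
    if n_sites != gmap.n_sites:
        raise ValueError("track and map site counts differ")
    pools = np.asarray(track.pools + ["NA"], dtype=object)
    # Row layout follows the label array: individual-major, then haplotype,
    # then site.
    recs = {
        "chrom": np.tile(np.concatenate([gmap.chrom, gmap.chrom]).astype(str), n_ind),
        "pos": np.tile(np.concatenate([gmap.pos, gmap.pos]), n_ind),
        "individual": np.repeat(np.asarray(track.samples, dtype=object), 2 * n_sites),
        "hap_index": np.tile(np.repeat([0, 1], n_sites), n_ind),
        "ancestry_label": pools[track.labels.reshape(-1)],
    }
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_tracks(path: str) -> tuple[AncestryTrack, pd.DataFrame]:
    """Read the ancestry-track TSV sidecar.

    Returns the track plus the (chrom, pos) site table in file order.
    Site order follows the first individual's first haplotype.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "individual", "hap_index", "ancestry_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file missing columns: {sorted(required - set(df.columns))}")
    samples = list(dict.fromkeys(df["individual"]))
    first = df[(df["individual"] == samples[0]) & (df["hap_index"] == 0)]
    sites = first[["chrom", "pos"]].reset_index(drop=True)
    n_sites = len(sites)
    pools = sorted(set(df["ancestry_label"]) - {"NA"})
    code = {p: k for k, p in enumerate(pools)}
    code["NA"] = -1
    labels = np.empty((len(samples), 2, n_sites), dtype=np.int16)
    arr = df["ancestry_label"].map(code).to_numpy(dtype=np.int16)
    expected = len(samples) * 2 * n_sites
    if len(arr) != expected:
        raise ValueError("track file is ragged: not every individual covers every site twice")
    labels[:] = arr.reshape(len(samples), 2, n_sites)
    return AncestryTrack(labels, pools, samples), sites
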