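"""Configuration and the end-to-end reproducible pipeline.

A single YAML document declares pools, map, crosses, panels and
imputation scenarios; :func:`run_pipeline` executes
simulate -> ancestry -> heterozygosity -> impute-eval, writes every
artifact under the output directory, and records a manifest with the
seed, package versions, per-stage timings and every file produced.  Two
runs with the same config produce byte-identical TSV/VCF outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    LocalAncestryModel,
    global_from_local,
    infer_local_ancestry,
    supervised_global_ancestry,
)
from .containers import GeneticMap
from .heterozygosity import het_table
from .imputation import ScenarioSpec, run_scenarios
from .simulate import (
    CrossbredCohort,
    CrossSpec,
    define_panels,
    make_ancestral_pools,
    make_cross,
)
from .vcfio import write_tracks, write_vcf

log = logging.getLogger("crossmosaic")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML round-trippable)."""

    seed: int = 0
    log_level: str = "INFO"
    pools: dict = field(
        default_factory=lambda: {
            "names": ["EU", "IND"],
            "n_hap": 60,
            "n_sites": 2000,
            "divergence": 0.25,
            "maf_floor": 0.05,
        }
    )
    map: dict = field(default_factory=lambda: {"length_cm": 100.0, "n_chrom": 1})
    crosses: list = field(default_factory=list)
    panels: dict = field(
        default_factory=lambda: {"fractions": [0.02, 0.1, 1.0], "missing_rates": [0.0, 0.0, 0.0]}
    )
    scenarios: list = field(default_factory=list)
    ancestry: dict = field(default_factory=lambda: {"run": False, "scheme": "two_way"})

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def cross_specs(self) -> list[CrossSpec]:
        specs = []
        for entry in self.crosses:
            e = dict(entry)
            kind = e.pop("type")
            n = int(e.pop("n"))
            label = e.pop("label", None)
            pools = e.pop("pools", [])
            seed = int(e.pop("seed", self.seed))
            if kind == "pure":
                spec = CrossSpec.pure(pools[0], n, seed)
            elif kind == "f1":
                spec = CrossSpec.f1(pools[0], pools[1], n, seed)
            elif kind == "f2":
                spec = CrossSpec.f2(pools[0], pools[1], n, seed)
            elif kind == "bc1":
                spec = CrossSpec.bc1(pools[0], pools[1], n, seed, recurrent=e.pop("recurrent", None))
            elif kind == "inter_se":
                spec = CrossSpec.inter_se(e.pop("recipe"), n, seed)
            elif kind == "three_way":
                spec = CrossSpec.three_way(pools[0], pools[1], pools[2], n, seed)
            elif kind == "custom":
                spec = CrossSpec(label or "custom", e.pop("sire"), e.pop("dam"), n, seed)
            else:
                raise ValueError(f"unknown cross type {kind!r}")
            if label:
                spec.label = label
            specs.append(spec)
        return specs

    def scenario_specs(self) -> list[ScenarioSpec]:
        return [ScenarioSpec(**s) for s in self.scenarios]

    def validate(self) -> None:
        """Fail before any computation if a scenario names a missing cohort."""
        labels = {s.label for s in self.cross_specs()}
        for s in self.scenario_specs():
            for name in [s.target, *s.reference]:
                if name not in labels:
                    raise ValueError(
                        f"scenario {s.name!r} references undeclared cohort {name!r}"
                    )


def _write_sites(gmap: GeneticMap, path: Path) -> None:
    gmap.site_table().to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute all configured stages; return (and write) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "versions": {
            "crossmosaic": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "files": [],
    }

    def record(path: Path) -> None:
        manifest["files"].append(str(path.relative_to(out)))

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    pcfg = dict(config.pools)
    names = pcfg.pop("names")
    gmap_kw = dict(config.map)
    pools, gmap = make_ancestral_pools(
        n_pools=len(names),
        n_hap=int(pcfg.get("n_hap", 60)),
        n_sites=int(pcfg.get("n_sites", 2000)),
        divergence=pcfg.get("divergence", 0.25),
        maf_floor=float(pcfg.get("maf_floor", 0.05)),
        map_length_cm=float(gmap_kw.get("length_cm", 100.0)),
        n_chrom=int(gmap_kw.get("n_chrom", 1)),
        seed=config.seed,
        names=names,
    )
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    _write_sites(gmap, sim_dir / "sites.tsv")
    record(sim_dir / "sites.tsv")
    cohorts: dict[str, CrossbredCohort] = {}
    for spec in config.cross_specs():
        cohort = make_cross(spec, pools, gmap)
        cohorts[spec.label] = cohort
        vcf_path = sim_dir / f"{spec.label}.vcf"
        write_vcf(cohort.genotypes, str(vcf_path), haplotypes=cohort.haplotypes)
        track_path = sim_dir / f"{spec.label}.tracks.tsv"
        write_tracks(cohort.truth, gmap, str(track_path))
        record(vcf_path)
        record(track_path)
        log.info("simulated cohort %s (%d individuals)", spec.label, cohort.n_individuals)
    manifest["stages"]["simulate"] = round(time.perf_counter() - t0, 3)

    # --- ancestry ---------------------------------------------------------
    inferred_tracks: dict[str, object] = {}
    if config.ancestry.get("run", False) and cohorts:
        t0 = time.perf_counter()
        anc_dir = out / "ancestry"
        anc_dir.mkdir(exist_ok=True)
        pool_freqs = pd.DataFrame({p.name: p.allele_freqs for p in pools})
        model = LocalAncestryModel()
        for label, cohort in cohorts.items():
            q = supervised_global_ancestry(cohort.genotypes, pool_freqs)
            q.rename_axis("individual").to_csv(anc_dir / f"{label}.supervised.tsv", sep="\t")
            record(anc_dir / f"{label}.supervised.tsv")
            track = infer_local_ancestry(cohort.haplotypes, pools, model, gmap)
            track.samples = list(cohort.samples)
            inferred_tracks[label] = track
            global_from_local(track).rename_axis("individual").to_csv(
                anc_dir / f"{label}.local_proportions.tsv", sep="\t"
            )
            record(anc_dir / f"{label}.local_proportions.tsv")
            write_tracks(track, gmap, str(anc_dir / f"{label}.inferred_tracks.tsv"))
            record(anc_dir / f"{label}.inferred_tracks.tsv")
        manifest["stages"]["ancestry"] = round(time.perf_counter() - t0, 3)

    # --- heterozygosity ---------------------------------------------------
    if cohorts:
        t0 = time.perf_counter()
        het_dir = out / "het"
        het_dir.mkdir(exist_ok=True)
        scheme = config.ancestry.get("scheme", "two_way")
        eu = config.ancestry.get("european_pool")
        for label, cohort in cohorts.items():
            track = inferred_tracks.get(label, cohort.truth)
            tab = het_table(cohort.genotypes, track, scheme=scheme, european_pool=eu)
            tab.to_csv(het_dir / f"{label}.het.tsv", sep="\t", index=False)
            record(het_dir / f"{label}.het.tsv")
        manifest["stages"]["het"] = round(time.perf_counter() - t0, 3)

    # --- impute-eval ------------------------------------------------------
    if config.scenarios:
        t0 = time.perf_counter()
        imp_dir = out / "impute_eval"
        imp_dir.mkdir(exist_ok=True)
        pans = define_panels(
            gmap.n_sites,
            tuple(config.panels.get("fractions", (0.02, 0.1, 1.0))),
            seed=config.seed,
            missing_rates=tuple(config.panels.get("missing_rates", (0.0, 0.0, 0.0))),
        )
        panel_map = {p.name: p for p in pans}
        reports = run_scenarios(
            config.scenario_specs(), cohorts, panel_map, seed=config.seed
        )
        summaries = [r.summary() for r in reports]
        with open(imp_dir / "accuracy.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        record(imp_dir / "accuracy.json")
        for r in reports:
            r.maf_table.to_csv(imp_dir / f"{r.scenario}.maf_bins.tsv", sep="\t", index=False)
            r.per_site.to_csv(imp_dir / f"{r.scenario}.per_site.tsv", sep="\t", index=False)
            record(imp_dir / f"{r.scenario}.maf_bins.tsv")
            record(imp_dir / f"{r.scenario}.per_site.tsv")
        manifest["stages"]["impute_eval"] = round(time.perf_counter() - t0, 3)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
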