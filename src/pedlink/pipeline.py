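"""End-to-end pipeline: simulate -> QC -> linkage -> WES filter -> gene-set
association -> validation.

The orchestrator runs the stage sequence used in family-based gene
discovery: genome-wide multipoint linkage per family and for family
combinations, rare-variant filtering inside the (padded) linkage regions,
per-family candidate gene sets, gene-based/gene-set association with
meta-analysis in independent case-control cohorts, then co-segregation and
GO-style enrichment summaries.  Reports are written as TSV files; a
failing stage aborts with its name while partial outputs are kept.
"""

from __future__ import annotations

import itertools
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (bonferroni_lookup, cohort_gene_stats, gene_set_tests,
                    meta_gene_table)
from .io import write_gmt, write_ped_map
from .linkage import (combine_curves, lod_multipoint, regions_frame,
                      select_regions)
from .qc import QCConfig, apply_qc
from .simulate import (CohortPanelSpec, CohortSpec, MarkerSpec,
                       PedigreeTemplate, SimConfig, WESSpec,
                       build_cohort_panel, build_marker_panel,
                       gene_drop_genotypes, simulate_cohorts,
                       simulate_pedigree, simulate_wes_calls)
from .types import AFFECTED, DiseaseModel, GenotypeTable, Individual, Pedigree
from .validate import carrier_summary, hypergeom_enrichment
from .wes import build_family_gene_sets, expand_and_intersect, filter_shared_rare

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "linkage", "wes", "assoc", "validate")


class ConfigError(ValueError):
    """Pipeline configuration invalid; raised before any computation."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full synthetic run.

    ``n_set_genes`` genes are planted in the driving (first) family's
    linkage region and given a liability effect in the cohorts, so the
    family's candidate gene set carries true signal.
    """

    seed: int
    n_families: int = 2
    template: PedigreeTemplate = PedigreeTemplate()
    markers: MarkerSpec = MarkerSpec()
    disease: DiseaseModel = field(default_factory=DiseaseModel.dominant)
    planted_chrom: int = 1
    planted_marker: int = 17
    min_affected: int = 8
    unknown_fraction: float = 0.10
    run_qc: bool = True
    qc: QCConfig = QCConfig()
    window_size: int = 10
    lod_threshold: float = 2.0
    n_set_genes: int = 3            # genes planted per family region
    effect_beta: float = 0.08       # liability effect per planted SNP
    wes: WESSpec = WESSpec()
    cohorts: tuple[CohortSpec, ...] = (CohortSpec("A", 300, 500),
                                       CohortSpec("B", 250, 450))
    cohort_panel: CohortPanelSpec = CohortPanelSpec(n_genes=120)
    wes_min_depth: int = 20
    wes_maf_ceiling: float = 0.01
    region_pad: int = 1_000_000
    assume_novel: bool = True
    background_size: int = 19_264
    n_go_sets: int = 40
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "assoc" in self.stages and not self.cohorts:
            raise ConfigError("association requested but no cohort data configured")
        if "wes" in self.stages and "linkage" not in self.stages:
            raise ConfigError("WES filtering requires the linkage stage")
        if self.n_set_genes * self.n_families > self.cohort_panel.n_genes:
            raise ConfigError("not enough cohort genes for the planted sets")


def small_config(seed: int) -> PipelineConfig:
    """A fast, small-scale configuration for smoke tests and examples."""
    return PipelineConfig(
        seed=seed,
        n_families=2,
        template=PedigreeTemplate(n_children=4, n_married=3,
                                  grandchildren=(1, 1, 1)),
        markers=MarkerSpec(n_chromosomes=1, markers_per_chromosome=20,
                           spacing_cm=3.0),
        planted_marker=9,
        min_affected=6,
        cohorts=(CohortSpec("A", 120, 200), CohortSpec("B", 100, 180)),
        cohort_panel=CohortPanelSpec(n_genes=40, max_snps_per_gene=6),
        n_set_genes=2,
        effect_beta=0.15,
        n_go_sets=15,
        # a 12-member family cannot reach LOD 2, and pruning at the full
        # 0.01 ceiling with so few samples strips nearly every marker;
        # both knobs are relaxed in proportion to this miniature's size
        lod_threshold=1.0,
        qc=QCConfig(prune_r2_ceiling=0.3),
    )


@dataclass
class PipelineResult:
    families: dict
    panel: object = None
    curves: dict = field(default_factory=dict)
    regions: list = field(default_factory=list)
    wes_variants: dict = field(default_factory=dict)
    gene_sets: dict = field(default_factory=dict)
    union_genes: list = field(default_factory=list)
    missing_in_cohort: list = field(default_factory=list)
    cohorts: list = field(default_factory=list)
    meta_table: pd.DataFrame | None = None
    set_results: pd.DataFrame | None = None
    bonferroni: dict | None = None
    segregation: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    qc_reports: dict = field(default_factory=dict)


def _family_sim_config(cfg: PipelineConfig, k: int,
                       region_genes: tuple[str, ...]) -> SimConfig:
    return SimConfig(
        seed=int(cfg.seed + 7919 * (k + 1)),
        template=cfg.template,
        markers=cfg.markers,
        disease=cfg.disease,
        planted_chrom=cfg.planted_chrom,
        planted_marker=cfg.planted_marker,
        min_affected=cfg.min_affected,
        unknown_fraction=cfg.unknown_fraction,
        wes=replace(cfg.wes, region_genes=region_genes),
        cohorts=cfg.cohorts,
        cohort_panel=cfg.cohort_panel,
    )


def _pick_sequenced(fam) -> list[str]:
    """Two affected members, preferring distant generations."""
    affected = fam.pedigree.affected_members()
    gen3 = [i for i in affected if i.startswith("G")]
    gen2 = [i for i in affected if i.startswith("C")]
    picks = (gen3[:1] + gen2[:1] + affected)
    out = list(dict.fromkeys(picks))[:2]
    if len(out) < 2:
        out = affected[:2]
    return out


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the configured stages and write TSV reports to ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 99])
    result = PipelineResult(families={})
    logf = outdir / "pipeline_log.txt"
    log_lines = [f"pedlink {__version__} python {platform.python_version()}",
                 f"seed {config.seed}", f"stages {','.join(config.stages)}"]

    cohort_panel = build_cohort_panel(config.cohort_panel,
                                      np.random.default_rng([config.seed, 14]))
    cohort_genes = list(dict.fromkeys(cohort_panel["gene"]))
    fam_labels = [f"P{k + 1}" for k in range(config.n_families)]
    planted = {lab: tuple(cohort_genes[k * config.n_set_genes:
                                       (k + 1) * config.n_set_genes])
               for k, lab in enumerate(fam_labels)}

    def stage(name):
        return name in config.stages

    try:
        # ---------------- simulate ----------------
        panel = build_marker_panel(config.markers,
                                   np.random.default_rng([config.seed, 10]))
        panel_full = panel  # pre-QC map; keeps the true locus position
        result.panel = panel
        for k, lab in enumerate(fam_labels):
            sim = _family_sim_config(config, k, planted[lab])
            fam = simulate_pedigree(sim)
            fam.pedigree.family_id = lab
            table = gene_drop_genotypes(fam, panel, sim)
            result.families[lab] = {"sim": sim, "fam": fam, "table": table}
            fam.truth_frame().to_csv(outdir / f"truth_{lab}.tsv", sep="\t",
                                     index=False)
            write_ped_map(fam.pedigree, panel, table,
                          outdir / f"{lab}.ped", outdir / f"{lab}.map")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    if stage("qc"):
        try:
            # families share one genotyping panel, so QC runs on the pooled
            # sample: individuals are prefixed with their family label and
            # the disjoint pedigrees are merged for the Mendel checks
            merged_inds, merged_ids, blocks = [], [], []
            for lab, entry in result.families.items():
                ped_f = entry["fam"].pedigree
                for iid in ped_f.members:
                    ind = ped_f[iid]
                    merged_inds.append(Individual(
                        f"{lab}:{iid}",
                        f"{lab}:{ind.father}" if ind.father else None,
                        f"{lab}:{ind.mother}" if ind.mother else None,
                        ind.sex, ind.affection))
                merged_ids.extend(f"{lab}:{i}" for i in entry["table"].ids)
                blocks.append(entry["table"].alleles)
            merged_ped = Pedigree(merged_inds, family_id="ALL")
            merged = GenotypeTable(merged_ids, panel.markers,
                                   np.concatenate(blocks, axis=0))
            qc_res = apply_qc(merged_ped, panel, merged, config.qc)
            result.qc_reports["ALL"] = qc_res.marker_report
            qc_res.marker_report.to_csv(outdir / "qc_report.tsv", sep="\t",
                                        index=False)
            keep = qc_res.panel.markers
            panel = qc_res.panel
            for lab, entry in result.families.items():
                ids = [f"{lab}:{i}" for i in entry["fam"].pedigree.members]
                sub = qc_res.table.subset_individuals(ids)
                entry["table"] = GenotypeTable(
                    entry["fam"].pedigree.members, keep, sub.alleles)
            result.panel = panel
            log_lines.append(f"qc retained {len(keep)} markers")
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", exc) from exc

    if stage("linkage"):
        try:
            per_family = {}
            for lab, entry in result.families.items():
                curves = {}
                for chrom in panel.chromosomes():
                    curves[chrom] = lod_multipoint(
                        entry["fam"].pedigree, panel, entry["table"],
                        config.disease, chrom=chrom,
                        window_size=config.window_size, label=lab)
                per_family[lab] = curves
            all_curves = []
            for lab, curves in per_family.items():
                all_curves.extend(curves.values())
            for r in range(2, len(fam_labels) + 1):
                for combo in itertools.combinations(fam_labels, r):
                    for chrom in panel.chromosomes():
                        all_curves.append(combine_curves(
                            [per_family[lab][chrom] for lab in combo],
                            label="+".join(combo)))
            result.curves = {(c.label, c.chrom): c for c in all_curves}
            result.regions = select_regions(all_curves, config.lod_threshold)
            curve_rows = []
            for c in all_curves:
                for bp, cm, lod in zip(c.bp, c.cm, c.lod):
                    curve_rows.append({"families": c.label, "chrom": c.chrom,
                                       "bp": int(bp), "cm": cm, "lod": lod})
            pd.DataFrame(curve_rows).to_csv(outdir / "lod_curves.tsv", sep="\t",
                                            index=False)
            regions_frame(result.regions).to_csv(outdir / "regions.tsv",
                                                 sep="\t", index=False)
            log_lines.append(f"linkage selected {len(result.regions)} regions")
        except Exception as exc:  # noqa: BLE001
            raise StageError("linkage", exc) from exc

    if stage("wes"):
        try:
            per_family_variants = {}
            for lab, entry in result.families.items():
                sequenced = _pick_sequenced(entry["fam"])
                calls = simulate_wes_calls(entry["fam"], sequenced,
                                           entry["sim"], panel_full)
                shared = filter_shared_rare(
                    calls, sequenced, min_depth=config.wes_min_depth,
                    maf_ceiling=config.wes_maf_ceiling,
                    assume_novel=config.assume_novel)
                in_region = expand_and_intersect(shared, result.regions, lab,
                                                 pad=config.region_pad)
                per_family_variants[lab] = in_region
                result.wes_variants[lab] = in_region
                in_region.to_csv(outdir / f"wes_candidates_{lab}.tsv",
                                 sep="\t", index=False)
            sets, union, missing = build_family_gene_sets(
                per_family_variants, set(cohort_genes))
            result.gene_sets = sets
            result.union_genes = union
            result.missing_in_cohort = missing
            gmt = {f"family_{lab}": fgs.gene_names
                   for lab, fgs in sets.items() if fgs.gene_names}
            if union:
                gmt["union"] = union
            if gmt:
                write_gmt(gmt, outdir / "gene_sets.gmt")
            log_lines.append(f"wes union gene set: {len(union)} genes")
        except Exception as exc:  # noqa: BLE001
            raise StageError("wes", exc) from exc

    if stage("assoc"):
        try:
            sim0 = next(iter(result.families.values()))["sim"]
            assoc_cfg = replace(
                sim0, seed=int(config.seed),
                effect_genes={g: config.effect_beta
                              for gs in planted.values() for g in gs})
            cohorts = simulate_cohorts(assoc_cfg, panel=cohort_panel)
            result.cohorts = cohorts
            per_cohort = {c.name: cohort_gene_stats(c.dosage, c.is_case,
                                                    c.snps, cohort=c.name)
                          for c in cohorts}
            sizes = {c.name: c.n for c in cohorts}
            meta = meta_gene_table(per_cohort, sizes)
            result.meta_table = meta
            meta.sort_values("p_meta").to_csv(outdir / "gene_assoc.tsv",
                                              sep="\t", index=False)
            set_rows = []
            candidates = {"union": result.union_genes or
                          [g for gs in planted.values() for g in gs]}
            for lab in fam_labels:
                genes = (result.gene_sets[lab].gene_names
                         if result.gene_sets else list(planted[lab]))
                candidates[lab] = genes
            for name, genes in candidates.items():
                present = meta[meta["gene"].isin(genes)]
                if len(present) < 2:
                    log.warning("set %s has <2 genes with cohort data", name)
                    continue
                res = gene_set_tests(meta, genes)
                res["set"] = name
                set_rows.append(res)
            result.set_results = pd.DataFrame(set_rows)
            result.set_results.to_csv(outdir / "geneset_tests.tsv", sep="\t",
                                      index=False)
            # gene-based lookup in the driving family's set
            lead = fam_labels[0]
            lead_genes = candidates.get(lead, [])
            ps = {r["gene"]: r["p_meta"] for _, r in meta.iterrows()
                  if r["gene"] in lead_genes}
            if ps:
                threshold, calls = bonferroni_lookup(ps)
                result.bonferroni = {"threshold": threshold, "calls": calls}
                pd.DataFrame([{"gene": g, "p_meta": ps[g], "significant": c}
                              for g, c in calls.items()]).to_csv(
                    outdir / "gene_lookup.tsv", sep="\t", index=False)
            log_lines.append("assoc done")
        except Exception as exc:  # noqa: BLE001
            raise StageError("assoc", exc) from exc

    if stage("validate"):
        try:
            lead = fam_labels[0]
            entry = result.families[lead]
            fam = entry["fam"]
            genotyped = fam.pedigree.members
            carriers_set = {i for i, c in fam.carrier_counts().items() if c > 0}
            variants = result.wes_variants.get(lead)
            labels = ([f"{r['chrom']}:{r['pos']}{r['ref']}>{r['alt']}"
                       for _, r in variants.iterrows()][:2]
                      if variants is not None and len(variants) else ["locus"])
            seg = carrier_summary(fam.pedigree,
                                  {lab: carriers_set for lab in labels},
                                  genotyped)
            result.segregation = seg.table
            seg.table.to_csv(outdir / "segregation.tsv", sep="\t", index=False)

            query = result.union_genes or [g for gs in planted.values()
                                           for g in gs]
            collection = _synthetic_go_collection(
                cohort_genes, query, config.n_go_sets, rng)
            enr = hypergeom_enrichment(query, collection,
                                       background_size=config.background_size)
            result.enrichment = enr
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            log_lines.append("validate done")
        except Exception as exc:  # noqa: BLE001
            raise StageError("validate", exc) from exc

    logf.write_text("\n".join(log_lines) + "\n")
    return result


def _synthetic_go_collection(universe: list[str], query: list[str],
                             n_sets: int, rng) -> dict[str, list[str]]:
    """A GO-like collection: random sets plus one enriched in the query."""
    collection = {}
    for k in range(n_sets):
        size = int(rng.integers(5, max(6, len(universe) // 4)))
        genes = list(rng.choice(universe, size=min(size, len(universe)),
                                replace=False))
        collection[f"GO_SET_{k + 1:03d}"] = genes
    if query:
        extra = [g for g in universe if g not in query]
        pad = list(rng.choice(extra, size=min(5, len(extra)), replace=False))
        collection["GO_QUERY_RELATED"] = list(query) + pad
    return collection
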