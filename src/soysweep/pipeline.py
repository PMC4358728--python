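"""End-to-end orchestration of the domestication-genomics analysis.

Sequences the stages — simulate (or load) genotypes, consensus assignment,
windowed diversity, the two sweep scans, fixation detection and coding
classification, population structure, and QTL narrowing with enrichment —
writes every stage table, and returns a serializable run report. All
randomness flows from the config seeds, so a rerun with an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, fixation, qtl, scan, structure
from .genotype import (
    GenotypeMatrix,
    assign_ml_genotypes,
    read_manifest,
    read_vcf,
    subset_population,
)
from .simulate import SimConfig, SimResult, simulate_populations, write_fixtures

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; either a simulation or input paths."""

    sim: SimConfig | None = None
    vcf: str | None = None
    manifest: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    qtl_bed: str | None = None
    categories: str | None = None
    out_dir: str = "soysweep_out"
    window: int = diversity.DEFAULT_WINDOW
    step: int = diversity.DEFAULT_STEP
    alpha: float = 0.05
    alpha_pbs_corrected: float = 0.001
    exclude_samples: list[str] = field(default_factory=list)
    fst_estimator: str = "hudson"
    bootstrap_reps: int = 100  # scaled-down default; raise to 1000 for full runs
    rarefaction_reps: int = 50
    permutation_reps: int = 1000
    seed: int = 0


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Aggregate all config problems instead of failing on the first."""
    errors: list[str] = []
    if cfg.step <= 0 or cfg.window < cfg.step:
        errors.append(f"require window >= step > 0, got {cfg.window}/{cfg.step}")
    for name, val in (("alpha", cfg.alpha), ("alpha_pbs_corrected", cfg.alpha_pbs_corrected)):
        if not (0.0 < val < 1.0):
            errors.append(f"{name} = {val} outside (0, 1)")
    if cfg.sim is None and (cfg.vcf is None or cfg.manifest is None):
        errors.append("need either a simulation config or vcf + manifest paths")
    if cfg.fst_estimator not in ("hudson", "weir_cockerham"):
        errors.append(f"unknown fst estimator {cfg.fst_estimator!r}")
    if cfg.bootstrap_reps < 1:
        errors.append("bootstrap_reps must be >= 1")
    if cfg.sim is not None:
        try:
            cfg.sim.validate()
        except ValueError as e:
            errors.append(str(e))
    return errors


@dataclass
class RunReport:
    """Per-stage record counts and summary numbers for one run."""

    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    diversity_reduction: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={"seed": cfg.seed, "window": cfg.window, "step": cfg.step})

    # ---- stage: inputs ----------------------------------------------------
    sim_result: SimResult | None = None
    if cfg.sim is not None:
        sim_result = simulate_populations(cfg.sim)
        fixture_paths = write_fixtures(sim_result, out / "fixtures")
        gm = sim_result.matrix
        gl = sim_result.likelihoods
        manifest = sim_result.manifest
        gff3 = str(fixture_paths["gff3"])
        fasta = str(fixture_paths["fasta"])
        qtl_bed = str(fixture_paths["qtl_bed"])
        categories_path = str(fixture_paths["categories"])
        chrom_lengths = cfg.sim.chrom_lengths()
    else:
        gm, gl, n_skipped = read_vcf(cfg.vcf)
        if n_skipped:
            report.warnings.append(f"read_vcf skipped {n_skipped} non-SNV record(s)")
        manifest = read_manifest(cfg.manifest)
        gff3, fasta = cfg.gff3, cfg.fasta
        qtl_bed, categories_path = cfg.qtl_bed, cfg.categories
        chrom_lengths = {
            str(c): int(gm.pos[gm.chrom.astype(str) == c].max())
            for c in dict.fromkeys(gm.chrom.astype(str))
        }
    manifest.validate_against(gm)
    report.counts["samples"] = gm.n_samples
    report.counts["snvs"] = gm.n_sites

    # ---- stage: consensus genotypes --------------------------------------
    if gl is not None:
        ml = assign_ml_genotypes(gl)
        consensus = ml.matrix
        report.counts["ml_ties"] = ml.n_ties
        report.counts["ml_uninformative"] = ml.n_uninformative
    else:
        consensus = gm
        report.warnings.append("no genotype likelihoods; using input calls as consensus")

    windows = diversity.sliding_windows(chrom_lengths, cfg.window, cfg.step)
    report.counts["windows"] = len(windows)
    total_span = sum(chrom_lengths.values())

    # ---- stage: diversity -------------------------------------------------
    pis = {}
    for group in ("wild", "landrace", "elite", "cultivated"):
        try:
            sub = subset_population(gm, manifest, group)
        except ValueError:
            report.warnings.append(f"group {group!r} empty; diversity skipped")
            continue
        stats = diversity.window_stats(sub, windows)
        stats.to_csv(out / f"diversity_{group}.tsv", sep="\t", index=False)
        pis[group] = diversity.mean_theta_pi(sub, total_span)
    if set(pis) == {"wild", "landrace", "elite", "cultivated"}:
        report.diversity_reduction = scan.diversity_reduction_summary(
            pis["wild"], pis["landrace"], pis["elite"], pis["cultivated"]
        )
        report.diversity_reduction.update({f"theta_pi_{k}": v for k, v in pis.items()})

    # ---- stage: rarefaction ----------------------------------------------
    for group in ("wild", "cultivated"):
        n_group = len(manifest.samples_for(group))
        if n_group == 0:
            continue
        ks = sorted(set(np.linspace(1, n_group, min(n_group, 10)).astype(int)))
        curve = diversity.snv_accumulation(
            gm, manifest, group, ks, reps=cfg.rarefaction_reps, seed=cfg.seed
        )
        curve.to_csv(out / f"rarefaction_{group}.tsv", sep="\t", index=False)

    # ---- stage: sweep scans -----------------------------------------------
    regions_dom: list[scan.SweepRegion] = []
    regions_imp: list[scan.SweepRegion] = []
    dom = scan.domestication_scan(
        gm, manifest, windows, alpha=cfg.alpha, exclude_samples=cfg.exclude_samples
    )
    dom.to_csv(out / "scan_domestication.tsv", sep="\t", index=False)
    regions_dom = scan.merge_windows(dom, "domestication")
    try:
        imp = scan.improvement_scan(
            gm, manifest, windows,
            alpha_corrected=cfg.alpha_pbs_corrected,
            exclude_samples=cfg.exclude_samples,
            estimator=cfg.fst_estimator,
        )
        imp.to_csv(out / "scan_improvement.tsv", sep="\t", index=False)
        regions_imp = scan.merge_windows(imp, "improvement")
    except ValueError as e:
        report.warnings.append(f"improvement scan skipped: {e}")
    all_regions = regions_dom + regions_imp
    scan.regions_to_bed(all_regions).to_csv(
        out / "sweep_regions.bed", sep="\t", index=False, header=False
    )
    report.counts["regions_domestication"] = len(regions_dom)
    report.counts["regions_improvement"] = len(regions_imp)
    report.counts["swept_mb_domestication"] = sum(r.span for r in regions_dom) / 1e6
    report.counts["swept_mb_improvement"] = sum(r.span for r in regions_imp) / 1e6

    # ---- stage: fixation --------------------------------------------------
    complete = np.all(consensus.calls >= 0, axis=0)
    if not complete.all():
        report.warnings.append(
            f"{int((~complete).sum())} site(s) with missing consensus calls "
            "excluded from fixation screening"
        )
        consensus = consensus.take_sites(complete)
    loci = fixation.detect_fixations(
        consensus, manifest, "cultivated", "wild", regions=all_regions
    )
    loci_wild = fixation.detect_fixations(
        consensus, manifest, "wild", "cultivated", regions=all_regions
    )
    if gff3 and fasta:
        from pyfaidx import Fasta

        genome = Fasta(fasta)
        models = fixation.read_gene_models(gff3)
        fixation.classify_loci(loci, models, genome)
        fixation.classify_loci(loci_wild, models, genome)
    table = fixation.loci_to_table(loci)
    table.to_csv(out / "fixations_cultivated.tsv", sep="\t", index=False)
    fixation.loci_to_table(loci_wild).to_csv(
        out / "fixations_wild.tsv", sep="\t", index=False
    )
    report.counts["fixations_cultivated"] = len(loci)
    report.counts["fixations_cultivated_in_sweep"] = int(table["in_sweep"].sum()) if len(table) else 0
    report.counts["fixations_wild"] = len(loci_wild)
    if len(table):
        report.counts["fixations_nonsynonymous"] = int((table["effect"] == "nonsynonymous").sum())
        report.counts["fixations_synonymous"] = int((table["effect"] == "synonymous").sum())

    density_windows = diversity.sliding_windows(chrom_lengths, cfg.window, cfg.window)
    density = fixation.fixation_density(loci, all_regions, density_windows)
    density.to_csv(out / "fixation_density.tsv", sep="\t", index=False)
    spectrum = fixation.wild_frequency_of_fixed(gm, manifest, loci)
    pd.DataFrame({"alt_count": np.arange(len(spectrum)), "n_sites": spectrum}).to_csv(
        out / "fixed_sfs_wild.tsv", sep="\t", index=False
    )

    # ---- stage: structure ---------------------------------------------—--
    struct_gm = _thin_sites(gm, max_sites=5000, seed=cfg.seed)
    coords, evr = structure.pca(struct_gm, n_components=5)
    pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    ).assign(sample=gm.samples, population=[manifest.labels[s] for s in gm.samples]).to_csv(
        out / "pca.tsv", sep="\t", index=False
    )
    (out / "pca_explained_variance.tsv").write_text(
        "\n".join(f"PC{i + 1}\t{v:.6f}" for i, v in enumerate(evr)) + "\n"
    )
    dm = structure.pairwise_distance(struct_gm)
    (out / "distances.phylip").write_text(dm.to_phylip())
    tree = structure.bootstrap_support(struct_gm, reps=cfg.bootstrap_reps, seed=cfg.seed)
    (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    report.counts["bootstrap_reps"] = cfg.bootstrap_reps

    # ---- stage: QTL + enrichment -----------------------------------------
    if qtl_bed and categories_path:
        qtls = qtl.read_qtl_bed(qtl_bed)
        has_fix = {
            (r.chrom, r.start, r.end): any(
                l.chrom == r.chrom and r.start + 1 <= l.pos <= r.end for l in loci
            )
            for r in all_regions
        }
        narrowed, summary = qtl.narrow_qtl(qtls, all_regions, has_fix)
        narrowed.to_csv(out / "qtl_narrowed.tsv", sep="\t", index=False)
        report.counts.update({f"qtl_{k}": v for k, v in summary.items()})

        categories = qtl.read_gene_categories(categories_path)
        if gff3:
            models = fixation.read_gene_models(gff3)
            spans = {
                m.gene_id: (m.chrom, min(s for s, e, _ in m.cds) - 1, max(e for s, e, _ in m.cds))
                for m in fixation.longest_transcript_per_gene(models)
            }
            background = set(spans)
            selected = qtl.genes_in_intervals(
                spans, [(r.chrom, r.start, r.end) for r in all_regions]
            )
            if selected:
                enr = qtl.fisher_enrichment(selected, background, categories)
                perm = qtl.permutation_enrichment(
                    selected, background, categories,
                    reps=cfg.permutation_reps, seed=cfg.seed,
                )
                enr = enr.merge(perm[["category", "p_perm"]], on="category", how="left")
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                report.counts["selected_genes"] = len(selected)
                report.counts["enrichment_categories"] = len(enr)

    # ---- truth-based recovery (simulation runs only) ----------------------
    if sim_result is not None and sim_result.truth.swept_regions:
        report.counts["sweep_recovery"] = sweep_recovery(
            sim_result.truth.swept_regions, all_regions
        )
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _thin_sites(gm: GenotypeMatrix, max_sites: int, seed: int) -> GenotypeMatrix:
    """Deterministic even thinning of sites for the structure stage."""
    if gm.n_sites <= max_sites:
        return gm
    idx = np.linspace(0, gm.n_sites - 1, max_sites).astype(int)
    return gm.take_sites(np.unique(idx))


def sweep_recovery(
    truth_regions, called_regions, by_transition: bool = True
) -> dict[str, float]:
    """Fraction of injected sweeps overlapped by a called region."""
    out: dict[str, float] = {}
    transitions = (
        sorted({t.transition for t in truth_regions}) if by_transition else [None]
    )
    for trans in transitions:
        truths = [t for t in truth_regions if trans is None or t.transition == trans]
        calls = [c for c in called_regions if trans is None or c.transition == trans]
        hit = sum(
            any(c.chrom == t.chrom and c.start < t.end and t.start < c.end for c in calls)
            for t in truths
        )
        key = trans or "all"
        out[key] = hit / len(truths) if truths else float("nan")
    return out
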