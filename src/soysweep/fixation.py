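"""Nucleotide-fixation loci and their coding consequences.

A nucleotide fixation locus is a SNV with a single (unique) genotype
across every individual of one population group while the comparison
group shows at least two distinct genotypes. Detection runs on consensus
matrices with no missing calls — build them with
:func:`soysweep.genotype.assign_ml_genotypes` first.

Loci are localized to sweep regions versus genome background, their
pre-domestication state is summarized as the wild-population frequency
spectrum, and coding consequences (synonymous / non-synonymous) are
classified from GFF3 gene models and the genome sequence, strand- and
phase-aware, using the standard nuclear code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import diversity
from .genotype import GenotypeMatrix, PopulationManifest, allele_counts_all, subset_population
from .scan import SweepRegion

logger = logging.getLogger(__name__)

EFFECTS = ("noncoding", "synonymous", "nonsynonymous", "unclassified")


@dataclass
class FixationLocus:
    """A site fixed in one population group and polymorphic in another."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    fixed_population: str
    fixed_genotype: int
    other_population: str
    in_sweep: bool = False
    region_id: str | None = None
    wild_alt_freq: float | None = None
    effect: str = "unclassified"
    gene_id: str | None = None


@dataclass
class GeneModel:
    """One transcript's CDS: 1-based inclusive segments with phase."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def ordered_cds(self) -> list[tuple[int, int, int]]:
        """Segments in transcription (5'→3') order."""
        segs = sorted(self.cds)
        return segs if self.strand == "+" else list(reversed(segs))


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse CDS gene models from GFF3 (in-memory gffutils db)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        cds = [
            (c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
            for c in db.children(mrna, featuretype="CDS")
        ]
        if not cds:
            continue
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds=sorted(cds),
            )
        )
    return models


def longest_transcript_per_gene(models: Sequence[GeneModel]) -> list[GeneModel]:
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or m.cds_length > cur.cds_length:
            best[m.gene_id] = m
    return list(best.values())


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_fixations(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    focal_group: str,
    other_group: str,
    regions: Sequence[SweepRegion] | None = None,
    wild_group: str = "wild",
) -> list[FixationLocus]:
    """Sites with a unique genotype in ``focal_group`` and ≥2 genotypes in
    ``other_group``.

    Requires a consensus matrix (no missing calls). When sweep ``regions``
    are given each locus is annotated with its region; when the matrix
    contains wild samples the wild alternate-allele frequency is recorded.
    """
    if np.any(gm.calls < 0):
        raise ValueError(
            "matrix contains missing calls; run assign_ml_genotypes to build "
            "a consensus matrix first"
        )
    focal = subset_population(gm, manifest, focal_group)
    other = subset_population(gm, manifest, other_group)
    focal_uniform = np.all(focal.calls == focal.calls[0:1, :], axis=0)
    other_poly = ~np.all(other.calls == other.calls[0:1, :], axis=0)
    hits = np.flatnonzero(focal_uniform & other_poly)

    n_uniform_het = int(np.sum(focal.calls[0, hits] == 1))
    if n_uniform_het:
        logger.warning(
            "detect_fixations: %d locus/loci fixed as uniform heterozygote "
            "(biologically implausible; kept)", n_uniform_het
        )

    wild_freq = None
    try:
        wild = subset_population(gm, manifest, wild_group)
        n_w, alt_w = allele_counts_all(wild.calls)
        with np.errstate(invalid="ignore"):
            wild_freq = np.where(n_w > 0, alt_w / np.maximum(n_w, 1), np.nan)
    except (ValueError, KeyError):
        pass

    loci: list[FixationLocus] = []
    for j in hits:
        in_sweep, region_id = _locate(str(gm.chrom[j]), int(gm.pos[j]), regions)
        loci.append(
            FixationLocus(
                chrom=str(gm.chrom[j]),
                pos=int(gm.pos[j]),
                ref_allele=str(gm.ref[j]),
                alt_allele=str(gm.alt[j]),
                fixed_population=focal_group,
                fixed_genotype=int(focal.calls[0, j]),
                other_population=other_group,
                in_sweep=in_sweep,
                region_id=region_id,
                wild_alt_freq=float(wild_freq[j]) if wild_freq is not None else None,
            )
        )
    return loci


def _locate(
    chrom: str, pos: int, regions: Sequence[SweepRegion] | None
) -> tuple[bool, str | None]:
    if not regions:
        return False, None
    for i, r in enumerate(regions):
        if r.chrom == chrom and r.start + 1 <= pos <= r.end:
            return True, f"{r.transition}_{i:04d}"
    return False, None


def fixation_density(
    loci: Sequence[FixationLocus],
    regions: Sequence[SweepRegion],
    windows: Sequence[diversity.GenomicWindow],
) -> pd.DataFrame:
    """Per-window fixation counts, stratified by sweep membership.

    ``windows`` should be non-overlapping (step = window size) so counts
    conserve: the column sum equals the number of loci falling in any
    window. A window is in-sweep when it overlaps any region.
    """
    by_chrom: dict[str, list[int]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus.pos)
    pos_sorted = {c: np.sort(np.array(p)) for c, p in by_chrom.items()}
    rows = []
    for w in windows:
        pos = pos_sorted.get(w.chrom)
        if pos is None:
            count = 0
        else:
            count = int(
                np.searchsorted(pos, w.end, "right")
                - np.searchsorted(pos, w.start + 1, "left")
            )
        in_sweep = any(
            r.chrom == w.chrom and r.start < w.end and w.start < r.end for r in regions
        )
        rows.append((w.chrom, w.start, w.end, count, in_sweep))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_fixations", "in_sweep"]
    )


def density_summary(density: pd.DataFrame) -> dict[str, float]:
    """Mean per-window fixation density genome-wide vs inside sweeps."""
    genome_mean = float(density["n_fixations"].mean())
    in_sweep = density.loc[density["in_sweep"], "n_fixations"]
    sweep_mean = float(in_sweep.mean()) if len(in_sweep) else float("nan")
    return {
        "genome_mean": genome_mean,
        "sweep_mean": sweep_mean,
        "ratio": sweep_mean / genome_mean if genome_mean > 0 else float("nan"),
    }


def wild_frequency_of_fixed(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    loci: Sequence[FixationLocus],
    wild_group: str = "wild",
) -> np.ndarray:
    """Wild-population SFS at loci fixed in cultivars.

    This is the pre-domestication state of the fixed variants: the
    spectrum of their alternate-allele counts among wild accessions.
    Loci absent from the matrix are skipped (counted in the log).
    """
    wild = subset_population(gm, manifest, wild_group)
    index = {(str(c), int(p)): j for j, (c, p) in enumerate(zip(wild.chrom, wild.pos))}
    site_idx = []
    n_missing = 0
    for locus in loci:
        j = index.get((locus.chrom, locus.pos))
        if j is None:
            n_missing += 1
        else:
            site_idx.append(j)
    if n_missing:
        logger.warning("wild_frequency_of_fixed: %d locus/loci not in matrix", n_missing)
    return diversity.sfs(wild, site_indices=site_idx)


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

def classify_coding_effect(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    gene_models: Sequence[GeneModel],
    genome,
) -> tuple[str, str | None]:
    """Coding effect of substituting alt for ref at (chrom, pos).

    ``genome`` is a pyfaidx.Fasta (or any mapping of chrom → indexable
    sequence). Returns (effect, gene_id): ``noncoding`` outside every CDS,
    else ``synonymous``/``nonsynonymous`` by translating the affected codon
    of the spliced CDS (reverse-complemented on minus strand, phase-aware);
    ``unclassified`` when the model is malformed (e.g. CDS length not
    divisible by 3 — logged) or the reference base disagrees.
    """
    for model in gene_models:
        if model.chrom != chrom:
            continue
        if not any(s <= pos <= e for s, e, _ in model.cds):
            continue
        if model.cds_length % 3 != 0:
            logger.warning(
                "classify_coding_effect: CDS length %d of %s not divisible "
                "by 3; skipped", model.cds_length, model.transcript_id,
            )
            return "unclassified", model.gene_id

        cds_seq, offset = _spliced_cds_and_offset(model, pos, genome)
        base_in_cds = cds_seq[offset]
        expected = ref_allele if model.strand == "+" else _complement(ref_allele)
        if base_in_cds != expected:
            logger.warning(
                "classify_coding_effect: genome base %s != REF %s at %s:%d; "
                "unclassified", base_in_cds, ref_allele, chrom, pos,
            )
            return "unclassified", model.gene_id

        phase0 = model.ordered_cds()[0][2]
        adj = offset - phase0
        if adj < 0 or adj >= (model.cds_length - phase0) // 3 * 3:
            return "unclassified", model.gene_id  # inside an incomplete codon
        codon_start = phase0 + (adj // 3) * 3
        codon_ref = cds_seq[codon_start : codon_start + 3]
        alt_in_cds = alt_allele if model.strand == "+" else _complement(alt_allele)
        within = offset - codon_start
        codon_alt = codon_ref[:within] + alt_in_cds + codon_ref[within + 1 :]
        aa_ref = str(Seq(codon_ref).translate())
        aa_alt = str(Seq(codon_alt).translate())
        effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return effect, model.gene_id
    return "noncoding", None


def _spliced_cds_and_offset(model: GeneModel, pos: int, genome) -> tuple[str, int]:
    """Spliced CDS sequence (transcript orientation) and the 0-based offset
    of genomic ``pos`` within it."""
    parts: list[str] = []
    offset = None
    running = 0
    for s, e, _ in model.ordered_cds():
        seg = str(genome[model.chrom][s - 1 : e]).upper()
        if model.strand == "-":
            seg = _revcomp(seg)
        if s <= pos <= e:
            within = (pos - s) if model.strand == "+" else (e - pos)
            offset = running + within
        parts.append(seg)
        running += e - s + 1
    if offset is None:
        raise ValueError(f"position {pos} not in CDS of {model.transcript_id}")
    return "".join(parts), offset


_COMP = str.maketrans("ACGT", "TGCA")


def _complement(base: str) -> str:
    return base.translate(_COMP)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def classify_loci(
    loci: Sequence[FixationLocus],
    gene_models: Sequence[GeneModel],
    genome,
    longest_only: bool = True,
) -> None:
    """Annotate ``effect`` and ``gene_id`` on loci in place."""
    models = longest_transcript_per_gene(gene_models) if longest_only else list(gene_models)
    for locus in loci:
        effect, gene_id = classify_coding_effect(
            locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele, models, genome
        )
        locus.effect = effect
        locus.gene_id = gene_id


def loci_to_table(loci: Sequence[FixationLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                l.chrom, l.pos, l.ref_allele, l.alt_allele, l.fixed_population,
                l.fixed_genotype, l.in_sweep, l.region_id, l.wild_alt_freq,
                l.effect, l.gene_id,
            )
            for l in loci
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "fixed_pop", "fixed_genotype",
            "in_sweep", "region_id", "wild_alt_freq", "effect", "gene_id",
        ],
    )
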