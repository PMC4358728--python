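"""Three-population synthetic genotype generator.

Emulates the statistical structure of a domestication series — a diverse
wild population, a landrace population derived through a domestication
bottleneck, and an elite population derived from the landraces through an
improvement bottleneck — with optional injected selective sweeps and the
nucleotide fixations they force.

The model is frequency-resampling rather than forward-in-time: ancestral
site frequencies follow the neutral spectrum (number of sites at derived
count i proportional to 1/i), each bottleneck resamples frequencies
through a small binomial founder pool sized so that expected
heterozygosity retention equals the configured fraction, and genotypes are
drawn under Hardy–Weinberg within each population. Sweeps fix a drawn
beneficial haplotype across the specified interval in the selected
population(s) — the focal site carries the alternate allele — with
hitchhiking decaying linearly over a half-width flank, so both the
diversity loss and the divergence signature of selection appear.
Read-backed genotype likelihoods come from a Poisson-depth binomial read
model. All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

from .genotype import (
    GenotypeLikelihoods,
    GenotypeMatrix,
    PopulationManifest,
    write_manifest,
    write_vcf,
)

Transition = Literal["domestication", "improvement"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSpec:
    """An injected sweep: interval (0-based half-open) and its transition."""

    chrom: str
    start: int
    end: int
    transition: Transition


@dataclass(frozen=True)
class FixedLocusTruth:
    """A locus the generator forced to fixation in one population group."""

    chrom: str
    pos: int
    population: str  # "cultivated" (domestication) or "elite" (improvement)


@dataclass
class SimTruth:
    """Ground-truth record of injected sweeps and forced fixations."""

    swept_regions: list[SweepSpec] = field(default_factory=list)
    fixed_loci: list[FixedLocusTruth] = field(default_factory=list)


@dataclass
class SimConfig:
    """Generator settings.

    Sample counts default to the 31 wild / 15 landrace / 24 elite design of
    the resequencing panels this generator emulates. ``theta`` is the
    per-site scaled mutation parameter of the ancestral (wild) population;
    the default 0.0038 matches wild-soybean per-nucleotide diversity.
    Bottleneck fractions are expected heterozygosity retention across each
    transition: landrace/wild 0.625 and elite/landrace 0.867 reproduce the
    observed 37.5% domestication and further ~8% improvement losses.
    """

    n_wild: int = 31
    n_landrace: int = 15
    n_elite: int = 24
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    theta: float = 0.0038
    bottleneck_domestication: float = 0.625
    bottleneck_improvement: float = 0.867
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    pool_haplotypes: int = 2000
    mean_depth: float = 10.0
    error_rate: float = 0.01
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def validate(self) -> None:
        for frac in (self.bottleneck_domestication, self.bottleneck_improvement):
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"retention fraction {frac} outside (0, 1]")
        if min(self.n_wild, self.n_landrace, self.n_elite) < 1:
            raise ValueError("all three populations need at least one sample")
        names = set(self.chrom_names())
        by_chrom: dict[str, list[SweepSpec]] = {}
        for sw in self.sweep_specs:
            if sw.chrom not in names:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not in genome")
            if not (0 <= sw.start < sw.end <= self.chrom_length):
                raise ValueError(f"sweep {sw} outside chromosome bounds")
            by_chrom.setdefault(sw.chrom, []).append(sw)
        for chrom, sws in by_chrom.items():
            sws = sorted(sws, key=lambda s: s.start)
            for a, b in zip(sws, sws[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping sweeps on {chrom}: {a} / {b}")


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    likelihoods: GenotypeLikelihoods
    manifest: PopulationManifest
    truth: SimTruth
    config: SimConfig


def _neutral_sites(
    rng: np.random.Generator, theta: float, length: int, pool: int
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (1-based, sorted) and pool frequencies of neutral sites.

    The number of sites at derived count i in the pool of ``pool``
    haplotypes is Poisson(theta * length / i), the infinite-sites neutral
    expectation, so realized diversity converges to theta per site.
    """
    counts = rng.poisson(theta * length / np.arange(1, pool))
    total = int(counts.sum())
    total = min(total, length)  # cannot place more sites than bases
    freqs = np.repeat(np.arange(1, pool) / pool, counts)[:total]
    rng.shuffle(freqs)
    positions = np.sort(rng.choice(length, size=total, replace=False)) + 1
    return positions, freqs


def _founder_resample(
    rng: np.random.Generator, p: np.ndarray, retention: float
) -> np.ndarray:
    """Resample frequencies through a binomial founder bottleneck.

    Expected heterozygosity after a founder pool of B haplotypes is
    (1 - 1/B) of the input. Two adjacent integer pool sizes are mixed per
    site with weights solving E[1/B] = 1 - retention, so any retention in
    (0, 1] is achieved exactly in expectation.
    """
    if retention >= 1.0:
        return p.copy()
    loss = 1.0 - retention  # = E[1/B]
    b_low = int(np.floor(1.0 / loss))  # 1/b_low >= loss >= 1/(b_low+1)
    if 1.0 / b_low == loss:
        sizes = np.full(p.shape, b_low)
    else:
        w_low = (loss - 1.0 / (b_low + 1)) / (1.0 / b_low - 1.0 / (b_low + 1))
        sizes = np.where(rng.random(p.shape) < w_low, b_low, b_low + 1)
    return rng.binomial(sizes, p) / sizes


def _apply_sweep(
    rng: np.random.Generator,
    pos: np.ndarray,
    p: np.ndarray,
    sw: SweepSpec,
    forced: np.ndarray,
    chrom_length: int,
) -> None:
    """Impose one sweep on a population's frequency array, in place.

    Inside [start, end) every site is fixed for the allele carried by the
    beneficial haplotype — a single ancestral draw h ~ Bernoulli(p) per
    site, with the alternate allele at the site nearest the region centre
    (the beneficial mutation itself). Outside the region, hitchhiking
    decays linearly over a flank of half the region width: the swept
    haplotype reaches frequency (1 - scale), so flank frequencies become
    (1-scale)·h + scale·p, eroding diversity and creating divergence that
    fades with distance. ``forced`` is marked True at sites driven to
    exact fixation.
    """
    halfw = max((sw.end - sw.start) // 2, 1)
    center = (sw.start + sw.end) // 2
    near = (pos >= sw.start + 1 - halfw) & (pos <= sw.end + halfw)
    idx = np.flatnonzero(near)
    if idx.size == 0:
        return
    h = (rng.random(idx.size) < p[idx]).astype(np.float64)
    inside = (pos[idx] >= sw.start + 1) & (pos[idx] <= sw.end)
    if inside.any():
        focal_local = np.argmin(np.abs(pos[idx] - center))
        h[focal_local] = 1.0  # the beneficial (alternate) allele
    dist_out = np.maximum(
        np.maximum(sw.start + 1 - pos[idx], pos[idx] - sw.end), 0
    )
    scale = np.minimum(dist_out / halfw, 1.0)
    p[idx] = (1.0 - scale) * h + scale * p[idx]
    forced[idx[inside]] = True


def simulate_populations(cfg: SimConfig) -> SimResult:
    """Generate the three-population genotype matrix and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    chrom_arrs, pos_arrs = [], []
    pw_arrs, pl_arrs, pe_arrs = [], [], []
    forced_cult, forced_elite = [], []  # per-chrom boolean masks

    sweeps_by_chrom: dict[str, list[SweepSpec]] = {}
    for sw in cfg.sweep_specs:
        sweeps_by_chrom.setdefault(sw.chrom, []).append(sw)

    for chrom in cfg.chrom_names():
        pos, p_wild = _neutral_sites(rng, cfg.theta, cfg.chrom_length, cfg.pool_haplotypes)
        p_land = _founder_resample(rng, p_wild, cfg.bottleneck_domestication)

        f_cult = np.zeros(pos.shape, dtype=bool)
        f_elite = np.zeros(pos.shape, dtype=bool)

        for sw in sweeps_by_chrom.get(chrom, []):
            if sw.transition == "domestication":
                # acts on the landrace founders; elite inherits the fixed
                # haplotype through its own founder resampling below
                _apply_sweep(rng, pos, p_land, sw, f_cult, cfg.chrom_length)

        p_elite = _founder_resample(rng, p_land, cfg.bottleneck_improvement)
        for sw in sweeps_by_chrom.get(chrom, []):
            if sw.transition == "improvement":
                _apply_sweep(rng, pos, p_elite, sw, f_elite, cfg.chrom_length)

        chrom_arrs.append(np.full(pos.shape, chrom, dtype=object))
        pos_arrs.append(pos)
        pw_arrs.append(p_wild)
        pl_arrs.append(p_land)
        pe_arrs.append(p_elite)
        forced_cult.append(f_cult)
        forced_elite.append(f_elite)

    chrom_all = np.concatenate(chrom_arrs)
    pos_all = np.concatenate(pos_arrs)
    p_wild = np.concatenate(pw_arrs)
    p_land = np.concatenate(pl_arrs)
    p_elite = np.concatenate(pe_arrs)
    f_cult = np.concatenate(forced_cult)
    f_elite = np.concatenate(forced_elite)

    # Hardy-Weinberg genotype draws within each population
    g_wild = rng.binomial(2, p_wild, size=(cfg.n_wild, p_wild.size))
    g_land = rng.binomial(2, p_land, size=(cfg.n_landrace, p_land.size))
    g_elite = rng.binomial(2, p_elite, size=(cfg.n_elite, p_elite.size))
    calls = np.vstack([g_wild, g_land, g_elite]).astype(np.int8)

    # keep only sites at which some accession carries the alternate allele
    discovered = (calls > 0).any(axis=0)
    chrom_all, pos_all = chrom_all[discovered], pos_all[discovered]
    p_wild = p_wild[discovered]
    f_cult, f_elite = f_cult[discovered], f_elite[discovered]
    calls = calls[:, discovered]

    ref, alt = _draw_alleles(rng, pos_all.size)
    samples = (
        [f"W{i + 1:02d}" for i in range(cfg.n_wild)]
        + [f"L{i + 1:02d}" for i in range(cfg.n_landrace)]
        + [f"E{i + 1:02d}" for i in range(cfg.n_elite)]
    )
    labels = (
        {s: "wild" for s in samples[: cfg.n_wild]}
        | {s: "landrace" for s in samples[cfg.n_wild : cfg.n_wild + cfg.n_landrace]}
        | {s: "elite" for s in samples[cfg.n_wild + cfg.n_landrace :]}
    )
    manifest = PopulationManifest(labels)
    gm = GenotypeMatrix(
        samples=samples, chrom=chrom_all, pos=pos_all, ref=ref, alt=alt, calls=calls
    )
    gl = _read_model_likelihoods(rng, gm, cfg.mean_depth, cfg.error_rate)

    truth = SimTruth(swept_regions=list(cfg.sweep_specs))
    wild_calls = calls[: cfg.n_wild, :]
    wild_poly = ~np.all(wild_calls == wild_calls[0:1, :], axis=0)
    for j in np.flatnonzero(f_cult & wild_poly):
        truth.fixed_loci.append(
            FixedLocusTruth(str(chrom_all[j]), int(pos_all[j]), "cultivated")
        )
    for j in np.flatnonzero(f_elite & ~f_cult & wild_poly):
        truth.fixed_loci.append(
            FixedLocusTruth(str(chrom_all[j]), int(pos_all[j]), "elite")
        )
    return SimResult(matrix=gm, likelihoods=gl, manifest=manifest, truth=truth, config=cfg)


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx].astype(object), _BASES[alt_idx].astype(object)


def _read_model_likelihoods(
    rng: np.random.Generator, gm: GenotypeMatrix, mean_depth: float, error: float
) -> GenotypeLikelihoods:
    """Poisson depth + binomial read model likelihoods for the true calls."""
    depth = rng.poisson(mean_depth, size=gm.calls.shape)
    mu_true = np.array([error, 0.5, 1.0 - error])[gm.calls]
    alt_reads = rng.binomial(depth, mu_true)
    lik = np.empty(gm.calls.shape + (3,), dtype=np.float64)
    for g, mu in enumerate((error, 0.5, 1.0 - error)):
        lik[:, :, g] = stats.binom.pmf(alt_reads, depth, mu)
    return GenotypeLikelihoods(
        samples=list(gm.samples),
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        likelihoods=lik,
    )


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete fixture file set for one simulation.

    Produces VCF (+PL), manifest TSV, truth TSV, a toy genome FASTA whose
    reference bases agree with the VCF REF column, a GFF3 with CDS gene
    models overlapping the sweeps, a QTL BED, and a gene→category TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {
        "vcf": out / "variants.vcf",
        "manifest": out / "populations.tsv",
        "truth": out / "truth.tsv",
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "qtl_bed": out / "qtl.bed",
        "categories": out / "gene_categories.tsv",
    }
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    # genome consistent with VCF REF alleles
    seqs: dict[str, np.ndarray] = {}
    for chrom in cfg.chrom_names():
        seqs[chrom] = _BASES[rng.integers(0, 4, size=cfg.chrom_length)].copy()
    gm = result.matrix
    for j in range(gm.n_sites):
        seqs[str(gm.chrom[j])][int(gm.pos[j]) - 1] = str(gm.ref[j])
    with open(paths["fasta"], "w") as fh:
        for chrom, arr in seqs.items():
            fh.write(f">{chrom}\n")
            s = "".join(arr)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")

    write_vcf(gm, paths["vcf"], gl=result.likelihoods, contig_lengths=cfg.chrom_lengths())
    write_manifest(result.manifest, paths["manifest"])

    with open(paths["truth"], "w") as fh:
        fh.write("type\tchrom\tstart\tend\tpos\tdetail\n")
        for sw in result.truth.swept_regions:
            fh.write(f"sweep\t{sw.chrom}\t{sw.start}\t{sw.end}\t.\t{sw.transition}\n")
        for fx in result.truth.fixed_loci:
            fh.write(f"fixation\t{fx.chrom}\t.\t.\t{fx.pos}\t{fx.population}\n")

    genes = _toy_gene_models(result, rng)
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in cfg.chrom_lengths().items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            gid, chrom, strand, cds = g
            gstart = min(s for s, _ in cds)
            gend = max(e for _, e in cds)
            fh.write(
                f"{chrom}\ttoy\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}\n"
            )
            mid = f"{gid}.1"
            fh.write(
                f"{chrom}\ttoy\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            segs = cds if strand == "+" else list(reversed(cds))
            phase = 0
            for s, e in segs:
                fh.write(
                    f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3

    with open(paths["qtl_bed"], "w") as fh:
        traits = ["seed_weight", "pod_number", "oil_content", "plant_height"]
        for i, sw in enumerate(result.truth.swept_regions):
            pad = 50_000
            start = max(0, sw.start - pad)
            end = min(cfg.chrom_length, sw.end + pad)
            fh.write(f"{sw.chrom}\t{start}\t{end}\t{traits[i % len(traits)]}\n")
        for chrom in cfg.chrom_names():  # background QTL away from sweeps
            fh.write(f"{chrom}\t0\t20000\tflower_number\n")

    with open(paths["categories"], "w") as fh:
        for gid, chrom, strand, cds in genes:
            in_sweep = any(
                sw.chrom == chrom and min(s for s, _ in cds) <= sw.end
                and max(e for _, e in cds) >= sw.start + 1
                for sw in result.truth.swept_regions
            )
            cat = "transcription_factor" if in_sweep else "metabolism"
            fh.write(f"{gid}\t{cat}\n")

    return paths


def _toy_gene_models(result: SimResult, rng: np.random.Generator):
    """Two-exon CDS gene models: one per sweep plus background genes."""
    cfg = result.config
    genes = []
    n = 0
    for sw in result.truth.swept_regions:
        center = (sw.start + sw.end) // 2
        genes.append(_make_gene(f"gene{n:03d}", sw.chrom, center, "+" if n % 2 == 0 else "-", cfg))
        n += 1
    for chrom in cfg.chrom_names():
        for anchor in range(100_000, cfg.chrom_length - 10_000, 250_000):
            genes.append(_make_gene(f"gene{n:03d}", chrom, anchor, "+" if n % 2 == 0 else "-", cfg))
            n += 1
    return genes


def _make_gene(gid: str, chrom: str, anchor: int, strand: str, cfg: SimConfig):
    """A gene with two CDS segments (150 bp + 151 bp + phase, total %3 == 0)."""
    s1 = max(1, min(anchor, cfg.chrom_length - 2000))
    cds = [(s1, s1 + 149), (s1 + 500, s1 + 652)]  # 150 + 153 bp, total % 3 == 0
    return (gid, chrom, strand, cds)
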