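"""Genotype matrices for multi-population SNV data.

The central container is :class:`GenotypeMatrix`, a samples × sites array of
diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing)
over biallelic single-nucleotide variants, together with site coordinates.
Populations are defined by a :class:`PopulationManifest` mapping samples to
``wild``, ``landrace`` or ``elite``; the ``cultivated`` group is the union of
landrace and elite.

Genotype likelihoods (one non-negative triple per sample × site) support
maximum-likelihood consensus assignment: each individual receives the
genotype with the highest likelihood, which is how consensus genotypes are
built before fixation screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

VALID_LABELS = ("wild", "landrace", "elite")
#: derived group: landrace ∪ elite
CULTIVATED = "cultivated"


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV at a 1-based coordinate."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single nucleotides, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes for ``samples`` × biallelic ``sites``.

    ``calls`` holds one int8 code per (sample, site); sites are kept sorted
    by (chrom, pos). Column access is via numpy arrays ``chrom``, ``pos``,
    ``ref`` and ``alt`` for speed; :meth:`site` materialises a
    :class:`VariantSite` view for a single column.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.pos)})"
            )
        if not self._is_sorted():
            order = np.lexsort((self.pos, self.chrom.astype(str)))
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.calls = self.calls[:, order]

    def _is_sorted(self) -> bool:
        if self.n_sites <= 1:
            return True
        c = self.chrom.astype(str)
        same = c[:-1] == c[1:]
        return bool(
            np.all(c[:-1] <= c[1:]) and np.all(self.pos[:-1][same] < self.pos[1:][same])
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def site(self, index: int) -> VariantSite:
        return VariantSite(
            chrom=str(self.chrom[index]),
            pos=int(self.pos[index]),
            ref_allele=str(self.ref[index]),
            alt_allele=str(self.alt[index]),
        )

    def sites(self) -> list[VariantSite]:
        return [self.site(i) for i in range(self.n_sites)]

    def take_samples(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def take_sites(self, mask_or_indices) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[mask_or_indices],
            pos=self.pos[mask_or_indices],
            ref=self.ref[mask_or_indices],
            alt=self.alt[mask_or_indices],
            calls=self.calls[:, mask_or_indices].copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom.astype(str), other.chrom.astype(str))
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref.astype(str), other.ref.astype(str))
            and np.array_equal(self.alt.astype(str), other.alt.astype(str))
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class GenotypeLikelihoods:
    """Per (sample, site) likelihood triples for (hom-ref, het, hom-alt).

    Shape is (n_samples, n_sites, 3); values are non-negative and need not
    be normalised. An all-zero triple means "no information" and yields a
    missing consensus call.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    likelihoods: np.ndarray

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=np.float64)
        expected = (len(self.samples), len(self.pos), 3)
        if self.likelihoods.shape != expected:
            raise ValueError(
                f"likelihood shape {self.likelihoods.shape} != {expected}"
            )
        if np.any(self.likelihoods < 0) or not np.all(np.isfinite(self.likelihoods)):
            raise ValueError("likelihoods must be finite and non-negative")


@dataclass
class MLAssignment:
    """Result of maximum-likelihood consensus genotype assignment."""

    matrix: GenotypeMatrix
    n_ties: int = 0
    n_uninformative: int = 0


@dataclass
class PopulationManifest:
    """Sample → population label map (wild / landrace / elite)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.labels.items() if l not in VALID_LABELS}
        if bad:
            raise ValueError(f"unknown population labels: {bad}")

    def samples_for(self, label: str) -> list[str]:
        """Samples in a population; ``cultivated`` = landrace ∪ elite."""
        if label == CULTIVATED:
            wanted = {"landrace", "elite"}
        elif label in VALID_LABELS:
            wanted = {label}
        else:
            raise KeyError(f"unknown population label {label!r}")
        return [s for s, l in self.labels.items() if l in wanted]

    def validate_against(self, gm: GenotypeMatrix, require_all_labels: bool = False) -> None:
        missing = [s for s in gm.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        if require_all_labels:
            for lab in VALID_LABELS:
                if not self.samples_for(lab):
                    raise ValueError(f"population {lab!r} is empty")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> PopulationManifest:
    """Read a 2-column TSV (sample, label)."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sample, label = parts
        if sample in labels:
            raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
        labels[sample] = label
    return PopulationManifest(labels)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    lines = [f"{s}\t{l}" for s, l in manifest.labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path: str | Path,
    skip_non_snv: bool = True,
) -> tuple[GenotypeMatrix, GenotypeLikelihoods | None, int]:
    """Read a multi-sample VCF into a genotype matrix.

    GT fields map 0/0→0, 0/1 or 1/0→1, 1/1→2, missing→-1. Multiallelic or
    non-SNV records are skipped (counted) when ``skip_non_snv`` is true,
    otherwise rejected. GL (log10) or PL fields, when present at every
    record, are returned as linear-scale :class:`GenotypeLikelihoods`.

    Returns (matrix, likelihoods-or-None, n_skipped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    call_cols: list[np.ndarray] = []
    gl_cols: list[np.ndarray] = []
    have_gl = True
    n_skipped = 0
    for rec in vcf:
        alt_list = rec.ALT
        if (
            len(alt_list) != 1
            or len(rec.REF) != 1
            or len(alt_list[0]) != 1
            or rec.REF not in NUCLEOTIDES
            or alt_list[0] not in NUCLEOTIDES
        ):
            if not skip_non_snv:
                raise VCFParseError(
                    f"{path}: non-biallelic-SNV record at {rec.CHROM}:{rec.POS}"
                )
            n_skipped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col is phasing
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        col = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(alt_list[0])
        call_cols.append(col)
        if have_gl:
            gl = _extract_likelihoods(rec, len(samples))
            if gl is None:
                have_gl = False
                gl_cols = []
            else:
                gl_cols.append(gl)
    if n_skipped:
        logger.warning("read_vcf: skipped %d non-biallelic-SNV record(s)", n_skipped)
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
    )
    gl_out = None
    if have_gl and gl_cols:
        gl_out = GenotypeLikelihoods(
            samples=samples,
            chrom=gm.chrom,
            pos=gm.pos,
            ref=gm.ref,
            alt=gm.alt,
            likelihoods=np.stack(gl_cols, axis=1),
        )
    return gm, gl_out, n_skipped


def _extract_likelihoods(rec, n_samples: int) -> np.ndarray | None:
    try:
        pl = rec.format("PL")
    except KeyError:
        pl = None
    if pl is not None and pl.shape == (n_samples, 3):
        pl = pl.astype(np.float64)
        pl[pl < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        with np.errstate(invalid="ignore"):
            lik = np.power(10.0, -pl / 10.0)
        lik[np.isnan(lik)] = 0.0
        return lik
    try:
        gl = rec.format("GL")
    except KeyError:
        gl = None
    if gl is not None and gl.shape == (n_samples, 3):
        gl = gl.astype(np.float64)
        lik = np.power(10.0, gl)
        lik[~np.isfinite(lik)] = 0.0
        return lik
    return None


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    gl: GenotypeLikelihoods | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VCF 4.2 file with GT (and PL when likelihoods are given)."""
    out = []
    out.append("##fileformat=VCFv4.2")
    out.append("##source=soysweep")
    if contig_lengths:
        for name, length in contig_lengths.items():
            out.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(gm.chrom.astype(str)):
            out.append(f"##contig=<ID={name}>")
    out.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    fmt = "GT"
    pl_codes = None
    if gl is not None:
        out.append(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
            '"Phred-scaled genotype likelihoods">'
        )
        fmt = "GT:PL"
        with np.errstate(divide="ignore"):
            phred = -10.0 * np.log10(gl.likelihoods)
        phred = phred - np.nanmin(
            np.where(np.isfinite(phred), phred, np.inf), axis=2, keepdims=True
        )
        phred[~np.isfinite(phred)] = 9999
        pl_codes = np.clip(np.rint(phred), 0, 9999).astype(int)
    out.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    for j in range(gm.n_sites):
        fields = [
            str(gm.chrom[j]),
            str(int(gm.pos[j])),
            ".",
            str(gm.ref[j]),
            str(gm.alt[j]),
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i in range(gm.n_samples):
            g = _GT_STRINGS[int(gm.calls[i, j])]
            if pl_codes is not None:
                g = f"{g}:{pl_codes[i, j, 0]},{pl_codes[i, j, 1]},{pl_codes[i, j, 2]}"
            fields.append(g)
        out.append("\t".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def assign_ml_genotypes(gl: GenotypeLikelihoods) -> MLAssignment:
    """Allocate to each individual the genotype with maximum likelihood.

    Ties go to the lowest genotype code and are counted; an all-zero triple
    carries no information, so the call is set missing and flagged.
    """
    lik = gl.likelihoods
    calls = np.argmax(lik, axis=2).astype(np.int8)  # argmax takes first max: lowest code
    maxval = np.max(lik, axis=2)
    n_max = np.sum(lik == maxval[..., None], axis=2)
    uninformative = maxval == 0
    ties = (n_max > 1) & ~uninformative
    calls[uninformative] = MISSING
    n_ties = int(ties.sum())
    n_unin = int(uninformative.sum())
    if n_ties:
        logger.info("assign_ml_genotypes: %d likelihood tie(s) broken to lowest code", n_ties)
    if n_unin:
        logger.warning("assign_ml_genotypes: %d all-zero likelihood triple(s) set missing", n_unin)
    gm = GenotypeMatrix(
        samples=list(gl.samples),
        chrom=gl.chrom.copy(),
        pos=gl.pos.copy(),
        ref=gl.ref.copy(),
        alt=gl.alt.copy(),
        calls=calls,
    )
    return MLAssignment(matrix=gm, n_ties=n_ties, n_uninformative=n_unin)


def subset_population(
    gm: GenotypeMatrix, manifest: PopulationManifest, label: str
) -> GenotypeMatrix:
    """Rows of ``gm`` belonging to a population, in original sample order."""
    members = set(manifest.samples_for(label))
    idx = [i for i, s in enumerate(gm.samples) if s in members]
    if not idx:
        raise ValueError(f"no samples in matrix belong to population {label!r}")
    return gm.take_samples(idx)


def allele_counts(gm: GenotypeMatrix, site_index: int) -> tuple[int, int]:
    """(total alleles, alt alleles) at one site over non-missing diploids."""
    col = gm.calls[:, site_index]
    ok = col >= 0
    return int(2 * ok.sum()), int(col[ok].sum())


def allele_counts_all(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allele counts for every site of a calls array.

    Returns (n_alleles, alt_count), each of length n_sites.
    """
    ok = calls >= 0
    n = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    return n.astype(np.int64), alt.astype(np.int64)
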