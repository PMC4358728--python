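"""QTL narrowing and gene-category enrichment.

QTL meta-analysis intersects reported QTL intervals with selective-sweep
regions that carry nucleotide fixations, retaining only the overlapping
footprint of each QTL; totals are computed on interval unions so
overlapping QTLs are not double counted.

Enrichment of gene categories among selected genes uses the one-sided
(over-representation) Fisher's exact / hypergeometric test, an optional
permutation test resampling gene sets of the observed size, and
Benjamini–Hochberg FDR correction across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .scan import SweepRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QTLInterval:
    """A trait interval in 0-based half-open coordinates."""

    trait: str
    chrom: str
    start: int
    end: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"QTL {self.trait}: end must exceed start")

    @property
    def span(self) -> int:
        return self.end - self.start


def read_qtl_bed(path: str | Path) -> list[QTLInterval]:
    """BED with the trait in the name (4th) column."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}: line {i + 1} needs chrom,start,end,trait")
        out.append(
            QTLInterval(
                trait=parts[3], chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                source_id=parts[4] if len(parts) > 4 else None,
            )
        )
    return out


def read_gene_categories(path: str | Path) -> dict[str, list[str]]:
    """2-column TSV gene → category (genes may repeat across categories)."""
    mapping: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, cat = line.split("\t")[:2]
        mapping.setdefault(gene, []).append(cat)
    return mapping


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def _union(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (book-ended runs merge)."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _union_length(by_chrom: Mapping[str, Sequence[tuple[int, int]]]) -> int:
    return sum(e - s for ivs in by_chrom.values() for s, e in _union(ivs))


def narrow_qtl(
    qtls: Sequence[QTLInterval],
    regions: Sequence[SweepRegion],
    region_has_fixation: Mapping[tuple[str, int, int], bool] | None = None,
    require_fixation: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Intersect QTLs with qualifying sweep regions.

    A region qualifies when it carries at least one fixation locus
    (``region_has_fixation`` keyed by (chrom, start, end)); pass
    ``require_fixation=False`` to use all sweep regions. Per QTL the
    retained footprint is the union of its intersections; QTLs with an
    empty footprint are dropped. The summary reports union-based input and
    retained Mb plus the traits still represented.
    """
    if require_fixation and region_has_fixation is not None:
        used = [
            r for r in regions
            if region_has_fixation.get((r.chrom, r.start, r.end), False)
        ]
    else:
        used = list(regions)
    reg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in used:
        reg_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    reg_by_chrom = {c: _union(v) for c, v in reg_by_chrom.items()}

    rows = []
    retained_by_chrom: dict[str, list[tuple[int, int]]] = {}
    input_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for q in qtls:
        input_by_chrom.setdefault(q.chrom, []).append((q.start, q.end))
        pieces = [
            (max(q.start, s), min(q.end, e))
            for s, e in reg_by_chrom.get(q.chrom, [])
            if s < q.end and q.start < e
        ]
        retained = sum(e - s for s, e in pieces)
        if retained == 0:
            continue
        retained_by_chrom.setdefault(q.chrom, []).extend(pieces)
        rows.append(
            (q.trait, q.chrom, q.start, q.end, q.span, retained,
             ";".join(f"{s}-{e}" for s, e in pieces))
        )
    table = pd.DataFrame(
        rows,
        columns=["trait", "chrom", "start", "end", "input_bp",
                 "retained_bp", "retained_intervals"],
    )
    summary = {
        "input_mb": _union_length(input_by_chrom) / 1e6,
        "retained_mb": _union_length(retained_by_chrom) / 1e6,
        "n_qtl_input": float(len(qtls)),
        "n_qtl_retained": float(len(table)),
        "n_traits_retained": float(table["trait"].nunique()) if len(table) else 0.0,
    }
    return table, summary


def genes_in_intervals(
    gene_spans: Mapping[str, tuple[str, int, int]],
    intervals: Sequence[tuple[str, int, int]],
) -> set[str]:
    """Genes whose span (chrom, start, end; half-open) overlaps any interval."""
    hits = set()
    for gid, (chrom, s, e) in gene_spans.items():
        for c2, s2, e2 in intervals:
            if chrom == c2 and s < e2 and s2 < e:
                hits.add(gid)
                break
    return hits


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    selected_genes: set[str],
    background_genes: set[str],
    categories: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided over-representation test per category, BH-corrected.

    ``categories`` maps gene → category list. P is the hypergeometric
    upper tail P(X ≥ k) of drawing k category genes in |selected| draws
    from the background. Categories with no background gene are skipped.
    """
    if not selected_genes <= background_genes:
        raise ValueError("selected genes must be a subset of the background")
    by_cat: dict[str, set[str]] = {}
    for gene, cats in categories.items():
        if gene not in background_genes:
            continue
        for c in cats:
            by_cat.setdefault(c, set()).add(gene)
    dropped = {c for g, cats in categories.items() for c in cats} - set(by_cat)
    if dropped:
        logger.info("fisher_enrichment: %d category(ies) absent from background", len(dropped))
    M = len(background_genes)
    K = len(selected_genes)
    rows = []
    for cat, members in sorted(by_cat.items()):
        m = len(members)
        k = len(members & selected_genes)
        p = float(sps.hypergeom.sf(k - 1, M, m, K))
        # odds ratio of the 2x2 table (selected x in-category)
        a, b = k, K - k
        c, d = m - k, M - K - (m - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((cat, k, K, m, M, odds, p))
    df = pd.DataFrame(
        rows, columns=["category", "k", "K", "m", "M", "odds_ratio", "p_fisher"]
    )
    if len(df):
        df["q_bh"] = bh_fdr(df["p_fisher"].to_numpy())
    else:
        df["q_bh"] = []
    return df


def permutation_enrichment(
    selected_genes: set[str],
    background_genes: set[str],
    categories: Mapping[str, Sequence[str]],
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical over-representation P per category.

    Draws ``reps`` gene sets of size |selected| uniformly from the
    background; empirical P = (1 + #{k* ≥ k_obs}) / (reps + 1), bounded
    away from zero by the add-one rule.
    """
    if reps < 100:
        raise ValueError("permutation test needs reps >= 100")
    bg = sorted(background_genes)
    rng = np.random.default_rng(seed)
    by_cat: dict[str, set[str]] = {}
    for gene, cats in categories.items():
        if gene not in background_genes:
            continue
        for c in cats:
            by_cat.setdefault(c, set()).add(gene)
    cats_sorted = sorted(by_cat)
    member_masks = np.array(
        [[g in by_cat[c] for g in bg] for c in cats_sorted], dtype=np.int64
    )
    obs = np.array([len(by_cat[c] & selected_genes) for c in cats_sorted])
    K = len(selected_genes)
    exceed = np.zeros(len(cats_sorted), dtype=np.int64)
    for _ in range(reps):
        idx = rng.choice(len(bg), size=K, replace=False)
        draw = np.zeros(len(bg), dtype=np.int64)
        draw[idx] = 1
        k_star = member_masks @ draw
        exceed += k_star >= obs
    p_emp = (1.0 + exceed) / (reps + 1.0)
    return pd.DataFrame({"category": cats_sorted, "k": obs, "p_perm": p_emp})


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
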