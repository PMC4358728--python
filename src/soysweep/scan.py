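"""Selective-sweep scans for two breeding transitions.

Domestication (wild → cultivated) is scanned with the genetic-bottleneck
model: windows with significantly low cultivated/wild θπ ratio AND
significantly low cultivated Tajima's D, both by Z test against the
genome-wide window distribution at P < 0.05, are called selected.

Improvement (landrace → elite) is scanned with the population branch
statistic (PBS): per window, pairwise Hudson Fst among elite, landrace and
wild are converted to branch lengths T = -ln(1 - Fst), and
PBS_elite = (T_EL + T_EW - T_LW) / 2 isolates frequency change on the
elite lineage. Windows are called at Bonferroni-corrected P < 0.001 on the
genome-standardized PBS.

Selected windows are merged (book-ended or overlapping) into sweep
regions, and overall diversity loss across the series is summarized
relative to the wild baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import GenomicWindow, window_slices, window_stats
from .genotype import GenotypeMatrix, PopulationManifest, allele_counts_all, subset_population

logger = logging.getLogger(__name__)

#: pseudocount per site stabilising the θπ ratio before the log transform
RATIO_PSEUDOCOUNT = 1e-5
#: Fst is capped below 1 so branch lengths stay finite
FST_CAP = 1.0 - 1e-6
MIN_WINDOWS_FOR_Z = 50


@dataclass(frozen=True)
class SweepRegion:
    """A merged run of selected windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    transition: Literal["domestication", "improvement"]
    n_windows: int
    min_p: float

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Fst and PBS
# ---------------------------------------------------------------------------

def _hudson_sums(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson (1992) numerator and denominator arrays.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    Sites with fewer than 2 alleles in either population yield NaN.
    """
    n1, a1 = allele_counts_all(calls_a)
    n2, a2 = allele_counts_all(calls_b)
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.divide(a1, n1, out=np.zeros(len(n1)), where=n1 > 0)
    p2 = np.divide(a2, n2, out=np.zeros(len(n2)), where=n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def _wc_sums(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for two
    populations: numerator a and denominator a + b + c."""
    ok_a = calls_a >= 0
    ok_b = calls_b >= 0
    n1 = ok_a.sum(axis=0).astype(float)  # diploid individuals
    n2 = ok_b.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ok_a, calls_a, 0).sum(axis=0) / (2 * n1)
        p2 = np.where(ok_b, calls_b, 0).sum(axis=0) / (2 * n2)
        h1 = (calls_a == 1).sum(axis=0) / n1
        h2 = (calls_b == 1).sum(axis=0) / n2
        n_bar = (n1 + n2) / 2.0
        n_c = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 / 2.0 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 / 2.0 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    usable = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    num = np.where(usable, a, np.nan)
    den = np.where(usable, a + b + c, np.nan)
    return num, den


_FST_SUMS = {"hudson": _hudson_sums, "weir_cockerham": _wc_sums}


def fst(
    gm: GenotypeMatrix,
    window: GenomicWindow,
    manifest: PopulationManifest,
    pop_a: str,
    pop_b: str,
    estimator: str = "hudson",
) -> float:
    """Window Fst between two populations (ratio of sums over sites).

    ``estimator`` is ``hudson`` (default) or ``weir_cockerham``. NaN when
    the window contains no site usable in both populations.
    """
    sub_a = subset_population(gm, manifest, pop_a)
    sub_b = subset_population(gm, manifest, pop_b)
    mask = (gm.chrom.astype(str) == window.chrom) & (
        (gm.pos >= window.start + 1) & (gm.pos <= window.end)
    )
    num, den = _FST_SUMS[estimator](sub_a.calls[:, mask], sub_b.calls[:, mask])
    ok = ~np.isnan(den) & (den > 0)
    if not ok.any():
        return float("nan")
    return float(num[ok].sum() / den[ok].sum())


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic for population A.

    PBS_A = (T_AB + T_AC - T_BC) / 2 with T = -ln(1 - Fst). Fst values at
    or above 1 are capped just below 1 (logged); negative window averages
    are clamped to 0 before the transform.
    """
    ts = []
    for f in (fst_ab, fst_ac, fst_bc):
        f = max(0.0, f)
        if f >= FST_CAP:
            logger.info("pbs: Fst %.6f capped at %.6f", f, FST_CAP)
            f = FST_CAP
        ts.append(-np.log(1.0 - f))
    return float((ts[0] + ts[1] - ts[2]) / 2.0)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------



def domestication_scan(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    windows: Sequence[GenomicWindow],
    alpha: float = 0.05,
    exclude_samples: Sequence[str] = (),
    pseudocount: float = RATIO_PSEUDOCOUNT,
    robust: bool = True,
) -> pd.DataFrame:
    """Bottleneck-model scan: low cultivated/wild θπ ratio and low D.

    Per window, computes pi_wild, pi_cultivated, the pseudocount-stabilised
    log ratio ln((πc+δ)/(πw+δ)), cultivated Tajima's D, genome-standardized
    Z scores and lower-tail normal P for both, and the joint selection
    flag (both P < alpha). Samples in ``exclude_samples`` are dropped first.
    """
    if exclude_samples:
        keep = [i for i, s in enumerate(gm.samples) if s not in set(exclude_samples)]
        gm = gm.take_samples(keep)
    wild = subset_population(gm, manifest, "wild")
    cult = subset_population(gm, manifest, "cultivated")
    stats_w = window_stats(wild, windows)
    stats_c = window_stats(cult, windows)

    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "pi_wild": stats_w["theta_pi"].to_numpy(),
            "pi_cultivated": stats_c["theta_pi"].to_numpy(),
            "d_cultivated": stats_c["tajima_d"].to_numpy(),
            "n_segregating": stats_w["n_segregating"].to_numpy()
            + stats_c["n_segregating"].to_numpy(),
        }
    )
    df["pi_ratio"] = df["pi_cultivated"] / df["pi_wild"].replace(0.0, np.nan)
    df["log_ratio"] = np.log(
        (df["pi_cultivated"] + pseudocount) / (df["pi_wild"] + pseudocount)
    )
    defined = (
        np.isfinite(df["log_ratio"])
        & np.isfinite(df["d_cultivated"])
        & ((df["pi_wild"] > 0) | (df["pi_cultivated"] > 0))
    )
    n_def = int(defined.sum())
    if n_def < MIN_WINDOWS_FOR_Z:
        raise ValueError(
            f"only {n_def} defined windows; need >= {MIN_WINDOWS_FOR_Z} "
            "for a stable Z standardization"
        )
    df["z_ratio"] = _zscore(df["log_ratio"], defined, robust=robust)
    df["z_d"] = _zscore(df["d_cultivated"], defined, robust=robust)
    df["p_ratio"] = sps.norm.cdf(df["z_ratio"])  # lower tail: low ratio
    df["p_d"] = sps.norm.cdf(df["z_d"])  # lower tail: low D
    df["selected"] = defined & (df["p_ratio"] < alpha) & (df["p_d"] < alpha)
    return df


def improvement_scan(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    windows: Sequence[GenomicWindow],
    alpha_corrected: float = 0.001,
    exclude_samples: Sequence[str] = (),
    estimator: str = "hudson",
    robust: bool = True,
) -> pd.DataFrame:
    """PBS scan for the landrace → elite transition.

    Per window: pairwise Hudson Fst (landrace-elite, landrace-wild,
    elite-wild), branch lengths T = -ln(1-Fst), PBS on the elite branch,
    genome-standardized Z, upper-tail P, and Bonferroni-corrected P
    (raw P × number of defined windows). Selected ⇔ p_bonferroni < alpha.
    """
    if exclude_samples:
        keep = [i for i, s in enumerate(gm.samples) if s not in set(exclude_samples)]
        gm = gm.take_samples(keep)
    manifest.validate_against(gm, require_all_labels=True)
    elite = subset_population(gm, manifest, "elite")
    land = subset_population(gm, manifest, "landrace")
    wild = subset_population(gm, manifest, "wild")

    sums = _FST_SUMS[estimator]
    num_le, den_le = sums(land.calls, elite.calls)
    num_lw, den_lw = sums(land.calls, wild.calls)
    num_ew, den_ew = sums(elite.calls, wild.calls)

    rows = []
    for w, sl in zip(windows, window_slices(gm, windows)):
        f_le = _ratio_of_sums(num_le, den_le, sl)
        f_lw = _ratio_of_sums(num_lw, den_lw, sl)
        f_ew = _ratio_of_sums(num_ew, den_ew, sl)
        if np.isnan(f_le) or np.isnan(f_lw) or np.isnan(f_ew):
            value = np.nan
        else:
            value = pbs(fst_ab=f_le, fst_ac=f_ew, fst_bc=f_lw)  # A = elite
        rows.append((w.chrom, w.start, w.end, f_le, f_lw, f_ew, value))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fst_le", "fst_lw", "fst_ew", "pbs_elite"]
    )
    for col, src in (("t_le", "fst_le"), ("t_lw", "fst_lw"), ("t_ew", "fst_ew")):
        df[col] = -np.log(1.0 - np.clip(df[src], 0.0, FST_CAP))
    defined = np.isfinite(df["pbs_elite"])
    n_def = int(defined.sum())
    if n_def < MIN_WINDOWS_FOR_Z:
        raise ValueError(
            f"only {n_def} defined windows; need >= {MIN_WINDOWS_FOR_Z} "
            "for a stable Z standardization"
        )
    df["z_pbs"] = _zscore(df["pbs_elite"], defined, robust=robust)
    df["p_raw"] = sps.norm.sf(df["z_pbs"])  # upper tail: high PBS
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * n_def)
    df["selected"] = defined & (df["p_bonferroni"] < alpha_corrected)
    return df


def _ratio_of_sums(num: np.ndarray, den: np.ndarray, mask) -> float:
    n = num[mask]
    d = den[mask]
    ok = ~np.isnan(d) & (d > 0)
    if not ok.any():
        return float("nan")
    return float(n[ok].sum() / d[ok].sum())


def _zscore(values: pd.Series, defined: np.ndarray, robust: bool = True) -> np.ndarray:
    """Genome-standardized scores over defined windows.

    By default the centre is the median and the spread the
    normal-consistent MAD (1.4826·median |x - med|): on a genome where
    selected regions are a small fraction of windows this coincides with
    the mean/sd Z score, but it stays calibrated on the neutral background
    when sweeps occupy a non-negligible share of a small genome, where
    plain moments are inflated by the very outliers the scan must detect.
    ``robust=False`` restores plain mean/sd standardization.
    """
    v = values.to_numpy(dtype=float)
    x = v[defined]
    if robust:
        mu = np.nanmedian(x)
        sd = 1.4826 * np.nanmedian(np.abs(x - mu))
        if sd == 0:
            sd = np.nanstd(x, ddof=1)
    else:
        mu = np.nanmean(x)
        sd = np.nanstd(x, ddof=1)
    if sd == 0:
        raise ValueError("zero spread across windows; Z scores undefined")
    out = np.full(v.shape, np.nan)
    out[defined] = (v[defined] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# region merging and diversity summary
# ---------------------------------------------------------------------------

def merge_windows(
    scan: pd.DataFrame,
    transition: Literal["domestication", "improvement"],
    p_column: str | None = None,
) -> list[SweepRegion]:
    """Merge selected windows into non-overlapping sweep regions.

    Overlapping or book-ended selected windows on one chromosome merge;
    each region records its window count and minimum P. Idempotent: the
    merged regions, re-merged, are unchanged.
    """
    if p_column is None:
        p_column = "p_ratio" if transition == "domestication" else "p_bonferroni"
    sel = scan.loc[scan["selected"]].sort_values(["chrom", "start"])
    regions: list[SweepRegion] = []
    cur = None
    for row in sel.itertuples(index=False):
        p = float(getattr(row, p_column, np.nan))
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], int(row.end))
            cur["n"] += 1
            cur["min_p"] = min(cur["min_p"], p)
        else:
            if cur is not None:
                regions.append(_region(cur, transition))
            cur = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "n": 1,
                "min_p": p,
            }
    if cur is not None:
        regions.append(_region(cur, transition))
    return regions


def _region(cur: dict, transition: str) -> SweepRegion:
    return SweepRegion(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        transition=transition,  # type: ignore[arg-type]
        n_windows=cur["n"],
        min_p=cur["min_p"],
    )


def regions_to_bed(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.transition, r.n_windows, r.min_p) for r in regions],
        columns=["chrom", "start", "end", "transition", "n_windows", "min_p"],
    )


def diversity_reduction_summary(
    theta_pi_wild: float,
    theta_pi_landrace: float,
    theta_pi_elite: float,
    theta_pi_cultivated: float,
) -> dict[str, float]:
    """Percent diversity retained and lost across the two transitions.

    All percentages are relative to the wild baseline:
    retention = 100·πcult/πwild; domestication reduction =
    100·(πwild-πlandrace)/πwild; improvement reduction =
    100·(πlandrace-πelite)/πwild. The two reductions telescope to the total
    wild → elite loss.
    """
    if theta_pi_wild <= 0:
        raise ValueError("wild diversity must be positive")
    return {
        "retention_pct": 100.0 * theta_pi_cultivated / theta_pi_wild,
        "domestication_reduction_pct": 100.0
        * (theta_pi_wild - theta_pi_landrace)
        / theta_pi_wild,
        "improvement_reduction_pct": 100.0
        * (theta_pi_landrace - theta_pi_elite)
        / theta_pi_wild,
    }
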