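"""Windowed nucleotide-diversity statistics.

Implements the sliding-window machinery (20 kb windows, 2 kb step by
default) and the three core estimators:

* θπ — average pairwise diversity per nucleotide, summed over segregating
  sites as the unbiased per-site heterozygosity ``n/(n-1) · 2p(1-p)`` and
  divided by the window span;
* θw — Watterson's estimator ``S / (a1 · span)`` with the harmonic number
  ``a1 = Σ_{i<n} 1/i`` for the window's haploid sample size;
* Tajima's D — the standardized difference of the window totals
  ``(Θπ − Θw) / sqrt(e1·S + e2·S·(S−1))`` with Tajima's (1989) constants.

Missing genotypes are handled per site: θπ uses each site's own allele
count, while θw and D take the window's median haploid n for the constants.
Per-site denominators use the full window span; a callable-length mode is
available behind a flag.

Also provides SNV accumulation (rarefaction) curves and site-frequency
spectra.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, PopulationManifest, allele_counts_all, subset_population

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000
DEFAULT_STEP = 2_000


@dataclass(frozen=True)
class GenomicWindow:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class TajimaConstants:
    """Tajima's (1989) normalising constants for haploid sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants require n >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def harmonic_a1(n: int) -> float:
    """a1 = Σ_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def sliding_windows(
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[GenomicWindow]:
    """Full-length sliding windows tiling each chromosome.

    Terminal partial windows are dropped so per-window statistics remain
    comparable; a chromosome shorter than the window yields a single
    whole-chromosome window (logged).
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    out: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        if length < window:
            logger.warning(
                "chromosome %s (%d bp) shorter than window (%d bp); "
                "using one whole-chromosome window",
                chrom, length, window,
            )
            out.append(GenomicWindow(chrom, 0, int(length)))
            continue
        n_windows = (length - window) // step + 1
        for k in range(n_windows):
            out.append(GenomicWindow(chrom, k * step, k * step + window))
    return out


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _window_mask(gm: GenotypeMatrix, window: GenomicWindow) -> np.ndarray:
    return (gm.chrom.astype(str) == window.chrom) & (
        (gm.pos >= window.start + 1) & (gm.pos <= window.end)
    )


def window_slices(
    gm: GenotypeMatrix, windows: Sequence[GenomicWindow]
) -> list[slice]:
    """Site-index slice per window, via binary search on the sorted sites."""
    chroms = gm.chrom.astype(str)
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        offsets[c] = (int(idx[0]), gm.pos[idx])
    out = []
    for w in windows:
        if w.chrom not in offsets:
            out.append(slice(0, 0))
            continue
        off, pos = offsets[w.chrom]
        lo = int(np.searchsorted(pos, w.start + 1, side="left"))
        hi = int(np.searchsorted(pos, w.end, side="right"))
        out.append(slice(off + lo, off + hi))
    return out


def per_site_pi(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site pairwise diversity and segregating-site mask.

    For each site with n ≥ 2 sampled alleles and alt frequency p, the
    contribution is ``n/(n-1) · 2p(1-p)`` (the mean pairwise difference);
    sites with n < 2 contribute 0 and are excluded from the mask.
    """
    n, alt = allele_counts_all(calls)
    pi = np.zeros(calls.shape[1], dtype=np.float64)
    usable = n >= 2
    p = np.zeros_like(pi)
    p[usable] = alt[usable] / n[usable]
    nn = n[usable].astype(np.float64)
    pi[usable] = nn / (nn - 1.0) * 2.0 * p[usable] * (1.0 - p[usable])
    segregating = usable & (alt > 0) & (alt < n)
    return pi, segregating


def theta_pi(
    gm: GenotypeMatrix, window: GenomicWindow, callable_span: int | None = None
) -> float:
    """Per-site pairwise diversity θπ for one window.

    ``callable_span`` replaces the window span as denominator when given
    (callable-length mode); otherwise the full span is used.
    """
    mask = _window_mask(gm, window)
    span = callable_span if callable_span is not None else window.span
    if not mask.any():
        return 0.0
    pi, _ = per_site_pi(gm.calls[:, mask])
    return float(pi.sum() / span)


def theta_w(
    gm: GenotypeMatrix, window: GenomicWindow, callable_span: int | None = None
) -> float:
    """Watterson's θw = S / (a1 · span) using the window's median haploid n."""
    mask = _window_mask(gm, window)
    span = callable_span if callable_span is not None else window.span
    if not mask.any():
        return 0.0
    calls = gm.calls[:, mask]
    n, alt = allele_counts_all(calls)
    seg = (n >= 2) & (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return 0.0
    n_med = int(np.median(n[n >= 2]))
    if n_med < 2:
        return float("nan")
    return float(S / (harmonic_a1(n_med) * span))


def tajimas_d(gm: GenotypeMatrix, window: GenomicWindow) -> float:
    """Tajima's D from window totals; NaN when undefined (S = 0 or n < 4)."""
    mask = _window_mask(gm, window)
    if not mask.any():
        return float("nan")
    calls = gm.calls[:, mask]
    pi, seg = per_site_pi(calls)
    n_arr, _ = allele_counts_all(calls)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n_med = int(np.median(n_arr[n_arr >= 2]))
    if n_med < 4:
        return float("nan")
    const = TajimaConstants.for_n(n_med)
    theta_pi_total = float(pi.sum())
    theta_w_total = S / const.a1
    var = const.e1 * S + const.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((theta_pi_total - theta_w_total) / np.sqrt(var))


def window_stats(
    gm: GenotypeMatrix,
    windows: Sequence[GenomicWindow],
) -> pd.DataFrame:
    """Per-window θπ, θw, Tajima's D, S and median haploid n as a table.

    Vectorised over all windows of all chromosomes; columns follow the
    BED-style export (chrom, start, end, ...).
    """
    pi_site, seg = per_site_pi(gm.calls)
    n_arr, _ = allele_counts_all(gm.calls)
    rows = []
    for w, sl in zip(windows, window_slices(gm, windows)):
        S = int(seg[sl].sum())
        pi_total = float(pi_site[sl].sum())
        n_in = n_arr[sl]
        n_in = n_in[n_in >= 2]
        n_med = int(np.median(n_in)) if n_in.size else 0
        tp = pi_total / w.span
        tw = S / (harmonic_a1(n_med) * w.span) if (S > 0 and n_med >= 2) else 0.0
        if S > 0 and n_med >= 4:
            c = TajimaConstants.for_n(n_med)
            var = c.e1 * S + c.e2 * S * (S - 1)
            d = (pi_total - S / c.a1) / np.sqrt(var) if var > 0 else np.nan
        else:
            d = np.nan
        rows.append((w.chrom, w.start, w.end, tp, tw, d, S, n_med))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end",
            "theta_pi", "theta_w", "tajima_d", "n_segregating", "n_haploid",
        ],
    )


def mean_theta_pi(gm: GenotypeMatrix, total_span: int) -> float:
    """Genome-average per-site θπ over a known total span."""
    pi, _ = per_site_pi(gm.calls)
    return float(pi.sum() / total_span)


# ---------------------------------------------------------------------------
# rarefaction and SFS
# ---------------------------------------------------------------------------

def snv_accumulation(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    group: str,
    k_values: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """SNV discovery (rarefaction) curve for one population group.

    For each subset size k, draws ``reps`` random subsets of accessions and
    counts sites at which at least one sampled accession carries the
    alternate allele. ``exhaustive`` enumerates all C(n, k) subsets instead
    of sampling. Returns a table (k, mean, sd, reps).
    """
    sub = subset_population(gm, manifest, group)
    carrier = sub.calls > 0  # het or hom-alt
    n = sub.n_samples
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        if not (1 <= k <= n):
            raise ValueError(f"k = {k} outside [1, {n}]")
        if k == n:
            counts = np.array([int(np.any(carrier, axis=0).sum())], dtype=float)
            n_draws = 1
        elif exhaustive:
            counts = np.array(
                [
                    int(np.any(carrier[list(combo), :], axis=0).sum())
                    for combo in itertools.combinations(range(n), k)
                ],
                dtype=float,
            )
            n_draws = len(counts)
        else:
            counts = np.empty(reps, dtype=float)
            for r in range(reps):
                idx = rng.choice(n, size=k, replace=False)
                counts[r] = np.any(carrier[idx, :], axis=0).sum()
            n_draws = reps
        rows.append((k, float(counts.mean()), float(counts.std(ddof=0)), n_draws))
    return pd.DataFrame(rows, columns=["k", "mean", "sd", "reps"])


def sfs(
    gm: GenotypeMatrix,
    site_indices: Sequence[int] | np.ndarray | None = None,
    folded: bool = False,
) -> np.ndarray:
    """Site-frequency spectrum: histogram of alternate-allele counts.

    The alternate allele is treated as derived (reference = ancestral).
    Sites with fewer than 2 sampled alleles are skipped. Bin i of the
    returned array counts sites with alt (or minor, when folded) count i;
    length is max observed n + 1.
    """
    calls = gm.calls if site_indices is None else gm.calls[:, list(site_indices)]
    if calls.shape[1] == 0:
        return np.zeros(0, dtype=np.int64)
    n, alt = allele_counts_all(calls)
    ok = n >= 2
    n, alt = n[ok], alt[ok]
    if n.size == 0:
        return np.zeros(0, dtype=np.int64)
    if folded:
        alt = np.minimum(alt, n - alt)
    spectrum = np.bincount(alt, minlength=int(n.max()) + 1)
    return spectrum.astype(np.int64)
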