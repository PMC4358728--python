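"""Fst/PBS estimators, the two sweep scans, and region merging."""

import numpy as np
import pandas as pd
import pytest

from soysweep import diversity, scan
from soysweep.genotype import PopulationManifest
from soysweep.scan import (
    diversity_reduction_summary,
    domestication_scan,
    fst,
    improvement_scan,
    merge_windows,
    pbs,
)
from soysweep.simulate import SimConfig, simulate_populations

from conftest import gm_from_calls


def _two_pop(calls_a, calls_b):
    calls = np.vstack([calls_a, calls_b]).astype(np.int8)
    names = [f"a{i}" for i in range(len(calls_a))] + [f"b{i}" for i in range(len(calls_b))]
    gm = gm_from_calls(calls, samples=names)
    manifest = PopulationManifest(
        {s: ("wild" if s.startswith("a") else "elite") for s in names}
    )
    return gm, manifest


class TestFst:
    def test_identical_frequencies_effectively_zero(self):
        """Equal allele frequencies: the unbiased estimator is ≤ 0 (small
        negative from the finite-sample correction) and clamps to 0 as PBS
        input; at large n it converges to 0."""
        a = [[0, 1, 2], [2, 1, 0], [1, 1, 1]]
        gm, manifest = _two_pop(a, a)
        w = diversity.GenomicWindow("chr01", 0, 10)
        value = fst(gm, w, manifest, "wild", "elite")
        assert -0.5 < value <= 0.0
        assert pbs(value, value, value) == 0.0
        big = [[0, 1, 2]] * 200 + [[2, 1, 0]] * 200 + [[1, 1, 1]] * 200
        gm2, manifest2 = _two_pop(big, big)
        assert fst(gm2, w, manifest2, "wild", "elite") == pytest.approx(0.0, abs=1e-2)

    def test_fixed_difference_approaches_one(self):
        a = [[0] * 3] * 20
        b = [[2] * 3] * 20
        gm, manifest = _two_pop(a, b)
        w = diversity.GenomicWindow("chr01", 0, 10)
        assert fst(gm, w, manifest, "wild", "elite") == pytest.approx(1.0, abs=1e-9)

    def test_single_site_hudson_oracle(self):
        """p_A=0.2, p_B=0.8, 10+10 haplotypes: independently coded
        numerator/denominator of the Hudson (1992) estimator."""
        a = [[2], [0], [0], [0], [0]]  # alt 2/10
        b = [[0], [2], [2], [2], [2]]  # alt 8/10
        gm, manifest = _two_pop(a, b)
        p1, p2, n1, n2 = 0.2, 0.8, 10, 10
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        w = diversity.GenomicWindow("chr01", 0, 10)
        assert fst(gm, w, manifest, "wild", "elite") == pytest.approx(num / den, abs=1e-12)

    def test_single_site_weir_cockerham_oracle(self):
        """Same table under the Weir & Cockerham (1984) components, coded
        independently from the 1984 paper's a, b, c expressions."""
        a = [[2], [0], [0], [0], [0]]
        b = [[0], [2], [2], [2], [2]]
        gm, manifest = _two_pop(a, b)
        n1 = n2 = 5.0  # diploid individuals
        p1, p2 = 0.2, 0.8
        h1 = h2 = 0.0  # no heterozygotes in the fixture
        n_bar = (n1 + n2) / 2
        n_c = (2 * n_bar - (n1**2 + n2**2) / (2 * n_bar)) / (2 - 1)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((2 - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a_comp = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1)
        )
        b_comp = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c_comp = h_bar / 2
        expected = a_comp / (a_comp + b_comp + c_comp)
        w = diversity.GenomicWindow("chr01", 0, 10)
        got = fst(gm, w, manifest, "wild", "elite", estimator="weir_cockerham")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_usable_sites_nan(self):
        gm, manifest = _two_pop([[-1]], [[0]])
        w = diversity.GenomicWindow("chr01", 0, 10)
        assert np.isnan(fst(gm, w, manifest, "wild", "elite"))


class TestPbs:
    def test_all_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_closed_form(self):
        """(-ln 0.5 - ln 0.5 - 0)/2 = ln 2 evaluated independently."""
        assert pbs(0.5, 0.5, 0.0) == pytest.approx(0.6931471805599453, abs=1e-12)

    def test_swapping_non_focal_populations_invariant(self):
        assert pbs(0.3, 0.6, 0.2) == pytest.approx(pbs(0.6, 0.3, 0.2), abs=1e-12)

    def test_fst_near_one_capped_finite(self):
        assert np.isfinite(pbs(1.0, 0.5, 0.1))

    def test_negative_fst_clamped(self):
        assert pbs(-0.05, 0.0, 0.0) == 0.0


class TestDomesticationScan:
    def test_injected_sweep_is_selected_and_genome_minimum(self, swept_sim):
        r = swept_sim
        windows = diversity.sliding_windows({"chr01": 1_000_000})
        df = domestication_scan(r.matrix, r.manifest, windows)
        sweep = r.truth.swept_regions[0]  # domestication at 300-340 kb
        in_sweep = (df["start"] < sweep.end) & (df["end"] > sweep.start)
        assert df.loc[in_sweep, "selected"].any()
        # the focal window attains the genome-minimum log ratio
        i_min = df["log_ratio"].idxmin()
        assert in_sweep[i_min]

    def test_null_false_selection_bounded(self):
        """Wild and 'cultivated' drawn from one panmictic population: the
        joint selected fraction stays below 2·α² + 0.01 over 20 seeds
        (loose bound: the two statistics are positively dependent)."""
        fracs = []
        for seed in range(20):
            r = simulate_populations(
                SimConfig(
                    n_chrom=1, chrom_length=1_000_000,
                    bottleneck_domestication=1.0, bottleneck_improvement=1.0,
                    seed=300 + seed,
                )
            )
            windows = diversity.sliding_windows({"chr01": 1_000_000})
            df = domestication_scan(r.matrix, r.manifest, windows)
            fracs.append(df["selected"].mean())
        assert np.mean(fracs) <= 2 * 0.05**2 + 0.01

    def test_exclusion_list_drops_samples(self, neutral_sim):
        r = neutral_sim
        windows = diversity.sliding_windows({"chr01": 300_000})
        df_all = domestication_scan(r.matrix, r.manifest, windows)
        df_excl = domestication_scan(
            r.matrix, r.manifest, windows, exclude_samples=["L01", "E01"]
        )
        assert not np.allclose(df_all["pi_cultivated"], df_excl["pi_cultivated"])
        assert np.allclose(df_all["pi_wild"], df_excl["pi_wild"])

    def test_too_few_windows_errors(self):
        gm = gm_from_calls(np.ones((4, 3), dtype=np.int8), samples=list("abcd"))
        manifest = PopulationManifest(
            {"a": "wild", "b": "wild", "c": "landrace", "d": "elite"}
        )
        with pytest.raises(ValueError, match="defined windows"):
            domestication_scan(gm, manifest, [diversity.GenomicWindow("chr01", 0, 3)])


class TestImprovementScan:
    def test_injected_sweep_attains_genome_max_pbs(self, swept_sim):
        r = swept_sim
        windows = diversity.sliding_windows({"chr01": 1_000_000})
        df = improvement_scan(r.matrix, r.manifest, windows)
        sweep = r.truth.swept_regions[1]  # improvement at 700-740 kb
        in_sweep = (df["start"] < sweep.end) & (df["end"] > sweep.start)
        i_max = df["pbs_elite"].idxmax()
        assert in_sweep[i_max]
        assert df.loc[in_sweep, "selected"].any()

    def test_null_no_selection(self):
        """Landrace and elite drawn from the same population: no window
        survives Bonferroni P < 0.001 in at least 19 of 20 seeds."""
        clean = 0
        for seed in range(20):
            r = simulate_populations(
                SimConfig(
                    n_chrom=1, chrom_length=1_000_000,
                    bottleneck_improvement=1.0, seed=400 + seed,
                )
            )
            windows = diversity.sliding_windows({"chr01": 1_000_000})
            df = improvement_scan(r.matrix, r.manifest, windows)
            clean += int(df["selected"].sum() == 0)
        assert clean >= 19

    def test_bonferroni_equals_raw_times_windows(self, swept_sim):
        windows = diversity.sliding_windows({"chr01": 1_000_000})
        df = improvement_scan(swept_sim.matrix, swept_sim.manifest, windows)
        n_def = int(np.isfinite(df["pbs_elite"]).sum())
        expected = np.minimum(1.0, df["p_raw"] * n_def)
        assert np.allclose(df["p_bonferroni"], expected, equal_nan=True)


def brute_force_union(intervals):
    """Per-base bitmap union of half-open intervals on one chromosome."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    bitmap = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        bitmap[s:e] = True
    out, start = [], None
    for i, b in enumerate(bitmap):
        if b and start is None:
            start = i
        elif not b and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, hi))
    return out


class TestMergeWindows:
    def _scan_frame(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "p_ratio"])
        df["selected"] = True
        return df

    def test_overlapping_windows_union(self):
        df = self._scan_frame([("chr01", 0, 20_000, 0.01), ("chr01", 2_000, 22_000, 0.02)])
        regions = merge_windows(df, "domestication")
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 22_000)
        assert regions[0].span == 22_000
        assert regions[0].n_windows == 2
        assert regions[0].min_p == 0.01

    def test_distant_windows_stay_separate(self):
        df = self._scan_frame([("chr01", 0, 20_000, 0.01), ("chr01", 120_000, 140_000, 0.01)])
        assert len(merge_windows(df, "domestication")) == 2

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(200, size=30, replace=False)) * 1_000
        rows = [("chr01", int(s), int(s) + 20_000, 0.01) for s in starts]
        regions = merge_windows(self._scan_frame(rows), "domestication")
        expected = brute_force_union([(r[1], r[2]) for r in rows])
        assert [(r.start, r.end) for r in regions] == expected

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        starts = np.sort(rng.choice(100, size=20, replace=False)) * 2_000
        rows = [("chr01", int(s), int(s) + 20_000, 0.01) for s in starts]
        once = merge_windows(self._scan_frame(rows), "domestication")
        again = merge_windows(
            self._scan_frame([(r.chrom, r.start, r.end, r.min_p) for r in once]),
            "domestication",
        )
        assert [(r.start, r.end) for r in once] == [(r.start, r.end) for r in again]


class TestDiversityReduction:
    def test_reported_series(self):
        """Printed θπ averages give 58.6% retention and 37.5% / 8.3%
        reductions to one decimal place."""
        out = diversity_reduction_summary(3.84e-3, 2.40e-3, 2.08e-3, 2.25e-3)
        assert round(out["retention_pct"], 1) == 58.6
        assert round(out["domestication_reduction_pct"], 1) == 37.5
        assert round(out["improvement_reduction_pct"], 1) == 8.3

    def test_equal_diversities(self):
        out = diversity_reduction_summary(1e-3, 1e-3, 1e-3, 1e-3)
        assert out["retention_pct"] == 100.0
        assert out["domestication_reduction_pct"] == 0.0
        assert out["improvement_reduction_pct"] == 0.0

    def test_reductions_telescope(self):
        out = diversity_reduction_summary(4e-3, 2.5e-3, 2e-3, 2.2e-3)
        total = 100 * (4e-3 - 2e-3) / 4e-3
        assert out["domestication_reduction_pct"] + out["improvement_reduction_pct"] == (
            pytest.approx(total, abs=1e-9)
        )

    def test_zero_wild_errors(self):
        with pytest.raises(ValueError):
            diversity_reduction_summary(0.0, 1e-3, 1e-3, 1e-3)
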