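import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promedip.array_model import ProbeSet, PromoterAnnotation, TSSWindow, normalize_center
from promedip.ks_peakcaller import (
    Peak,
    call_hypomethylated,
    call_peaks,
    call_promoters,
    classify_methylation_location,
    ks_probe_scores,
    one_sided_ks,
    promoter_methylated,
)


def _flat_probeset(ratios, spacing=100, length=50, chrom="chr1"):
    rows = [
        (chrom, i * spacing, i * spacing + length, float(r)) for i, r in enumerate(ratios)
    ]
    return ProbeSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio"]))


class TestOneSidedKS:
    def test_window_identical_to_background_multiset(self):
        win = [0.1, 0.5, 0.9]
        res = one_sided_ks(win, win * 10)
        assert res.d_statistic == 0.0
        assert res.p_value == 1.0

    def test_complete_separation(self, rng):
        bg = rng.normal(0, 1, 1000)
        win = bg.max() + 1 + rng.random(10)
        res = one_sided_ks(win, bg)
        assert res.d_statistic == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_exact_null_matches_independent_exact_oracle(self, rng):
        """The lattice-path DP reproduces scipy's exact one-sided two-sample tail."""
        for _ in range(20):
            win = rng.normal(0.2, 1, int(rng.integers(3, 9)))
            bg = rng.normal(0, 1, 40)
            ours = one_sided_ks(win, bg, method="exact")
            ref = stats.ks_2samp(bg, win, alternative="greater", method="exact")
            assert ours.d_statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_analytic_p_tracks_permutation_oracle(self, rng):
        for _ in range(10):
            win = rng.normal(0, 1, 5)
            bg = rng.normal(0, 1, 30)
            analytic = one_sided_ks(win, bg).p_value
            perm = one_sided_ks(win, bg, method="permutation", n_permutations=20_000, rng=rng).p_value
            mc_sd = np.sqrt(perm * (1 - perm) / 20_000)
            assert abs(analytic - perm) <= 0.10 * perm + 4 * mc_sd

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            one_sided_ks([], [1.0, 2.0])


class TestKsProbeScores:
    def test_flat_array_scores_nothing(self):
        prof = ks_probe_scores(_flat_probeset(np.zeros(100)))
        assert np.all(prof["p"] == 1.0)

    def test_planted_block_in_noiseless_array(self):
        ratios = np.zeros(200)
        ratios[100:110] = 2.0  # 1-kb block at 100-bp spacing
        prof = ks_probe_scores(_flat_probeset(ratios))
        block = prof.iloc[102:108]  # interior probes: windows fully inside the block
        flank = pd.concat([prof.iloc[:90], prof.iloc[120:]])
        assert np.all(block["p"] <= 0.01)
        assert np.all(flank["p"] > 0.5)

    def test_invariant_to_additive_shift(self, rng):
        ratios = rng.normal(size=300)
        a = ks_probe_scores(_flat_probeset(ratios))
        b = ks_probe_scores(_flat_probeset(ratios + 5.0))
        assert np.allclose(a["p"], b["p"]) and np.allclose(a["d"], b["d"])

    def test_rank_based_invariance_under_monotone_transform(self, rng):
        ratios = rng.normal(size=300)
        a = ks_probe_scores(_flat_probeset(ratios))
        b = ks_probe_scores(_flat_probeset(np.exp(ratios)))
        assert np.allclose(a["p"], b["p"])

    def test_sparse_windows_left_unscored(self):
        # probes 1 kb apart: each 750-bp window holds only the probe itself
        ps = _flat_probeset(np.random.default_rng(0).normal(size=20), spacing=1000)
        prof = ks_probe_scores(ps)
        assert np.all(~prof["scored"]) and np.all(prof["p"] == 1.0)


def _brute_force_peaks(profile, p_cutoff=0.01, min_probes=2, max_gap=1000):
    """Independent run scanner over the scored probe table."""
    peaks = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        run = []
        rows = list(sub.itertuples(index=False))
        for row in rows:
            if row.p <= p_cutoff and (
                not run or row.midpoint - run[-1].midpoint <= max_gap
            ):
                run.append(row)
            else:
                if len(run) >= min_probes:
                    peaks.append((chrom, run[0].start, run[-1].end, len(run)))
                run = [row] if row.p <= p_cutoff else []
        if len(run) >= min_probes:
            peaks.append((chrom, run[0].start, run[-1].end, len(run)))
    return peaks


class TestCallPeaks:
    def _profile(self, pvals, spacing=100):
        n = len(pvals)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * spacing,
                "end": np.arange(n) * spacing + 50,
                "midpoint": np.arange(n) * spacing + 25.0,
                "p": pvals,
            }
        )

    def test_two_adjacent_qualifying_probes_form_one_peak(self):
        peaks = call_peaks(self._profile([0.5, 0.005, 0.008, 0.5]))
        assert len(peaks) == 1
        assert peaks[0].n_probes == 2
        assert peaks[0].min_p == pytest.approx(0.005)

    def test_isolated_probe_is_not_a_peak(self):
        assert call_peaks(self._profile([0.5, 0.001, 0.5])) == []

    def test_gap_breaks_runs(self):
        prof = self._profile([0.001, 0.001, 0.001, 0.001], spacing=100)
        prof.loc[2:, ["start", "end", "midpoint"]] += 5000
        peaks = call_peaks(prof, max_gap_bp=1000)
        assert len(peaks) == 2 and all(p.n_probes == 2 for p in peaks)

    def test_matches_bruteforce_run_scanner_on_random_profiles(self, rng):
        for _ in range(200):
            pvals = rng.random(int(rng.integers(5, 40))) ** 2
            prof = self._profile(pvals)
            got = [(p.chrom, p.start, p.end, p.n_probes) for p in call_peaks(prof)]
            assert got == _brute_force_peaks(prof)


class TestPromoterCalls:
    GENE = PromoterAnnotation("g", "chr1", 10_000, "+")
    WIN = TSSWindow(-1000, 0)

    def test_single_replicate_peak_is_not_enough(self):
        pk = [Peak("chr1", 9400, 9600, 3, 1e-4)]
        assert not promoter_methylated(self.GENE, pk, [], self.WIN)
        assert promoter_methylated(self.GENE, pk, pk, self.WIN)

    def test_overlap_is_half_open(self):
        touching = [Peak("chr1", 10_000, 10_200, 2, 1e-3)]  # starts exactly at TSS
        assert not promoter_methylated(self.GENE, touching, touching, self.WIN)
        assert promoter_methylated(self.GENE, touching, touching, TSSWindow(0, 1000))

    def test_minus_strand_window_maps_upstream(self):
        gene = PromoterAnnotation("g", "chr1", 10_000, "-")
        upstream_peak = [Peak("chr1", 10_200, 10_400, 2, 1e-3)]  # genomic right = upstream
        assert promoter_methylated(gene, upstream_peak, upstream_peak, self.WIN)
        assert not promoter_methylated(gene, upstream_peak, upstream_peak, TSSWindow(0, 1000))

    def test_location_categories(self):
        up = [Peak("chr1", 9100, 9400, 3, 1e-3)]  # rel [-900, -600)
        span = [Peak("chr1", 9800, 10_300, 4, 1e-3)]  # rel [-200, +300)
        assert classify_methylation_location(self.GENE, up, up) == "up_only"
        assert classify_methylation_location(self.GENE, span, span) == "tss_both"
        assert classify_methylation_location(self.GENE, [], []) == "none"


class TestCallHypomethylated:
    def _profile(self, pvals, start=9000, spacing=100):
        n = len(pvals)
        pos = start + np.arange(n) * spacing
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": pos,
                "end": pos + 50,
                "midpoint": pos + 25.0,
                "p": pvals,
            }
        )

    GENE = PromoterAnnotation("g", "chr1", 10_000, "+")

    def test_all_probes_confidently_nonenriched(self):
        prof = self._profile(np.ones(8), start=9100)
        assert call_hypomethylated(self.GENE, prof, prof) == "yes"

    def test_single_uncertain_probe_in_one_replicate_vetoes(self):
        clean = self._profile(np.ones(8), start=9100)
        dirty = clean.copy()
        dirty.loc[3, "p"] = 0.5
        assert call_hypomethylated(self.GENE, clean, dirty) == "no"

    def test_insufficient_coverage_gives_no_call(self):
        prof = self._profile(np.ones(2), start=9400)
        assert call_hypomethylated(self.GENE, prof, prof) == "no_call"


class TestSimulatedCallsAgainstOracle:
    def test_call_promoters_equals_pergene_operations(self, fast_profiles, fast_promoters):
        """The indexed batch caller agrees with the per-gene interval logic."""
        prof1, prof2 = fast_profiles
        calls = call_promoters(fast_promoters, prof1, prof2, stage="MBT")
        pk1, pk2 = call_peaks(prof1), call_peaks(prof2)
        region = TSSWindow(-5000, 1000)
        for gene, call in zip(fast_promoters, calls):
            assert call.methylated == promoter_methylated(gene, pk1, pk2, region)
            expected_cat = (
                classify_methylation_location(gene, pk1, pk2) if call.methylated else "none"
            )
            assert call.category == expected_cat
            assert call.hypomethylated == call_hypomethylated(gene, prof1, prof2)

    def test_methylated_set_monotone_in_p_cutoff(self, fast_profiles, fast_promoters):
        prof1, prof2 = fast_profiles
        strict = {
            c.gene_id
            for c in call_promoters(fast_promoters, prof1, prof2, p_cutoff=0.001)
            if c.methylated
        }
        loose = {
            c.gene_id
            for c in call_promoters(fast_promoters, prof1, prof2, p_cutoff=0.01)
            if c.methylated
        }
        assert strict <= loose

    def test_no_promoter_both_upstream_methylated_and_hypomethylated(
        self, fast_profiles, fast_promoters
    ):
        prof1, prof2 = fast_profiles
        calls = call_promoters(fast_promoters, prof1, prof2)
        assert not any(
            c.category in ("up_only", "tss_both") and c.hypomethylated == "yes" for c in calls
        )

    def test_null_probe_fraction_below_cutoff_is_calibrated(self):
        """Under a global null, ~<=1% of probes (plus smoothing inflation) pass p<=0.01."""
        from promedip import SimulationConfig, assign_truth, simulate_tiling_experiment

        cfg = SimulationConfig.fast(
            n_genes=100,
            seed=9,
            fraction_hypomethylated=0.0,
            fraction_methylated={"pre_MBT": 0.0, "MBT": 0.0, "post_MBT": 0.0},
            mosaic_fraction=0.0,
        )
        rep1, _ = simulate_tiling_experiment(cfg, assign_truth(cfg), stages=["MBT"])["MBT"]
        prof = ks_probe_scores(normalize_center(rep1))
        assert (prof["p"] <= 0.01).mean() <= 0.02
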