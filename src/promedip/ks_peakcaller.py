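"""Windowed one-sided Kolmogorov-Smirnov probe scoring and peak calling.

The enrichment statistic for a probe is the one-sided two-sample KS
statistic ``D+ = sup_x [F_bg(x) - F_win(x)]`` comparing the log2 ratios
of all probes within a genomic window centered on the probe (default
750 bp) against the rest of the array.  Large ``D+`` means the window
distribution is stochastically larger than the background, i.e. locally
MeDIP-enriched.  The probe's score is the p-value of the windowed test.

Three null models are available for the p-value:

``asymptotic``
    ``p = exp(-2 d^2 m n / (m + n))``, the first-order large-sample tail.
    This smooth score is the one used for array scoring: it reproduces the
    NimbleScan-style semantics in which confidently *non*-enriched probes
    carry p-values arbitrarily close to 1, which the hypomethylation call
    (all window probes p >= 0.99 in both replicates) relies on.  Under an
    exact finite-sample null, ``P(D+ > 0)`` is bounded away from 1 for
    small windows, so p >= 0.99 would be unattainable and the rule
    degenerate; only the smooth asymptotic score makes it meaningful.

``exact``
    Exact finite-sample tail probability ``P(D+ >= d)`` under the
    permutation null for continuous data, computed by a lattice-path
    count over all interleavings (O(m*n) dynamic program).  Default for
    standalone two-sample tests at feasible sizes; agrees with a
    permutation oracle up to Monte-Carlo error.

``permutation``
    Monte-Carlo label-shuffle estimate with add-one smoothing.

Peaks are maximal runs of >= 2 consecutive probes with p <= 0.01, and a
promoter is scored methylated when the TSS-relative analysis window
overlaps at least one peak in both MeDIP replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np
import pandas as pd

from .array_model import ProbeSet, PromoterAnnotation, TSSWindow

__all__ = [
    "KSResult",
    "Peak",
    "MethylationCall",
    "one_sided_ks",
    "ks_probe_scores",
    "call_peaks",
    "promoter_methylated",
    "classify_methylation_location",
    "call_hypomethylated",
    "call_promoters",
    "write_peaks_bed",
]

# Window-size floor below which a probe is left unscored (p = 1): an
# "all probes" rule over a near-empty window would be vacuous.
DEFAULT_MIN_WINDOW_PROBES = 4
# Runs of qualifying probes are broken across tiling gaps larger than this.
DEFAULT_MAX_GAP_BP = 1000
# Exact DP budget: m*n lattice cells.
_EXACT_BUDGET = 2_000_000


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    method: str
    n_window: int
    n_background: int


@dataclass(frozen=True)
class Peak:
    """Maximal run of consecutively enriched probes."""

    chrom: str
    start: int
    end: int
    n_probes: int
    min_p: float


@dataclass(frozen=True)
class MethylationCall:
    gene_id: str
    stage: str
    methylated: bool
    category: str  # up_only | down_only | tss_both | none
    hypomethylated: str  # yes | no | no_call


def _dplus(window_values: np.ndarray, background_sorted: np.ndarray) -> float:
    """One-sided statistic sup_x [F_bg(x) - F_win(x)], clamped to [0, 1].

    The supremum is attained just below a window value, so it suffices to
    evaluate ``F_bg(x^-) - F_win(x^-)`` at each window value (ties handled
    by counting strictly smaller values on both sides).
    """
    win = np.sort(np.asarray(window_values, dtype=float))
    m = win.size
    n = background_sorted.size
    f_bg = np.searchsorted(background_sorted, win, side="left") / n
    f_win = np.searchsorted(win, win, side="left") / m
    d = float(np.max(f_bg - f_win))
    return min(1.0, max(0.0, d))


def _asymptotic_p(d: float, m: int, n: int) -> float:
    p = exp(-2.0 * d * d * m * n / (m + n))
    return min(1.0, max(np.nextafter(0.0, 1.0), p))


def _exact_p(d: float, m: int, n: int) -> float:
    """Exact P(D+ >= d) for continuous data by counting lattice paths.

    An interleaving of the pooled order statistics avoids {D+ >= d} iff at
    the moment the (k+1)-th window value is placed (0-based k) with j
    background values already placed, ``j/n - k/m < d``.  Paths are counted
    with a DP over (window placed, background placed), normalized by
    C(m+n, m).  Survival probabilities are propagated as path fractions to
    stay in floating range.
    """
    if d <= 0.0:
        return 1.0
    # dp[j] = probability mass of partial orderings with i window and j
    # background values placed that never hit the rejection boundary.
    dp = np.zeros(n + 1)
    dp[:] = 0.0
    dp[0] = 1.0
    # Transition weights follow the hypergeometric draw-without-replacement
    # process: given i window and j background placed, the next pooled value
    # is a window value w.p. (m-i)/(m+n-i-j).
    for j in range(1, n + 1):
        dp[j] = dp[j - 1] * (n - j + 1) / (m + n - j + 1)
    for i in range(1, m + 1):
        new = np.zeros(n + 1)
        k = i - 1
        # placing window value k is allowed only while j/n - k/m < d
        for j in range(0, n + 1):
            total = 0.0
            if j > 0:
                total += new[j - 1] * (n - j + 1) / (m + n - i - j + 1)
            if j / n - k / m < d - 1e-12:
                total += dp[j] * (m - i + 1) / (m + n - i - j + 1)
            new[j] = total
        dp = new
    return min(1.0, max(0.0, 1.0 - float(dp[n])))


def _permutation_p(
    window_values: np.ndarray,
    background_values: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo label-shuffle p-value (rank-based, assumes continuous data)."""
    win = np.asarray(window_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    m, n = win.size, bg.size
    d0 = _dplus(win, np.sort(bg))
    total = m + n
    k = np.arange(m)
    exceed = 0
    chunk = max(1, min(n_permutations, int(2e7 // total)))
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        u = rng.random((c, total))
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        r = np.sort(idx, axis=1)  # pooled ranks of the permuted window sample
        d = np.clip(((r - k) / n - k / m).max(axis=1), 0.0, None)
        exceed += int(np.sum(d >= d0 - 1e-12))
        done += c
    return (1 + exceed) / (n_permutations + 1)


def one_sided_ks(
    window_values,
    background_values,
    method: str = "auto",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> KSResult:
    """One-sided two-sample KS test: is the window stochastically larger?

    Returns the statistic ``D+ = sup_x [F_bg(x) - F_win(x)]`` and its
    p-value.  ``method`` is ``auto`` (exact finite-sample null when
    ``m*n`` is small enough, else asymptotic), ``exact``, ``asymptotic``
    or ``permutation``.
    """
    win = np.asarray(window_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    if win.size == 0:
        raise ValueError("window sample is empty")
    if bg.size == 0:
        raise ValueError("background sample is empty")
    m, n = int(win.size), int(bg.size)
    d = _dplus(win, np.sort(bg))
    if method == "auto":
        method = "exact" if m * n <= _EXACT_BUDGET else "asymptotic"
    if method == "asymptotic":
        p = _asymptotic_p(d, m, n)
    elif method == "exact":
        p = _exact_p(d, m, n)
    elif method == "permutation":
        if rng is None:
            rng = np.random.default_rng()
        p = _permutation_p(win, bg, n_permutations, rng)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return KSResult(d, max(p, np.nextafter(0.0, 1.0)), method, m, n)


def _tie_safe_rank_base(w_sorted: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per row: number of values strictly smaller than each sorted entry."""
    nrow, ncol = w_sorted.shape
    idx = np.broadcast_to(np.arange(ncol), (nrow, ncol))
    new_run = np.ones_like(w_sorted, dtype=bool)
    new_run[:, 1:] = w_sorted[:, 1:] != w_sorted[:, :-1]
    starts = np.where(new_run, idx, 0)
    starts = np.maximum.accumulate(starts, axis=1)
    return np.where(valid, starts, 0)


def ks_probe_scores(
    ps: ProbeSet,
    window_bp: int = 750,
    min_window_probes: int = DEFAULT_MIN_WINDOW_PROBES,
    p_method: str = "asymptotic",
    background: str = "array",
) -> pd.DataFrame:
    """Score every probe with the windowed one-sided KS test.

    For each probe, the window sample is the set of ratios of all probes
    (on the same chromosome) whose midpoint lies within ``window_bp/2`` of
    the probe midpoint; the background is every other probe on the array
    (``background="array"``) or on the same chromosome
    (``background="chrom"``).  Probes with fewer than ``min_window_probes``
    window members are left unscored (p = 1, ``scored = False``).

    Returns the KS profile: one row per probe with columns ``chrom``,
    ``start``, ``end``, ``midpoint``, ``ratio``, ``d``, ``p``,
    ``n_window``, ``scored``, in probe order.
    """
    if p_method not in ("asymptotic", "exact"):
        raise ValueError("p_method must be 'asymptotic' or 'exact'")
    df = ps.df
    total = len(df)
    if total == 0:
        raise ValueError("empty ProbeSet")
    half = window_bp / 2.0
    all_sorted = np.sort(df["ratio"].to_numpy())

    out_d = np.zeros(total)
    out_p = np.ones(total)
    out_m = np.zeros(total, dtype=np.int64)
    scored = np.zeros(total, dtype=bool)

    for _, sub in df.groupby("chrom", sort=False):
        pos = sub.index.to_numpy()
        mids = 0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy())
        ratios = sub["ratio"].to_numpy()
        order = np.argsort(mids, kind="stable")  # coordinate order != midpoint order for mixed lengths
        pos, mids, ratios = pos[order], mids[order], ratios[order]
        a = np.searchsorted(mids, mids - half, side="left")
        b = np.searchsorted(mids, mids + half, side="right")
        m = b - a
        out_m[pos] = m
        ok = m >= min_window_probes
        if not ok.any():
            continue
        if background == "chrom":
            bg_sorted = np.sort(ratios)
            n_total_local = ratios.size
        else:
            bg_sorted = all_sorted
            n_total_local = total

        max_m = int(m[ok].max())
        rows = np.flatnonzero(ok)
        gather = a[rows, None] + np.arange(max_m)[None, :]
        valid = gather < b[rows, None]
        w = np.where(valid, ratios[np.clip(gather, 0, ratios.size - 1)], np.inf)
        w_sorted = np.sort(w, axis=1)
        cwl = _tie_safe_rank_base(w_sorted, valid)  # of window values strictly below
        flat = w_sorted.ravel()
        finite = np.isfinite(flat)
        call = np.zeros(flat.size, dtype=np.int64)
        call[finite] = np.searchsorted(bg_sorted, flat[finite], side="left")
        call = call.reshape(w_sorted.shape)  # of array values strictly below
        mm = m[rows][:, None].astype(float)
        nn = (n_total_local - m[rows])[:, None].astype(float)
        diff = (call - cwl) / nn - cwl / mm
        diff = np.where(valid, diff, -np.inf)
        d = np.clip(diff.max(axis=1), 0.0, 1.0)
        mn = m[rows] * (n_total_local - m[rows])
        if p_method == "asymptotic":
            p = np.exp(-2.0 * d * d * mn / n_total_local)
        else:
            p = np.array([_exact_p(di, int(mi), int(n_total_local - mi)) for di, mi in zip(d, m[rows])])
        out_d[pos[rows]] = d
        out_p[pos[rows]] = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        scored[pos[rows]] = True

    profile = df.copy()
    profile["midpoint"] = 0.5 * (profile["start"] + profile["end"])
    profile["d"] = out_d
    profile["p"] = out_p
    profile["n_window"] = out_m
    profile["scored"] = scored
    profile.attrs["replicate_id"] = ps.replicate_id
    profile.attrs["stage"] = ps.stage
    profile.attrs["window_bp"] = window_bp
    return profile


def call_peaks(
    profile: pd.DataFrame,
    p_cutoff: float = 0.01,
    min_probes: int = 2,
    max_gap_bp: int | None = DEFAULT_MAX_GAP_BP,
) -> list[Peak]:
    """Maximal runs of >= ``min_probes`` consecutive probes with p <= cutoff.

    Consecutive means adjacent in array order on the same chromosome;
    runs are additionally broken where the midpoint gap between adjacent
    probes exceeds ``max_gap_bp`` (tiling discontinuities).  The peak
    interval spans from the first member's start to the last member's end.
    """
    peaks: list[Peak] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        q = (sub["p"].to_numpy() <= p_cutoff)
        mids = sub["midpoint"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pvals = sub["p"].to_numpy()
        i = 0
        n = len(sub)
        while i < n:
            if not q[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and q[j + 1]
                and (max_gap_bp is None or mids[j + 1] - mids[j] <= max_gap_bp)
            ):
                j += 1
            if j - i + 1 >= min_probes:
                peaks.append(
                    Peak(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_probes=int(j - i + 1),
                        min_p=float(pvals[i : j + 1].min()),
                    )
                )
            i = j + 1
    return peaks


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return max(a_start, b_start) < min(a_end, b_end)


def promoter_methylated(
    gene: PromoterAnnotation,
    peaks_rep1: list[Peak],
    peaks_rep2: list[Peak],
    window: TSSWindow,
) -> bool:
    """Replicate-consistent methylation call for one promoter window.

    True iff the strand-aware genomic image of the TSS-relative window
    overlaps at least one peak in replicate 1 AND at least one in
    replicate 2 (non-empty half-open intersection).
    """
    g_lo, g_hi = window.genomic(gene)

    def _hit(peaks: list[Peak]) -> bool:
        return any(
            pk.chrom == gene.chrom and _overlaps(g_lo, g_hi, pk.start, pk.end) for pk in peaks
        )

    return _hit(peaks_rep1) and _hit(peaks_rep2)


def classify_methylation_location(
    gene: PromoterAnnotation,
    peaks_rep1: list[Peak],
    peaks_rep2: list[Peak],
    up: TSSWindow = TSSWindow(-1000, 0),
    down: TSSWindow = TSSWindow(0, 1000),
) -> str:
    """Partition methylated promoters by peak location relative to the TSS.

    ``up_only`` (-1/0 kb), ``down_only`` (0/+1 kb), ``tss_both`` (both
    windows hit) or ``none``.
    """
    u = promoter_methylated(gene, peaks_rep1, peaks_rep2, up)
    d = promoter_methylated(gene, peaks_rep1, peaks_rep2, down)
    if u and d:
        return "tss_both"
    if u:
        return "up_only"
    if d:
        return "down_only"
    return "none"


def _window_probe_mask(profile_chrom: pd.DataFrame, gene: PromoterAnnotation, window: TSSWindow) -> np.ndarray:
    """Probes whose footprint intersects the TSS-relative window.

    Footprint membership (rather than midpoint containment) makes the
    hypomethylation call strictly incompatible with an overlapping peak:
    any peak overlapping the window contains a qualifying probe whose
    footprint lies inside it.
    """
    starts = profile_chrom["start"].to_numpy()
    ends = profile_chrom["end"].to_numpy()
    if gene.strand == "+":
        rel_lo = starts - gene.tss
        rel_hi = ends - gene.tss
    else:
        rel_lo = gene.tss - ends + 1
        rel_hi = gene.tss - starts + 1
    return (rel_lo < window.hi) & (rel_hi > window.lo)


def call_hypomethylated(
    gene: PromoterAnnotation,
    profile_rep1: pd.DataFrame,
    profile_rep2: pd.DataFrame,
    window: TSSWindow = TSSWindow(-1000, 0),
    p_floor: float = 0.99,
    min_probes_present: int = 3,
) -> str:
    """Tri-state hypomethylation call for the upstream promoter window.

    ``yes`` iff the window holds >= ``min_probes_present`` probes and every
    one of them has KS p >= ``p_floor`` in BOTH replicates (confidently
    non-enriched, i.e. below genome-average methylation); ``no_call`` if
    probe coverage is insufficient in either replicate; ``no`` otherwise.
    """
    verdicts = []
    for prof in (profile_rep1, profile_rep2):
        sub = prof[prof["chrom"] == gene.chrom]
        mask = _window_probe_mask(sub, gene, window)
        pvals = sub["p"].to_numpy()[mask]
        if pvals.size < min_probes_present:
            return "no_call"
        verdicts.append(bool(np.all(pvals >= p_floor)))
    return "yes" if all(verdicts) else "no"


class _PeakIndex:
    """Per-chromosome sorted peak intervals for O(log n) overlap queries."""

    def __init__(self, peaks: list[Peak]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[Peak]] = {}
        for pk in peaks:
            grouped.setdefault(pk.chrom, []).append(pk)
        for chrom, pks in grouped.items():
            starts = np.array([pk.start for pk in pks])
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            ends = np.array([pk.end for pk in pks])[order]
            # peaks within a replicate are disjoint, so running max keeps
            # the query correct even if end order is perturbed
            self.by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, g_lo: int, g_hi: int) -> bool:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends_max = entry
        idx = int(np.searchsorted(starts, g_hi, side="left")) - 1
        return idx >= 0 and ends_max[idx] > g_lo


class _ProfileIndex:
    """Per-chromosome probe arrays for fast footprint-window queries."""

    def __init__(self, profile: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        for chrom, sub in profile.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            pvals = sub["p"].to_numpy()[order]
            self.by_chrom[chrom] = (starts, ends, pvals, int((ends - starts).max()))

    def window_pvalues(self, chrom: str, g_lo: int, g_hi: int) -> np.ndarray:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return np.empty(0)
        starts, ends, pvals, max_len = entry
        hi = int(np.searchsorted(starts, g_hi, side="left"))
        lo = int(np.searchsorted(starts, g_lo - max_len, side="left"))
        sl = slice(lo, hi)
        mask = ends[sl] > g_lo
        return pvals[sl][mask]


def call_promoters(
    promoters: list[PromoterAnnotation],
    profile_rep1: pd.DataFrame,
    profile_rep2: pd.DataFrame,
    stage: str = "",
    region: TSSWindow = TSSWindow(-5000, 1000),
    up: TSSWindow = TSSWindow(-1000, 0),
    down: TSSWindow = TSSWindow(0, 1000),
    p_cutoff: float = 0.01,
    min_probes: int = 2,
    hypo_floor: float = 0.99,
    min_probes_present: int = 3,
    max_gap_bp: int | None = DEFAULT_MAX_GAP_BP,
) -> list[MethylationCall]:
    """Full per-promoter calling for one stage (both replicates).

    Peaks are called once per replicate; each promoter is then scored
    methylated on the analysis ``region`` (default -5/+1 kb), located
    into up/down/TSS categories, and tested for hypomethylation on the
    ``up`` window.  Equivalent to looping the per-gene operations, with
    indexed interval queries.
    """
    peaks1 = call_peaks(profile_rep1, p_cutoff=p_cutoff, min_probes=min_probes, max_gap_bp=max_gap_bp)
    peaks2 = call_peaks(profile_rep2, p_cutoff=p_cutoff, min_probes=min_probes, max_gap_bp=max_gap_bp)
    pidx1, pidx2 = _PeakIndex(peaks1), _PeakIndex(peaks2)
    fidx1, fidx2 = _ProfileIndex(profile_rep1), _ProfileIndex(profile_rep2)

    calls = []
    for gene in promoters:
        def _meth(window: TSSWindow) -> bool:
            g_lo, g_hi = window.genomic(gene)
            return pidx1.overlaps(gene.chrom, g_lo, g_hi) and pidx2.overlaps(gene.chrom, g_lo, g_hi)

        methylated = _meth(region)
        if methylated:
            u, d = _meth(up), _meth(down)
            category = "tss_both" if (u and d) else "up_only" if u else "down_only" if d else "none"
        else:
            category = "none"

        g_lo, g_hi = up.genomic(gene)
        hypo = "yes"
        for fidx in (fidx1, fidx2):
            pvals = fidx.window_pvalues(gene.chrom, g_lo, g_hi)
            if pvals.size < min_probes_present:
                hypo = "no_call"
                break
            if not np.all(pvals >= hypo_floor):
                hypo = "no"
        calls.append(MethylationCall(gene.gene_id, stage, methylated, category, hypo))
    return calls


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """Write peaks as BED6 with score = -10*log10(min_p)."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            score = -10.0 * np.log10(max(pk.min_p, 1e-300))
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{i}\t{score:.2f}\t.\n")
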