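"""Promoter-level summaries across developmental stages.

Metagene profiles average log2 MeDIP/input ratios of many genes aligned
at the TSS into fixed-width bins; stage comparisons track which genes
maintain, gain or lose a methylation call between consecutive stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_model import ProbeSet, PromoterAnnotation, TSSWindow, map_probes_to_promoter

__all__ = [
    "MetageneProfile",
    "StageComparison",
    "metagene_profile",
    "median_methylation_level",
    "stage_transitions",
]


@dataclass
class MetageneProfile:
    """Binned average TSS-relative methylation profile.

    ``bin_edges`` has length ``n_bins + 1``; ``mean_ratio[i]`` is the mean
    replicate-averaged ratio of all probes from all genes whose relative
    midpoint falls in ``[bin_edges[i], bin_edges[i+1])`` (NaN for empty
    bins).
    """

    bin_edges: np.ndarray
    mean_ratio: np.ndarray
    n_probes: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean_ratio": self.mean_ratio,
                "n_probes": self.n_probes,
            }
        )


@dataclass
class StageComparison:
    stages: list[str]
    sets: dict[str, set] = field(default_factory=dict)
    maintained: dict[tuple[str, str], set] = field(default_factory=dict)
    gained: dict[tuple[str, str], set] = field(default_factory=dict)
    lost: dict[tuple[str, str], set] = field(default_factory=dict)
    percent_increase: dict[tuple[str, str], float] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = []
        for pair in self.maintained:
            rows.append(
                {
                    "from_stage": pair[0],
                    "to_stage": pair[1],
                    "maintained": len(self.maintained[pair]),
                    "gained": len(self.gained[pair]),
                    "lost": len(self.lost[pair]),
                    "percent_increase": self.percent_increase[pair],
                }
            )
        return pd.DataFrame(rows)


def _averaged_probes(ps_rep1: ProbeSet, ps_rep2: ProbeSet) -> ProbeSet:
    """Replicate-averaged ratios; requires identical probe coordinates."""
    a, b = ps_rep1.df, ps_rep2.df
    if len(a) != len(b) or not (
        a[["chrom", "start", "end"]].reset_index(drop=True).equals(
            b[["chrom", "start", "end"]].reset_index(drop=True)
        )
    ):
        raise ValueError("replicates must share identical probe coordinates")
    return ps_rep1.with_ratios(0.5 * (a["ratio"].to_numpy() + b["ratio"].to_numpy()))


def _gene_qualifies(
    profile: pd.DataFrame, gene: PromoterAnnotation, window: TSSWindow, p_cutoff: float
) -> bool:
    sub = profile[profile["chrom"] == gene.chrom]
    mids = sub["midpoint"].to_numpy()
    rel = mids - gene.tss if gene.strand == "+" else gene.tss - mids
    inside = (rel >= window.lo) & (rel < window.hi)
    return bool(np.any(sub["p"].to_numpy()[inside] <= p_cutoff))


def metagene_profile(
    genes: list[PromoterAnnotation],
    ps_rep1: ProbeSet,
    ps_rep2: ProbeSet,
    window: TSSWindow = TSSWindow(-2000, 2000),
    bin_bp: int = 100,
    profiles: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    p_cutoff: float = 0.01,
) -> MetageneProfile:
    """TSS-aligned average methylation profile over a gene set.

    Replicate ratios are averaged probe-wise before binning.  When KS
    profiles are supplied, gene membership is restricted to genes with
    high enrichment probability: at least one probe with p <= ``p_cutoff``
    inside the window in both replicates.
    """
    if not genes:
        raise ValueError("metagene_profile requires a non-empty gene set")
    span = window.hi - window.lo
    if span % bin_bp != 0:
        raise ValueError(f"bin width {bin_bp} must divide the window span {span}")
    if profiles is not None:
        prof1, prof2 = profiles
        genes = [
            g
            for g in genes
            if _gene_qualifies(prof1, g, window, p_cutoff)
            and _gene_qualifies(prof2, g, window, p_cutoff)
        ]
        if not genes:
            raise ValueError("no gene passes the enrichment-probability filter")

    avg = _averaged_probes(ps_rep1, ps_rep2)
    edges = np.arange(window.lo, window.hi + bin_bp, bin_bp)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in genes:
        mapped = map_probes_to_promoter(avg, gene, window)
        if len(mapped) == 0:
            continue
        idx = np.floor_divide(mapped["rel_pos"].to_numpy() - window.lo, bin_bp).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(sums, idx, mapped["ratio"].to_numpy())
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetageneProfile(edges, means, counts, n_genes=len(genes))


def median_methylation_level(
    genes: list[PromoterAnnotation],
    ps_rep1: ProbeSet,
    ps_rep2: ProbeSet,
    window: TSSWindow = TSSWindow(-1000, 0),
) -> float:
    """Median over genes of the mean replicate-averaged ratio in the window."""
    if not genes:
        raise ValueError("median_methylation_level requires a non-empty gene set")
    avg = _averaged_probes(ps_rep1, ps_rep2)
    gene_means = []
    for gene in genes:
        mapped = map_probes_to_promoter(avg, gene, window)
        if len(mapped):
            gene_means.append(float(mapped["ratio"].mean()))
    if not gene_means:
        return float("nan")
    return float(np.median(gene_means))


def stage_transitions(calls_by_stage: pd.DataFrame, stages: list[str]) -> StageComparison:
    """Maintenance/gain/loss set algebra between consecutive stages.

    ``calls_by_stage`` is a boolean DataFrame indexed by gene id with one
    column per stage (True = gene carries the call at that stage).  For
    each consecutive stage pair the maintained/gained/lost sets are
    reported together with the percent increase
    ``(later - earlier) / earlier * 100``.
    """
    missing = [s for s in stages if s not in calls_by_stage.columns]
    if missing:
        raise ValueError(f"stages absent from call matrix: {missing}")
    if calls_by_stage.index.has_duplicates:
        raise ValueError("duplicate gene ids in call matrix")
    comp = StageComparison(stages=list(stages))
    for s in stages:
        comp.sets[s] = set(calls_by_stage.index[calls_by_stage[s].astype(bool)])
    for earlier, later in zip(stages[:-1], stages[1:]):
        a, b = comp.sets[earlier], comp.sets[later]
        pair = (earlier, later)
        comp.maintained[pair] = a & b
        comp.gained[pair] = b - a
        comp.lost[pair] = a - b
        comp.percent_increase[pair] = (
            100.0 * (len(b) - len(a)) / len(a) if len(a) else float("nan")
        )
    return comp
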