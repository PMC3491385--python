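"""Contingency statistics linking methylation state to genomic features.

Cross-tabulations of promoter methylation/hypomethylation calls against
CpG class, expression cohorts, histone-mark calls and post-ZGA
expression, tested with the two-sided Fisher exact test
(probability-mass extremity criterion) or the Yates-corrected
chi-square.  No multiple-testing correction is applied by default (raw
per-test thresholds); an optional Benjamini-Hochberg helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyResult",
    "fisher_exact_2x2",
    "chisq_yates",
    "proportion_enrichment",
    "mark_by_methylation_table",
    "expression_by_mark_and_methylation",
    "set_overlap_report",
    "benjamini_hochberg",
]

MARKS = ("h3k4me3", "h3k9me3", "h3k27me3")
COHORTS = ("maternal_degraded", "maternal_zygotic", "zygotic", "undetected")


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    test: str
    statistic: float = float("nan")
    continuity_added: bool = False


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    return t.astype(np.int64)


def _sample_odds_ratio(t: np.ndarray) -> tuple[float, bool]:
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        return float(a * d / (b * c)), True
    return float(a * d / (b * c)), False


def fisher_exact_2x2(table, alternative: str = "two-sided") -> ContingencyResult:
    """Fisher's exact test for a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all tables with the
    same margins that are as or less probable than the observed one.  The
    sample odds ratio ``ad/bc`` is reported (0.5 added to every cell only
    when a zero cell would make it degenerate, flagged).
    """
    t = _as_table(table)
    if t.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(t, alternative=alternative)
    oddsr, cont = _sample_odds_ratio(t)
    return ContingencyResult(
        tuple(map(tuple, t.tolist())), oddsr, float(p), "fisher_exact", continuity_added=cont
    )


def chisq_yates(table) -> ContingencyResult:
    """Chi-square test with Yates' continuity correction, 1 df.

    ``chi2 = sum (max(|O - E| - 0.5, 0))^2 / E`` over the four cells.
    Requires all row and column margins positive.
    """
    t = _as_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square requires all margins > 0")
    expected = np.outer(rows, cols) / t.sum()
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    oddsr, cont = _sample_odds_ratio(t)
    return ContingencyResult(
        tuple(map(tuple, t.tolist())),
        oddsr,
        max(p, np.nextafter(0.0, 1.0)),
        "chisq_yates",
        statistic=chi2,
        continuity_added=cont,
    )


def proportion_enrichment(feature_set, background, annotation) -> dict:
    """Is an annotation enriched in a gene set relative to its background?

    Builds the 2x2 table (in/out of ``feature_set``) x (annotated or not)
    where "out" is ``background`` minus the feature set, and applies the
    Fisher exact test.  ``annotation`` maps gene id -> bool (dict or
    pandas Series).  Returns the test result plus both proportions.
    """
    feature_set = set(feature_set)
    background = set(background)
    if not feature_set:
        raise ValueError("empty feature set")
    if not feature_set <= background:
        raise ValueError("feature set must be contained in the background")
    ann = annotation if isinstance(annotation, dict) else annotation.to_dict()
    rest = background - feature_set
    a = sum(bool(ann.get(g, False)) for g in feature_set)
    b = len(feature_set) - a
    c = sum(bool(ann.get(g, False)) for g in rest)
    d = len(rest) - c
    result = fisher_exact_2x2([[a, b], [c, d]])
    return {
        "result": result,
        "proportion_feature": a / len(feature_set),
        "proportion_background": (a + c) / len(background),
        "n_feature": len(feature_set),
        "n_background": len(background),
    }


def _strata(gft: pd.DataFrame, stage: str) -> dict[str, pd.DataFrame]:
    """Mutually exclusive methylation strata for one stage.

    ``no_me`` = promoters with genome-average methylation, i.e. neither
    statistically methylated nor hypomethylated.
    """
    meth = gft[f"methylated_{stage}"].astype(bool)
    hypo = gft[f"hypomethylated_{stage}"] == "yes"
    return {
        "methylated": gft[meth & ~hypo],
        "hypomethylated": gft[hypo & ~meth],
        "no_me": gft[~meth & ~hypo],
    }


def mark_by_methylation_table(gft: pd.DataFrame, stage: str, marks=MARKS) -> dict:
    """Histone-mark proportions across methylation strata, with tests.

    For each mark, reports the proportion of marked promoters within the
    methylated, hypomethylated and genome-average (``no_me``) strata and a
    Fisher test comparing the methylated vs hypomethylated strata.
    Missing strata yield a partial result with a flag.
    """
    strata = _strata(gft, stage)
    out: dict = {"stage": stage, "proportions": {}, "tests": {}, "flags": []}
    for name, sub in strata.items():
        if len(sub) == 0:
            out["flags"].append(f"empty stratum: {name}")
    for mark in marks:
        col = f"{mark}_{stage}"
        if col not in gft.columns:
            out["flags"].append(f"missing mark calls: {col}")
            continue
        props = {}
        for name, sub in strata.items():
            props[name] = float(sub[col].astype(bool).mean()) if len(sub) else float("nan")
        out["proportions"][mark] = props
        me, hy = strata["methylated"], strata["hypomethylated"]
        if len(me) and len(hy):
            a = int(me[col].astype(bool).sum())
            c = int(hy[col].astype(bool).sum())
            out["tests"][mark] = fisher_exact_2x2([[a, len(me) - a], [c, len(hy) - c]])
    return out


def expression_by_mark_and_methylation(gft: pd.DataFrame, stage: str, marks=MARKS) -> dict:
    """Percent of genes expressed post-ZGA by methylation state and marking.

    For every (methylation stratum x mark presence) cell reports the
    percentage of genes with ``expressed_post_zga``; within each stratum,
    marked vs unmarked genes are compared with the Yates-corrected
    chi-square.  Cells with a zero margin are excluded with a flag.
    """
    if "expressed_post_zga" not in gft.columns:
        raise ValueError("expressed_post_zga column required")
    strata = _strata(gft, stage)
    out: dict = {"stage": stage, "percent_expressed": {}, "tests": {}, "flags": []}
    for mark in marks:
        col = f"{mark}_{stage}"
        if col not in gft.columns:
            out["flags"].append(f"missing mark calls: {col}")
            continue
        for name, sub in strata.items():
            if len(sub) == 0:
                continue
            marked = sub[sub[col].astype(bool)]
            unmarked = sub[~sub[col].astype(bool)]
            for label, cell in ((f"{name}|{mark}+", marked), (f"{name}|{mark}-", unmarked)):
                if len(cell):
                    out["percent_expressed"][label] = 100.0 * float(
                        cell["expressed_post_zga"].astype(bool).mean()
                    )
            table = [
                [int(marked["expressed_post_zga"].astype(bool).sum()), int((~marked["expressed_post_zga"].astype(bool)).sum())],
                [int(unmarked["expressed_post_zga"].astype(bool).sum()), int((~unmarked["expressed_post_zga"].astype(bool)).sum())],
            ]
            t = np.asarray(table)
            if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
                out["flags"].append(f"degenerate cell skipped: {name}|{mark}")
                continue
            out["tests"][f"{name}|{mark}"] = chisq_yates(table)
    return out


def set_overlap_report(sets: dict[str, set]) -> dict:
    """Venn region counts, per-set percentages and pairwise Jaccard indices."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("set_overlap_report handles 2 or 3 sets")
    union = set().union(*sets.values())
    regions = {}
    for signature in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if signature >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(sets[n] for n in inside)) - set().union(
            *(sets[n] for n in outside), set()
        )
        regions["&".join(inside)] = len(region)
    percents = {}
    for a, b in combinations(names, 2):
        inter = len(sets[a] & sets[b])
        percents[f"{a}->{b}"] = 100.0 * inter / len(sets[a]) if sets[a] else float("nan")
        percents[f"{b}->{a}"] = 100.0 * inter / len(sets[b]) if sets[b] else float("nan")
    jaccard = {
        f"{a}|{b}": (len(sets[a] & sets[b]) / len(sets[a] | sets[b]) if sets[a] | sets[b] else float("nan"))
        for a, b in combinations(names, 2)
    }
    return {
        "regions": regions,
        "set_sizes": {n: len(sets[n]) for n in names},
        "union_size": len(union),
        "percent_overlap": percents,
        "jaccard": jaccard,
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
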