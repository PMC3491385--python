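"""High/low CpG promoter classification (zebrafish-adapted Takai-Jones scan).

A promoter is classified from its 1-kb upstream sequence: a 500-bp
window slides over the sequence and the promoter is a high-CpG promoter
(HCP) if any window has an observed/expected CpG ratio >= 0.65 and a CG
content > 0.30 (strict); otherwise it is a low-CpG promoter (LCP).

o/e CG ratio of a window of effective length L (N bases excluded from
all counts and from L):

    o/e = N_CpG * L / (N_C * N_G)

with N_CpG the number of overlapping "CG" dinucleotides.  The scan step
defaults to 1 bp (exhaustive); the 10-bp step is used for density
profiling only.  CpG islands over longer regions are maximal merges of
qualifying windows, and a gene sitting in a cluster of >= 3 islands is
flagged (CGI cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PromoterSequence",
    "CpGClass",
    "oe_cg_ratio",
    "cg_content",
    "classify_promoter",
    "cg_density_profile",
    "count_cgi_and_clusters",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class PromoterSequence:
    """1-kb upstream promoter sequence, 5'->3' on the gene's strand, ending at the TSS."""

    gene_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - _ALPHABET:
            raise ValueError(f"{self.gene_id}: sequence contains non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)

    @property
    def short(self) -> bool:
        return len(self.sequence) < 1000


@dataclass(frozen=True)
class CpGClass:
    gene_id: str
    cpg_class: str  # HCP | LCP
    best_offset: int
    best_oe: float
    best_cg: float
    short_sequence: bool = False
    high_n_fraction: bool = False


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(N_C, N_G, N_CpG, effective length) with N positions excluded."""
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return n_c, n_g, n_cg, length


def oe_cg_ratio(seq: str) -> float:
    """Observed/expected CpG ratio ``N_CpG * L / (N_C * N_G)`` (0 if no C or no G)."""
    if len(seq) < 2:
        raise ValueError("oe_cg_ratio requires a sequence of length >= 2")
    n_c, n_g, n_cg, length = _counts(seq.upper())
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cg * length / (n_c * n_g)


def cg_content(seq: str) -> float:
    """Fraction of C+G bases (N excluded from counts and length)."""
    if len(seq) == 0:
        raise ValueError("cg_content requires a non-empty sequence")
    n_c, n_g, _, length = _counts(seq.upper())
    if length == 0:
        return 0.0
    return (n_c + n_g) / length


def _window_stats(seq: str, window_bp: int, step_bp: int):
    """Vectorized per-window (offset, oe, cg, n_fraction) via cumulative counts."""
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = s == ord("C")
    is_g = s == ord("G")
    is_n = s == ord("N")
    is_cg = np.zeros(len(s), dtype=bool)
    if len(s) >= 2:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    cc, cgc, cnn, ccg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    offsets = np.arange(0, len(s) - window_bp + 1, step_bp)
    hi = offsets + window_bp
    n_c = cc[hi] - cc[offsets]
    n_g = cgc[hi] - cgc[offsets]
    n_n = cnn[hi] - cnn[offsets]
    # only CG pairs fully inside the window
    n_cg = ccg[hi - 1] - ccg[offsets]
    length = window_bp - n_n
    denom = n_c * n_g
    oe = np.where(denom > 0, n_cg * length / np.maximum(denom, 1), 0.0)
    cg = np.where(length > 0, (n_c + n_g) / np.maximum(length, 1), 0.0)
    return offsets, oe, cg, n_n / window_bp


def classify_promoter(
    ps: PromoterSequence,
    window_bp: int = 500,
    step_bp: int = 1,
    oe_min: float = 0.65,
    cg_min: float = 0.30,
    cg_strict: bool = True,
) -> CpGClass:
    """Classify a promoter as HCP or LCP by the sliding-window scan.

    HCP iff any full window at offsets {0, step, 2*step, ...} satisfies
    ``oe >= oe_min`` and ``cg > cg_min`` (strict by default, per the
    "content of >0.30" criterion; set ``cg_strict=False`` for inclusive).
    Sequences shorter than the window are LCP with a short-sequence flag.
    The recorded best window maximizes (oe, cg), ties to smallest offset.
    """
    seq = ps.sequence
    if len(seq) < window_bp:
        return CpGClass(ps.gene_id, "LCP", 0, 0.0, 0.0, short_sequence=True)
    offsets, oe, cg, n_frac = _window_stats(seq, window_bp, step_bp)
    cg_ok = cg > cg_min if cg_strict else cg >= cg_min
    qual = (oe >= oe_min) & cg_ok
    cls = "HCP" if bool(qual.any()) else "LCP"
    pool = np.flatnonzero(qual) if qual.any() else np.arange(len(offsets))
    best = pool[np.lexsort((-cg[pool], -oe[pool]))][0]
    return CpGClass(
        ps.gene_id,
        cls,
        int(offsets[best]),
        float(oe[best]),
        float(cg[best]),
        high_n_fraction=bool(n_frac[best] > 0.10),
    )


def cg_density_profile(seq: str, window_bp: int = 500, step_bp: int = 10) -> np.ndarray:
    """Per-offset (offset, cg_content, oe_ratio) records for density plots."""
    seq = seq.upper()
    if len(seq) < window_bp:
        raise ValueError("sequence shorter than the profiling window")
    offsets, oe, cg, _ = _window_stats(seq, window_bp, step_bp)
    out = np.zeros(len(offsets), dtype=[("offset", int), ("cg_content", float), ("oe_ratio", float)])
    out["offset"], out["cg_content"], out["oe_ratio"] = offsets, cg, oe
    return out


def count_cgi_and_clusters(
    region_seq: str,
    window_bp: int = 500,
    step_bp: int = 10,
    oe_min: float = 0.65,
    cg_min: float = 0.30,
    cg_strict: bool = True,
) -> tuple[int, bool, list[tuple[int, int]]]:
    """Count CpG islands in a region and flag CGI clusters (>= 3 islands).

    Islands are maximal merges of qualifying windows: windows whose spans
    overlap or touch collapse into one island interval.  Returns
    ``(n_cgi, is_cluster, island_intervals)``.
    """
    region_seq = region_seq.upper()
    if len(region_seq) < window_bp:
        raise ValueError("region shorter than the scanning window")
    offsets, oe, cg, _ = _window_stats(region_seq, window_bp, step_bp)
    cg_ok = cg > cg_min if cg_strict else cg >= cg_min
    qual = np.flatnonzero((oe >= oe_min) & cg_ok)
    islands: list[tuple[int, int]] = []
    for idx in qual:
        lo, hi = int(offsets[idx]), int(offsets[idx]) + window_bp
        if islands and lo <= islands[-1][1]:
            islands[-1] = (islands[-1][0], max(islands[-1][1], hi))
        else:
            islands.append((lo, hi))
    return len(islands), len(islands) >= 3, islands
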