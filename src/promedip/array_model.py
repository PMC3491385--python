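"""Data model and I/O for tiling-array probes and promoter annotation.

Probes are stored per replicate as a coordinate-sorted table of
``(chrom, start, end, ratio)`` rows, where ``ratio`` is the log2
MeDIP/input intensity of the probe.  All genomic coordinates are 0-based,
half-open.  Promoters are anchored at the transcription start site (TSS)
and all promoter-level analyses work in TSS-relative coordinates
(upstream negative, half-open windows ``[lo, hi)``), which makes minus-
and plus-strand genes exactly symmetric.

The probe position used for TSS-relative mapping is the interval
midpoint, the usual convention for tiling arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Probe",
    "PromoterAnnotation",
    "TSSWindow",
    "ProbeSet",
    "ProbeTableError",
    "read_probe_table",
    "write_probe_table",
    "read_promoter_table",
    "normalize_center",
    "map_probes_to_promoter",
    "maxsixty",
    "replicate_correlation",
]

PROBE_COLUMNS = ("chrom", "start", "end", "ratio")


class ProbeTableError(ValueError):
    """Raised for malformed probe tables (missing columns, bad rows)."""


@dataclass(frozen=True)
class Probe:
    """A single tiling probe with its log2 MeDIP/input ratio."""

    chrom: str
    start: int
    end: int
    ratio: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"probe interval invalid: start={self.start} end={self.end}")
        if not np.isfinite(self.ratio):
            raise ValueError("probe ratio must be finite")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class PromoterAnnotation:
    """A gene promoter: stable id, TSS position and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class TSSWindow:
    """A TSS-relative half-open window ``[lo, hi)`` in bp (upstream negative)."""

    lo: int
    hi: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window invalid: lo={self.lo} hi={self.hi}")

    def genomic(self, promoter: PromoterAnnotation) -> tuple[int, int]:
        """Map to a genomic half-open interval, strand-aware.

        On the minus strand a relative position ``r`` corresponds to
        genomic position ``tss - r``, so ``[lo, hi)`` maps to
        ``[tss - hi + 1, tss - lo + 1)``.
        """
        if promoter.strand == "+":
            return promoter.tss + self.lo, promoter.tss + self.hi
        return promoter.tss - self.hi + 1, promoter.tss - self.lo + 1

    def __contains__(self, rel_pos: float) -> bool:
        return self.lo <= rel_pos < self.hi


@dataclass
class ProbeSet:
    """Coordinate-sorted probes of one array replicate.

    Parameters
    ----------
    df
        Table with columns ``chrom``, ``start``, ``end``, ``ratio``.
    replicate_id
        Label of the MeDIP replicate (e.g. ``"rep1"``).
    stage
        Opaque stage label (``pre_MBT``, ``MBT``, ``post_MBT``, ``sperm`` ...).
    """

    df: pd.DataFrame
    replicate_id: str = "rep1"
    stage: str = ""

    def __post_init__(self):
        missing = [c for c in PROBE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ProbeTableError(f"probe table missing column(s): {missing}")
        df = self.df.loc[:, list(PROBE_COLUMNS)].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["ratio"] = df["ratio"].astype(float)
        bad = df.index[(df["end"] <= df["start"]) | ~np.isfinite(df["ratio"])]
        if len(bad):
            raise ProbeTableError(
                f"invalid probe rows (end<=start or non-finite ratio) at rows: {list(bad[:10])}"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "start", "end"])
        if dup.any():
            raise ProbeTableError(
                f"duplicate probe coordinates within replicate at rows: {list(df.index[dup][:10])}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.df["start"].to_numpy() + self.df["end"].to_numpy())

    @property
    def ratios(self) -> np.ndarray:
        return self.df["ratio"].to_numpy()

    def with_ratios(self, ratios: np.ndarray) -> "ProbeSet":
        df = self.df.copy()
        df["ratio"] = np.asarray(ratios, dtype=float)
        return ProbeSet(df, replicate_id=self.replicate_id, stage=self.stage)


def read_probe_table(path, fmt: str = "tsv", replicate_id: str = "rep1", stage: str = "") -> ProbeSet:
    """Read a probe table from TSV (header required) or NimbleScan-style GFF.

    The TSV must carry columns ``chrom``, ``start``, ``end``, ``ratio``.
    GFF input uses the score field as the log2 ratio and converts the
    1-based inclusive GFF interval to 0-based half-open.  Malformed rows
    are reported with their line numbers.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing:
            raise ProbeTableError(f"{path}: missing column(s) {missing}")
    elif fmt == "gff":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ProbeTableError(f"{path}:{lineno}: expected >=6 GFF fields")
                try:
                    rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), float(parts[5])))
                except ValueError as exc:
                    raise ProbeTableError(f"{path}:{lineno}: {exc}") from None
        df = pd.DataFrame(rows, columns=list(PROBE_COLUMNS))
    else:
        raise ValueError(f"unknown probe table format: {fmt!r}")

    bad = df.index[pd.to_numeric(df["end"]) <= pd.to_numeric(df["start"])]
    if len(bad):
        # +2: one for the header, one for 1-based line numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise ProbeTableError(f"{path}: end<=start at line(s) {lines}")
    return ProbeSet(df, replicate_id=replicate_id, stage=stage)


def write_probe_table(ps: ProbeSet, path) -> None:
    """Write a ProbeSet as a 4-column TSV (round-trips with read_probe_table)."""
    ps.df.to_csv(path, sep="\t", index=False)


def read_promoter_table(path, fmt: str = "tsv") -> list[PromoterAnnotation]:
    """Read promoter annotation from TSV (gene_id/chrom/tss/strand) or BED6.

    For BED6 input the name field is the gene id and the TSS is the
    thickStart column (column 7 when present, else strand-dependent
    interval edge).
    """
    promoters = []
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            promoters.append(PromoterAnnotation(str(row.gene_id), str(row.chrom), int(row.tss), str(row.strand)))
    elif fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ProbeTableError(f"{path}:{lineno}: BED6 requires >=6 fields")
                chrom, start, end, name, _score, strand = parts[:6]
                tss = int(parts[6]) if len(parts) > 6 else (int(start) if strand == "+" else int(end) - 1)
                promoters.append(PromoterAnnotation(name, chrom, tss, strand))
    else:
        raise ValueError(f"unknown promoter table format: {fmt!r}")
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ProbeTableError(f"{path}: duplicate gene ids")
    return promoters


def _tukey_biweight_location(x: np.ndarray, c: float = 6.0, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Tukey biweight (bisquare) location estimate, MAD-scaled."""
    x = np.asarray(x, dtype=float)
    mu = float(np.median(x))
    mad = float(np.median(np.abs(x - mu)))
    if mad == 0.0:
        return mu
    for _ in range(max_iter):
        u = (x - mu) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        mu_new = float(np.sum(w * x) / w.sum())
        if abs(mu_new - mu) < tol:
            mu = mu_new
            break
        mu = mu_new
    return mu


def normalize_center(ps: ProbeSet, estimator: str = "median") -> ProbeSet:
    """Center probe ratios on zero.

    ``estimator`` is ``"median"`` (default; idempotent and rank-preserving)
    or ``"biweight"`` (Tukey biweight location).  Coordinates and probe
    order are unchanged.
    """
    if len(ps) == 0:
        raise ValueError("cannot center an empty ProbeSet")
    r = ps.ratios
    if estimator == "median":
        center = float(np.median(r))
    elif estimator == "biweight":
        center = _tukey_biweight_location(r)
    else:
        raise ValueError(f"unknown centering estimator: {estimator!r}")
    return ps.with_ratios(r - center)


def map_probes_to_promoter(ps: ProbeSet, promoter: PromoterAnnotation, window: TSSWindow) -> pd.DataFrame:
    """Map probes into TSS-relative coordinates of one promoter.

    Returns a DataFrame with columns ``rel_pos`` and ``ratio`` containing
    only probes on the promoter's chromosome whose midpoint falls in
    ``[window.lo, window.hi)`` after the strand-aware transform
    ``rel = mid - tss`` (+ strand) or ``rel = tss - mid`` (- strand),
    ordered by relative position.
    """
    sub = ps.df[ps.df["chrom"] == promoter.chrom]
    mids = 0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy())
    rel = mids - promoter.tss if promoter.strand == "+" else promoter.tss - mids
    keep = (rel >= window.lo) & (rel < window.hi)
    out = pd.DataFrame({"rel_pos": rel[keep], "ratio": sub["ratio"].to_numpy()[keep]})
    return out.sort_values("rel_pos", kind="mergesort").reset_index(drop=True)


def maxsixty(values, window_probes: int = 60) -> float:
    """Summary methylation intensity of a promoter region (MaxSixty).

    Maximum over all runs of ``window_probes`` consecutive probes of the
    mean log2 ratio; if fewer probes are available, the mean of all.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("maxsixty requires at least one probe")
    if v.size < window_probes:
        return float(v.mean())
    csum = np.concatenate([[0.0], np.cumsum(v)])
    means = (csum[window_probes:] - csum[:-window_probes]) / window_probes
    return float(means.max())


def replicate_correlation(a, b) -> float:
    """Pearson correlation of paired per-promoter summaries of two replicates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate_correlation needs two equal-length vectors, n >= 3")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("correlation undefined: zero variance in one replicate")
    return float(np.corrcoef(a, b)[0, 1])
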