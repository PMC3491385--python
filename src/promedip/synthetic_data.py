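"""Synthetic promoter tiling-array data with known ground truth.

Emulates the study design the analysis pipeline targets: duplicate
MeDIP-chip hybridizations on arrays tiling -15 kb to +5 kb around the
TSS of each RefSeq promoter, together with 1-kb upstream promoter
sequences of controlled CpG composition, expression-cohort labels and
histone-mark calls with configurable association to methylation state.

Signal model per probe (log2 MeDIP/input ratio):

    ratio = shift(position) + sigma * (sqrt(rho) * Z_shared + sqrt(1 - rho) * Z_rep)

where ``shift`` is ``+effect_size`` inside a planted methylated domain,
``-hypo_effect_size`` inside the hypomethylated domain of a
hypomethylated-truth promoter (below genome average, the defining
property of hypomethylation here), a small sub-threshold bump inside
mosaic patches of genome-average promoters, and 0 elsewhere.
``Z_shared`` is common to the two replicates (biological signal),
``Z_rep`` is replicate-specific noise; ``rho`` is the shared fraction of
the noise variance.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .array_model import ProbeSet, PromoterAnnotation
from .cpg_classifier import PromoterSequence, classify_promoter, _window_stats

__all__ = ["SimulationConfig", "simulate_promoter_sequences", "simulate_tiling_experiment",
           "simulate_cohorts_and_marks", "simulate_bundle", "write_bundle", "truth_promoters"]

STAGES = ("pre_MBT", "MBT", "post_MBT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_fraction_methylated():
    # Methylated-gene counts over the 12,697 RefSeq promoters: 4,108 pre-MBT
    # and 5,702 at the MBT; post-MBT shows a further modest increase.
    return {"pre_MBT": 0.32, "MBT": 0.45, "post_MBT": 0.47}


def _default_category_mixture():
    return {"up_only": 0.35, "down_only": 0.25, "tss_both": 0.40}


def _default_mark_log_odds():
    # H3K4me3 preferentially on hypomethylated promoters, H3K9me3 on
    # methylated ones, H3K27me3 indifferent.
    return {
        "h3k4me3": {"intercept": -1.0, "methylated": 0.0, "hypomethylated": 2.0},
        "h3k9me3": {"intercept": -1.5, "methylated": 2.0, "hypomethylated": 0.0},
        "h3k27me3": {"intercept": -1.0, "methylated": 0.0, "hypomethylated": 0.0},
    }


def _default_expression_log_odds():
    return {
        "intercept": -0.5,
        "hypomethylated": 1.0,
        "methylated": -0.5,
        "h3k4me3": 1.1,
        "h3k9me3": -1.1,
        "h3k27me3": 0.3,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic arrays.

    Defaults reproduce the emulated experiment: two MeDIP replicates per
    stage, probes every 100 bp tiling -15 kb..+5 kb around each TSS,
    methylation effect of +1.0 log2 units over planted domains, probe
    noise SD 0.3 with 80% of the noise variance shared between
    replicates, 65% HCPs, stage-wise methylated fractions 0.32/0.45/0.47
    and a hypomethylated fraction of 0.41.
    """

    n_genes: int = 1000
    tile_lo: int = -15000
    tile_hi: int = 5000
    probe_spacing: int = 100
    probe_length: int = 50
    effect_size: float = 1.0
    hypo_effect_size: float = 1.0
    noise_sd: float = 0.3
    replicate_shared_fraction: float = 0.8
    stages: tuple = STAGES
    fraction_methylated: dict = field(default_factory=_default_fraction_methylated)
    fraction_hypomethylated: float = 0.41
    fraction_hcp: float = 0.65
    category_mixture: dict = field(default_factory=_default_category_mixture)
    hypo_span: tuple = (-1400, 400)
    mosaic_fraction: float = 0.5
    mosaic_effect: float = 0.25
    mosaic_patch_bp: int = 300
    n_mosaic_patches: int = 2
    cohort_mixture: tuple = (0.15, 0.13, 0.09, 0.63)
    mark_log_odds: dict = field(default_factory=_default_mark_log_odds)
    expression_log_odds: dict = field(default_factory=_default_expression_log_odds)
    seed: int = 0

    def __post_init__(self):
        for name, val in (
            ("fraction_hypomethylated", self.fraction_hypomethylated),
            ("fraction_hcp", self.fraction_hcp),
            ("mosaic_fraction", self.mosaic_fraction),
            ("replicate_shared_fraction", self.replicate_shared_fraction),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.fraction_methylated.values()):
            raise ValueError("fraction_methylated values must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_spacing <= 0 or self.probe_length <= 0:
            raise ValueError("probe spacing/length must be > 0")
        if max(self.fraction_methylated.values()) + self.fraction_hypomethylated > 1.0:
            raise ValueError("methylated + hypomethylated fractions exceed 1")
        if not np.isclose(sum(self.cohort_mixture), 1.0):
            raise ValueError("cohort mixture must sum to 1")

    @classmethod
    def fast(cls, **overrides) -> "SimulationConfig":
        """Reduced geometry (-5 kb..+1 kb, fewer genes) for quick tests.

        Note the truncated tiling inflates the below-average fraction of
        the array background, which weakens hypomethylation calling; use
        the full default geometry to emulate the real experiment.
        """
        defaults = dict(n_genes=200, tile_lo=-5000, tile_hi=1000)
        defaults.update(overrides)
        return cls(**defaults)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# Gene layout and truth assignment


_GENE_SPACING = 40_000  # > 2 * 15 kb: tiled extents never overlap
_CHROMS = 25


def _layout(cfg: SimulationConfig) -> pd.DataFrame:
    rng = cfg.rng(1)
    idx = np.arange(cfg.n_genes)
    chrom_id = idx % _CHROMS
    rank = idx // _CHROMS
    tss = 20_000 + rank * _GENE_SPACING
    strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    # numeric chrom suffix ordered by zero-padding so lexicographic sort is stable
    chrom = np.array([f"chr{c + 1:02d}" for c in chrom_id])
    return pd.DataFrame(
        {"gene_id": [f"gene{i:05d}" for i in idx], "chrom": chrom, "tss": tss, "strand": strand}
    )


_CATEGORY_DOMAINS = {
    # TSS-relative planted methylated domains, chosen so their probe
    # footprints stay strictly inside the intended -1/0 or 0/+1 kb window
    "up_only": ((-900, -150),),
    "down_only": ((150, 900),),
    "tss_both": ((-450, 450),),
}


def assign_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-gene ground truth: CpG class, methylation state and domains."""
    layout = _layout(cfg)
    rng = cfg.rng(2)
    n = cfg.n_genes

    hcp = rng.random(n) < cfg.fraction_hcp

    # One latent uniform per gene drives the nested stage-wise state:
    # v < f_hypo            -> hypomethylated (all stages)
    # v < f_hypo + f_meth_s -> methylated from the first stage where it holds
    v = rng.random(n)
    hypo = v < cfg.fraction_hypomethylated
    onset = np.full(n, "", dtype=object)
    for stage in cfg.stages:
        f = cfg.fraction_methylated[stage]
        newly = (~hypo) & (v < cfg.fraction_hypomethylated + f) & (onset == "")
        onset[newly] = stage
    state = np.where(hypo, "hypomethylated", np.where(onset != "", "methylated", "no_me"))

    cats = list(cfg.category_mixture)
    probs = np.array([cfg.category_mixture[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    category = np.full(n, "", dtype=object)
    meth_mask = state == "methylated"
    category[meth_mask] = rng.choice(cats, size=int(meth_mask.sum()), p=probs)

    mosaic = (state == "no_me") & (rng.random(n) < cfg.mosaic_fraction)
    # one patch per equal-width block of the proximal region, so patches of a
    # gene never overlap (keeps the planted shift exactly mosaic_effect)
    span_lo = max(cfg.tile_lo + 200, -4500)
    span_hi = min(cfg.tile_hi - 200, 900)
    block = (span_hi - span_lo) // cfg.n_mosaic_patches
    patch_lo = np.stack(
        [
            rng.integers(span_lo + j * block, span_lo + (j + 1) * block - cfg.mosaic_patch_bp, size=n)
            for j in range(cfg.n_mosaic_patches)
        ],
        axis=1,
    )

    truth = layout.copy()
    truth["cpg_class"] = np.where(hcp, "HCP", "LCP")
    truth["state"] = state
    truth["onset_stage"] = onset
    truth["category"] = category
    truth["mosaic"] = mosaic
    truth["mosaic_patches"] = [
        ";".join(f"{lo}:{lo + cfg.mosaic_patch_bp}" for lo in row) if mos else ""
        for row, mos in zip(patch_lo, mosaic)
    ]
    for stage in cfg.stages:
        order = {s: i for i, s in enumerate(cfg.stages)}
        truth[f"methylated_{stage}"] = [
            o != "" and order[o] <= order[stage] for o in onset
        ]
        truth[f"hypomethylated_{stage}"] = hypo
    return truth


def truth_promoters(truth: pd.DataFrame) -> list[PromoterAnnotation]:
    return [
        PromoterAnnotation(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in truth.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Promoter sequences


def _batch_markov(rng, n_seqs: int, length: int, pi: np.ndarray, cpg_factor: float) -> np.ndarray:
    """Dinucleotide-Markov base sampling with CpG transition suppression."""
    trans = np.tile(pi, (4, 1))
    trans[1, 2] *= cpg_factor  # C -> G
    trans /= trans.sum(axis=1, keepdims=True)
    trans_cum = np.cumsum(trans, axis=1)
    pi_cum = np.cumsum(pi)
    out = np.empty((n_seqs, length), dtype=np.int8)
    out[:, 0] = np.searchsorted(pi_cum, rng.random(n_seqs), side="right")
    for i in range(1, length):
        u = rng.random(n_seqs)
        rows = trans_cum[out[:, i - 1]]
        out[:, i] = (rows < u[:, None]).sum(axis=1)
    return np.clip(out, 0, 3)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# CpG-depleted (LCP-like) composition: CG fraction ~0.35, o/e ~0.15
_LCP_PI = np.array([0.325, 0.175, 0.175, 0.325])
_LCP_CPG_FACTOR = 0.15
# CpG-island composition for planted HCP segments: i.i.d., o/e ~1, CG ~0.55
_HCP_PI = np.array([0.225, 0.275, 0.275, 0.225])

_SEQ_LEN = 1000
_ISLAND_LEN = 500


def simulate_promoter_sequences(cfg: SimulationConfig, truth: pd.DataFrame, max_rounds: int = 30):
    """1-kb upstream sequences with the planted CpG class of each gene.

    HCP-truth genes carry a planted 500-bp CpG-island segment (o/e >= 0.8
    and CG content >= 0.5, safely above the classification thresholds) on
    a CpG-depleted background; LCP-truth genes are CpG-depleted
    throughout (every 500-bp window o/e <= 0.4).  Each emitted sequence
    is verified against the step-1 classifier and resampled on violation.
    """
    rng = cfg.rng(3)
    n = len(truth)
    is_hcp = (truth["cpg_class"] == "HCP").to_numpy()
    seqs = _batch_markov(rng, n, _SEQ_LEN, _LCP_PI, _LCP_CPG_FACTOR)
    offsets = rng.integers(0, _SEQ_LEN - _ISLAND_LEN + 1, size=n)
    islands = _batch_markov(rng, int(is_hcp.sum()), _ISLAND_LEN, _HCP_PI, 1.0)
    for row, gi in enumerate(np.flatnonzero(is_hcp)):
        seqs[gi, offsets[gi] : offsets[gi] + _ISLAND_LEN] = islands[row]

    def violates(gi: int) -> bool:
        s = _to_str(seqs[gi])
        cls = classify_promoter(PromoterSequence(truth["gene_id"].iat[gi], s))
        if is_hcp[gi]:
            seg = s[offsets[gi] : offsets[gi] + _ISLAND_LEN]
            _, oe, cg, _ = _window_stats(seg, _ISLAND_LEN, 1)
            return not (cls.cpg_class == "HCP" and oe[0] >= 0.8 and cg[0] >= 0.5)
        _, oe, _, _ = _window_stats(s, _ISLAND_LEN, 1)
        return not (cls.cpg_class == "LCP" and float(oe.max()) <= 0.4)

    pending = [gi for gi in range(n) if violates(gi)]
    for _ in range(max_rounds):
        if not pending:
            break
        still = []
        for gi in pending:
            if is_hcp[gi]:
                seqs[gi] = _batch_markov(rng, 1, _SEQ_LEN, _LCP_PI, _LCP_CPG_FACTOR)[0]
                offsets[gi] = rng.integers(0, _SEQ_LEN - _ISLAND_LEN + 1)
                seqs[gi, offsets[gi] : offsets[gi] + _ISLAND_LEN] = _batch_markov(
                    rng, 1, _ISLAND_LEN, _HCP_PI, 1.0
                )[0]
            else:
                seqs[gi] = _batch_markov(rng, 1, _SEQ_LEN, _LCP_PI, _LCP_CPG_FACTOR)[0]
            if violates(gi):
                still.append(gi)
        pending = still
    if pending:
        raise RuntimeError(f"could not realize CpG composition for {len(pending)} genes")

    records = [
        PromoterSequence(truth["gene_id"].iat[gi], _to_str(seqs[gi])) for gi in range(n)
    ]
    island_offsets = np.where(is_hcp, offsets, -1)
    return records, island_offsets


# ---------------------------------------------------------------------------
# Tiling signal


def _gene_domains(cfg: SimulationConfig, row, stage: str) -> list[tuple[int, int, float]]:
    """Active (rel_lo, rel_hi, shift) effects of one gene at one stage."""
    effects = []
    if row.state == "methylated" and bool(getattr(row, f"methylated_{stage}")):
        for lo, hi in _CATEGORY_DOMAINS[row.category]:
            effects.append((lo, hi, cfg.effect_size))
    elif row.state == "hypomethylated":
        effects.append((cfg.hypo_span[0], cfg.hypo_span[1], -cfg.hypo_effect_size))
    elif row.mosaic:
        for patch in row.mosaic_patches.split(";"):
            lo, hi = (int(x) for x in patch.split(":"))
            effects.append((lo, hi, cfg.mosaic_effect))
    return effects


def simulate_tiling_experiment(
    cfg: SimulationConfig, truth: pd.DataFrame, stages=None
) -> dict[str, tuple[ProbeSet, ProbeSet]]:
    """Duplicate-MeDIP probe tables per stage with planted domain signal.

    Probes tile ``[tile_lo, tile_hi)`` TSS-relative at ``probe_spacing``
    with footprints of ``probe_length``; coordinates are genomic and
    strand-aware (midpoint ``tss + r`` on +, ``tss - r`` on -).  Returns
    ``{stage: (rep1, rep2)}``.
    """
    stages = list(cfg.stages if stages is None else stages)
    n_probes_per_gene = (cfg.tile_hi - cfg.tile_lo) // cfg.probe_spacing
    rel_mids = cfg.tile_lo + cfg.probe_spacing // 2 + cfg.probe_spacing * np.arange(n_probes_per_gene)

    tss = truth["tss"].to_numpy()
    plus = (truth["strand"] == "+").to_numpy()
    gmid = np.where(plus[:, None], tss[:, None] + rel_mids, tss[:, None] - rel_mids)
    half_len = cfg.probe_length // 2
    starts = (gmid - half_len).astype(np.int64)
    ends = (gmid + (cfg.probe_length - half_len)).astype(np.int64)
    chroms = np.repeat(truth["chrom"].to_numpy(), n_probes_per_gene)

    out: dict[str, tuple[ProbeSet, ProbeSet]] = {}
    for stage in stages:
        stream = 10 + list(cfg.stages).index(stage)
        rng = cfg.rng(stream)
        shift = np.zeros((len(truth), n_probes_per_gene))
        for gi, row in enumerate(truth.itertuples(index=False)):
            for lo, hi, eff in _gene_domains(cfg, row, stage):
                shift[gi, (rel_mids >= lo) & (rel_mids < hi)] += eff
        shared = rng.standard_normal(shift.shape)
        reps = []
        for rep_id in ("rep1", "rep2"):
            eps = rng.standard_normal(shift.shape)
            rho = cfg.replicate_shared_fraction
            ratio = shift + cfg.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)
            df = pd.DataFrame(
                {
                    "chrom": chroms,
                    "start": starts.ravel(),
                    "end": ends.ravel(),
                    "ratio": ratio.ravel(),
                }
            )
            reps.append(ProbeSet(df, replicate_id=rep_id, stage=stage))
        out[stage] = tuple(reps)
    return out


# ---------------------------------------------------------------------------
# Cohorts, histone marks and expression


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohorts_and_marks(cfg: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """GeneFeatureTable with planted cohort/mark/expression associations.

    Cohort labels are multinomial draws from ``cohort_mixture``
    (maternal-degraded, maternal-zygotic, zygotic, undetected).  Each
    histone mark is a per-stage Bernoulli draw from a logistic model on
    the gene's true methylation state at that stage; the post-ZGA
    expression flag is a logistic draw on the pre-MBT state and marks.
    """
    from .integration_stats import COHORTS

    rng = cfg.rng(4)
    n = len(truth)
    gft = truth[["gene_id", "cpg_class", "state"]].copy()
    gft["cohort"] = rng.choice(list(COHORTS), size=n, p=np.asarray(cfg.cohort_mixture))

    for stage in cfg.stages:
        meth = truth[f"methylated_{stage}"].to_numpy().astype(float)
        hypo = truth[f"hypomethylated_{stage}"].to_numpy().astype(float)
        gft[f"methylated_{stage}"] = meth.astype(bool)
        gft[f"hypomethylated_{stage}"] = np.where(hypo.astype(bool), "yes", "no")
        for mark, beta in cfg.mark_log_odds.items():
            eta = beta["intercept"] + beta["methylated"] * meth + beta["hypomethylated"] * hypo
            gft[f"{mark}_{stage}"] = rng.random(n) < _sigmoid(eta)

    first = cfg.stages[0]
    beta = cfg.expression_log_odds
    eta = (
        beta["intercept"]
        + beta["methylated"] * truth[f"methylated_{first}"].to_numpy().astype(float)
        + beta["hypomethylated"] * truth[f"hypomethylated_{first}"].to_numpy().astype(float)
    )
    for mark in cfg.mark_log_odds:
        eta = eta + beta.get(mark, 0.0) * gft[f"{mark}_{first}"].to_numpy().astype(float)
    gft["expressed_post_zga"] = rng.random(n) < _sigmoid(eta)
    return gft


# ---------------------------------------------------------------------------
# Bundles


def simulate_bundle(cfg: SimulationConfig, stages=None, sequences: bool = True):
    """Full synthetic data bundle: truth, sequences, probe sets, feature table."""
    truth = assign_truth(cfg)
    records = None
    if sequences:
        records, island_offsets = simulate_promoter_sequences(cfg, truth)
        truth = truth.assign(island_offset=island_offsets)
    experiments = simulate_tiling_experiment(cfg, truth, stages=stages)
    gft = simulate_cohorts_and_marks(cfg, truth)
    return {"config": cfg, "truth": truth, "sequences": records, "experiments": experiments, "gft": gft}


def write_bundle(bundle: dict, outdir) -> None:
    """Serialize a bundle: FASTA, probe TSVs, truth/feature TSVs, config YAML."""
    import os

    import yaml
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    from .array_model import write_probe_table

    os.makedirs(outdir, exist_ok=True)
    cfg = bundle["config"]
    cfg_dict = asdict(cfg)
    cfg_dict["stages"] = list(cfg.stages)
    cfg_dict["cohort_mixture"] = list(cfg.cohort_mixture)
    cfg_dict["hypo_span"] = list(cfg.hypo_span)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    bundle["truth"].to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    bundle["gft"].to_csv(os.path.join(outdir, "gene_features.tsv"), sep="\t", index=False)
    if bundle["sequences"] is not None:
        recs = [
            SeqRecord(Seq(ps.sequence), id=ps.gene_id, description="")
            for ps in bundle["sequences"]
        ]
        SeqIO.write(recs, os.path.join(outdir, "promoters.fasta"), "fasta")
    for stage, (rep1, rep2) in bundle["experiments"].items():
        write_probe_table(rep1, os.path.join(outdir, f"probes_{stage}_rep1.tsv"))
        write_probe_table(rep2, os.path.join(outdir, f"probes_{stage}_rep2.tsv"))
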