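"""Synthetic count matrices with planted housekeeping structure.

The generator emulates a transcripts x samples RNA-seq count matrix
grouped into tissues. Expression is log-normal around per-tissue mean
levels (biological noise) and counts are Poisson draws around the
RPKM-implied expectations given transcript lengths and library sizes
(counting noise) — the minimal structure under which SD-of-log2 and
max-fold-change stability criteria are meaningful.

Planted classes:

* ``hk_reference`` — stable and abundant in every tissue (candidate
  reference grade: low SD, mean RPKM comfortably above 30);
* ``hk_low`` — stable everywhere but modestly expressed (housekeeping,
  yet below the reference-candidate abundance floor);
* ``violator_expression`` — one designated tissue forced far below the
  1-RPKM expression floor;
* ``violator_sd`` — one designated tissue with a bimodal level
  (half the samples shifted up, half down) giving SD of log2 RPKM
  near 1.5, well above the criterion;
* ``violator_mfc`` — one designated tissue with a low baseline and a
  single high-outlier sample driving max/mean of log2 RPKM >= 2.5;
* ``marginal`` (optional) — true SD just above 1 in one tissue, so it
  slips past the criterion only under small-sample estimation error;
* ``background`` — a handful of highly abundant transcripts that absorb
  the bulk of each library (as ribosomal/mitochondrial transcripts do in
  real libraries) so that realized RPKM values land on the planted
  targets; each has one designated dropout tissue, making it fail the
  expression criterion.

Class margins are fixed so that, at the default sample sizes, planted
membership is unambiguous: detection recovers the HK partition exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMetadata, TranscriptAnnotation

__all__ = [
    "SynthConfig",
    "SynthData",
    "generate",
    "generate_anticorrelated_isoforms",
    "generate_tissue_private_instability",
]

RPKM_SCALE = 1e9  # reads per kilobase per million = 1e3 * 1e6


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults give 10 tissues x 8 samples with 200 planted HK transcripts
    (half reference-grade) and 100 violators of each criterion.
    """

    n_tissues: int = 10
    samples_per_tissue: int = 8
    n_hk: int = 200
    n_reference_grade: int = 100  # subset of n_hk in the abundant band
    n_violators_per_criterion: int = 100
    n_background: int = 50
    n_pseudogene_flagged: int = 0  # reference-grade HK whose gene has a pseudogene
    n_unsupported: int = 0  # HK-like expression without RefSeq/CCDS support
    n_marginal: int = 0  # true SD just above the criterion in one tissue
    noise_sd_log2: float = 0.2
    violator_noise_sd_log2: float = 0.1
    marginal_sd_log2: float = 1.15
    depth_range: tuple[int, int] = (20_000_000, 30_000_000)
    length_range_bp: tuple[int, int] = (500, 5000)
    ref_band_log2: tuple[float, float] = (5.5, 8.0)  # RPKM ~45-256
    low_band_log2: tuple[float, float] = (2.5, 3.5)  # RPKM ~5.7-11.3
    dropout_rpkm: float = 0.1
    sd_bimodal_offset: float = 1.4  # half-offset; designed SD ~= 1.5
    mfc_baseline_log2: float = 0.8
    mfc_outlier_offset: float = 2.0  # designed MFC ~= 2.67
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 1 or self.samples_per_tissue < 1:
            raise ValueError("need at least one tissue and one sample per tissue")
        if not (0 <= self.n_reference_grade <= self.n_hk):
            raise ValueError("n_reference_grade must lie within n_hk")
        if self.n_pseudogene_flagged > self.n_reference_grade:
            raise ValueError("n_pseudogene_flagged exceeds reference-grade class")
        if self.noise_sd_log2 > 0.3:
            raise ValueError(
                "HK noise_sd_log2 > 0.3 erodes the margin to the SD < 1 criterion"
            )
        if 2 ** self.low_band_log2[0] <= 2.0:
            raise ValueError("low expression band too close to the 1-RPKM floor")
        if self.dropout_rpkm >= 0.5:
            raise ValueError("dropout level too close to the 1-RPKM floor")
        if self.n_violators_per_criterion > 0 and self.samples_per_tissue > 1:
            designed_sd = self.sd_bimodal_offset * math.sqrt(
                self.samples_per_tissue / (self.samples_per_tissue - 1)
            )
            if designed_sd < 1.3:
                raise ValueError(
                    f"bimodal SD design {designed_sd:.2f} overlaps the SD < 1 criterion"
                )
            base, off = self.mfc_baseline_log2, self.mfc_outlier_offset
            n = self.samples_per_tissue
            designed_mfc = (base + off) / ((base * (n - 1) + base + off) / n)
            if designed_mfc < 2.3:
                raise ValueError(
                    f"outlier MFC design {designed_mfc:.2f} overlaps the MFC < 2 criterion"
                )
        if self.marginal_sd_log2 <= 1.0:
            raise ValueError("marginal class SD must exceed the criterion")


@dataclass
class SynthData:
    """Generator output: counts, metadata, annotation and truth labels."""

    counts: CountMatrix
    metadata: list[SampleMetadata]
    annotation: list[TranscriptAnnotation]
    truth: pd.DataFrame  # index transcript_id; columns: class, is_hk

    @property
    def true_hk(self) -> list[str]:
        return list(self.truth.index[self.truth["is_hk"]])


def _tissue_names(n: int) -> list[str]:
    return [f"tissue_{i:02d}" for i in range(n)]


def _band(rng: np.random.Generator, band: tuple[float, float], shape) -> np.ndarray:
    return rng.uniform(band[0], band[1], size=shape)


def generate(config: SynthConfig) -> SynthData:
    """Generate a seeded synthetic dataset with planted HK structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, S = config.n_tissues, config.samples_per_tissue
    tissues = _tissue_names(T)

    classes: list[str] = []
    classes += ["hk_reference"] * config.n_reference_grade
    classes += ["hk_low"] * (config.n_hk - config.n_reference_grade)
    classes += ["violator_expression"] * config.n_violators_per_criterion
    classes += ["violator_sd"] * config.n_violators_per_criterion
    classes += ["violator_mfc"] * config.n_violators_per_criterion
    classes += ["unsupported"] * config.n_unsupported
    classes += ["marginal"] * config.n_marginal
    classes += ["background"] * config.n_background
    n_tx = len(classes)
    cls = np.array(classes)

    tids = [f"TX{i:06d}" for i in range(n_tx)]
    lengths = np.exp(
        rng.uniform(
            math.log(config.length_range_bp[0]),
            math.log(config.length_range_bp[1]),
            size=n_tx,
        )
    ).astype(int)

    # per (transcript, tissue) mean log2 RPKM
    mean_log2 = np.zeros((n_tx, T))
    designated = np.full(n_tx, -1)  # tissue index a violator/background targets
    noise_sd = np.full(n_tx, config.noise_sd_log2)

    ref_like = np.isin(
        cls,
        [
            "hk_reference",
            "violator_expression",
            "violator_sd",
            "violator_mfc",
            "unsupported",
            "marginal",
        ],
    )
    mean_log2[ref_like] = _band(rng, config.ref_band_log2, (int(ref_like.sum()), T))
    low = cls == "hk_low"
    mean_log2[low] = _band(rng, config.low_band_log2, (int(low.sum()), T))

    counter = 0
    for i in range(n_tx):
        c = cls[i]
        if c in ("violator_expression", "violator_sd", "violator_mfc", "marginal", "background"):
            designated[i] = counter % T
            counter += 1
        if c.startswith("violator"):
            noise_sd[i] = config.violator_noise_sd_log2
        if c == "violator_expression":
            mean_log2[i, designated[i]] = math.log2(config.dropout_rpkm)
        elif c == "violator_mfc":
            mean_log2[i, designated[i]] = config.mfc_baseline_log2

    # background absorbs the residual library mass per tissue so that the
    # sum of RPKM * length approaches the RPKM scale and realized RPKM
    # values land on the planted targets
    bg = np.flatnonzero(cls == "background")
    if bg.size:
        nonbg = np.flatnonzero(cls != "background")
        for τ in range(T):
            s_other = float(np.sum(2.0 ** mean_log2[nonbg, τ] * lengths[nonbg]))
            active = [i for i in bg if designated[i] != τ]
            if not active:
                raise ValueError(
                    "infeasible config: a tissue has no active background transcripts"
                )
            residual = RPKM_SCALE - s_other
            if residual <= 0:
                raise ValueError(
                    "infeasible config: planted expression exceeds the library budget"
                )
            per_tx_mass = residual / len(active)
            for i in active:
                mean_log2[i, τ] = math.log2(per_tx_mass / lengths[i])
        for i in bg:
            mean_log2[i, designated[i]] = math.log2(config.dropout_rpkm / 2)
            noise_sd[i] = config.violator_noise_sd_log2

    # samples
    sample_ids, sample_tissue_idx = [], []
    for τ, tissue in enumerate(tissues):
        for s in range(S):
            sample_ids.append(f"{tissue}_s{s:02d}")
            sample_tissue_idx.append(τ)
    sample_tissue_idx = np.array(sample_tissue_idx)
    lib_sizes = rng.integers(
        config.depth_range[0], config.depth_range[1] + 1, size=len(sample_ids)
    )

    # per-sample target log2 RPKM = tissue mean + structural offsets + noise
    X = mean_log2[:, sample_tissue_idx].astype(float)
    X += rng.normal(0.0, 1.0, size=X.shape) * noise_sd[:, None]
    for i in range(n_tx):
        τ = designated[i]
        if τ < 0:
            continue
        in_tissue = np.flatnonzero(sample_tissue_idx == τ)
        if cls[i] == "violator_sd" and S > 1:
            half = config.sd_bimodal_offset
            offs = np.where(np.arange(in_tissue.size) % 2 == 0, half, -half)
            X[i, in_tissue] += offs
        elif cls[i] == "violator_mfc" and S > 1:
            X[i, in_tissue[0]] += config.mfc_outlier_offset
        elif cls[i] == "marginal":
            extra = math.sqrt(config.marginal_sd_log2 ** 2 - noise_sd[i] ** 2)
            X[i, in_tissue] += rng.normal(0.0, extra, size=in_tissue.size)

    lam = (2.0 ** X) * lengths[:, None] * lib_sizes[None, :] / RPKM_SCALE
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)
    metadata = [
        SampleMetadata(
            sample_id=sid,
            tissue=tissues[τ],
            depth=int(lib_sizes[k]),
            alignment_rate=0.9,
            protocol="mRNA_enrichment",
            layout="paired",
        )
        for k, (sid, τ) in enumerate(zip(sample_ids, sample_tissue_idx))
    ]
    pseudo_flagged = set(range(config.n_pseudogene_flagged))  # first ref-grade rows
    annotation = [
        TranscriptAnnotation(
            transcript_id=tids[i],
            gene_id=f"GN{i:06d}",
            gene_symbol=f"SYN{i:04d}",
            length_bp=int(lengths[i]),
            is_protein_coding=True,
            has_supported_model=cls[i] != "unsupported",
            gene_has_pseudogene=(i in pseudo_flagged),
        )
        for i in range(n_tx)
    ]
    is_hk = np.isin(cls, ["hk_reference", "hk_low"])
    truth = pd.DataFrame(
        {"class": cls, "is_hk": is_hk},
        index=pd.Index(tids, name="transcript_id"),
    )
    return SynthData(CountMatrix(counts_df), metadata, annotation, truth)


def generate_anticorrelated_isoforms(
    n_genes: int = 20,
    n_single_isoform: int = 10,
    n_tissues: int = 4,
    samples_per_tissue: int = 6,
    gene_rpkm: float = 60.0,
    low_fraction: float = 0.05,
    length_bp: int = 2000,
    depth: int = 20_000_000,
    n_background: int = 10,
    seed: int = 0,
) -> SynthData:
    """Genes whose two isoforms sum to a constant but individually swing.

    Each two-isoform gene has isoform RPKMs x and C - x with x alternating
    between ``low_fraction * C`` and ``(1 - low_fraction) * C`` across
    samples: the gene level is constant (passes the stability criteria)
    while each isoform's log2 SD is far above 1 (fails). Single-isoform
    control genes are constant at C and behave identically under gene- and
    transcript-level analysis. Background transcripts absorb the library
    mass so realized RPKM tracks the targets.
    """
    rng = np.random.default_rng(seed)
    tissues = _tissue_names(n_tissues)
    S = samples_per_tissue
    tids, gene_of, cls = [], [], []
    for g in range(n_genes):
        for iso in ("a", "b"):
            tids.append(f"ISO{g:04d}{iso}")
            gene_of.append(f"GENE{g:04d}")
            cls.append("anticorrelated_isoform")
    for g in range(n_single_isoform):
        tids.append(f"CTL{g:04d}")
        gene_of.append(f"CTLG{g:04d}")
        cls.append("single_isoform_control")
    for b in range(n_background):
        tids.append(f"BG{b:04d}")
        gene_of.append(f"BGG{b:04d}")
        cls.append("background")
    n_tx = len(tids)
    lengths = np.full(n_tx, length_bp)

    n_samples = n_tissues * S
    sample_ids = [f"{t}_s{s:02d}" for t in tissues for s in range(S)]
    rpkm_target = np.zeros((n_tx, n_samples))
    x_hi = (1.0 - low_fraction) * gene_rpkm
    x_lo = low_fraction * gene_rpkm
    row = 0
    for g in range(n_genes):
        phase = np.arange(n_samples) % 2
        a = np.where(phase == 0, x_hi, x_lo)
        rpkm_target[row] = a
        rpkm_target[row + 1] = gene_rpkm - a
        row += 2
    for g in range(n_single_isoform):
        rpkm_target[row] = gene_rpkm
        row += 1
    planted_mass = float(np.max(rpkm_target.sum(axis=0) * length_bp))
    residual = RPKM_SCALE - planted_mass
    if residual <= 0:
        raise ValueError("infeasible: planted expression exceeds the library budget")
    if n_background:
        rpkm_target[row:] = residual / (n_background * length_bp)

    lam = rpkm_target * lengths[:, None] * depth / RPKM_SCALE
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)
    metadata = [
        SampleMetadata(
            sample_id=sid,
            tissue=sid.rsplit("_s", 1)[0],
            depth=depth,
            alignment_rate=0.9,
            protocol="mRNA_enrichment",
            layout="paired",
        )
        for sid in sample_ids
    ]
    annotation = [
        TranscriptAnnotation(
            transcript_id=tids[i],
            gene_id=gene_of[i],
            gene_symbol=gene_of[i],
            length_bp=length_bp,
        )
        for i in range(n_tx)
    ]
    truth = pd.DataFrame(
        {
            "class": cls,
            "is_hk": [c == "single_isoform_control" for c in cls],
        },
        index=pd.Index(tids, name="transcript_id"),
    )
    return SynthData(CountMatrix(counts_df), metadata, annotation, truth)


def generate_tissue_private_instability(
    n_tissues: int = 52,
    samples_per_tissue: int = 3,
    block_size: int = 4,
    n_always_stable: int = 52,
    noise_sd_log2: float = 0.2,
    band_log2: tuple[float, float] = (5.5, 8.0),
    depth: int = 25_000_000,
    seed: int = 0,
) -> SynthData:
    """Stress fixture for the tissue-diversity simulation.

    Every tissue privately destabilizes a disjoint block of
    ``block_size`` transcripts (drives them far below the 1-RPKM floor
    there); ``n_always_stable`` transcripts are stable everywhere. The
    number of transcripts stable across a set of g tissues is then
    exactly ``n_always_stable + block_size * (n_tissues - g)``: strictly
    decreasing in g.
    """
    rng = np.random.default_rng(seed)
    tissues = _tissue_names(n_tissues)
    n_block_tx = n_tissues * block_size
    n_tx = n_always_stable + n_block_tx
    tids = [f"TX{i:06d}" for i in range(n_tx)]
    lengths = np.exp(rng.uniform(math.log(500), math.log(5000), size=n_tx)).astype(int)

    mean_log2 = _band(rng, band_log2, (n_tx, n_tissues))
    destab_tissue = np.full(n_tx, -1)
    for τ in range(n_tissues):
        block = range(n_always_stable + τ * block_size, n_always_stable + (τ + 1) * block_size)
        for i in block:
            destab_tissue[i] = τ
            mean_log2[i, τ] = math.log2(0.002)

    S = samples_per_tissue
    sample_ids, tissue_idx = [], []
    for τ, t in enumerate(tissues):
        for s in range(S):
            sample_ids.append(f"{t}_s{s:02d}")
            tissue_idx.append(τ)
    tissue_idx = np.array(tissue_idx)
    X = mean_log2[:, tissue_idx] + rng.normal(0, noise_sd_log2, (n_tx, len(sample_ids)))
    lam = (2.0 ** X) * lengths[:, None] * depth / RPKM_SCALE
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)
    metadata = [
        SampleMetadata(
            sample_id=sid,
            tissue=tissues[τ],
            depth=depth,
            alignment_rate=0.9,
            protocol="mRNA_enrichment",
            layout="paired",
        )
        for sid, τ in zip(sample_ids, tissue_idx)
    ]
    annotation = [
        TranscriptAnnotation(
            transcript_id=tids[i],
            gene_id=f"GN{i:06d}",
            gene_symbol=f"SYN{i:04d}",
            length_bp=int(lengths[i]),
        )
        for i in range(n_tx)
    ]
    truth = pd.DataFrame(
        {
            "class": np.where(destab_tissue >= 0, "tissue_private_unstable", "always_stable"),
            "is_hk": destab_tissue < 0,
            "destabilized_tissue": [
                tissues[τ] if τ >= 0 else "" for τ in destab_tissue
            ],
        },
        index=pd.Index(tids, name="transcript_id"),
    )
    return SynthData(CountMatrix(counts_df), metadata, annotation, truth)
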