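"""Per-tissue expression-stability statistics and housekeeping calls.

A transcript is called housekeeping (HK) when, in every analyzed tissue,
it is expressed above the 1-RPKM floor, its log2 RPKM standard deviation
is below 1, and its maximum fold change (max over mean of log2 RPKM) is
below 2 — and its transcript model is protein-coding with RefSeq/CCDS
support. A gene is HK when at least one of its transcripts qualifies.

Statistics are computed within each tissue and the criteria must hold in
all tissues; a ``pooled`` mode computing a single statistic across all
samples is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import annotation_frame
from .normalize import NormalizedExpression

__all__ = ["StabilityProfile", "HKCallSet", "stability_stats", "call_hk", "summarize_to_gene"]

#: pseudocount added inside log2 only; far below the 1-RPKM expression
#: floor so it can never flip the expression criterion.
DEFAULT_PSEUDOCOUNT = 1e-3


def stability_stats(
    expr: NormalizedExpression,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per (transcript, tissue) stability statistics.

    Returns a DataFrame with columns ``transcript_id``, ``tissue``,
    ``mean_rpkm`` (arithmetic mean of RPKM), ``sd_log2`` (sample SD,
    ddof=1, of log2(RPKM + pseudo)), ``mfc`` (max over mean of
    log2(RPKM + pseudo)), ``mfc_valid`` (False when the mean log2 is
    non-positive, where the ratio is ill-defined) and ``n_samples``.
    Tissues with a single sample get sd_log2 = 0 and mfc = 1.

    ``pooled=True`` computes one row per transcript across all samples
    (tissue label ``"__pooled__"``).
    """
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    groups = (
        {"__pooled__": expr.sample_ids}
        if pooled
        else {t: expr.samples_in(t) for t in expr.tissues()}
    )
    frames = []
    for tissue, samples in groups.items():
        x = expr.rpkm[samples].to_numpy(dtype=float)
        n = x.shape[1]
        logx = np.log2(x + pseudo)
        mean_rpkm = x.mean(axis=1)
        if n == 1:
            sd = np.zeros(x.shape[0])
            mfc = np.ones(x.shape[0])
            mean_log = logx[:, 0]
        else:
            sd = logx.std(axis=1, ddof=1)
            mean_log = logx.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                mfc = logx.max(axis=1) / mean_log
        valid = mean_log > 0
        if n == 1:
            mfc = np.ones(x.shape[0])
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": expr.transcript_ids,
                    "tissue": tissue,
                    "mean_rpkm": mean_rpkm,
                    "sd_log2": sd,
                    "mfc": mfc,
                    "mfc_valid": valid,
                    "n_samples": n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class HKCallSet:
    """HK transcript and gene calls with per-criterion provenance.

    ``transcripts`` has one row per transcript: the per-criterion pass
    flags (each criterion must hold in every tissue), ``is_hk_transcript``,
    and comma-separated lists of the tissues failing each criterion.
    ``genes`` has one row per gene with ``is_hk_gene``.
    """

    transcripts: pd.DataFrame
    genes: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def hk_transcripts(self) -> list[str]:
        df = self.transcripts
        return list(df.index[df["is_hk_transcript"]])

    @property
    def hk_genes(self) -> list[str]:
        df = self.genes
        return list(df.index[df["is_hk_gene"]])

    def to_frame(self) -> pd.DataFrame:
        return self.transcripts.rename_axis("transcript_id")

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "hk_transcripts": self.hk_transcripts,
            "hk_genes": self.hk_genes,
        }


def _failing(stats: pd.DataFrame, fail_mask: pd.Series) -> pd.Series:
    """Comma-joined failing tissues per transcript (empty string if none)."""
    failed = stats.loc[fail_mask.to_numpy(), ["transcript_id", "tissue"]]
    joined = failed.groupby("transcript_id")["tissue"].apply(
        lambda s: ",".join(sorted(s))
    )
    return joined


def call_hk(
    stats: pd.DataFrame,
    annotation,
    rpkm_min: float = 1.0,
    sd_max: float = 1.0,
    mfc_max: float = 2.0,
    allow_complementary_isoforms: bool = False,
) -> HKCallSet:
    """Apply the HK criteria to per-tissue stability statistics.

    A transcript passes when it is protein-coding with a supported model
    and, in every tissue: mean RPKM > ``rpkm_min``, SD of log2 RPKM <
    ``sd_max``, and MFC < ``mfc_max`` (tissues where the MFC denominator
    is non-positive fail the MFC criterion by convention). A gene is HK
    when at least one of its transcripts passes in all tissues; with
    ``allow_complementary_isoforms`` a gene is additionally HK when the
    union of its transcripts' per-tissue passing sets covers all tissues.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    tissues = sorted(stats["tissue"].unique())
    counts_per_transcript = stats.groupby("transcript_id")["tissue"].nunique()
    incomplete = counts_per_transcript[counts_per_transcript != len(tissues)]
    if len(incomplete):
        raise ValueError(
            f"transcripts with missing tissue coverage: {list(incomplete.index[:5])}"
        )
    missing_ann = [
        t for t in counts_per_transcript.index if t not in ann.index
    ]
    if missing_ann:
        raise ValueError(
            f"transcripts missing from annotation: {missing_ann[:5]}"
        )

    s = stats
    ok_expr = s["mean_rpkm"] > rpkm_min
    ok_sd = s["sd_log2"] < sd_max
    ok_mfc = (s["mfc"] < mfc_max) & s["mfc_valid"]

    per_tx = pd.DataFrame(index=pd.Index(sorted(counts_per_transcript.index), name="transcript_id"))
    grouped = pd.DataFrame(
        {
            "transcript_id": s["transcript_id"],
            "ok_expr": ok_expr,
            "ok_sd": ok_sd,
            "ok_mfc": ok_mfc,
        }
    ).groupby("transcript_id")
    allpass = grouped[["ok_expr", "ok_sd", "ok_mfc"]].all()
    per_tx["pass_expression"] = allpass["ok_expr"]
    per_tx["pass_sd"] = allpass["ok_sd"]
    per_tx["pass_mfc"] = allpass["ok_mfc"]
    per_tx["pass_model"] = (
        ann.loc[per_tx.index, "is_protein_coding"]
        & ann.loc[per_tx.index, "has_supported_model"]
    )
    per_tx["is_hk_transcript"] = (
        per_tx["pass_expression"]
        & per_tx["pass_sd"]
        & per_tx["pass_mfc"]
        & per_tx["pass_model"]
    )
    for col, mask in (
        ("fail_expression_tissues", ~ok_expr),
        ("fail_sd_tissues", ~ok_sd),
        ("fail_mfc_tissues", ~ok_mfc),
    ):
        per_tx[col] = _failing(s, mask).reindex(per_tx.index).fillna("")
    per_tx["gene_id"] = ann.loc[per_tx.index, "gene_id"]

    genes = per_tx.groupby("gene_id")["is_hk_transcript"].any().to_frame("is_hk_gene")
    if allow_complementary_isoforms:
        # a gene also qualifies when its isoforms' passing tissues jointly
        # cover every tissue, even if no single isoform passes everywhere
        model_ok = (
            ann.loc[s["transcript_id"], "is_protein_coding"].to_numpy()
            & ann.loc[s["transcript_id"], "has_supported_model"].to_numpy()
        )
        tissue_pass = pd.DataFrame(
            {
                "gene_id": ann.loc[s["transcript_id"], "gene_id"].to_numpy(),
                "tissue": s["tissue"].to_numpy(),
                "ok": (ok_expr & ok_sd & ok_mfc).to_numpy() & model_ok,
            }
        )
        covered = (
            tissue_pass.groupby(["gene_id", "tissue"])["ok"].any().groupby("gene_id").all()
        )
        genes["is_hk_gene"] = genes["is_hk_gene"] | covered.reindex(genes.index).fillna(False)

    genes.index.name = "gene_id"
    return HKCallSet(
        transcripts=per_tx,
        genes=genes,
        params={
            "rpkm_min": rpkm_min,
            "sd_max": sd_max,
            "mfc_max": mfc_max,
            "allow_complementary_isoforms": allow_complementary_isoforms,
            "tissues": tissues,
        },
    )


def summarize_to_gene(
    expr: NormalizedExpression, annotation
) -> tuple[NormalizedExpression, pd.DataFrame]:
    """Collapse transcript RPKM to gene level (sum over isoforms).

    Returns the gene-level expression (gene IDs as row index) together
    with a gene-level pseudo-annotation frame usable by :func:`call_hk`:
    a gene is protein-coding / supported when any of its transcripts is.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    missing = [t for t in expr.transcript_ids if t not in ann.index]
    if missing:
        raise ValueError(f"transcripts missing from annotation: {missing[:5]}")
    gene_of = ann.loc[expr.transcript_ids, "gene_id"]
    gene_rpkm = expr.rpkm.groupby(gene_of.to_numpy()).sum()
    gene_rpkm.index.name = "gene_id"

    by_gene = ann.loc[expr.transcript_ids].groupby("gene_id")
    gene_ann = pd.DataFrame(
        {
            "gene_id": by_gene["gene_id"].first(),
            "gene_symbol": by_gene["gene_symbol"].first(),
            "length_bp": by_gene["length_bp"].max(),
            "is_protein_coding": by_gene["is_protein_coding"].any(),
            "has_supported_model": by_gene["has_supported_model"].any(),
            "gene_has_pseudogene": by_gene["gene_has_pseudogene"].any(),
        }
    )
    gene_ann.index.name = "transcript_id"  # gene rows act as their own "transcript"
    gene_expr = NormalizedExpression(
        rpkm=gene_rpkm,
        tmm_factors=expr.tmm_factors,
        library_sizes=expr.library_sizes,
        tissue_of=expr.tissue_of,
    )
    return gene_expr, gene_ann
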