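"""Tissue-selective candidate reference transcripts and Score Product ranking.

Within a tissue, HK transcripts that are especially stable (SD of log2
RPKM < 0.5) and abundant (mean RPKM >= 30, optional filter) and whose
gene has no known pseudogene are candidate reference transcripts for
qPCR normalization. Candidates are ranked by the Score Product: each of
the three metrics (mean RPKM, SD, MFC) is converted to a rank score —
n for the best of n candidates (highest expression, lowest SD, lowest
MFC), 1 for the worst, ties averaged — and SP is the geometric mean of
the three scores. Rank 1 is the candidate with the highest SP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .detect import HKCallSet
from .io import annotation_frame

__all__ = ["select_candidates", "score_product", "rank_all_tissues"]


def select_candidates(
    hk: HKCallSet,
    stats: pd.DataFrame,
    annotation,
    tissue: str,
    sd_max: float = 0.5,
    mean_min: float = 30.0,
    apply_mean_filter: bool = True,
) -> list[str]:
    """HK transcripts suitable as qPCR references in ``tissue``.

    Keeps HK transcripts with, in the given tissue, SD of log2 RPKM <
    ``sd_max`` and (when ``apply_mean_filter``) mean RPKM >= ``mean_min``,
    excluding isoforms of genes with known pseudogenes. The mean-RPKM
    floor guards against targets with very high or undetectable Ct;
    disabling it exposes the full stable list.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    available = sorted(stats["tissue"].unique())
    if tissue not in available:
        raise ValueError(f"unknown tissue {tissue!r}; available: {available}")
    in_tissue = stats[stats["tissue"] == tissue].set_index("transcript_id")
    out = []
    for tid in hk.hk_transcripts:
        row = in_tissue.loc[tid]
        if row["sd_log2"] >= sd_max:
            continue
        if apply_mean_filter and row["mean_rpkm"] < mean_min:
            continue
        if bool(ann.loc[tid, "gene_has_pseudogene"]):
            continue
        out.append(tid)
    return out


def score_product(entries: pd.DataFrame) -> pd.DataFrame:
    """Score Product ranking of one tissue's candidates.

    ``entries``: DataFrame indexed by transcript ID with columns
    ``mean_rpkm``, ``sd_log2``, ``mfc``. Returns the same rows with
    ``score1`` (expression; n = highest mean RPKM), ``score2`` (n =
    lowest SD), ``score3`` (n = lowest MFC), ``sp`` (geometric mean of
    the three, k = 3) and ``rank`` (1 = highest SP; ties broken by lower
    SD, then lower MFC, then transcript ID).
    """
    if len(entries) == 0:
        raise ValueError("no candidate entries to rank")
    df = entries.copy()
    df["score1"] = rankdata(df["mean_rpkm"].to_numpy())  # n = highest expression
    df["score2"] = rankdata(-df["sd_log2"].to_numpy())  # n = lowest SD
    df["score3"] = rankdata(-df["mfc"].to_numpy())  # n = lowest MFC
    df["sp"] = (df["score1"] * df["score2"] * df["score3"]) ** (1.0 / 3.0)
    order = sorted(
        df.index,
        key=lambda t: (-df.at[t, "sp"], df.at[t, "sd_log2"], df.at[t, "mfc"], str(t)),
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    df["rank"] = ranks.reindex(df.index)
    return df  # input row order preserved; sort by "rank" for presentation


def rank_all_tissues(
    hk: HKCallSet,
    stats: pd.DataFrame,
    annotation,
    sd_max: float = 0.5,
    mean_min: float = 30.0,
    apply_mean_filter: bool = True,
) -> dict[str, pd.DataFrame]:
    """Candidate selection + Score Product for every tissue.

    Tissues with no candidates map to an empty DataFrame (reported
    explicitly rather than omitted).
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    out: dict[str, pd.DataFrame] = {}
    cols = ["mean_rpkm", "sd_log2", "mfc"]
    for tissue in sorted(stats["tissue"].unique()):
        cands = select_candidates(
            hk, stats, ann, tissue,
            sd_max=sd_max, mean_min=mean_min, apply_mean_filter=apply_mean_filter,
        )
        if not cands:
            out[tissue] = pd.DataFrame(
                columns=cols + ["score1", "score2", "score3", "sp", "rank"]
            )
            continue
        in_tissue = (
            stats[stats["tissue"] == tissue]
            .set_index("transcript_id")
            .loc[cands, cols]
        )
        ranked = score_product(in_tissue).sort_values("rank")
        ranked.insert(0, "gene_symbol", ann.loc[ranked.index, "gene_symbol"].to_numpy())
        out[tissue] = ranked
    return out


def stable_tissues_of(
    hk: HKCallSet,
    stats: pd.DataFrame,
    annotation,
    transcript_id: str,
    sd_max: float = 0.5,
    mean_min: float = 30.0,
    apply_mean_filter: bool = True,
) -> list[str]:
    """Tissues in which a transcript qualifies as a candidate reference."""
    return [
        t
        for t in sorted(stats["tissue"].unique())
        if transcript_id
        in select_candidates(
            hk, stats, annotation, t,
            sd_max=sd_max, mean_min=mean_min, apply_mean_filter=apply_mean_filter,
        )
    ]
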