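"""Validation machinery: geNorm M stability and subsampling simulations.

geNorm M (Vandesompele et al. 2002): for candidates j and k, V_jk is the
standard deviation across samples of log2(x_j / x_k); M_j is the mean of
V_jk over all k != j. Lower M means more stable. The stepwise procedure
iteratively drops the least stable candidate and recomputes M until two
remain.

The two subsampling simulations probe how the number of transcripts
satisfying the HK criteria responds to (a) the diversity of tissues
analyzed and (b) the number of samples per tissue — both seeded and
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import DEFAULT_PSEUDOCOUNT, call_hk, stability_stats
from .io import CountMatrix, annotation_frame
from .normalize import NormalizedExpression, normalize_by_tissue

__all__ = [
    "GenormResult",
    "SubsampleResult",
    "genorm_m",
    "simulate_tissue_diversity",
    "simulate_sample_size",
]


@dataclass
class GenormResult:
    """geNorm output: M per candidate, stability ranking, exclusion order."""

    m_values: pd.Series  # index: candidate IDs
    ranking: list[str]  # ascending M (most stable first)
    stepwise_exclusion_order: list[str]  # least stable first; final pair last

    def to_frame(self) -> pd.DataFrame:
        return (
            self.m_values.rename("genorm_m")
            .rename_axis("candidate")
            .reset_index()
            .sort_values("genorm_m", kind="mergesort")
            .reset_index(drop=True)
        )

    def to_dict(self) -> dict:
        return {
            "m_values": self.m_values.to_dict(),
            "ranking": self.ranking,
            "stepwise_exclusion_order": self.stepwise_exclusion_order,
        }


def _pairwise_m(logx: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_samples(logx_j - logx_k)."""
    m = np.zeros(logx.shape[0])
    for j in range(logx.shape[0]):
        sds = [
            np.std(logx[j] - logx[k], ddof=1)
            for k in range(logx.shape[0])
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return m


def genorm_m(
    expr: pd.DataFrame,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> GenormResult:
    """geNorm expression-stability measure for candidate references.

    ``expr``: candidates x samples table of positive relative quantities
    (RPKM, or relative qPCR quantities). Requires at least two candidates
    and two samples. Ties in M are broken lexicographically.
    """
    if expr.shape[0] < 2:
        raise ValueError("geNorm requires at least 2 candidates")
    if expr.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    x = expr.to_numpy(dtype=float) + pseudo
    if (x <= 0).any():
        raise ValueError("expression values must be positive after pseudocount")
    logx = np.log2(x)
    ids = list(expr.index)
    m_all = pd.Series(_pairwise_m(logx), index=ids, name="genorm_m")
    ranking = list(m_all.sort_values(kind="mergesort").index)

    # stepwise exclusion: drop the highest-M candidate, recompute, repeat
    remaining = list(ids)
    exclusion: list[str] = []
    while len(remaining) > 2:
        sub = logx[[ids.index(r) for r in remaining]]
        m = pd.Series(_pairwise_m(sub), index=remaining)
        worst = m.sort_values(ascending=False, kind="mergesort").index[0]
        exclusion.append(worst)
        remaining.remove(worst)
    exclusion.extend(sorted(remaining, key=lambda r: (-m_all[r], r)))
    return GenormResult(
        m_values=m_all, ranking=ranking, stepwise_exclusion_order=exclusion
    )


@dataclass
class SubsampleResult:
    """Per-permutation stable-transcript counts for each group size."""

    group_sizes: list[int]
    n_permutations: int
    counts: np.ndarray  # shape (len(group_sizes), n_permutations)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.group_sizes), self.n_permutations):
            raise ValueError("counts shape does not match group sizes / permutations")

    @property
    def median_stable_count(self) -> pd.Series:
        return pd.Series(
            np.median(self.counts, axis=1),
            index=pd.Index(self.group_sizes, name="group_size"),
            name="median_stable_count",
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.group_sizes, name="group_size"),
            columns=[f"perm_{i}" for i in range(self.n_permutations)],
        )
        df.insert(0, "median_stable_count", self.median_stable_count)
        return df

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "median_stable_count": self.median_stable_count.to_dict(),
            "per_permutation_counts": self.counts.tolist(),
            "params": self.params,
        }


def _tissue_pass_table(
    expr: NormalizedExpression,
    annotation: pd.DataFrame,
    rpkm_min: float,
    sd_max: float,
    mfc_max: float,
    pseudo: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Boolean transcript x tissue pass table plus the model-support vector.

    Because each criterion must hold in every tissue, the HK status on any
    tissue subset is the AND of the per-tissue columns — so the table is
    computed once and subsets are evaluated by column conjunction.
    """
    stats = stability_stats(expr, pseudo=pseudo)
    ok = (
        (stats["mean_rpkm"] > rpkm_min)
        & (stats["sd_log2"] < sd_max)
        & (stats["mfc"] < mfc_max)
        & stats["mfc_valid"]
    )
    table = (
        pd.DataFrame(
            {
                "transcript_id": stats["transcript_id"],
                "tissue": stats["tissue"],
                "ok": ok,
            }
        )
        .pivot(index="transcript_id", columns="tissue", values="ok")
        .fillna(False)
    )
    model_ok = (
        annotation.loc[table.index, "is_protein_coding"].to_numpy()
        & annotation.loc[table.index, "has_supported_model"].to_numpy()
    )
    return table, model_ok


def simulate_tissue_diversity(
    expr: NormalizedExpression,
    annotation,
    group_sizes: Sequence[int] = (5, 10, 15, 20, 30, 50),
    n_perm: int = 100,
    seed: int = 0,
    rpkm_min: float = 1.0,
    sd_max: float = 1.0,
    mfc_max: float = 2.0,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> SubsampleResult:
    """How tissue diversity affects the number of stable (HK) transcripts.

    For each group size g, draws g tissues without replacement (n_perm
    permutations, seeded) and counts the transcripts meeting every HK
    criterion in all g tissues. Per-tissue normalization is reused from
    the full data: dropping other tissues does not change the factors
    within an untouched tissue.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    tissues = expr.tissues()
    for g in group_sizes:
        if g > len(tissues):
            raise ValueError(
                f"group size {g} exceeds available tissues ({len(tissues)})"
            )
    table, model_ok = _tissue_pass_table(expr, ann, rpkm_min, sd_max, mfc_max, pseudo)
    passmat = table.to_numpy(dtype=bool)
    col_of = {t: i for i, t in enumerate(table.columns)}

    children = np.random.SeedSequence(seed).spawn(len(group_sizes))
    counts = np.zeros((len(group_sizes), n_perm), dtype=np.int64)
    for gi, (g, child) in enumerate(zip(group_sizes, children)):
        rng = np.random.default_rng(child)
        for p in range(n_perm):
            chosen = rng.choice(len(tissues), size=g, replace=False)
            cols = [col_of[tissues[i]] for i in chosen]
            counts[gi, p] = int(
                (passmat[:, cols].all(axis=1) & model_ok).sum()
            )
    return SubsampleResult(
        group_sizes=list(group_sizes),
        n_permutations=n_perm,
        counts=counts,
        seed=seed,
        params={
            "mode": "tissue_diversity",
            "rpkm_min": rpkm_min,
            "sd_max": sd_max,
            "mfc_max": mfc_max,
        },
    )


def simulate_sample_size(
    counts: CountMatrix,
    meta,
    annotation,
    sizes: Sequence[int],
    n_perm: int = 100,
    seed: int = 0,
    rpkm_min: float = 1.0,
    sd_max: float = 1.0,
    mfc_max: float = 2.0,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> SubsampleResult:
    """How within-tissue sample size affects the stable-transcript count.

    For each requested per-tissue sample count, draws that many samples
    within every tissue (without replacement, seeded), re-runs per-tissue
    TMM normalization on the subset — subsampling within a tissue changes
    that tissue's factors — and counts transcripts meeting every HK
    criterion in all tissues. Operates on raw counts because TMM must be
    recomputed per subset.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    if isinstance(meta, pd.Series):
        tissue_of = meta.astype(str)
    else:
        tissue_of = pd.Series({m.sample_id: m.tissue for m in meta})
    tissue_of = tissue_of.reindex(counts.sample_ids)
    by_tissue = {
        t: list(tissue_of.index[tissue_of == t]) for t in tissue_of.unique()
    }
    for k in sizes:
        short = [t for t, s in by_tissue.items() if len(s) < k]
        if short:
            raise ValueError(
                f"requested {k} samples per tissue but tissues {short[:5]} have fewer"
            )

    children = np.random.SeedSequence(seed).spawn(len(sizes))
    out = np.zeros((len(sizes), n_perm), dtype=np.int64)
    for ki, (k, child) in enumerate(zip(sizes, children)):
        rng = np.random.default_rng(child)
        for p in range(n_perm):
            chosen: list[str] = []
            for t in by_tissue:
                samples = by_tissue[t]
                idx = rng.choice(len(samples), size=k, replace=False)
                chosen.extend(samples[i] for i in idx)
            sub = counts.subset_samples(chosen)
            expr = normalize_by_tissue(sub, tissue_of[chosen], ann)
            stats = stability_stats(expr, pseudo=pseudo)
            calls = call_hk(
                stats, ann, rpkm_min=rpkm_min, sd_max=sd_max, mfc_max=mfc_max
            )
            out[ki, p] = len(calls.hk_transcripts)
    return SubsampleResult(
        group_sizes=list(sizes),
        n_permutations=n_perm,
        counts=out,
        seed=seed,
        params={
            "mode": "sample_size",
            "rpkm_min": rpkm_min,
            "sd_max": sd_max,
            "mfc_max": mfc_max,
        },
    )
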