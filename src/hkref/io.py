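"""Input/output: count matrices, sample metadata, transcript annotation.

Containers are thin dataclasses around pandas objects; every reader
validates the invariants the downstream pipeline relies on (unique IDs,
non-negative integer counts, positive transcript lengths).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "TranscriptAnnotation",
    "ValidationError",
    "read_counts",
    "read_metadata",
    "read_annotation",
    "filter_samples",
    "write_results",
    "annotation_frame",
    "strip_version",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.N`` version suffix from an Ensembl-style ID."""
    return _VERSION_RE.sub("", identifier)


@dataclass
class CountMatrix:
    """Raw transcript x sample read counts.

    ``counts`` is a DataFrame indexed by transcript ID with sample IDs as
    columns; values are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0:
            raise ValidationError("no transcripts in count matrix")
        if df.shape[1] == 0:
            raise ValidationError("no samples in count matrix")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript IDs: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (arr < 0).any():
            bad = df.index[(arr < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for transcripts: {bad[:5]}")
        if not np.allclose(arr, np.round(arr.astype(float))):
            raise ValidationError("counts must be integers")
        self.counts = df.astype(np.int64)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_transcripts(self, transcript_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(transcript_ids)])


@dataclass
class SampleMetadata:
    """Per-sample library metadata used by the quality filters.

    Fields that a source does not provide (e.g. alignment rate in some
    consortium downloads) may be ``None``; the corresponding filter is
    then treated as not applicable.
    """

    sample_id: str
    tissue: str
    depth: int | None = None
    alignment_rate: float | None = None
    protocol: str | None = None  # "mRNA_enrichment" or "other"
    layout: str | None = None  # "paired" or "single"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample_id")
        if not self.tissue:
            raise ValidationError(f"sample {self.sample_id}: empty tissue")
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"sample {self.sample_id}: negative depth")
        if self.alignment_rate is not None and not (0.0 <= self.alignment_rate <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: alignment_rate {self.alignment_rate} "
                "outside [0, 1]"
            )
        if self.layout is not None and self.layout not in ("paired", "single"):
            raise ValidationError(f"sample {self.sample_id}: bad layout {self.layout!r}")


@dataclass
class TranscriptAnnotation:
    """Transcript-level annotation: gene linkage, length and model support."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    length_bp: int
    is_protein_coding: bool = True
    has_supported_model: bool = True
    gene_has_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: length_bp {self.length_bp} < 1"
            )


def annotation_frame(annotations: Iterable[TranscriptAnnotation]) -> pd.DataFrame:
    """Tabulate annotations as a DataFrame indexed by transcript ID."""
    rows = list(annotations)
    if not rows:
        raise ValidationError("empty annotation")
    df = pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in rows],
            "gene_id": [a.gene_id for a in rows],
            "gene_symbol": [a.gene_symbol for a in rows],
            "length_bp": [a.length_bp for a in rows],
            "is_protein_coding": [a.is_protein_coding for a in rows],
            "has_supported_model": [a.has_supported_model for a in rows],
            "gene_has_pseudogene": [a.gene_has_pseudogene for a in rows],
        }
    ).set_index("transcript_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate transcript IDs in annotation: {dups[:5]}")
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(
    path: str | Path,
    format: str = "tsv",
    strip_versions: bool = False,
) -> CountMatrix:
    """Read a transcript x sample count matrix.

    Parameters
    ----------
    path
        TSV/CSV with the transcript ID in the first column and sample IDs
        in the header, or a MatrixMarket ``.mtx`` file with sidecar
        ``<path>.rows`` / ``<path>.cols`` ID files (one ID per line).
    format
        One of ``tsv``, ``csv``, ``mtx``.
    strip_versions
        Strip trailing ``.N`` version suffixes from transcript IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
            raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
        if df.shape[0] == 0:
            raise ValidationError(f"{path}: no transcripts")
    elif format == "mtx":
        from scipy.io import mmread

        rows_path = Path(str(path) + ".rows")
        cols_path = Path(str(path) + ".cols")
        for side in (rows_path, cols_path):
            if not side.exists():
                raise FileNotFoundError(f"missing MTX sidecar ID file: {side}")
        mat = mmread(str(path))
        transcript_ids = rows_path.read_text().split()
        sample_ids = cols_path.read_text().split()
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(transcript_ids), len(sample_ids)):
            raise ValidationError(
                f"{path}: matrix shape {dense.shape} does not match sidecar IDs "
                f"({len(transcript_ids)} rows, {len(sample_ids)} cols)"
            )
        df = pd.DataFrame(dense, index=transcript_ids, columns=sample_ids)
    else:
        raise ValueError(f"unknown count format {format!r}")
    df.index = df.index.astype(str)
    if strip_versions:
        df.index = [strip_version(t) for t in df.index]
    df.index.name = None
    df.columns.name = None
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    sep = "\t" if format == "tsv" else ","
    cm.counts.rename_axis("transcript").to_csv(path, sep=sep)


_META_COLUMNS = ["sample_id", "tissue", "depth", "alignment_rate", "protocol", "layout"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from a TSV with the standard column set.

    Mandatory columns: ``sample_id``, ``tissue``. Optional: ``depth``,
    ``alignment_rate``, ``protocol``, ``layout`` (missing columns or empty
    cells become ``None``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    for col in ("sample_id", "tissue"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    out: list[SampleMetadata] = []
    for _, row in df.iterrows():
        def _get(col: str):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return row[col]

        depth = _get("depth")
        rate = _get("alignment_rate")
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                tissue=str(row["tissue"]),
                depth=int(depth) if depth is not None else None,
                alignment_rate=float(rate) if rate is not None else None,
                protocol=_get("protocol"),
                layout=_get("layout"),
            )
        )
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample IDs")
    return out


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in meta])[_META_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


_ANN_COLUMNS = [
    "transcript_id",
    "gene_id",
    "gene_symbol",
    "length_bp",
    "is_protein_coding",
    "has_supported_model",
    "gene_has_pseudogene",
]


def read_annotation(
    path: str | Path,
    format: str = "tsv",
    strip_versions: bool = False,
) -> list[TranscriptAnnotation]:
    """Read transcript annotation from a flat TSV or an Ensembl-style GTF.

    For GTF input, ``length_bp`` is the sum of exon lengths (1-based
    inclusive coordinates, overlapping exons merged per transcript);
    ``is_protein_coding`` comes from ``transcript_biotype``/``gene_biotype``
    and ``has_supported_model`` from CCDS/RefSeq support tags
    (``tag "CCDS"``, ``tag "RefSeq"``, ``ccds_id`` or ``basic``).
    A ``gene_has_pseudogene`` attribute is honoured when present and
    defaults to False (GTF does not record pseudogene parentage).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_annotation_tsv(path, strip_versions)
    if format == "gtf":
        return _read_annotation_gtf(path, strip_versions)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_annotation_tsv(path: Path, strip_versions: bool) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "gene_id", "length_bp"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    out = []
    for _, row in df.iterrows():
        tid = str(row["transcript_id"])
        if strip_versions:
            tid = strip_version(tid)
        out.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=str(row["gene_id"]),
                gene_symbol=str(row.get("gene_symbol", row["gene_id"])),
                length_bp=int(row["length_bp"]),
                is_protein_coding=_as_bool(row.get("is_protein_coding", True)),
                has_supported_model=_as_bool(row.get("has_supported_model", True)),
                gene_has_pseudogene=_as_bool(row.get("gene_has_pseudogene", False)),
            )
        )
    ids = [a.transcript_id for a in out]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate transcript IDs")
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "t", "1", "yes")
    return bool(value)


_SUPPORT_TAGS = ("ccds", "refseq", "basic")


def _read_annotation_gtf(path: Path, strip_versions: bool) -> list[TranscriptAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # exon intervals per transcript; merge overlaps before summing
    exons: dict[str, list[tuple[int, int]]] = {}
    chrom_of: dict[str, str] = {}
    attrs_of: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype != "exon":
            if feat.featuretype == "transcript":
                tids = feat.attributes.get("transcript_id", [])
                if tids:
                    attrs_of.setdefault(tids[0], dict(feat.attributes))
            continue
        tids = feat.attributes.get("transcript_id", [])
        if not tids:
            continue
        tid = tids[0]
        prev_chrom = chrom_of.setdefault(tid, feat.seqid)
        if prev_chrom != feat.seqid:
            raise ValidationError(
                f"inconsistent annotation: transcript {tid} has exons on "
                f"{prev_chrom} and {feat.seqid}"
            )
        exons.setdefault(tid, []).append((feat.start, feat.end))
        attrs_of.setdefault(tid, dict(feat.attributes))

    out = []
    for tid, attrs in attrs_of.items():
        intervals = exons.get(tid)
        if not intervals:
            import warnings

            warnings.warn(f"transcript {tid} has no exons; excluded")
            continue
        length = _merged_length(intervals)
        biotype = (
            attrs.get("transcript_biotype", attrs.get("gene_biotype", [""]))[0].lower()
        )
        tags = [t.lower() for t in attrs.get("tag", [])]
        supported = (
            any(any(s in t for s in _SUPPORT_TAGS) for t in tags)
            or "ccds_id" in attrs
        )
        out_tid = strip_version(tid) if strip_versions else tid
        gene_id = attrs.get("gene_id", ["?"])[0]
        out.append(
            TranscriptAnnotation(
                transcript_id=out_tid,
                gene_id=strip_version(gene_id) if strip_versions else gene_id,
                gene_symbol=attrs.get("gene_name", [gene_id])[0],
                length_bp=length,
                is_protein_coding=biotype == "protein_coding",
                has_supported_model=supported,
                gene_has_pseudogene=_as_bool(
                    attrs.get("gene_has_pseudogene", ["false"])[0]
                ),
            )
        )
    return out


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, overlaps merged."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = ivs[0]
    for start, end in ivs[1:]:
        if start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    total += cur_end - cur_start + 1
    return total


def write_annotation(
    annotations: Sequence[TranscriptAnnotation], path: str | Path
) -> None:
    pd.DataFrame([a.__dict__ for a in annotations])[_ANN_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample-level quality filtering
# ---------------------------------------------------------------------------


def filter_samples(
    meta: Sequence[SampleMetadata],
    min_depth: int = 20_000_000,
    min_alignment: float = 0.70,
    require_paired: bool = True,
    require_mrna: bool = True,
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply library-quality filters to sample metadata.

    A sample is kept when its sequencing depth is at least ``min_depth``
    reads, its alignment rate is strictly greater than ``min_alignment``,
    and (when required) the library is paired-end and built from an mRNA
    enrichment protocol. Fields recorded as ``None`` make the
    corresponding filter not applicable for that sample.

    Returns the kept sample IDs (input order preserved) and a report
    mapping each excluded sample to its exclusion reasons.
    """
    kept: list[str] = []
    report: dict[str, list[str]] = {}
    for m in meta:
        reasons = []
        if m.depth is not None and m.depth < min_depth:
            reasons.append(f"depth {m.depth} < {min_depth}")
        if m.alignment_rate is not None and not (m.alignment_rate > min_alignment):
            reasons.append(f"alignment_rate {m.alignment_rate} <= {min_alignment}")
        if require_paired and m.layout is not None and m.layout != "paired":
            reasons.append(f"layout {m.layout} != paired")
        if require_mrna and m.protocol is not None and m.protocol != "mRNA_enrichment":
            reasons.append(f"protocol {m.protocol} != mRNA_enrichment")
        if reasons:
            report[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    if not kept:
        report["__summary__"] = ["no samples passed the quality filters"]
    return kept, report


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def write_results(obj, path: str | Path, format: str = "csv") -> None:
    """Write a pipeline result object to CSV or JSON.

    Objects exposing ``to_frame()`` are written as a CSV table with a
    deterministic column order; objects exposing ``to_dict()`` (or plain
    dicts of DataFrames, e.g. per-tissue rankings) are written as JSON.
    """
    path = Path(path)
    if format == "csv":
        if hasattr(obj, "to_frame"):
            frame = obj.to_frame()
        elif isinstance(obj, pd.DataFrame):
            frame = obj
        else:
            raise TypeError(f"cannot write {type(obj).__name__} as CSV")
        frame.to_csv(path, index=not isinstance(frame.index, pd.RangeIndex))
    elif format == "json":
        payload = _jsonable(obj)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def _jsonable(obj):
    if hasattr(obj, "to_dict") and not isinstance(obj, (pd.DataFrame, pd.Series)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index().to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
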