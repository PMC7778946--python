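"""qPCR primer-pair quality control.

Checks each pair against the design constraints used for reference-
transcript primers: per-primer GC content between 50 and 60%, melting
temperature between 50 and 65 C with a pair difference below 3 C,
amplicon length between 75 and 200 bp, no single-base runs longer than
4, and an advisory screen for hairpin / primer-dimer potential.

Melting temperatures use the nearest-neighbor thermodynamic model
(SantaLucia 2004 unified parameters) with the Owczarzy monovalent +
magnesium salt correction, evaluated at 50 mM Na+, 1.5 mM Mg2+ and
200 nM oligo unless overridden.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "PrimerPair",
    "PrimerQCReport",
    "gc_content",
    "melting_temperature",
    "reverse_complement",
    "check_pair",
    "read_primer_table",
    "check_table",
]

_DNA_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MIN_PRIMER_LEN = 8


def _validate_seq(seq: str) -> str:
    s = seq.strip().upper()
    if not s:
        raise ValueError("empty primer sequence")
    if not _DNA_RE.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in primer sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return _validate_seq(seq).translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage of a primer sequence: 100 * (#G + #C) / length."""
    s = _validate_seq(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def melting_temperature(
    seq: str,
    na_mM: float = 50.0,
    mg_mM: float = 1.5,
    oligo_nM: float = 200.0,
) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    SantaLucia (2004) unified NN parameters; Owczarzy (2008) salt
    correction covering both monovalent and divalent ions. ``oligo_nM``
    is the annealing oligo concentration (primer assumed in excess over
    template).
    """
    s = _validate_seq(seq)
    if len(s) < MIN_PRIMER_LEN:
        raise ValueError(
            f"sequence of length {len(s)} too short for NN Tm (min {MIN_PRIMER_LEN})"
        )
    return float(
        _mt.Tm_NN(
            s,
            nn_table=_mt.DNA_NN4,
            Na=na_mM,
            Mg=mg_mM,
            dnac1=oligo_nM,
            dnac2=0,
            saltcorr=7,
        )
    )


def max_homopolymer_run(seq: str) -> int:
    s = _validate_seq(seq)
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _longest_complementary_run(a: str, b: str) -> tuple[int, bool]:
    """Longest antiparallel complementary stretch between two primers.

    Equivalent to the longest common substring of ``a`` and the reverse
    complement of ``b``. Returns (length, involves_three_prime_end):
    the flag is set when a maximal-length run reaches the 3' end of
    either primer.
    """
    rb = reverse_complement(b)
    n, m = len(a), len(rb)
    best = 0
    best_3p = False
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] >= best:
                    # run ends at a[i-1] / rb[j-1]; rb position j-1 maps to
                    # b position m-j, so the run touches b's 3' end when
                    # the run start in rb is index j-cur[j] == 0
                    at_3p = (i == n) or (j - cur[j] == 0)
                    if cur[j] > best:
                        best = cur[j]
                        best_3p = at_3p
                    else:
                        best_3p = best_3p or at_3p
        prev = cur
    return best, best_3p


@dataclass
class PrimerPair:
    """A qPCR primer pair with its measurable design properties."""

    forward_seq: str
    reverse_seq: str
    target_transcript: str = ""
    amplicon_length: int | None = None
    spans_junction: bool | None = None

    def __post_init__(self) -> None:
        self.forward_seq = _validate_seq(self.forward_seq)
        self.reverse_seq = _validate_seq(self.reverse_seq)
        if self.amplicon_length is not None:
            if self.amplicon_length < max(len(self.forward_seq), len(self.reverse_seq)):
                raise ValueError(
                    "amplicon_length shorter than a primer "
                    f"({self.amplicon_length} bp)"
                )


@dataclass
class PrimerQCReport:
    """Per-check results with measured values; overall pass on mandatory checks."""

    checks: pd.DataFrame  # columns: check, value, passed, mandatory
    overall_pass: bool
    target_transcript: str = ""
    tm_model: str = "NN SantaLucia 2004 / Owczarzy 2008 salt correction"

    def to_frame(self) -> pd.DataFrame:
        df = self.checks.copy()
        df.insert(0, "target_transcript", self.target_transcript)
        return df

    def to_dict(self) -> dict:
        return {
            "target_transcript": self.target_transcript,
            "overall_pass": self.overall_pass,
            "tm_model": self.tm_model,
            "checks": self.checks.to_dict(orient="records"),
        }


def check_pair(
    pair: PrimerPair,
    tm_lo: float = 50.0,
    tm_hi: float = 65.0,
    dtm_max: float = 3.0,
    gc_lo: float = 50.0,
    gc_hi: float = 60.0,
    amp_lo: int = 75,
    amp_hi: int = 200,
    max_homopolymer: int = 4,
    max_comp_run: int = 6,
    max_comp_run_3p: int = 4,
    na_mM: float = 50.0,
    mg_mM: float = 1.5,
    oligo_nM: float = 200.0,
) -> PrimerQCReport:
    """Evaluate every design constraint for one primer pair.

    Mandatory checks: GC range (both primers), Tm range (both), Tm
    difference, amplicon length range, homopolymer runs. The hairpin /
    primer-dimer screen (a complementary stretch of ``max_comp_run`` or
    more bases anywhere, or ``max_comp_run_3p`` or more reaching a 3'
    end) and the exon-junction flag are advisory and do not affect
    ``overall_pass``. Range bounds are inclusive; the Tm difference must
    be strictly below ``dtm_max``.
    """
    gc_f = gc_content(pair.forward_seq)
    gc_r = gc_content(pair.reverse_seq)
    tm_f = melting_temperature(pair.forward_seq, na_mM, mg_mM, oligo_nM)
    tm_r = melting_temperature(pair.reverse_seq, na_mM, mg_mM, oligo_nM)
    dtm = abs(tm_f - tm_r)
    homo = max(
        max_homopolymer_run(pair.forward_seq), max_homopolymer_run(pair.reverse_seq)
    )
    hairpin_f, hp_f_3p = _longest_complementary_run(pair.forward_seq, pair.forward_seq)
    hairpin_r, hp_r_3p = _longest_complementary_run(pair.reverse_seq, pair.reverse_seq)
    dimer, dimer_3p = _longest_complementary_run(pair.forward_seq, pair.reverse_seq)

    def _struct_ok(run: int, at_3p: bool) -> bool:
        return run < max_comp_run and not (at_3p and run >= max_comp_run_3p)

    rows = [
        ("gc_forward", gc_f, gc_lo <= gc_f <= gc_hi, True),
        ("gc_reverse", gc_r, gc_lo <= gc_r <= gc_hi, True),
        ("tm_forward", tm_f, tm_lo <= tm_f <= tm_hi, True),
        ("tm_reverse", tm_r, tm_lo <= tm_r <= tm_hi, True),
        ("tm_delta", dtm, dtm < dtm_max, True),
        ("homopolymer", float(homo), homo <= max_homopolymer, True),
        (
            "hairpin",
            float(max(hairpin_f, hairpin_r)),
            _struct_ok(hairpin_f, hp_f_3p) and _struct_ok(hairpin_r, hp_r_3p),
            False,
        ),
        ("dimer", float(dimer), _struct_ok(dimer, dimer_3p), False),
    ]
    if pair.amplicon_length is not None:
        rows.insert(
            5,
            (
                "amplicon_range",
                float(pair.amplicon_length),
                amp_lo <= pair.amplicon_length <= amp_hi,
                True,
            ),
        )
    if pair.spans_junction is not None:
        rows.append(("junction_flag", float(pair.spans_junction), True, False))

    checks = pd.DataFrame(rows, columns=["check", "value", "passed", "mandatory"])
    overall = bool(checks.loc[checks["mandatory"], "passed"].all())
    return PrimerQCReport(
        checks=checks, overall_pass=overall, target_transcript=pair.target_transcript
    )


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read a primer-pair TSV: columns forward, reverse, target_transcript,
    optional amplicon_length and spans_junction."""
    df = pd.read_csv(path, sep="\t")
    for col in ("forward", "reverse"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    pairs = []
    for _, row in df.iterrows():
        amp = row.get("amplicon_length")
        spans = row.get("spans_junction")
        pairs.append(
            PrimerPair(
                forward_seq=str(row["forward"]),
                reverse_seq=str(row["reverse"]),
                target_transcript=str(row.get("target_transcript", "")),
                amplicon_length=int(amp) if pd.notna(amp) else None,
                spans_junction=bool(spans) if pd.notna(spans) else None,
            )
        )
    return pairs


def check_table(pairs: list[PrimerPair], **kwargs) -> pd.DataFrame:
    """QC a list of primer pairs; one summary row per pair."""
    rows = []
    for pair in pairs:
        rep = check_pair(pair, **kwargs)
        vals = rep.checks.set_index("check")["value"]
        passed = rep.checks.set_index("check")["passed"]
        row = {"target_transcript": pair.target_transcript, "overall_pass": rep.overall_pass}
        for name in vals.index:
            row[name] = vals[name]
            row[f"{name}_pass"] = bool(passed[name])
        rows.append(row)
    return pd.DataFrame(rows)
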