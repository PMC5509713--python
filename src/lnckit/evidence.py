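"""Tabular similarity/domain/signal-peptide evidence and per-track screens.

Hit tables use the ubiquitous 12-column tab-separated layout (query id,
subject id, percent identity, alignment length, mismatches, gap opens,
q_start, q_end, s_start, s_end, e-value, bit score; 1-based inclusive
coordinates, s_start > s_end marking a minus-strand subject).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align

from .seqcore import Transcript

__all__ = [
    "HitRecord",
    "EvidenceBundle",
    "parse_hit_table",
    "write_hit_table",
    "symbiont_contaminants",
    "coding_evidence_flags",
    "parse_signal_calls",
    "builtin_local_align",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    def to_line(self) -> str:
        # %r on floats keeps the round trip through parse_hit_table exact
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.percent_identity!r}",
                str(self.alignment_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.e_value!r}",
                f"{self.bit_score!r}",
            ]
        )


@dataclass
class EvidenceBundle:
    """Per-transcript evidence flags aggregated across all tracks.

    ``plek_coding`` may be None when no precomputed coding/noncoding call
    is available (the k-mer model is used instead downstream).
    """

    symbiont_hit: set[str] = field(default_factory=set)
    protein_hit: set[str] = field(default_factory=set)
    domain_hit: set[str] = field(default_factory=set)
    signal_peptide: set[str] = field(default_factory=set)
    housekeeping_hit: set[str] = field(default_factory=set)
    plek_coding: dict[str, bool] | None = None
    best_evalue: dict[str, float] = field(default_factory=dict)


def parse_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (no header)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_line() + "\n")


def symbiont_contaminants(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
    e_cutoff: float = 1e-3,
    rule: str = "and",
) -> set[str]:
    """Transcripts flagged as symbiont contamination.

    A transcript is a contaminant iff some hit covers more than half of
    the query AND (default) more than half of the subject, at e-value
    below ``e_cutoff``.  ``rule="or"`` relaxes the coverage condition to
    either side (the wording of the source criterion admits both
    readings).
    """
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    contaminants: set[str] = set()
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"no recorded length for query {hit.query_id!r}")
        if hit.subject_id not in subject_lengths:
            raise KeyError(f"no recorded length for subject {hit.subject_id!r}")
        if hit.e_value >= e_cutoff:
            continue
        q_cov = hit.alignment_length > 0.5 * query_lengths[hit.query_id]
        s_cov = hit.alignment_length > 0.5 * subject_lengths[hit.subject_id]
        ok = (q_cov and s_cov) if rule == "and" else (q_cov or s_cov)
        if ok:
            contaminants.add(hit.query_id)
    return contaminants


def parse_signal_calls(path: str | Path) -> set[str]:
    """Read a two-column (transcript_id, {Y,N}) signal-peptide call table."""
    positives: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            tid, call = parts
            if call not in ("Y", "N"):
                raise ValueError(f"{path}:{lineno}: call must be Y or N, got {call!r}")
            if call == "Y":
                positives.add(tid)
    return positives


def coding_evidence_flags(
    protein_hits: Iterable[HitRecord],
    domain_hits: Iterable[HitRecord],
    signal_positives: Iterable[str],
    e_protein: float = 1e-4,
    e_domain: float | None = None,
) -> EvidenceBundle:
    """Aggregate the three protein-coding evidence tracks.

    protein_hit: any protein-database hit at e-value <= ``e_protein``.
    domain_hit: any domain hit (optionally thresholded by ``e_domain``).
    signal_peptide: listed positive in the call table.
    """
    bundle = EvidenceBundle()
    for hit in protein_hits:
        if hit.e_value <= e_protein:
            bundle.protein_hit.add(hit.query_id)
            prev = bundle.best_evalue.get(hit.query_id, math.inf)
            bundle.best_evalue[hit.query_id] = min(prev, hit.e_value)
    for hit in domain_hits:
        if e_domain is None or hit.e_value <= e_domain:
            bundle.domain_hit.add(hit.query_id)
    bundle.signal_peptide = set(signal_positives)
    return bundle


def builtin_local_align(
    query: Transcript,
    subject: Transcript,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> list[HitRecord]:
    """Best local alignment, reported as a 12-column hit record.

    Fixture-grade replacement for an external similarity search: the
    e-value is a crude length-scaled transform e = m*n*2^(-bit) with
    bit = score/2, not a database statistic.  Returns an empty list when
    the best local score is <= 0.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignments = aligner.align(query.sequence, subject.sequence)
    if len(alignments) == 0 or alignments.score <= 0:
        return []
    aln = alignments[0]
    q_blocks, s_blocks = aln.aligned
    q_start = int(q_blocks[0][0])
    q_end = int(q_blocks[-1][1])
    s_start = int(s_blocks[0][0])
    s_end = int(s_blocks[-1][1])

    matches = 0
    mismatches = 0
    aligned_cols = 0
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        for qi, si in zip(range(qa, qb), range(sa, sb)):
            aligned_cols += 1
            if query.sequence[qi] == subject.sequence[si]:
                matches += 1
            else:
                mismatches += 1
    gap_opens = len(q_blocks) - 1
    # alignment length includes gapped columns
    gap_cols = (q_end - q_start - aligned_cols) + (s_end - s_start - aligned_cols)
    alignment_length = aligned_cols + gap_cols

    bit = alignments.score / 2.0
    e_value = len(query.sequence) * len(subject.sequence) * 2.0 ** (-bit)
    hit = HitRecord(
        query_id=query.id,
        subject_id=subject.id,
        percent_identity=100.0 * matches / aligned_cols,
        alignment_length=alignment_length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
        e_value=e_value,
        bit_score=alignments.score,
    )
    return [hit]
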