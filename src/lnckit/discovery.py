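"""The stepwise lncRNA discovery cascade with a per-transcript audit trail.

Seven independent predicates are evaluated for every transcript:

1. symbiont contamination (reciprocal >50% coverage hit at e < 1e-3),
2. protein-coding evidence (protein / domain / signal-peptide tracks),
3. minimum length (default 300 nt),
4. longest stop-to-stop ORF size (default <= 75 aa),
5. housekeeping non-coding RNA hit,
6. minimum overall expression (default 10 raw counts summed over
   libraries),
7. k-mer coding-potential call (score <= threshold means noncoding).

A transcript is a high-confidence lncRNA iff every predicate passes; the
final class otherwise names the first failing predicate in cascade order,
but all predicates are always evaluated so the trace is complete and the
surviving set does not depend on evaluation order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .evidence import EvidenceBundle
from .seqcore import KmerModel, Transcript, kmer_coding_score, longest_orf_aa

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "CASCADE_ORDER",
    "classify_transcripts",
    "summarize_filters",
    "write_traces",
    "write_summary",
]

# predicate name -> class label assigned when it is the first failure
CASCADE_ORDER: tuple[tuple[str, str], ...] = (
    ("is_symbiont", "contaminant"),
    ("has_coding_evidence", "mRNA-like"),
    ("too_short", "short"),
    ("orf_too_long", "coding-ORF"),
    ("is_housekeeping", "housekeeping"),
    ("low_expression", "low-expression"),
    ("kmer_coding", "coding-by-kmer"),
)


@dataclass
class FilterConfig:
    min_length_nt: int = 300
    max_orf_aa: int = 75
    min_total_counts: int = 10
    e_protein: float = 1e-4
    e_symbiont: float = 1e-3
    plek_threshold: float = 0.0
    contaminant_rule: str = "and"
    strands: tuple[str, ...] = ("+", "-")
    per_library_min: bool = False  # min_total_counts applies per library

    def validate(self) -> None:
        if self.min_length_nt < 1 or self.max_orf_aa < 1 or self.min_total_counts < 0:
            raise ValueError("thresholds must be positive")
        if self.contaminant_rule not in ("and", "or"):
            raise ValueError(f"contaminant_rule must be 'and' or 'or'")
        if not self.strands or any(s not in ("+", "-") for s in self.strands):
            raise ValueError("strands must be a non-empty subset of {+,-}")


@dataclass
class FilterTrace:
    transcript_id: str
    predicates: dict[str, bool]
    final_class: str

    FIELDS = tuple(name for name, _ in CASCADE_ORDER)

    @classmethod
    def from_predicates(
        cls,
        transcript_id: str,
        predicates: Mapping[str, bool],
        order: Sequence[tuple[str, str]] = CASCADE_ORDER,
    ) -> "FilterTrace":
        final = "lncRNA"
        for name, label in order:
            if predicates[name]:
                final = label
                break
        return cls(transcript_id, dict(predicates), final)


def classify_transcripts(
    transcripts: Sequence[Transcript],
    evidence: EvidenceBundle,
    counts: Mapping[str, Sequence[int]] | Mapping[str, int],
    config: FilterConfig | None = None,
    kmer_model: KmerModel | None = None,
    order: Sequence[tuple[str, str]] = CASCADE_ORDER,
) -> tuple[set[str], list[FilterTrace]]:
    """Run the full cascade; return the lncRNA id set plus all traces.

    ``counts`` maps transcript id to either per-library raw counts or a
    pre-summed total; missing transcripts count 0.  The k-mer predicate
    uses ``kmer_model`` when supplied, else the bundle's precomputed
    coding/noncoding calls; with neither, it passes vacuously.
    ``order`` only affects which first-failing predicate a trace names;
    the surviving set is the plain conjunction and is order-free.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    config = config or FilterConfig()
    config.validate()

    lncrnas: set[str] = set()
    traces: list[FilterTrace] = []
    for t in transcripts:
        raw = counts.get(t.id, 0)
        if isinstance(raw, (int, float)):
            total = int(raw)
            low_expr = total < config.min_total_counts
        else:
            total = int(sum(raw))
            if config.per_library_min:
                low_expr = any(int(c) < config.min_total_counts for c in raw)
            else:
                low_expr = total < config.min_total_counts

        if kmer_model is not None:
            kmer_coding = kmer_coding_score(t, kmer_model) > config.plek_threshold
        elif evidence.plek_coding is not None:
            kmer_coding = evidence.plek_coding.get(t.id, False)
        else:
            kmer_coding = False

        predicates = {
            "is_symbiont": t.id in evidence.symbiont_hit,
            "has_coding_evidence": (
                t.id in evidence.protein_hit
                or t.id in evidence.domain_hit
                or t.id in evidence.signal_peptide
            ),
            "too_short": t.length < config.min_length_nt,
            "orf_too_long": longest_orf_aa(t, config.strands) > config.max_orf_aa,
            "is_housekeeping": t.id in evidence.housekeeping_hit,
            "low_expression": low_expr,
            "kmer_coding": kmer_coding,
        }
        trace = FilterTrace.from_predicates(t.id, predicates, order)
        traces.append(trace)
        if trace.final_class == "lncRNA":
            lncrnas.add(t.id)
    return lncrnas, traces


def summarize_filters(traces: Sequence[FilterTrace]) -> list[tuple[str, int]]:
    """Count transcripts per final class, in cascade order then lncRNA."""
    if not traces:
        raise ValueError("no traces to summarize")
    counts = Counter(tr.final_class for tr in traces)
    order = [label for _, label in CASCADE_ORDER] + ["lncRNA"]
    return [(label, counts[label]) for label in order if counts[label] > 0]


def write_traces(traces: Sequence[FilterTrace], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(FilterTrace.FIELDS) + "\tfinal_class\n")
        for tr in traces:
            flags = "\t".join("1" if tr.predicates[f] else "0" for f in FilterTrace.FIELDS)
            fh.write(f"{tr.transcript_id}\t{flags}\t{tr.final_class}\n")


def write_summary(summary: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("final_class\tcount\n")
        for label, n in summary:
            fh.write(f"{label}\t{n}\n")
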