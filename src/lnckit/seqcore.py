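"""Sequence I/O, stop-to-stop ORF finding and k-mer coding-potential scoring.

ORFs here are *stop-to-stop*: maximal runs of codons between consecutive
stop codons (or between a sequence end and the nearest stop) in each
reading frame.  No start codon is required; the longest such run is what
the coding-size filter downstream inspects.

The k-mer classifier is a simple log-odds model over all k-mers of size
1..k_max, trained from a coding and a noncoding sequence set.  It stands
in for an external SVM-based coding/noncoding tool: a transcript whose
mean log-odds is at or below a threshold (default 0) is called noncoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Transcript",
    "OrfRecord",
    "KmerModel",
    "read_fasta",
    "write_fasta",
    "find_orfs",
    "longest_orf_aa",
    "train_kmer_model",
    "kmer_coding_score",
]

_IUPAC_DNA = set("ACGTN")

# standard genetic code, stop codons map to "*"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript: uppercase DNA over ACGTN."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in _IUPAC_DNA), None)
        if bad is not None:
            raise ValueError(
                f"transcript {self.id!r}: non-IUPAC character "
                f"{self.sequence[bad]!r} at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A stop-to-stop codon run, with coordinates on the forward strand.

    ``start``/``end`` are a 0-based half-open nucleotide interval on the
    forward strand of the transcript; ``frame`` is the 0..2 offset on the
    strand the ORF was read from.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_length: int
    peptide: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF interval length must be divisible by 3")
        if self.aa_length != (self.end - self.start) // 3:
            raise ValueError("aa_length inconsistent with interval")
        if "*" in self.peptide:
            raise ValueError("peptide must not contain a stop symbol")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U to T."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA, normalizing case and U->T.

    Raises ``ValueError`` on duplicate ids, empty records, or characters
    outside ACGTN (position reported).
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate transcript id {record.id!r} in {path}")
        seen.add(record.id)
        seq = normalize_sequence(str(record.seq))
        if not seq:
            raise ValueError(f"empty sequence for record {record.id!r} in {path}")
        transcripts.append(Transcript(record.id, seq))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_codon(codon: str) -> str:
    # codons containing N translate to X and never count as stops
    if "N" in codon:
        return "X"
    return _CODON_TABLE[codon]


def _orfs_one_strand(transcript_id: str, seq: str, strand: str, length: int) -> list[OrfRecord]:
    records: list[OrfRecord] = []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons <= 0:
            continue
        run_start = 0  # codon index where the current stop-free run began
        peptide: list[str] = []
        for ci in range(n_codons + 1):
            is_stop = True  # sentinel codon past the end terminates the run
            if ci < n_codons:
                codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
                aa = _translate_codon(codon)
                is_stop = aa == "*"
            if is_stop:
                if peptide:
                    s_nt = frame + 3 * run_start
                    e_nt = frame + 3 * ci
                    if strand == "-":
                        s_nt, e_nt = length - e_nt, length - s_nt
                    records.append(
                        OrfRecord(
                            transcript_id=transcript_id,
                            strand=strand,
                            frame=frame,
                            start=s_nt,
                            end=e_nt,
                            aa_length=ci - run_start,
                            peptide="".join(peptide),
                        )
                    )
                run_start = ci + 1
                peptide = []
            else:
                peptide.append(aa)
    return records


def find_orfs(transcript: Transcript, strands: Iterable[str] = ("+", "-")) -> list[OrfRecord]:
    """Enumerate stop-to-stop ORFs on the requested strands.

    Coordinates are always reported on the forward strand.  Sequences
    shorter than one codon yield an empty list.
    """
    strand_set = list(dict.fromkeys(strands))
    if not strand_set or any(s not in ("+", "-") for s in strand_set):
        raise ValueError(f"strands must be a non-empty subset of {{+,-}}, got {strands!r}")
    seq = transcript.sequence
    out: list[OrfRecord] = []
    for strand in strand_set:
        s = seq if strand == "+" else reverse_complement(seq)
        out.extend(_orfs_one_strand(transcript.id, s, strand, len(seq)))
    return out


def longest_orf_aa(transcript: Transcript, strands: Iterable[str] = ("+", "-")) -> int:
    """Longest stop-to-stop ORF length in amino acids (0 if no codon fits)."""
    orfs = find_orfs(transcript, strands)
    return max((o.aa_length for o in orfs), default=0)


@dataclass
class KmerModel:
    """Log-odds of coding vs noncoding k-mer usage for k = 1..k_max."""

    k_max: int
    pseudocount: float
    log_odds: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k_max={self.k_max}\tpseudocount={self.pseudocount!r}\n")
            for kmer in sorted(self.log_odds):
                fh.write(f"{kmer}\t{self.log_odds[kmer]!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerModel":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing k-mer model header")
            fields = dict(item.split("=", 1) for item in header[1:].split("\t"))
            model = cls(k_max=int(fields["k_max"]), pseudocount=float(fields["pseudocount"]))
            for line in fh:
                kmer, value = line.rstrip("\n").split("\t")
                model.log_odds[kmer] = float(value)
        return model


def _kmer_counts(sequences: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue  # k-mers containing N are skipped
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return counts, total


def _all_kmers(k: int) -> Iterable[str]:
    from itertools import product

    for tup in product("ACGT", repeat=k):
        yield "".join(tup)


def train_kmer_model(
    coding: Iterable[Transcript],
    noncoding: Iterable[Transcript],
    k_max: int = 5,
    pseudocount: float = 1.0,
) -> KmerModel:
    """Train the log-odds model from a coding and a noncoding set.

    log_odds[w] = log p_coding(w) - log p_noncoding(w), each estimated
    with additive smoothing: (count(w)+c) / (total_k + c*4^k).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    coding_seqs = [t.sequence for t in coding]
    noncoding_seqs = [t.sequence for t in noncoding]
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")

    model = KmerModel(k_max=k_max, pseudocount=pseudocount)
    for k in range(1, k_max + 1):
        c_counts, c_total = _kmer_counts(coding_seqs, k)
        n_counts, n_total = _kmer_counts(noncoding_seqs, k)
        denom = pseudocount * 4**k
        for w in _all_kmers(k):
            lc = math.log((c_counts.get(w, 0) + pseudocount) / (c_total + denom))
            ln = math.log((n_counts.get(w, 0) + pseudocount) / (n_total + denom))
            model.log_odds[w] = lc - ln
    return model


def kmer_coding_score(transcript: Transcript, model: KmerModel) -> float:
    """Mean log-odds over all k-mers (k = 1..k_max) of the sequence.

    Positive scores look coding; the downstream rule calls a transcript
    noncoding iff score <= threshold (default 0).  k-mers containing N
    are skipped; a sequence with no usable k-mer scores 0.
    """
    seq = transcript.sequence
    if len(seq) < 1:
        raise ValueError("transcript must contain at least one base")
    total = 0.0
    n = 0
    for k in range(1, model.k_max + 1):
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            total += model.log_odds[w]
            n += 1
    return total / n if n else 0.0


def plek_calls_from_table(path: str | Path) -> dict[str, bool]:
    """Adapter for a precomputed coding/noncoding call table.

    Two tab-separated columns: transcript_id, label.  Labels "coding"/"C"
    (case-insensitive) mean coding; "noncoding"/"NC"/"N" mean noncoding.
    Returns id -> is_coding.
    """
    calls: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            tid, label = parts
            label_l = label.strip().lower()
            if label_l in ("coding", "c"):
                calls[tid] = True
            elif label_l in ("noncoding", "non-coding", "nc", "n"):
                calls[tid] = False
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
    return calls
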