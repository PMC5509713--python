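"""FPKM, two-library differential expression and BH adjustment.

The per-transcript test is the Audic-Claverie two-library Poisson test:
conditional on a count of x in library 1, the count in library 2 follows
a negative binomial with n = x + 1 and p = 1 / (1 + r), r being the
ratio of library totals.  Two-sided p-values double the smaller tail and
cap at 1.  The test is pluggable so an alternative can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CountsTable",
    "DEResult",
    "compute_fpkm",
    "audic_claverie_p",
    "bh_adjust",
    "call_differential",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_de_results",
]


@dataclass
class CountsTable:
    """Raw fragment counts per (transcript, sample) plus mapping totals."""

    samples: list[str]
    counts: dict[str, list[int]]  # transcript_id -> counts per sample
    totals: dict[str, int]  # sample_id -> total mapped fragments

    def __post_init__(self) -> None:
        for tid, row in self.counts.items():
            if len(row) != len(self.samples):
                raise ValueError(f"{tid}: {len(row)} counts for {len(self.samples)} samples")
            if any(c < 0 for c in row):
                raise ValueError(f"{tid}: negative count")

    def column(self, sample: str) -> dict[str, int]:
        idx = self.samples.index(sample)
        return {tid: row[idx] for tid, row in self.counts.items()}

    def total_by_transcript(self) -> dict[str, int]:
        return {tid: sum(row) for tid, row in self.counts.items()}


@dataclass
class DEResult:
    transcript_id: str
    fpkm1: float
    fpkm2: float
    log2fc: float
    p_raw: float
    q_bh: float
    status: str  # up / down / ns; "up" = higher in sample 2


def compute_fpkm(count: float, transcript_length_nt: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length_nt < 1:
        raise ValueError("transcript length must be >= 1 nt")
    if total_mapped < 1:
        raise ValueError("total mapped fragments must be >= 1")
    return count * 1e9 / (transcript_length_nt * total_mapped)


def audic_claverie_p(x: int, y: int, total1: int, total2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x vs y.

    With r = total2/total1, P(Y=y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),
    i.e. Y | x ~ NegBin(n = x+1, p = 1/(1+r)).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if total1 < 1 or total2 < 1:
        raise ValueError("library totals must be >= 1")
    r = total2 / total1
    p_success = 1.0 / (1.0 + r)
    lower = stats.nbinom.cdf(y, x + 1, p_success)  # P(Y <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)  # P(Y >= y)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _audic_claverie_p_vec(
    x: np.ndarray, y: np.ndarray, total1: int, total2: int
) -> np.ndarray:
    r = total2 / total1
    p_success = 1.0 / (1.0 + r)
    lower = stats.nbinom.cdf(y, x + 1, p_success)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def call_differential(
    counts: CountsTable,
    lengths: Mapping[str, int],
    sample_pair: tuple[str, str],
    fc_pseudo: float = 0.01,
    lfc_cutoff: float = 1.0,
    alpha: float = 0.05,
    use_raw_p: bool = False,
    test: Callable[[int, int, int, int], float] | None = None,
) -> list[DEResult]:
    """Differential expression between two libraries.

    Direction convention: ``status == "up"`` means higher expression in
    the SECOND sample of ``sample_pair`` (log2fc = log2(fpkm2/fpkm1) >= +1).
    Significance requires both |log2fc| >= ``lfc_cutoff`` and adjusted
    (or raw, with ``use_raw_p``) p below ``alpha``.
    """
    s1, s2 = sample_pair
    for s in (s1, s2):
        if s not in counts.samples:
            raise KeyError(f"sample {s!r} not in counts table")
    tids = list(counts.counts)
    if not tids:
        raise ValueError("empty transcript list")
    c1 = counts.column(s1)
    c2 = counts.column(s2)
    t1, t2 = counts.totals[s1], counts.totals[s2]

    x = np.array([c1[tid] for tid in tids])
    y = np.array([c2[tid] for tid in tids])
    if test is None:
        p_raw = _audic_claverie_p_vec(x, y, t1, t2)
    else:
        p_raw = np.array([test(int(xi), int(yi), t1, t2) for xi, yi in zip(x, y)])
    q = bh_adjust(p_raw.tolist())

    results: list[DEResult] = []
    for i, tid in enumerate(tids):
        if tid not in lengths:
            raise KeyError(f"no length recorded for transcript {tid!r}")
        fpkm1 = compute_fpkm(int(x[i]), lengths[tid], t1)
        fpkm2 = compute_fpkm(int(y[i]), lengths[tid], t2)
        log2fc = math.log2((fpkm2 + fc_pseudo) / (fpkm1 + fc_pseudo))
        sig_p = p_raw[i] < alpha if use_raw_p else q[i] < alpha
        if sig_p and log2fc >= lfc_cutoff:
            status = "up"
        elif sig_p and log2fc <= -lfc_cutoff:
            status = "down"
        else:
            status = "ns"
        results.append(DEResult(tid, fpkm1, fpkm2, log2fc, float(p_raw[i]), float(q[i]), status))
    return results


def read_counts_tsv(path: str | Path) -> CountsTable:
    """Read a counts table.

    Layout: optional ``#totals:<tab>v1<tab>v2...`` comment, then a header
    ``transcript_id<tab>sampleA<tab>sampleB...``, then one row per
    transcript.  Without a totals line the column sums are used.
    """
    totals_row: list[int] | None = None
    samples: list[str] | None = None
    counts: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#totals:"):
                totals_row = [int(v) for v in line.split("\t")[1:]]
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if samples is None:
                samples = parts[1:]
                continue
            counts[parts[0]] = [int(v) for v in parts[1:]]
    if samples is None:
        raise ValueError(f"{path}: missing header line")
    if totals_row is None:
        totals_row = [sum(row[i] for row in counts.values()) for i in range(len(samples))]
    if len(totals_row) != len(samples):
        raise ValueError(f"{path}: totals line does not match sample columns")
    return CountsTable(samples, counts, dict(zip(samples, totals_row)))


def write_counts_tsv(table: CountsTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#totals:\t" + "\t".join(str(table.totals[s]) for s in table.samples) + "\n")
        fh.write("transcript_id\t" + "\t".join(table.samples) + "\n")
        for tid in table.counts:
            fh.write(tid + "\t" + "\t".join(str(c) for c in table.counts[tid]) + "\n")


def write_de_results(
    results: Sequence[DEResult], path: str | Path, sample_pair: tuple[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        if sample_pair:
            fh.write(
                f"# log2fc = log2(fpkm[{sample_pair[1]}]/fpkm[{sample_pair[0]}]); "
                f"'up' = higher in {sample_pair[1]}\n"
            )
        fh.write("transcript_id\tfpkm1\tfpkm2\tlog2fc\tp\tq\tstatus\n")
        for r in results:
            fh.write(
                f"{r.transcript_id}\t{r.fpkm1:.6g}\t{r.fpkm2:.6g}\t{r.log2fc:.6g}\t"
                f"{r.p_raw:.6g}\t{r.q_bh:.6g}\t{r.status}\n"
            )
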