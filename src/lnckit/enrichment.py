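"""Hypergeometric pathway over-representation with Bonferroni correction.

The statistic is P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n):
the upper-tail probability of drawing at least m pathway members in n
draws from a universe of N annotated genes of which M belong to the
pathway.  It is evaluated in log space via log-gamma so large counts do
not overflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import inf, lgamma
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "enrichment_p",
    "bonferroni_adjust",
    "enrich",
    "read_annotation_tsv",
    "write_enrichment_results",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    N: int  # annotated universe size
    n: int  # DE genes within the universe
    M: int  # pathway size
    m: int  # DE genes in the pathway
    p_raw: float
    p_corrected: float
    significant: bool


def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def enrichment_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Summed in log space over the upper tail i = m..min(n, M), which
    equals 1 minus the printed lower partial sum but avoids cancellation
    when the tail is tiny.
    """
    if not (0 <= m <= min(n, M) and n <= N and M <= N and 0 <= M and 0 <= n):
        raise ValueError(f"invalid urn arguments N={N}, n={n}, M={M}, m={m}")
    if m == 0:
        return 1.0
    log_denom = _log_choose(N, n)
    terms = [
        _log_choose(M, i) + _log_choose(N - M, n - i) - log_denom
        for i in range(m, min(n, M) + 1)
    ]
    terms = [t for t in terms if t > -inf]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """min(1, p * k) with k = number of tested hypotheses."""
    k = len(p_values)
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * k))
    return out


def enrich(
    de_gene_ids: Iterable[str],
    annotation: Sequence[PathwayAnnotation],
    alpha: float = 0.05,
    de_status: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every pathway with at least one DE member.

    The universe N is the set of genes carrying any pathway annotation;
    DE ids outside it are dropped with a warning.  Results are sorted by
    raw p, ties broken by pathway id.  ``de_status`` (id -> up/down) is
    only used by the report writer.
    """
    universe: set[str] = set()
    for pw in annotation:
        universe.update(pw.members)
    if not universe:
        raise ValueError("annotation universe is empty")
    de_set = set(de_gene_ids)
    dropped = de_set - universe
    if dropped:
        logger.warning(
            "%d DE ids absent from the annotated universe were dropped", len(dropped)
        )
    de_in = de_set & universe
    N, n = len(universe), len(de_in)

    tested: list[tuple[PathwayAnnotation, int, float]] = []
    for pw in annotation:
        m = len(pw.members & de_in)
        if m == 0:
            continue
        tested.append((pw, m, enrichment_p(N, n, len(pw.members), m)))
    corrected = bonferroni_adjust([p for _, _, p in tested])
    results = [
        EnrichmentResult(
            pathway_id=pw.pathway_id,
            name=pw.name,
            N=N,
            n=n,
            M=len(pw.members),
            m=m,
            p_raw=p,
            p_corrected=pc,
            significant=pc <= alpha,
        )
        for (pw, m, p), pc in zip(tested, corrected)
    ]
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results


def read_annotation_tsv(path: str | Path) -> list[PathwayAnnotation]:
    """Read pathway_id <tab> name <tab> comma-separated gene ids."""
    annotation: list[PathwayAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            pid, name, genes = parts
            members = frozenset(g for g in genes.split(",") if g)
            annotation.append(PathwayAnnotation(pid, name, members))
    return annotation


def write_enrichment_results(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    de_status: Mapping[str, str] | None = None,
    annotation: Sequence[PathwayAnnotation] | None = None,
) -> None:
    ann_by_id = {pw.pathway_id: pw for pw in annotation} if annotation else {}
    with open(path, "w") as fh:
        fh.write("pathway\tpathway_id\tm/M\tup/down\tp\tp_corrected\tsignificant\n")
        for r in results:
            updown = "-"
            if de_status is not None and r.pathway_id in ann_by_id:
                members = ann_by_id[r.pathway_id].members
                up = sum(1 for g in members if de_status.get(g) == "up")
                down = sum(1 for g in members if de_status.get(g) == "down")
                updown = f"{up}/{down}"
            fh.write(
                f"{r.name}\t{r.pathway_id}\t{r.m}/{r.M}\t{updown}\t"
                f"{r.p_raw:.6e}\t{r.p_corrected:.6e}\t{int(r.significant)}\n"
            )
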