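"""Conserved regions, interaction-only duplex folding, and the edge gates.

The folding engine computes the minimum-free-energy *intermolecular*
duplex between two RNAs (no intramolecular structure): a chain of base
pairs, antiparallel, where consecutive pairs are scored by a
nearest-neighbor stack table and separated stretches by an affine
interior/bulge loop penalty (open cost plus a per-unpaired-nucleotide
cost, bounded span per side), plus a duplex initiation cost.  Stack free
energies are rescaled from the table's reference temperature via
dG(T) = dH - T/T_ref * (dH - dG_ref) (temperatures in kelvin).

Candidate duplexes then pass three gates: the lncRNA-side hybridization
site must lie in a conserved region, the energy must be at or below a
cutoff (default -20 kcal/mol) and the pairing must be near-perfect
(paired fraction of the site, default >= 0.9).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from math import inf
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .evidence import HitRecord

__all__ = [
    "ConservedRegion",
    "EnergyModel",
    "DuplexResult",
    "InteractionEdge",
    "load_energy_model",
    "default_energy_model",
    "toy_energy_model",
    "conserved_regions_from_hits",
    "merge_intervals",
    "duplex_fold",
    "gate_interactions",
    "build_network",
    "OVERLAP_RULES",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_KELVIN = 273.15

OVERLAP_RULES = ("half-coverage", "any-overlap", "full-containment")


@dataclass(frozen=True)
class ConservedRegion:
    """A lncRNA interval aligning to a known lncRNA reference entry."""

    lncrna_id: str
    start: int
    end: int  # 0-based half-open
    source_subject_id: str = "."
    source_e_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region interval [{self.start}, {self.end})")


@dataclass
class DuplexResult:
    lncrna_id: str
    mrna_id: str
    lncrna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    energy: float
    paired_positions: list[tuple[int, int]]

    @property
    def paired_fraction(self) -> float:
        start, end = self.lncrna_interval
        return len(self.paired_positions) / (end - start)


@dataclass
class InteractionEdge:
    duplex: DuplexResult
    in_conserved_region: bool
    passes_energy: bool
    passes_pairing: bool

    @property
    def accepted(self) -> bool:
        return self.in_conserved_region and self.passes_energy and self.passes_pairing


class EnergyModel:
    """Nearest-neighbor stack energies plus affine loop and init terms.

    ``stack_dg``/``stack_dh`` are indexed [x1, x2, z, w] where x1 x2 is
    the 5'->3' dinucleotide on the first strand and z, w are the bases
    paired with x1 and x2 respectively.  A zero-length "loop" move (open
    cost, no unpaired bases) exists as an alternative to stacking; it is
    never favorable for positive open costs but keeps the recursion
    uniform.
    """

    def __init__(
        self,
        stack_dg: np.ndarray,
        stack_dh: np.ndarray,
        pair_ok: np.ndarray,
        init_dg: float = 4.09,
        loop_open: float = 3.0,
        loop_ext: float = 0.3,
        max_loop_span: int = 15,
        temperature_c: float = 25.0,
        temperature_ref_c: float = 37.0,
    ) -> None:
        if max_loop_span < 1:
            raise ValueError("max_loop_span must be >= 1")
        self.stack_dg = stack_dg
        self.stack_dh = stack_dh
        self.pair_ok = pair_ok
        self.init_dg = float(init_dg)
        self.loop_open = float(loop_open)
        self.loop_ext = float(loop_ext)
        self.max_loop_span = int(max_loop_span)
        self.temperature_c = float(temperature_c)
        self.temperature_ref_c = float(temperature_ref_c)

    def stacks_at(self, temperature_c: float | None = None) -> np.ndarray:
        """Stack dG rescaled to the working temperature."""
        t = self.temperature_c if temperature_c is None else temperature_c
        t_k = t + _KELVIN
        t_ref_k = self.temperature_ref_c + _KELVIN
        with np.errstate(invalid="ignore"):
            scaled = self.stack_dh - t_k * (self.stack_dh - self.stack_dg) / t_ref_k
        # keep disallowed stacks at +inf (inf - inf above would yield nan)
        scaled = np.where(np.isfinite(self.stack_dg), scaled, inf)
        return scaled


def _expand_symmetry(dg: np.ndarray, dh: np.ndarray) -> None:
    # a stack read from the other strand (x1x2/zw -> w z / x2 x1) is the
    # same physical object and inherits its energy
    for x1 in range(4):
        for x2 in range(4):
            for z in range(4):
                for w in range(4):
                    if np.isfinite(dg[x1, x2, z, w]) and not np.isfinite(dg[w, z, x2, x1]):
                        dg[w, z, x2, x1] = dg[x1, x2, z, w]
                        dh[w, z, x2, x1] = dh[x1, x2, z, w]


def load_energy_model(path: str | Path) -> EnergyModel:
    """Load an energy model from its TSV parameter file.

    Records: ``stack  XY/ZW  dG  dH`` (Z pairs X, W pairs Y), plus
    ``init``, ``loop_open``, ``loop_ext``, ``max_loop_span``,
    ``temperature_c``, ``temperature_ref_c``, ``default_stack`` and
    ``pair`` (allowed base pairs) records.
    """
    stack_dg = np.full((4, 4, 4, 4), inf)
    stack_dh = np.full((4, 4, 4, 4), inf)
    pair_ok = np.zeros((4, 4), dtype=bool)
    params: dict[str, float] = {}
    default_stack: tuple[float, float] | None = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rtype = parts[0]
            if rtype == "stack":
                mo = re.fullmatch(r"([ACGU]{2})/([ACGU]{2})", parts[1])
                if not mo:
                    raise ValueError(f"{path}:{lineno}: bad stack context {parts[1]!r}")
                (x1, x2), (z, w) = mo.group(1), mo.group(2)
                idx = tuple(_BASE_INDEX[c] for c in (x1, x2, z, w))
                stack_dg[idx] = float(parts[2])
                stack_dh[idx] = float(parts[3])
            elif rtype == "pair":
                a, b = parts[1]
                pair_ok[_BASE_INDEX[a], _BASE_INDEX[b]] = True
            elif rtype == "default_stack":
                default_stack = (float(parts[2]), float(parts[3]))
            else:
                params[rtype] = float(parts[2])

    _expand_symmetry(stack_dg, stack_dh)
    if default_stack is not None:
        for x1 in range(4):
            for x2 in range(4):
                for z in range(4):
                    for w in range(4):
                        if pair_ok[x1, z] and pair_ok[x2, w] and not np.isfinite(
                            stack_dg[x1, x2, z, w]
                        ):
                            stack_dg[x1, x2, z, w] = default_stack[0]
                            stack_dh[x1, x2, z, w] = default_stack[1]
    # a stack requires both of its pairs to be allowed
    for x1 in range(4):
        for z in range(4):
            if not pair_ok[x1, z]:
                stack_dg[x1, :, z, :] = inf
                stack_dg[:, x1, :, z] = inf

    return EnergyModel(
        stack_dg=stack_dg,
        stack_dh=stack_dh,
        pair_ok=pair_ok,
        init_dg=params.get("init", 0.0),
        loop_open=params.get("loop_open", inf),
        loop_ext=params.get("loop_ext", 0.0),
        max_loop_span=int(params.get("max_loop_span", 15)),
        temperature_c=params.get("temperature_c", 25.0),
        temperature_ref_c=params.get("temperature_ref_c", 37.0),
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lnckit").joinpath("data", name)))


def default_energy_model() -> EnergyModel:
    """The shipped Turner-style nearest-neighbor table (25 C working temp)."""
    return load_energy_model(_data_path("stacks_default.tsv"))


def toy_energy_model() -> EnergyModel:
    """The shipped test model: WC stack -2, GU stack -1, loops forbidden."""
    return load_energy_model(_data_path("stacks_toy.tsv"))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def conserved_regions_from_hits(
    hits: Iterable[HitRecord],
    lncrna_lengths: Mapping[str, int],
    e_cutoff: float = 1e-3,
) -> list[ConservedRegion]:
    """Query-side intervals of reference-lncRNA hits, merged per lncRNA.

    Hits above ``e_cutoff`` are ignored; 1-based inclusive query
    coordinates become 0-based half-open.  The strict mode uses
    e_cutoff = 1e-3; the loose mode for differentially expressed lncRNAs
    relaxes it (e.g. to 10).
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    by_lnc: dict[str, list[tuple[int, int, str, float]]] = {}
    for hit in hits:
        if hit.e_value > e_cutoff:
            continue
        if hit.query_id not in lncrna_lengths:
            raise KeyError(f"no recorded length for lncRNA {hit.query_id!r}")
        if hit.q_end > lncrna_lengths[hit.query_id]:
            raise ValueError(
                f"hit interval [{hit.q_start},{hit.q_end}] exceeds length of {hit.query_id!r}"
            )
        by_lnc.setdefault(hit.query_id, []).append(
            (hit.q_start - 1, hit.q_end, hit.subject_id, hit.e_value)
        )
    regions: list[ConservedRegion] = []
    for lnc_id in sorted(by_lnc):
        rows = by_lnc[lnc_id]
        merged = merge_intervals([(s, e) for s, e, _, _ in rows])
        for start, end in merged:
            contributing = [r for r in rows if r[0] < end and r[1] > start]
            best = min(contributing, key=lambda r: r[3])
            regions.append(ConservedRegion(lnc_id, start, end, best[2], best[3]))
    return regions


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unsupported base {exc.args[0]!r} in sequence") from exc


def duplex_fold(
    lncrna_seq: str,
    mrna_seq: str,
    model: EnergyModel,
    temperature_c: float | None = None,
    lncrna_id: str = "lncrna",
    mrna_id: str = "mrna",
) -> DuplexResult | None:
    """Minimum-free-energy intermolecular duplex, or None.

    Returns None when no complementary pair exists or the best duplex is
    not stabilizing (energy >= 0).  N bases never pair.
    """
    if not lncrna_seq or not mrna_seq:
        raise ValueError("sequences must be non-empty")
    a = _encode(lncrna_seq.replace("N", "A"))  # placeholder; N masked below
    b = _encode(mrna_seq.replace("N", "A"))
    a_n = np.array([c == "N" for c in lncrna_seq])
    b_n = np.array([c == "N" for c in mrna_seq])
    n, m = len(a), len(b)
    br = b[::-1]  # j indexes the reversed mRNA; original position = m-1-j
    br_n = b_n[::-1]

    stacks = model.stacks_at(temperature_c)
    pairable = model.pair_ok[a][:, br]
    pairable[a_n, :] = False
    pairable[:, br_n] = False
    if not pairable.any():
        return None

    open_g, ext_g, init_g = model.loop_open, model.loop_ext, model.init_dg
    span = model.max_loop_span

    H = np.full((n, m), inf)
    W = np.full((n, m), inf)  # H[i,j] - ext*(i+j), for loop candidates
    jidx = np.arange(m)
    ext_j = ext_g * jidx

    loops_possible = np.isfinite(open_g)
    for i in range(n):
        row = np.full(m, inf)
        mask = pairable[i]
        if mask.any():
            cand = np.full(m, init_g)
            if i > 0:
                # stacking on the previous pair
                srow = np.full(m, inf)
                srow[1:] = H[i - 1, :-1] + stacks[a[i - 1], a[i], br[:-1], br[1:]]
                cand = np.minimum(cand, srow)
                if loops_possible:
                    # bulge/interior loop closing at (i, j): predecessor pair
                    # (x, y) with x in [i-1-span, i-1], y in [j-1-span, j-1]
                    lo = max(0, i - 1 - span)
                    colmin = np.min(W[lo:i, :], axis=0)
                    wm = np.full(m, inf)
                    for d in range(1, span + 2):
                        if d < m:
                            wm[d:] = np.minimum(wm[d:], colmin[:-d])
                        else:
                            break
                    lrow = open_g + ext_g * (i - 1) + ext_g * (jidx - 1) + wm
                    cand = np.minimum(cand, lrow)
            row = np.where(mask, cand, inf)
        H[i] = row
        W[i] = row - ext_g * i - ext_j

    best = H.min()
    if not best < 0:
        return None
    bi, bj = np.unravel_index(int(H.argmin()), H.shape)

    pairs = _traceback(H, int(bi), int(bj), a, br, stacks, model, pairable)
    lnc_pos = [i for i, _ in pairs]
    mrna_pos = [m - 1 - j for _, j in pairs]
    paired = sorted(zip(lnc_pos, mrna_pos))
    return DuplexResult(
        lncrna_id=lncrna_id,
        mrna_id=mrna_id,
        lncrna_interval=(min(lnc_pos), max(lnc_pos) + 1),
        mrna_interval=(min(mrna_pos), max(mrna_pos) + 1),
        energy=float(best),
        paired_positions=paired,
    )


def _traceback(
    H: np.ndarray,
    i: int,
    j: int,
    a: np.ndarray,
    br: np.ndarray,
    stacks: np.ndarray,
    model: EnergyModel,
    pairable: np.ndarray,
) -> list[tuple[int, int]]:
    # predecessor recovery by local recomputation; tolerance absorbs the
    # different floating summation order of the vectorized forward pass
    tol = 1e-6
    open_g, ext_g, init_g = model.loop_open, model.loop_ext, model.init_dg
    span = model.max_loop_span
    pairs = [(i, j)]
    while True:
        val = H[i, j]
        nxt: tuple[int, int] | None = None
        best_diff = tol
        if i > 0 and j > 0 and pairable[i - 1, j - 1]:
            cand = H[i - 1, j - 1] + stacks[a[i - 1], a[i], br[j - 1], br[j]]
            diff = abs(val - cand)
            if diff < best_diff:
                best_diff, nxt = diff, (i - 1, j - 1)
        if nxt is None and np.isfinite(open_g):
            for x in range(max(0, i - 1 - span), i):
                for y in range(max(0, j - 1 - span), j):
                    cand = H[x, y] + open_g + ext_g * ((i - 1 - x) + (j - 1 - y))
                    diff = abs(val - cand)
                    if diff < best_diff:
                        best_diff, nxt = diff, (x, y)
        if nxt is None:
            if abs(val - init_g) >= tol:  # pragma: no cover - internal check
                raise RuntimeError("duplex traceback failed to find a predecessor")
            return pairs
        i, j = nxt
        pairs.append((i, j))


def _coverage(interval: tuple[int, int], regions: Sequence[tuple[int, int]]) -> float:
    start, end = interval
    covered = 0
    for rs, re_ in regions:
        covered += max(0, min(end, re_) - max(start, rs))
    return covered / (end - start)


def gate_interactions(
    duplexes: Iterable[DuplexResult],
    conserved_regions: Iterable[ConservedRegion],
    energy_cutoff: float = -20.0,
    min_paired_fraction: float = 0.9,
    overlap_rule: str = "half-coverage",
) -> list[InteractionEdge]:
    """Annotate every duplex with the three gates.

    ``overlap_rule``: "half-coverage" (>= 50% of the lncRNA-side site
    covered by conserved regions), "any-overlap", or "full-containment".
    All edges are returned, accepted or not, so rejections are auditable.
    """
    if overlap_rule not in OVERLAP_RULES:
        raise ValueError(f"overlap_rule must be one of {OVERLAP_RULES}, got {overlap_rule!r}")
    regions_by_lnc: dict[str, list[tuple[int, int]]] = {}
    for region in conserved_regions:
        regions_by_lnc.setdefault(region.lncrna_id, []).append((region.start, region.end))
    edges: list[InteractionEdge] = []
    for dup in duplexes:
        regions = regions_by_lnc.get(dup.lncrna_id, [])
        cov = _coverage(dup.lncrna_interval, regions) if regions else 0.0
        if overlap_rule == "half-coverage":
            in_region = cov >= 0.5
        elif overlap_rule == "any-overlap":
            in_region = cov > 0.0
        else:
            in_region = cov >= 1.0
        edges.append(
            InteractionEdge(
                duplex=dup,
                in_conserved_region=in_region,
                passes_energy=dup.energy <= energy_cutoff,
                passes_pairing=dup.paired_fraction >= min_paired_fraction,
            )
        )
    return edges


def build_network(edges: Iterable[InteractionEdge]) -> tuple[dict, list[InteractionEdge]]:
    """Bipartite lncRNA-mRNA graph summary from accepted edges."""
    import networkx as nx

    accepted = sorted(
        (e for e in edges if e.accepted),
        key=lambda e: (e.duplex.lncrna_id, e.duplex.mrna_id),
    )
    graph = nx.Graph()
    for e in accepted:
        graph.add_node(e.duplex.lncrna_id, bipartite="lncrna")
        graph.add_node(e.duplex.mrna_id, bipartite="mrna")
        graph.add_edge(e.duplex.lncrna_id, e.duplex.mrna_id)
    lnc_nodes = sorted(n for n, d in graph.nodes(data=True) if d["bipartite"] == "lncrna")
    mrna_nodes = sorted(n for n, d in graph.nodes(data=True) if d["bipartite"] == "mrna")
    summary = {
        "n_lncrna": len(lnc_nodes),
        "n_mrna": len(mrna_nodes),
        "n_edges": graph.number_of_edges(),
        "lncrna_degrees": {n: graph.degree(n) for n in lnc_nodes},
        "mrna_degrees": {n: graph.degree(n) for n in mrna_nodes},
    }
    return summary, accepted


def write_edges_tsv(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "lncrna_id\tmrna_id\tlnc_start\tlnc_end\tmrna_start\tmrna_end\t"
            "energy\tpaired_fraction\tin_region\taccepted\n"
        )
        for e in edges:
            d = e.duplex
            fh.write(
                f"{d.lncrna_id}\t{d.mrna_id}\t{d.lncrna_interval[0]}\t{d.lncrna_interval[1]}\t"
                f"{d.mrna_interval[0]}\t{d.mrna_interval[1]}\t{d.energy:.2f}\t"
                f"{d.paired_fraction:.4f}\t{int(e.in_conserved_region)}\t{int(e.accepted)}\n"
            )


def write_regions_bed(regions: Iterable[ConservedRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.lncrna_id}\t{r.start}\t{r.end}\t{r.source_subject_id}\n")


def parse_rnaplex_output(path: str | Path) -> list[DuplexResult]:
    """Adapter for native RNAplex result lines (production ingestion).

    Expects repeated blocks of two ``>id`` lines (target mRNA first, then
    the query lncRNA, as RNAplex prints them) followed by a structure
    line ``((..&..)) start,end : start,end (energy)`` with 1-based
    inclusive coordinates.
    """
    results: list[DuplexResult] = []
    pat = re.compile(
        r"^(?P<struct>[.()]+&[.()]+)\s+(?P<qs>\d+),(?P<qe>\d+)\s*:\s*"
        r"(?P<ts>\d+),(?P<te>\d+)\s*\((?P<en>[-\d.]+)\)"
    )
    target_id = query_id = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if target_id is None or query_id is not None:
                    target_id, query_id = line[1:].split()[0], None
                else:
                    query_id = line[1:].split()[0]
                continue
            mo = pat.match(line)
            if not mo or target_id is None or query_id is None:
                continue
            left, right = mo.group("struct").split("&")
            t0, t1 = int(mo.group("qs")) - 1, int(mo.group("qe"))
            q0, q1 = int(mo.group("ts")) - 1, int(mo.group("te"))
            # pair '(' of the target part with ')' of the query part
            opens = [t0 + k for k, c in enumerate(left) if c == "("]
            closes = [q0 + k for k, c in enumerate(right) if c == ")"]
            paired = list(zip(sorted(closes), sorted(opens, reverse=True)))
            results.append(
                DuplexResult(
                    lncrna_id=query_id,
                    mrna_id=target_id,
                    lncrna_interval=(q0, q1),
                    mrna_interval=(t0, t1),
                    energy=float(mo.group("en")),
                    paired_positions=sorted(paired),
                )
            )
            target_id = query_id = None
    return results
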