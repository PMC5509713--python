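from __future__ import annotations

from math import inf

import numpy as np
import pytest

from lnckit.evidence import HitRecord
from lnckit.interaction import (
    ConservedRegion,
    DuplexResult,
    EnergyModel,
    build_network,
    conserved_regions_from_hits,
    default_energy_model,
    duplex_fold,
    gate_interactions,
    merge_intervals,
    parse_rnaplex_output,
    toy_energy_model,
)
from lnckit.seqcore import reverse_complement

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def toy_stack(p1, p2) -> float:
    return -2.0 if (p1 in WC and p2 in WC) else -1.0


def brute_contiguous(a: str, b: str) -> float | None:
    """Exhaustive MFE over contiguous antiparallel runs (toy model: no loops)."""
    best = None
    for i in range(len(a)):
        for j in range(len(b) - 1, -1, -1):
            k, e, prev = 0, 0.0, None
            while i + k < len(a) and j - k >= 0 and (a[i + k], b[j - k]) in PAIRS:
                cur = (a[i + k], b[j - k])
                if prev is not None:
                    e += toy_stack(prev, cur)
                    if e < 0 and (best is None or e < best):
                        best = e
                prev, k = cur, k + 1
    return best


def brute_with_loops(a: str, b: str, model: EnergyModel) -> float | None:
    """Exhaustive enumeration of all pair chains under the loop model.

    Works on (a, reversed b) so both indices increase along the chain;
    a pair (i, j) joins a[i] with the original b position len(b)-1-j.
    """
    br = b[::-1]
    n, m = len(a), len(br)
    span = model.max_loop_span
    stacks = model.stacks_at()
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    best: list[float | None] = [None]

    def extend(i: int, j: int, energy: float) -> None:
        if energy < 0 and (best[0] is None or energy < best[0]):
            best[0] = energy
        for ni in range(i + 1, min(n, i + 2 + span)):
            for nj in range(j + 1, min(m, j + 2 + span)):
                if (a[ni], br[nj]) not in PAIRS:
                    continue
                if ni == i + 1 and nj == j + 1:
                    step = stacks[enc[a[i]], enc[a[ni]], enc[br[j]], enc[br[nj]]]
                    extend(ni, nj, energy + step)
                    # a zero-length loop is also a legal (worse) alternative
                    if np.isfinite(model.loop_open):
                        extend(ni, nj, energy + model.loop_open)
                elif np.isfinite(model.loop_open):
                    u, v = ni - i - 1, nj - j - 1
                    extend(ni, nj, energy + model.loop_open + model.loop_ext * (u + v))

    for i in range(n):
        for j in range(m):
            if (a[i], br[j]) in PAIRS:
                extend(i, j, model.init_dg)
    return best[0]


class TestConservedRegions:
    def make_hit(self, q="lnc1", qs=1, qe=30, e=1e-6):
        return HitRecord(q, "ref1", 95.0, qe - qs + 1, 1, 0, qs, qe, 1, qe - qs + 1,
                        e, 50.0)

    def test_no_hits(self):
        assert conserved_regions_from_hits([], {"lnc1": 100}) == []

    def test_merge_forced(self):
        hits = [self.make_hit(qs=1, qe=30), self.make_hit(qs=20, qe=50)]
        regions = conserved_regions_from_hits(hits, {"lnc1": 100})
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 50)

    def test_evalue_modes(self):
        hit = self.make_hit(e=5.0)
        assert conserved_regions_from_hits([hit], {"lnc1": 100}, e_cutoff=1e-3) == []
        loose = conserved_regions_from_hits([hit], {"lnc1": 100}, e_cutoff=10.0)
        assert len(loose) == 1

    def test_interval_exceeds_length(self):
        with pytest.raises(ValueError):
            conserved_regions_from_hits([self.make_hit(qe=200)], {"lnc1": 100})

    def test_missing_length(self):
        with pytest.raises(KeyError):
            conserved_regions_from_hits([self.make_hit()], {})

    def test_merge_intervals_adjacent(self):
        assert merge_intervals([(0, 10), (10, 20), (25, 30)]) == [(0, 20), (25, 30)]


class TestDuplexFold:
    def test_no_complementary_pair(self):
        assert duplex_fold("AAAA", "AAAA", toy_energy_model()) is None

    def test_forced_stack_run(self):
        d = duplex_fold("GGGG", "CCCC", toy_energy_model())
        assert d.energy == pytest.approx(-6.0)
        assert len(d.paired_positions) == 4
        assert d.lncrna_interval == (0, 4) and d.mrna_interval == (0, 4)
        # antiparallel: increasing on the lncRNA, decreasing on the mRNA
        mrna_sides = [j for _, j in d.paired_positions]
        assert mrna_sides == sorted(mrna_sides, reverse=True)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            duplex_fold("", "ACGT", toy_energy_model())

    def test_gu_stack_weighting(self):
        # second pair is the G.T wobble; the stack touching it scores -1
        d = duplex_fold("GG", "TC", toy_energy_model())
        assert d is not None and d.energy == pytest.approx(-1.0)

    def test_matches_contiguous_oracle(self):
        toy = toy_energy_model()
        rng = np.random.default_rng(1234)
        bases = list("ACGT")
        for _ in range(150):
            a = "".join(rng.choice(bases, size=int(rng.integers(2, 13))))
            b = "".join(rng.choice(bases, size=int(rng.integers(2, 13))))
            expected = brute_contiguous(a, b)
            d = duplex_fold(a, b, toy)
            got = None if d is None else d.energy
            if expected is None:
                assert got is None, (a, b)
            else:
                assert got == pytest.approx(expected), (a, b)

    def test_matches_loop_oracle(self):
        model = EnergyModel(
            stack_dg=toy_energy_model().stack_dg,
            stack_dh=toy_energy_model().stack_dh,
            pair_ok=toy_energy_model().pair_ok,
            init_dg=0.5,
            loop_open=1.5,
            loop_ext=0.25,
            max_loop_span=3,
            temperature_c=37.0,
            temperature_ref_c=37.0,
        )
        rng = np.random.default_rng(77)
        bases = list("ACGT")
        for _ in range(60):
            a = "".join(rng.choice(bases, size=int(rng.integers(2, 9))))
            b = "".join(rng.choice(bases, size=int(rng.integers(2, 9))))
            expected = brute_with_loops(a, b, model)
            d = duplex_fold(a, b, model)
            got = None if d is None else d.energy
            if expected is None:
                assert got is None, (a, b)
            else:
                assert got == pytest.approx(expected), (a, b)

    def test_swap_symmetry(self):
        # the duplex of (a, b) is the duplex of (b, a) read from the other
        # strand; the toy table is mirror-symmetric so energies agree
        toy = toy_energy_model()
        rng = np.random.default_rng(5)
        bases = list("ACGT")
        for _ in range(40):
            a = "".join(rng.choice(bases, size=int(rng.integers(4, 20))))
            b = "".join(rng.choice(bases, size=int(rng.integers(4, 20))))
            d1 = duplex_fold(a, b, toy)
            d2 = duplex_fold(b, a, toy)
            e1 = None if d1 is None else d1.energy
            e2 = None if d2 is None else d2.energy
            if e1 is None:
                assert e2 is None
            else:
                assert e1 == pytest.approx(e2), (a, b)

    def test_revcomp_swap_symmetry_wc_only(self):
        # reverse-complement-and-swap maps G.U wobbles onto non-pairs, so
        # the invariance is asserted on a WC-only pairing model
        toy = toy_energy_model()
        wc_only = EnergyModel(
            stack_dg=toy.stack_dg.copy(), stack_dh=toy.stack_dh.copy(),
            pair_ok=toy.pair_ok.copy(), init_dg=toy.init_dg,
            loop_open=toy.loop_open, loop_ext=toy.loop_ext,
            max_loop_span=toy.max_loop_span,
            temperature_c=37.0, temperature_ref_c=37.0,
        )
        enc = {"A": 0, "C": 1, "G": 2, "T": 3}
        wc_only.pair_ok[enc["G"], enc["T"]] = False
        wc_only.pair_ok[enc["T"], enc["G"]] = False
        rng = np.random.default_rng(6)
        bases = list("ACGT")
        for _ in range(40):
            a = "".join(rng.choice(bases, size=int(rng.integers(4, 20))))
            b = "".join(rng.choice(bases, size=int(rng.integers(4, 20))))
            d1 = duplex_fold(a, b, wc_only)
            d2 = duplex_fold(reverse_complement(b), reverse_complement(a), wc_only)
            e1 = None if d1 is None else d1.energy
            e2 = None if d2 is None else d2.energy
            if e1 is None:
                assert e2 is None
            else:
                assert e1 == pytest.approx(e2), (a, b)

    def test_n_bases_never_pair(self):
        assert duplex_fold("GNGN", "CNCN", toy_energy_model()) is None

    def test_temperature_rescaling(self):
        model = default_energy_model()
        at_ref = model.stacks_at(model.temperature_ref_c)
        finite = np.isfinite(model.stack_dg)
        assert np.allclose(at_ref[finite], model.stack_dg[finite])
        # colder is more stabilizing for these enthalpy-dominated stacks
        at_cold = model.stacks_at(25.0)
        assert (at_cold[finite] < model.stack_dg[finite]).all()

    def test_paired_fraction_bounds(self):
        d = duplex_fold("GGGGG", "CCCCC", toy_energy_model())
        assert 0 < d.paired_fraction <= 1


def make_duplex(energy=-25.0, lnc=(10, 40), frac=1.0, lnc_id="l1", mrna_id="m1"):
    width = lnc[1] - lnc[0]
    n_pairs = int(round(frac * width))
    pairs = [(lnc[0] + k, 200 - k) for k in range(n_pairs)]
    return DuplexResult(lnc_id, mrna_id, lnc, (200 - n_pairs + 1, 201), energy, pairs)


class TestGates:
    REGION = [ConservedRegion("l1", 0, 50)]

    def test_all_gates_pass(self):
        (edge,) = gate_interactions([make_duplex()], self.REGION)
        assert edge.accepted

    def test_energy_gate(self):
        (edge,) = gate_interactions([make_duplex(energy=-15.0)], self.REGION)
        assert not edge.accepted and not edge.passes_energy
        assert edge.in_conserved_region and edge.passes_pairing

    def test_outside_region(self):
        (edge,) = gate_interactions([make_duplex(lnc=(60, 90))], self.REGION)
        assert not edge.accepted and not edge.in_conserved_region

    def test_pairing_gate(self):
        (edge,) = gate_interactions([make_duplex(frac=0.5)], self.REGION)
        assert not edge.accepted and not edge.passes_pairing

    def test_half_coverage_rule(self):
        # interval [40, 60): 10 of 20 positions covered -> exactly 50%
        (edge,) = gate_interactions([make_duplex(lnc=(40, 60))], self.REGION)
        assert edge.in_conserved_region
        (edge,) = gate_interactions([make_duplex(lnc=(41, 62))], self.REGION)
        assert not edge.in_conserved_region

    def test_any_overlap_and_full_containment(self):
        dup = make_duplex(lnc=(45, 70))
        (any_edge,) = gate_interactions([dup], self.REGION, overlap_rule="any-overlap")
        assert any_edge.in_conserved_region
        (full_edge,) = gate_interactions([dup], self.REGION,
                                         overlap_rule="full-containment")
        assert not full_edge.in_conserved_region

    def test_unknown_rule_error(self):
        with pytest.raises(ValueError):
            gate_interactions([make_duplex()], self.REGION, overlap_rule="sometimes")

    def test_energy_cutoff_monotonicity(self):
        rng = np.random.default_rng(2)
        duplexes = [make_duplex(energy=float(-rng.uniform(5, 40))) for _ in range(30)]
        accepted_sets = []
        for cutoff in (-10.0, -20.0, -30.0):
            edges = gate_interactions(duplexes, self.REGION, energy_cutoff=cutoff)
            accepted_sets.append({id(e.duplex) for e in edges if e.accepted})
        assert accepted_sets[2] <= accepted_sets[1] <= accepted_sets[0]


class TestNetwork:
    def test_empty(self):
        summary, accepted = build_network([])
        assert summary["n_edges"] == 0 and summary["n_lncrna"] == 0
        assert accepted == []

    def test_counting(self):
        edges = []
        for li in ("l1", "l2"):
            for mi in ("m1", "m2", "m3"):
                dup = make_duplex(lnc_id=li, mrna_id=mi)
                edges.extend(gate_interactions([dup], [ConservedRegion(li, 0, 50)]))
        summary, accepted = build_network(edges)
        assert summary["n_lncrna"] == 2 and summary["n_mrna"] == 3
        assert summary["n_edges"] == 6
        assert len(accepted) == 6

    def test_node_conservation(self):
        edges = gate_interactions(
            [make_duplex(), make_duplex(mrna_id="m2")],
            [ConservedRegion("l1", 0, 50)],
        )
        summary, _ = build_network(edges)
        assert summary["n_lncrna"] + summary["n_mrna"] == 1 + 2


def test_parse_rnaplex_output(tmp_path):
    path = tmp_path / "plex.out"
    path.write_text(
        ">mrna_1\n>lnc_1\n((((&)))) 3,6 : 11,14 (-5.20)\n"
    )
    (dup,) = parse_rnaplex_output(path)
    assert dup.lncrna_id == "lnc_1" and dup.mrna_id == "mrna_1"
    assert dup.energy == pytest.approx(-5.2)
    assert dup.lncrna_interval == (10, 14) and dup.mrna_interval == (2, 6)
    assert len(dup.paired_positions) == 4
    lnc_sides = [i for i, _ in dup.paired_positions]
    mrna_sides = [j for _, j in dup.paired_positions]
    assert lnc_sides == sorted(lnc_sides)
    assert mrna_sides == sorted(mrna_sides, reverse=True)
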