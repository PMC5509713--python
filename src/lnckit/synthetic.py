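"""Seeded synthetic transcriptomes with a ground-truth manifest.

The generator emits everything the analysis consumes: transcripts of six
planted classes (mRNA-like, lncRNA, symbiont contaminant, housekeeping,
too-short, small-ORF coding), the five evidence tables the discovery
cascade reads, two-condition negative-binomial counts with planted
differential expression, a pathway annotation map, and interaction
plants (a conserved region on a lncRNA whose exact reverse complement is
spliced into a target mRNA) together with decoys that the gates must
reject.  All randomness flows from one integer seed.

Shipped reference sequences (symbiont-like, rRNA-like and a small known
lncRNA database) were generated once with a fixed seed and are read from
the package data directory, so parsers see stable bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evidence import EvidenceBundle, HitRecord, symbiont_contaminants, write_hit_table
from .expression import CountsTable, write_counts_tsv
from .interaction import (
    ConservedRegion,
    conserved_regions_from_hits,
    default_energy_model,
    duplex_fold,
    gate_interactions,
    write_regions_bed,
)
from .seqcore import Transcript, longest_orf_aa, reverse_complement, write_fasta

__all__ = [
    "SimConfig",
    "TruthManifest",
    "simulate_transcriptome",
    "emit_evidence_tables",
    "simulate_counts",
    "plant_interactions",
    "generate_all",
    "nb_draws",
    "load_reference_fasta",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

CLASSES = ("mrna", "lncrna", "contaminant", "housekeeping", "short", "small_orf")


@dataclass
class SimConfig:
    seed: int = 42
    n_mrna: int = 150
    n_lncrna: int = 200
    n_contaminant: int = 50
    n_housekeeping: int = 40
    n_short: int = 40
    n_small_orf: int = 20
    mrna_orf_aa: tuple[int, int] = (120, 250)
    utr_length: tuple[int, int] = (40, 150)
    lncrna_length: tuple[int, int] = (320, 700)
    short_length: tuple[int, int] = (50, 250)
    small_orf_aa: tuple[int, int] = (90, 130)
    max_orf_aa: int = 75
    housekeeping_mutation_rate: float = 0.02
    nb_mean_range: tuple[float, float] = (20.0, 300.0)
    nb_dispersion: float = 0.02
    de_fraction: float = 0.15
    de_fold: float = 4.0
    min_lncrna_counts: int = 10
    n_plants: int = 5
    n_decoys_outside: int = 4
    n_decoys_half: int = 4
    segment_length: int = 30
    n_pathways: int = 8
    pathway_size: tuple[int, int] = (10, 30)

    def validate(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_contaminant", "n_housekeeping",
                     "n_short", "n_small_orf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lncrna_length[0] < 300:
            raise ValueError("lncRNA length range must start at >= 300 nt")
        if self.de_fold <= 1:
            raise ValueError("de_fold must be > 1")
        if self.segment_length < 10:
            raise ValueError("segment_length must be >= 10 nt")
        if not 0 <= self.housekeeping_mutation_rate <= 0.02:
            raise ValueError("housekeeping mutation rate must be in [0, 0.02]")


@dataclass
class TruthManifest:
    classes: dict[str, str] = field(default_factory=dict)
    de_truth: dict[str, dict] = field(default_factory=dict)
    regions: list[dict] = field(default_factory=list)
    edges: list[dict] = field(default_factory=list)
    flipped_evidence: list[str] = field(default_factory=list)

    @property
    def lncrna_ids(self) -> set[str]:
        return {tid for tid, cls in self.classes.items() if cls == "lncrna"}

    def class_ids(self, cls: str) -> list[str]:
        return [tid for tid, c in self.classes.items() if c == cls]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "de_truth": self.de_truth,
            "regions": self.regions,
            "edges": self.edges,
            "flipped_evidence": self.flipped_evidence,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes=payload["classes"],
            de_truth=payload["de_truth"],
            regions=payload["regions"],
            edges=payload["edges"],
            flipped_evidence=payload["flipped_evidence"],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tclass\tis_de\tfold\tdirection\n")
            for tid in self.classes:
                de = self.de_truth.get(tid, {})
                fh.write(
                    f"{tid}\t{self.classes[tid]}\t{int(de.get('is_de', False))}\t"
                    f"{de.get('fold', 1.0)}\t{de.get('direction', '.')}\n"
                )


def load_reference_fasta(name: str) -> list[Transcript]:
    """Load one of the shipped reference FASTA files from package data."""
    from .seqcore import read_fasta

    return read_fasta(Path(str(resources.files("lnckit").joinpath("data", name))))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _random_codons(rng: np.random.Generator, n_aa: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n_aa)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_mut = int(round(rate * len(chars)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(chars), size=n_mut, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _sample_lncrna(rng: np.random.Generator, config: SimConfig) -> str:
    # rejection-sample until the longest stop-to-stop ORF on both strands
    # is small enough to survive the ORF filter
    lo, hi = config.lncrna_length
    for _ in range(1000):
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if longest_orf_aa(Transcript("x", seq)) <= config.max_orf_aa:
            return seq
    raise RuntimeError("could not sample a lncRNA satisfying the ORF bound")


def simulate_transcriptome(config: SimConfig) -> tuple[list[Transcript], TruthManifest]:
    """Generate all six transcript classes plus the truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = TruthManifest()
    transcripts: list[Transcript] = []

    symbiont_refs = load_reference_fasta("symbiont_ref.fasta")
    rrna_refs = load_reference_fasta("rrna_ref.fasta")

    def add(tid: str, seq: str, cls: str) -> None:
        transcripts.append(Transcript(tid, seq))
        manifest.classes[tid] = cls

    for k in range(config.n_mrna):
        aa = int(rng.integers(*config.mrna_orf_aa))
        utr5 = _random_seq(rng, int(rng.integers(*config.utr_length)))
        utr3 = _random_seq(rng, int(rng.integers(*config.utr_length)))
        stop = _STOPS[rng.integers(0, 3)]
        add(f"mrna_{k:04d}", utr5 + "ATG" + _random_codons(rng, aa) + stop + utr3, "mrna")

    for k in range(config.n_lncrna):
        add(f"lnc_{k:04d}", _sample_lncrna(rng, config), "lncrna")

    for k in range(config.n_contaminant):
        ref = symbiont_refs[rng.integers(0, len(symbiont_refs))]
        frac = rng.uniform(0.6, 0.9)
        length = int(frac * ref.length)
        start = int(rng.integers(0, ref.length - length + 1))
        seq = _mutate(rng, ref.sequence[start : start + length], 0.01)
        add(f"sym_{k:04d}", seq, "contaminant")

    for k in range(config.n_housekeeping):
        ref = rrna_refs[rng.integers(0, len(rrna_refs))]
        for _ in range(100):
            seq = _mutate(rng, ref.sequence, config.housekeeping_mutation_rate)
            if longest_orf_aa(Transcript("x", seq)) <= config.max_orf_aa:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not mutate housekeeping copy within ORF bound")
        add(f"hk_{k:04d}", seq, "housekeeping")

    for k in range(config.n_short):
        add(f"short_{k:04d}", _random_seq(rng, int(rng.integers(*config.short_length))), "short")

    for k in range(config.n_small_orf):
        aa = int(rng.integers(*config.small_orf_aa))
        pad = max(0, (310 - 3 * aa) // 2) + int(rng.integers(10, 80))
        stop5 = _STOPS[rng.integers(0, 3)]
        stop3 = _STOPS[rng.integers(0, 3)]
        seq = (
            _random_seq(rng, pad) + stop5 + _random_codons(rng, aa) + stop3
            + _random_seq(rng, pad)
        )
        add(f"sorf_{k:04d}", seq, "small_orf")

    return transcripts, manifest


@dataclass
class EvidenceTables:
    symbiont: list[HitRecord]
    protein: list[HitRecord]
    domain: list[HitRecord]
    signal_positive: list[str]
    housekeeping: list[HitRecord]
    plek_calls: dict[str, bool]  # id -> is_coding
    symbiont_subject_lengths: dict[str, int]


def _hit(q, s, qlen, e, ident=98.0, s_start=1) -> HitRecord:
    return HitRecord(
        query_id=q,
        subject_id=s,
        percent_identity=ident,
        alignment_length=qlen,
        mismatches=int(qlen * (100 - ident) / 100),
        gap_opens=0,
        q_start=1,
        q_end=qlen,
        s_start=s_start,
        s_end=s_start + qlen - 1,
        e_value=e,
        bit_score=2.0 * qlen,
    )


def emit_evidence_tables(
    transcripts: Sequence[Transcript],
    manifest: TruthManifest,
    config: SimConfig,
    noise_rate: float = 0.0,
) -> EvidenceTables:
    """Build the five evidence tracks implied by the planted classes.

    Noiseless tables make discovery recover the manifest exactly:
    contaminants get symbiont hits satisfying the reciprocal-coverage
    rule, mRNAs get strong protein hits (some also domain/signal),
    housekeeping copies get housekeeping-RNA hits, lncRNAs get nothing.
    With ``noise_rate`` > 0 a seeded fraction of transcripts has its
    protein-track evidence flipped, and is recorded in the manifest.
    """
    rng = np.random.default_rng(config.seed + 1)
    by_id = {t.id: t for t in transcripts}
    symbiont_refs = load_reference_fasta("symbiont_ref.fasta")
    ref_lengths = {t.id: t.length for t in symbiont_refs}
    tables = EvidenceTables([], [], [], [], [], {}, ref_lengths)

    for t in transcripts:
        cls = manifest.classes[t.id]
        if cls == "contaminant":
            # the full transcript aligns back to its source reference; the
            # slice fraction (>= 0.6) guarantees >50% subject coverage
            ref = min(
                ref_lengths,
                key=lambda rid: abs(ref_lengths[rid] - t.length / 0.75),
            )
            tables.symbiont.append(_hit(t.id, ref, t.length, 1e-30, ident=99.0))
        elif cls == "mrna":
            tables.protein.append(_hit(t.id, f"prot_{t.id}", t.length, 1e-20))
            k = int(t.id.split("_")[1])
            if k % 3 == 0:
                tables.domain.append(_hit(t.id, "PF00001_like", min(180, t.length), 1e-8))
            if k % 5 == 0:
                tables.signal_positive.append(t.id)
        elif cls == "housekeeping":
            tables.housekeeping.append(_hit(t.id, "RF00001_like", t.length, 1e-12))
        tables.plek_calls[t.id] = cls in ("mrna", "small_orf")

    if noise_rate > 0:
        n_flip = int(round(noise_rate * len(transcripts)))
        flip_ids = sorted(
            rng.choice([t.id for t in transcripts], size=n_flip, replace=False)
        )
        flipped_protein = {h.query_id for h in tables.protein}
        for tid in flip_ids:
            if tid in flipped_protein:
                tables.protein = [h for h in tables.protein if h.query_id != tid]
            else:
                tables.protein.append(_hit(tid, f"noise_prot_{tid}", by_id[tid].length, 1e-10))
        manifest.flipped_evidence = list(flip_ids)
    return tables


def evidence_bundle_from_tables(
    tables: EvidenceTables,
    transcripts: Sequence[Transcript],
    config: SimConfig | None = None,
) -> EvidenceBundle:
    """Aggregate emitted tables into the discovery-facing bundle."""
    from .evidence import coding_evidence_flags

    e_protein = 1e-4
    bundle = coding_evidence_flags(tables.protein, tables.domain, tables.signal_positive,
                                   e_protein=e_protein)
    q_lengths = {t.id: t.length for t in transcripts}
    bundle.symbiont_hit = symbiont_contaminants(
        tables.symbiont, q_lengths, tables.symbiont_subject_lengths
    )
    bundle.housekeeping_hit = {h.query_id for h in tables.housekeeping}
    bundle.plek_coding = dict(tables.plek_calls)
    return bundle


def nb_draws(
    rng: np.random.Generator, mean: float, dispersion: float, size: int | None = None
):
    """Negative-binomial draws with var = mean + dispersion * mean^2.

    dispersion == 0 degenerates to Poisson.
    """
    if mean < 0 or dispersion < 0:
        raise ValueError("mean and dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_counts(manifest: TruthManifest, config: SimConfig) -> CountsTable:
    """Two-condition counts with planted fold changes.

    Direction "up" means a higher mean in the second (bleaching) sample.
    True lncRNAs are guaranteed an overall count of at least the
    discovery threshold so expression never silently reclassifies them.
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = ["healthy", "bleaching"]
    counts: dict[str, list[int]] = {}
    # fixed-size DE sets (not per-transcript coin flips) so small fixtures
    # still carry a usable planted signal
    de_set: set[str] = set()
    for cls in ("mrna", "lncrna"):
        ids = manifest.class_ids(cls)
        n_de = min(len(ids), max(5, round(config.de_fraction * len(ids)))) if ids else 0
        de_set.update(rng.choice(ids, size=n_de, replace=False))
    for tid, cls in manifest.classes.items():
        base = rng.uniform(*config.nb_mean_range)
        is_de = tid in de_set
        direction = "."
        m1 = m2 = base
        if is_de:
            direction = "up" if rng.random() < 0.5 else "down"
            if direction == "up":
                m2 = base * config.de_fold
            else:
                m1 = base * config.de_fold
        row = [int(nb_draws(rng, m1, config.nb_dispersion)),
               int(nb_draws(rng, m2, config.nb_dispersion))]
        if cls == "lncrna":
            while sum(row) < config.min_lncrna_counts:  # pragma: no cover - rare
                row = [int(nb_draws(rng, m1, config.nb_dispersion)),
                       int(nb_draws(rng, m2, config.nb_dispersion))]
        counts[tid] = row
        manifest.de_truth[tid] = {
            "is_de": bool(is_de),
            "fold": config.de_fold if is_de else 1.0,
            "direction": direction,
        }
    totals = {
        s: sum(row[i] for row in counts.values()) for i, s in enumerate(samples)
    }
    return CountsTable(samples, counts, totals)


def _splice(seq: str, pos: int, insert: str) -> str:
    return seq[:pos] + insert + seq[pos + len(insert) :]


def plant_interactions(
    transcripts: list[Transcript],
    manifest: TruthManifest,
    config: SimConfig,
) -> tuple[list[Transcript], list[HitRecord], list[ConservedRegion]]:
    """Plant true interactions and decoys; returns updated transcripts.

    For each true plant, a segment of a lncRNA is declared conserved (a
    reference-database hit covering it is emitted) and its exact reverse
    complement is spliced into a target mRNA.  "outside" decoys place
    the complementary segment outside the lncRNA's conserved region;
    "half" decoys use a weakly pairing A/T half-length segment inside
    the region.  Every plant is verified against the default energy
    model and gates, resampling positions until the intended gate
    outcome holds.
    """
    rng = np.random.default_rng(config.seed + 3)
    noncode_refs = load_reference_fasta("noncode_ref.fasta")
    by_id = {t.id: t for t in transcripts}
    lnc_ids = sorted(manifest.lncrna_ids)
    mrna_ids = sorted(manifest.class_ids("mrna"))
    n_needed = config.n_plants + config.n_decoys_outside + config.n_decoys_half
    if len(lnc_ids) < n_needed or len(mrna_ids) < n_needed:
        raise ValueError("not enough lncRNAs/mRNAs for the requested plants")

    chosen_lnc = list(rng.choice(lnc_ids, size=n_needed, replace=False))
    chosen_mrna = list(rng.choice(mrna_ids, size=n_needed, replace=False))
    model = default_energy_model()
    hits: list[HitRecord] = []
    regions: list[ConservedRegion] = []
    seg_len = config.segment_length
    half_len = seg_len // 2

    kinds = (
        [None] * config.n_plants
        + ["outside"] * config.n_decoys_outside
        + ["half"] * config.n_decoys_half
    )
    for idx, kind in enumerate(kinds):
        lnc = by_id[chosen_lnc[idx]]
        mrna = by_id[chosen_mrna[idx]]
        ref = noncode_refs[int(rng.integers(0, len(noncode_refs)))]
        for attempt in range(30):
            lnc_seq = lnc.sequence
            if kind is None:
                seg_start = int(rng.integers(0, lnc.length - seg_len + 1))
                region = (seg_start, seg_start + seg_len)
                segment = lnc_seq[seg_start : seg_start + seg_len]
            elif kind == "outside":
                # conserved region in the first half, segment in the second
                region = (0, seg_len)
                seg_start = int(rng.integers(lnc.length // 2, lnc.length - seg_len + 1))
                segment = lnc_seq[seg_start : seg_start + seg_len]
            else:  # half-length, weak A/T-only pairing
                seg_start = int(rng.integers(0, lnc.length - half_len + 1))
                segment = "".join("AT"[i] for i in rng.integers(0, 2, half_len))
                lnc_seq = _splice(lnc_seq, seg_start, segment)
                region = (max(0, seg_start - 5), min(lnc.length, seg_start + half_len + 5))
            mrna_pos = int(rng.integers(0, mrna.length - len(segment) + 1))
            mrna_seq = _splice(mrna.sequence, mrna_pos, reverse_complement(segment))

            cand_lnc = Transcript(lnc.id, lnc_seq)
            if longest_orf_aa(cand_lnc) > config.max_orf_aa:
                continue
            dup = duplex_fold(lnc_seq, mrna_seq, model,
                              lncrna_id=lnc.id, mrna_id=mrna.id)
            if dup is None:
                continue
            cand_region = ConservedRegion(lnc.id, region[0], region[1], ref.id, 1e-8)
            edge = gate_interactions([dup], [cand_region])[0]
            ok = edge.accepted if kind is None else not edge.accepted
            if ok:
                by_id[lnc.id] = cand_lnc
                by_id[mrna.id] = Transcript(mrna.id, mrna_seq)
                regions.append(cand_region)
                hits.append(
                    HitRecord(
                        query_id=lnc.id,
                        subject_id=ref.id,
                        percent_identity=96.0,
                        alignment_length=region[1] - region[0],
                        mismatches=1,
                        gap_opens=0,
                        q_start=region[0] + 1,
                        q_end=region[1],
                        s_start=1,
                        s_end=region[1] - region[0],
                        e_value=1e-8,
                        bit_score=50.0,
                    )
                )
                manifest.regions.append(
                    {"lncrna_id": lnc.id, "start": region[0], "end": region[1]}
                )
                manifest.edges.append(
                    {
                        "lncrna_id": lnc.id,
                        "mrna_id": mrna.id,
                        "decoy": kind,
                        "lnc_start": seg_start,
                        "lnc_end": seg_start + len(segment),
                        "mrna_pos": mrna_pos,
                    }
                )
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place interaction plant {idx} ({kind})")

    updated = [by_id[t.id] for t in transcripts]
    return updated, hits, regions


def _make_pathways(
    manifest: TruthManifest, config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, str, list[str]]]:
    mrna_ids = manifest.class_ids("mrna")
    de_ids = [
        tid for tid in mrna_ids if manifest.de_truth.get(tid, {}).get("is_de", False)
    ]
    pathways: list[tuple[str, str, list[str]]] = []
    for k in range(config.n_pathways):
        size = int(rng.integers(*config.pathway_size))
        members = sorted(rng.choice(mrna_ids, size=min(size, len(mrna_ids)), replace=False))
        pathways.append((f"pw{k:03d}", f"random pathway {k}", members))
    if de_ids:
        # one pathway made of planted DE genes so enrichment has signal
        n_de = max(1, min(len(de_ids), 15))
        members = sorted(rng.choice(de_ids, size=n_de, replace=False))
        pathways.append(("pw_de", "planted DE pathway", members))
    return pathways


def generate_all(config: SimConfig, outdir: str | Path) -> TruthManifest:
    """Run the whole generator and write every output file to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, manifest = simulate_transcriptome(config)
    counts = simulate_counts(manifest, config)
    transcripts, noncode_hits, regions = plant_interactions(transcripts, manifest, config)
    tables = emit_evidence_tables(transcripts, manifest, config)

    write_fasta(transcripts, outdir / "transcripts.fasta")
    for cls in CLASSES:
        ids = set(manifest.class_ids(cls))
        write_fasta([t for t in transcripts if t.id in ids], outdir / f"{cls}.fasta")

    write_hit_table(tables.symbiont, outdir / "symbiont_hits.tsv")
    write_hit_table(tables.protein, outdir / "protein_hits.tsv")
    write_hit_table(tables.domain, outdir / "domain_hits.tsv")
    write_hit_table(tables.housekeeping, outdir / "housekeeping_hits.tsv")
    write_hit_table(noncode_hits, outdir / "noncode_hits.tsv")
    with open(outdir / "signal_calls.tsv", "w") as fh:
        for t in transcripts:
            flag = "Y" if t.id in set(tables.signal_positive) else "N"
            fh.write(f"{t.id}\t{flag}\n")
    with open(outdir / "plek_calls.tsv", "w") as fh:
        for t in transcripts:
            label = "coding" if tables.plek_calls[t.id] else "noncoding"
            fh.write(f"{t.id}\t{label}\n")

    write_counts_tsv(counts, outdir / "counts.tsv")
    write_regions_bed(regions, outdir / "planted_regions.bed")

    rng = np.random.default_rng(config.seed + 4)
    with open(outdir / "pathways.tsv", "w") as fh:
        for pid, name, members in _make_pathways(manifest, config, rng):
            fh.write(f"{pid}\t{name}\t{','.join(members)}\n")

    manifest.to_tsv(outdir / "manifest.tsv")
    manifest.to_json(outdir / "manifest.json")
    return manifest
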