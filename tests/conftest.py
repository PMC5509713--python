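from __future__ import annotations

import pytest

from lnckit.discovery import classify_transcripts
from lnckit.synthetic import (
    SimConfig,
    emit_evidence_tables,
    evidence_bundle_from_tables,
    plant_interactions,
    simulate_counts,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def sim42():
    """The headline seed-42 fixture: 500 transcripts, noiseless evidence."""
    config = SimConfig(seed=42)
    transcripts, manifest = simulate_transcriptome(config)
    counts = simulate_counts(manifest, config)
    transcripts, noncode_hits, regions = plant_interactions(transcripts, manifest, config)
    tables = emit_evidence_tables(transcripts, manifest, config)
    bundle = evidence_bundle_from_tables(tables, transcripts)
    return {
        "config": config,
        "transcripts": transcripts,
        "manifest": manifest,
        "counts": counts,
        "noncode_hits": noncode_hits,
        "regions": regions,
        "tables": tables,
        "bundle": bundle,
    }


@pytest.fixture(scope="session")
def sim42_classified(sim42):
    lnc_ids, traces = classify_transcripts(
        sim42["transcripts"], sim42["bundle"], sim42["counts"].total_by_transcript()
    )
    return lnc_ids, traces


def small_config(seed: int = 42) -> SimConfig:
    """A cheap configuration for tests that run the generator repeatedly."""
    return SimConfig(
        seed=seed,
        n_mrna=40,
        n_lncrna=60,
        n_contaminant=12,
        n_housekeeping=10,
        n_short=10,
        n_small_orf=8,
        n_plants=3,
        n_decoys_outside=2,
        n_decoys_half=2,
    )
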