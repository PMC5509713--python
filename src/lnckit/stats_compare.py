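"""Distribution comparison (two-sample KS) and the shared-lncRNA rule."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import kolmogorov

from .evidence import HitRecord

__all__ = ["KsOutcome", "ks_two_sample", "shared_lncrnas"]


@dataclass(frozen=True)
class KsOutcome:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KsOutcome:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    p-value comes from the asymptotic Kolmogorov distribution evaluated
    at sqrt(n1*n2/(n1+n2)) * D.
    """
    x = np.sort(np.asarray(a, dtype=float))
    y = np.sort(np.asarray(b, dtype=float))
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(n1 * n2 / (n1 + n2))
    p = float(min(1.0, max(0.0, kolmogorov(en * d))))
    return KsOutcome(d_statistic=d, p_value=p, n1=n1, n2=n2)


def ks_two_sample_permutation(
    a: Sequence[float], b: Sequence[float], n_perm: int = 2000, seed: int = 0
) -> KsOutcome:
    """Exact-style permutation p-value for small samples (test utility)."""
    observed = ks_two_sample(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = ks_two_sample(pooled[:n1], pooled[n1:]).d_statistic
        if d >= observed.d_statistic - 1e-12:
            hits += 1
    return KsOutcome(observed.d_statistic, (hits + 1) / (n_perm + 1), n1, len(b))


def shared_lncrnas(
    hits_between_species: Iterable[HitRecord],
    lengths_a: Mapping[str, int],
    lengths_b: Mapping[str, int],
) -> set[tuple[str, str]]:
    """Cross-species shared lncRNA pairs.

    A pair is shared iff some hit's matching region is longer than half
    of BOTH compared lncRNAs (the stricter reading of the criterion).
    """
    shared: set[tuple[str, str]] = set()
    for hit in hits_between_species:
        if hit.query_id not in lengths_a:
            raise KeyError(f"no recorded length for query lncRNA {hit.query_id!r}")
        if hit.subject_id not in lengths_b:
            raise KeyError(f"no recorded length for subject lncRNA {hit.subject_id!r}")
        if hit.alignment_length > 0.5 * lengths_a[hit.query_id] and (
            hit.alignment_length > 0.5 * lengths_b[hit.subject_id]
        ):
            shared.add((hit.query_id, hit.subject_id))
    return shared
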