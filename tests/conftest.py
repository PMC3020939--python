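"""Shared fixtures and independent brute-force oracles.

The oracles work on explicit per-basepair sets and never touch the
package's interval arithmetic, so agreement between the two is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnvbench import CNVCall, GenomicInterval, ReferenceCNV


# ---------------------------------------------------------------------------
# per-basepair oracles


def bp_set(interval: GenomicInterval) -> set[tuple[str, int]]:
    return {(interval.chrom, p) for p in range(interval.start, interval.end)}


def oracle_intersection(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(bp_set(a) & bp_set(b))


def oracle_union(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(bp_set(a) | bp_set(b))


def oracle_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = oracle_intersection(a, b)
    return inter / oracle_union(a, b) if inter else 0.0


def oracle_recovered(ref: ReferenceCNV, calls, threshold: float,
                     require_state: bool) -> bool:
    """Exhaustive all-pairs recovery decision for one reference."""
    for c in calls:
        if c.copy_number == 2:
            continue
        if c.sample_id != ref.sample_id:
            continue
        if oracle_fraction(ref.interval, c.interval) >= threshold:
            if not require_state or c.state == ref.state:
                return True
    return False


# ---------------------------------------------------------------------------
# random generators for small fixtures


def random_interval(rng: np.random.Generator, chrom="chr1", max_pos=10_000,
                    max_len=2_000) -> GenomicInterval:
    start = int(rng.integers(0, max_pos - 1))
    length = int(rng.integers(1, max_len))
    return GenomicInterval(chrom, start, min(start + length, max_pos))


def random_calls(rng, n, samples=("S1", "S2"), caller="X") -> list[CNVCall]:
    out = []
    for _ in range(n):
        out.append(
            CNVCall(
                interval=random_interval(rng),
                sample_id=str(rng.choice(samples)),
                copy_number=int(rng.choice([0, 1, 2, 3, 4])),
                caller=caller,
                lod=float(rng.uniform(0, 20)),
            )
        )
    return out


def random_refs(rng, n, samples=("S1", "S2"), source="T") -> list[ReferenceCNV]:
    out = []
    for _ in range(n):
        out.append(
            ReferenceCNV(
                interval=random_interval(rng),
                sample_id=str(rng.choice(samples)),
                state=str(rng.choice(["deletion", "duplication"])),
                source=source,
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20110113)
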