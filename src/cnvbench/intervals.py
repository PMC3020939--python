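"""Genomic-interval data model and overlap arithmetic.

Every statistic in the benchmarking pipeline reduces to interval overlap on
0-based half-open coordinates. The central matching statistic is the
*combined-span overlap fraction*: intersection length divided by the set-union
length of the two intervals. A truth CNV counts as recovered when some call
reaches a fraction of at least 0.25; cross-program common-CNV matching uses
0.50. Text I/O elsewhere in the package is 1-based inclusive (the display
convention of CNV coordinates such as ``chr8:39354760-39506122``); conversion
happens at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DELETION = "deletion"
NORMAL = "normal"
DUPLICATION = "duplication"
UNKNOWN = "unknown"

#: valid states for a reference (truth-set) CNV
REFERENCE_STATES = frozenset({DELETION, DUPLICATION, UNKNOWN})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic segment, 0-based half-open ``[start, end)``.

    Zero-length intervals are rejected: a CNV with no extent is meaningless
    and silently admitting them would poison length arithmetic downstream.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # 1-based inclusive display form
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def state_from_copy_number(copy_number: int) -> str:
    """Map an integer copy number to a CNV state (diploid baseline of 2)."""
    if copy_number < 2:
        return DELETION
    if copy_number > 2:
        return DUPLICATION
    return NORMAL


@dataclass(frozen=True)
class CNVCall:
    """One caller-emitted CNV in one sample.

    ``lod`` is the caller-reported log-odds of the stated copy number versus
    the flanking copy number; some segmentation callers emit none, so it is
    optional. State (deletion/normal/duplication) is derived from
    ``copy_number``, never stored: calls at copy number 2 are non-events and
    are excluded from matching and singleton analysis.
    """

    interval: GenomicInterval
    sample_id: str
    copy_number: int
    caller: str
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError(f"negative copy number: {self.copy_number}")
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"negative LOD score: {self.lod}")

    @property
    def state(self) -> str:
        return state_from_copy_number(self.copy_number)


@dataclass(frozen=True)
class ReferenceCNV:
    """One truth-set CNV in one sample.

    ``state`` may be ``"unknown"`` — some truth sets report the presence of a
    variant without its direction; such references can be matched but cannot
    participate in the state-consistency requirement.
    """

    interval: GenomicInterval
    sample_id: str
    state: str
    source: str

    def __post_init__(self) -> None:
        if self.state not in REFERENCE_STATES:
            raise ValueError(
                f"reference state must be one of {sorted(REFERENCE_STATES)}, got {self.state!r}"
            )


class ProbeMap:
    """Sorted per-chromosome array-probe positions.

    Positions are 0-based and strictly increasing within a chromosome;
    membership of a probe in an interval follows the half-open rule
    ``start <= p < end``. Probe counts are the size stratification used by the
    recovery tables (a CNV spanning more markers is easier to call).
    """

    def __init__(self, positions: Mapping[str, Sequence[int]],
                 probe_ids: Optional[Mapping[str, Sequence[str]]] = None):
        self._pos: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[str]] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            order = np.argsort(arr, kind="stable")
            arr = arr[order]
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"duplicate probe positions on {chrom}")
            self._pos[chrom] = arr
            if probe_ids is not None and chrom in probe_ids:
                ids = list(probe_ids[chrom])
                self._ids[chrom] = [ids[i] for i in order]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def n_probes(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return int(self.positions(chrom).size)
        return int(sum(a.size for a in self._pos.values()))

    def count(self, interval: GenomicInterval) -> int:
        return count_probes(interval, self)


@dataclass(frozen=True)
class CNVRegion:
    """A cluster of per-sample reference CNVs treated as one locus.

    ``frequency`` is the fraction of the cohort carrying any member CNV;
    recovery as a function of this frequency is the pipeline's probe for the
    common-variant reference problem (callers that build their two-copy
    reference from the batch itself degrade as carriers become common).
    """

    interval: GenomicInterval
    members: tuple[ReferenceCNV, ...]
    carriers: frozenset[str]
    frequency: float

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"region frequency must be in (0, 1], got {self.frequency}")
        if not self.members:
            raise ValueError("region must have at least one member CNV")
        for m in self.members:
            if intersection_length(m.interval, self.interval) < 1:
                raise ValueError("region member does not overlap the region interval")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


# ---------------------------------------------------------------------------
# interval arithmetic


def intersection_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 if disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def combined_span_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Set-union length of two same-chromosome intervals.

    This is the denominator of the matching statistic ("the total length
    spanned by the two calls combined"). Different chromosomes are a caller
    error here: there is no meaningful union length across chromosomes.
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"combined span undefined across chromosomes ({a.chrom} vs {b.chrom})"
        )
    return a.length + b.length - intersection_length(a, b)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Intersection length over set-union length; symmetric; in [0, 1].

    Returns 0.0 for intervals on different chromosomes, so callers may apply
    it without pre-filtering by chromosome.
    """
    if a.chrom != b.chrom:
        return 0.0
    inter = intersection_length(a, b)
    if inter == 0:
        return 0.0
    return inter / combined_span_length(a, b)


def count_probes(interval: GenomicInterval, probes: ProbeMap) -> int:
    """Number of probe positions p with ``start <= p < end`` (binary search)."""
    pos = probes.positions(interval.chrom)
    if pos.size == 0:
        if interval.chrom not in probes.chromosomes:
            logger.warning("chromosome %s absent from probe map", interval.chrom)
        return 0
    lo = int(np.searchsorted(pos, interval.start, side="left"))
    hi = int(np.searchsorted(pos, interval.end, side="left"))
    return hi - lo


# ---------------------------------------------------------------------------
# region clustering


def merge_into_regions(
    refs: Iterable[ReferenceCNV],
    total_samples: int,
    rule: str = "any-overlap",
    min_fraction: float = 0.25,
) -> list[CNVRegion]:
    """Cluster per-sample reference CNVs into regions and assign frequencies.

    Single-linkage clustering on the same chromosome. Under the default
    ``"any-overlap"`` rule two CNVs link when they share at least 1 bp; under
    ``"fraction"`` they must reach ``min_fraction`` combined-span overlap.
    The region interval is the union span of its members; frequency is
    distinct carrier samples / ``total_samples``.

    Every input CNV lands in exactly one region (the clustering partitions
    the input).
    """
    refs = list(refs)
    if not refs:
        return []
    distinct = {r.sample_id for r in refs}
    if total_samples < len(distinct):
        raise ValueError(
            f"total_samples={total_samples} < {len(distinct)} distinct sample ids"
        )
    if rule not in ("any-overlap", "fraction"):
        raise ValueError(f"unknown clustering rule {rule!r}")

    by_chrom: dict[str, list[ReferenceCNV]] = {}
    for r in refs:
        by_chrom.setdefault(r.interval.chrom, []).append(r)

    regions: list[CNVRegion] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        if rule == "any-overlap":
            clusters = _sweep_clusters(group)
        else:
            clusters = _fraction_clusters(group, min_fraction)
        for members in clusters:
            start = min(m.interval.start for m in members)
            end = max(m.interval.end for m in members)
            carriers = frozenset(m.sample_id for m in members)
            regions.append(
                CNVRegion(
                    interval=GenomicInterval(chrom, start, end),
                    members=tuple(members),
                    carriers=carriers,
                    frequency=len(carriers) / total_samples,
                )
            )
    return regions


def _sweep_clusters(sorted_refs: list[ReferenceCNV]) -> list[list[ReferenceCNV]]:
    # start-sorted sweep: >=1 bp overlap chains iff next.start < running max end
    clusters: list[list[ReferenceCNV]] = []
    current: list[ReferenceCNV] = []
    max_end = -1
    for r in sorted_refs:
        if current and r.interval.start < max_end:
            current.append(r)
            max_end = max(max_end, r.interval.end)
        else:
            if current:
                clusters.append(current)
            current = [r]
            max_end = r.interval.end
    if current:
        clusters.append(current)
    return clusters


def _fraction_clusters(
    sorted_refs: list[ReferenceCNV], min_fraction: float
) -> list[list[ReferenceCNV]]:
    # union-find over pairs passing the combined-span threshold; candidate
    # pairs restricted to the any-overlap sweep clusters (a fraction link
    # implies a >=1 bp link, so no cross-sweep pair can qualify)
    out: list[list[ReferenceCNV]] = []
    for block in _sweep_clusters(sorted_refs):
        n = len(block)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if block[j].interval.start >= block[i].interval.end:
                    break
                if overlap_fraction(block[i].interval, block[j].interval) >= min_fraction:
                    parent[find(i)] = find(j)
        groups: dict[int, list[ReferenceCNV]] = {}
        for i, r in enumerate(block):
            groups.setdefault(find(i), []).append(r)
        out.extend(groups.values())
    return out
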