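"""Recovery-rate evaluation of a CNV call set against a truth set.

A reference CNV is *recovered* when at least one non-diploid call in the
same sample shares at least a threshold fraction (default 0.25) of the
combined span of the two intervals. Two criteria are reported side by side:

* ``korn_only`` — any-direction matching (the original recovery statistic);
* ``with_consistency`` — additionally the call must be in the same direction
  as the reference (a call at 0 or 1 copies must correspond to a deletion,
  and a call above 2 copies to a duplication).

Switching consistency on can only remove matches, so the with-consistency
rate is never above the any-direction rate; the size of the drop measures
how often a caller detects a variant but mislabels its direction.

Recovery is existential and many-to-many: several calls may recover one
reference and one call may recover several references; no one-to-one
assignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    UNKNOWN,
    CNVCall,
    CNVRegion,
    ProbeMap,
    ReferenceCNV,
    count_probes,
    overlap_fraction,
)

#: probe-count strata for the recovery-by-length table. The printed strata
#: "6-10" and "10-20" share the value 10; bins here are disjoint integer
#: ranges so that every reference falls in exactly one stratum.
DEFAULT_PROBE_BINS: tuple[tuple[int, Optional[int]], ...] = (
    (1, 1), (2, 5), (6, 10), (11, 20), (21, None),
)

#: carrier-frequency strata, half-open (lo, hi]
DEFAULT_FREQUENCY_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0),
)


@dataclass(frozen=True)
class MatchResult:
    """Pairing of one reference CNV with the calls that recover it."""

    ref_index: int
    ref: ReferenceCNV
    call_indices: tuple[int, ...]
    best_overlap: float
    state_consistent: bool
    recovered_korn_only: bool
    recovered_with_consistency: bool
    recovered: bool  # under the criterion selected at match time

    def __post_init__(self) -> None:
        if self.recovered_with_consistency and not self.recovered_korn_only:
            raise ValueError("consistency criterion cannot add matches")


def match_reference(
    refs: Sequence[ReferenceCNV],
    calls: Sequence[CNVCall],
    threshold: float = 0.25,
    require_state: bool = False,
) -> list[MatchResult]:
    """Match every reference CNV against a call set, within sample and
    chromosome.

    Calls at copy number 2 never participate. With ``require_state`` the
    ``recovered`` flag demands direction agreement; references of unknown
    direction are then unevaluable and rejected.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"overlap threshold must be in (0, 1], got {threshold}")
    if require_state and any(r.state == UNKNOWN for r in refs):
        raise ValueError(
            "state-consistent matching requested but the truth set contains "
            "references of unknown direction"
        )

    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, c in enumerate(calls):
        if c.copy_number == 2:
            continue
        key = (c.sample_id, c.interval.chrom)
        trees.setdefault(key, IntervalTree()).addi(c.interval.start, c.interval.end, i)

    results: list[MatchResult] = []
    for ri, ref in enumerate(refs):
        tree = trees.get((ref.sample_id, ref.interval.chrom))
        matched: list[int] = []
        best = 0.0
        consistent = False
        if tree is not None:
            for iv in tree.overlap(ref.interval.start, ref.interval.end):
                call = calls[iv.data]
                frac = overlap_fraction(ref.interval, call.interval)
                best = max(best, frac)
                if frac >= threshold:
                    matched.append(iv.data)
                    if call.state == ref.state:
                        consistent = True
        korn = bool(matched)
        with_cons = korn and consistent
        results.append(
            MatchResult(
                ref_index=ri,
                ref=ref,
                call_indices=tuple(sorted(matched)),
                best_overlap=best,
                state_consistent=consistent,
                recovered_korn_only=korn,
                recovered_with_consistency=with_cons,
                recovered=with_cons if require_state else korn,
            )
        )
    return results


@dataclass
class RecoveryTable:
    """Binned recovery counts: per stratum the number of references, the
    number recovered and the recovery rate (NaN for an empty stratum)."""

    table: pd.DataFrame
    n_excluded: int = 0  # references outside all bins (e.g. spanning 0 probes)

    def __post_init__(self) -> None:
        t = self.table
        if (t["n_recovered"] > t["n_reference"]).any():
            raise ValueError("recovered count exceeds reference count in a bin")

    @property
    def total_reference(self) -> int:
        return int(self.table["n_reference"].sum())

    def rate(self, bin_label: str) -> float:
        row = self.table.loc[self.table["bin"] == bin_label]
        if row.empty:
            raise KeyError(bin_label)
        return float(row["rate"].iloc[0])


def _probe_bin_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def _validate_probe_bins(bins) -> None:
    covered: set[int] = set()
    for lo, hi in bins:
        hi_eff = hi if hi is not None else lo + 10_000
        if lo > hi_eff:
            raise ValueError(f"inverted probe bin ({lo}, {hi})")
        span = set(range(lo, hi_eff + 1))
        if covered & span:
            raise ValueError("probe bins overlap")
        covered |= span


def recovery_by_probe_bin(
    matches: Sequence[MatchResult],
    probes: ProbeMap,
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_PROBE_BINS,
) -> RecoveryTable:
    """Recovery stratified by the number of array probes a reference spans.

    References spanning no probe of the manifest are not assignable to any
    stratum; they are excluded from the table and reported via
    ``n_excluded`` (an array caller cannot in principle see them).
    """
    _validate_probe_bins(bins)
    rows = []
    counts = {b: [0, 0] for b in bins}
    excluded = 0
    for m in matches:
        n = count_probes(m.ref.interval, probes)
        placed = False
        for lo, hi in bins:
            if n >= lo and (hi is None or n <= hi):
                counts[(lo, hi)][0] += 1
                counts[(lo, hi)][1] += int(m.recovered)
                placed = True
                break
        if not placed:
            excluded += 1
    for lo, hi in bins:
        total, rec = counts[(lo, hi)]
        rows.append(
            {
                "bin": _probe_bin_label(lo, hi),
                "n_reference": total,
                "n_recovered": rec,
                "rate": rec / total if total else float("nan"),
            }
        )
    return RecoveryTable(table=pd.DataFrame(rows), n_excluded=excluded)


def region_frequency_of(
    refs: Sequence[ReferenceCNV], regions: Sequence[CNVRegion]
) -> list[float]:
    """Frequency each reference inherits from the region containing it."""
    freq: dict[ReferenceCNV, float] = {}
    for region in regions:
        if not region.members:
            raise ValueError("region without member CNVs")
        for member in region.members:
            freq[member] = region.frequency
    out = []
    for r in refs:
        if r not in freq:
            raise ValueError(f"reference {r.interval} of {r.sample_id} not in any region")
        out.append(freq[r])
    return out


def recovery_by_frequency_bin(
    matches: Sequence[MatchResult],
    regions: Sequence[CNVRegion],
    bins: Sequence[tuple[float, float]] = DEFAULT_FREQUENCY_BINS,
) -> RecoveryTable:
    """Recovery stratified by carrier frequency of the reference's region.

    Each per-sample reference inherits its region's frequency; the rate per
    stratum is recovered/total over the references in it (the form consistent
    with printed per-bin counts such as 537/669). Bins are half-open
    ``(lo, hi]``.
    """
    freqs = region_frequency_of([m.ref for m in matches], regions)
    rows = []
    for lo, hi in bins:
        idx = [i for i, f in enumerate(freqs) if lo < f <= hi]
        total = len(idx)
        rec = sum(int(matches[i].recovered) for i in idx)
        rows.append(
            {
                "bin": f"{lo:g}<a<={hi:g}",
                "n_reference": total,
                "n_recovered": rec,
                "rate": rec / total if total else float("nan"),
            }
        )
    return RecoveryTable(table=pd.DataFrame(rows))


@dataclass
class RegionSensitivity:
    """Per-region sensitivity with distribution summary.

    ``share_high`` is the fraction of regions recovered in more than 90% of
    their carriers; ``share_low`` the fraction recovered in at most 10%.
    Together they capture the empirical all-or-nothing behaviour of array
    CNV callers across loci.
    """

    per_region: pd.DataFrame
    share_high: float
    share_low: float


def per_region_sensitivity(
    matches: Sequence[MatchResult], regions: Sequence[CNVRegion]
) -> RegionSensitivity:
    """Per-region recovery rate: recovered carriers / carriers."""
    recovered_by_ref = {m.ref: m.recovered for m in matches}
    rows = []
    for i, region in enumerate(regions):
        carriers = sorted(region.carriers)
        if not carriers:
            raise ValueError("region without carriers")
        rec_samples = {
            m.sample_id
            for m in region.members
            if recovered_by_ref.get(m, False)
        }
        rows.append(
            {
                "region": i,
                "interval": str(region.interval),
                "frequency": region.frequency,
                "n_carriers": len(carriers),
                "n_recovered": len(rec_samples),
                "sensitivity": len(rec_samples) / len(carriers),
            }
        )
    df = pd.DataFrame(rows)
    n = len(df)
    share_high = float((df["sensitivity"] > 0.9).sum() / n) if n else float("nan")
    share_low = float((df["sensitivity"] <= 0.1).sum() / n) if n else float("nan")
    return RegionSensitivity(per_region=df, share_high=share_high, share_low=share_low)
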