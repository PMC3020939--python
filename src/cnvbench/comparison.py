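"""Cross-truth-set concordance, singleton identification and
program-specific classification, and per-individual CNV size profiles.

Two call or truth sets over the same individuals rarely agree perfectly:
detection platforms differ in resolution (dense aCGH finds many small
events, paired-end sequencing finds mid-sized ones), so a small event from
one set can sit inside a much larger event from the other and still fail a
combined-span overlap threshold. The concordance table quantifies this by
interval size, in both directions.

Singletons — variants seen exactly once in a whole cohort and overlapping no
other call — are the rare-CNV currency of case/control studies; whether a
singleton is reproduced by an independent caller (``shared``) or not
(``program-specific``) is a cheap proxy for its credibility before any
wet-lab validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    DELETION,
    DUPLICATION,
    NORMAL,
    CNVCall,
    GenomicInterval,
    ReferenceCNV,
    overlap_fraction,
)
from .io import CallSetTable

#: size strata in kb, half-open (lo, hi]
DEFAULT_SIZE_BINS_KB: tuple[tuple[float, float], ...] = (
    (0, 5), (5, 10), (10, 50), (50, 100), (100, 1000),
)


def _size_bin_label(lo: float, hi: float) -> str:
    if lo == 0:
        return f"<={hi:g}"
    return f"{lo:g}-{hi:g}"


def _assign_size_bin(length_bp: int, bins: Sequence[tuple[float, float]]) -> Optional[str]:
    kb = length_bp / 1000.0
    for lo, hi in bins:
        if lo < kb <= hi:
            return _size_bin_label(lo, hi)
    return None


def _interval_of(x) -> GenomicInterval:
    return x.interval


def _sample_of(x) -> str:
    return x.sample_id


# ---------------------------------------------------------------------------
# cross-dataset concordance


def cross_dataset_consistency(
    set_a: Sequence,
    set_b: Sequence,
    threshold: float = 0.25,
    size_bins: Sequence[tuple[float, float]] = DEFAULT_SIZE_BINS_KB,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Two-directional, many-to-many concordance between two CNV sets.

    Both sets are restricted to their common samples. A CNV is *matched*
    when at least one CNV of the other set, in the same sample, shares at
    least ``threshold`` of their combined span; one CNV may match several
    partners and vice versa (no exclusivity). Direction (deletion vs
    duplication) is not compared. Results are stratified by interval size.

    Accepts any records with ``interval`` and ``sample_id`` attributes
    (:class:`~cnvbench.intervals.ReferenceCNV` or CNV calls). CNVs larger
    than the last bin edge are reported in an overflow stratum.
    """
    a = list(set_a)
    b = list(set_b)
    common = {_sample_of(x) for x in a} & {_sample_of(x) for x in b}
    if not common:
        raise ValueError("the two sets share no samples; concordance undefined")
    a = [x for x in a if _sample_of(x) in common]
    b = [x for x in b if _sample_of(x) in common]

    rows = []
    for direction, src, dst, lab in (
        (f"{label_a}->{label_b}", a, b, label_a),
        (f"{label_b}->{label_a}", b, a, label_b),
    ):
        trees: dict[tuple[str, str], IntervalTree] = {}
        for x in dst:
            iv = _interval_of(x)
            key = (_sample_of(x), iv.chrom)
            trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, iv)
        binned: dict[str, list[int]] = {}
        order = [_size_bin_label(lo, hi) for lo, hi in size_bins]
        overflow = f">{size_bins[-1][1]:g}"
        for x in src:
            iv = _interval_of(x)
            bin_label = _assign_size_bin(iv.length, size_bins) or overflow
            tree = trees.get((_sample_of(x), iv.chrom))
            matched = False
            if tree is not None:
                matched = any(
                    overlap_fraction(iv, hit.data) >= threshold
                    for hit in tree.overlap(iv.start, iv.end)
                )
            tot_mat = binned.setdefault(bin_label, [0, 0])
            tot_mat[0] += 1
            tot_mat[1] += int(matched)
        for bin_label in order + ([overflow] if overflow in binned else []):
            total, matched = binned.get(bin_label, [0, 0])
            rows.append(
                {
                    "direction": direction,
                    "set": lab,
                    "size_bin_kb": bin_label,
                    "n_total": total,
                    "n_matched": matched,
                    "pct_matched": 100.0 * matched / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def matched_pairs(
    set_a: Sequence, set_b: Sequence, threshold: float = 0.25
) -> set[tuple[int, int]]:
    """Index pairs (i, j) with set_a[i] matching set_b[j] at the threshold.

    The matched-pair relation is symmetric: transposing the pair set of the
    opposite direction yields the same set.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for j, x in enumerate(set_b):
        iv = _interval_of(x)
        trees.setdefault((_sample_of(x), iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, j
        )
    pairs = set()
    for i, x in enumerate(set_a):
        iv = _interval_of(x)
        tree = trees.get((_sample_of(x), iv.chrom))
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if overlap_fraction(iv, _interval_of(set_b[hit.data])) >= threshold:
                pairs.add((i, hit.data))
    return pairs


# ---------------------------------------------------------------------------
# singletons


def find_singletons(
    calls: CallSetTable,
    cnv_class: str,
    same_class_only: bool = False,
) -> list[CNVCall]:
    """Deletions or duplications occurring exactly once in the whole cohort.

    A call of the requested class is a singleton when it overlaps (by at
    least 1 bp, in *any* sample) no other non-diploid call from the same
    caller. By default overlap with a call of either class disqualifies
    (the strictest reading of "did not overlap with any other CNVs");
    ``same_class_only`` restricts the disqualifying overlaps to the same
    class.
    """
    if cnv_class not in (DELETION, DUPLICATION):
        raise ValueError(f"cnv_class must be deletion or duplication, got {cnv_class!r}")
    events = [c for c in calls if c.state != NORMAL]
    tree_by_chrom: dict[str, IntervalTree] = {}
    for i, c in enumerate(events):
        tree_by_chrom.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, i
        )
    singles = []
    for i, c in enumerate(events):
        if c.state != cnv_class:
            continue
        tree = tree_by_chrom[c.interval.chrom]
        clash = False
        for hit in tree.overlap(c.interval.start, c.interval.end):
            j = hit.data
            if j == i:
                continue
            if same_class_only and events[j].state != cnv_class:
                continue
            clash = True
            break
        if not clash:
            singles.append(c)
    return singles


def classify_program_specific(
    singletons_by_caller: Mapping[str, Sequence[CNVCall]],
    cnv_class: str,
) -> pd.DataFrame:
    """Split each caller's singletons into shared vs program-specific.

    A singleton is *shared* when it overlaps by at least 1 bp (any sample)
    a singleton of the same class from at least one other caller; otherwise
    it is *program-specific*. Note the deliberate contrast with recovery
    matching: sharing here is any-basepair, not fractional.
    """
    if len(singletons_by_caller) < 2:
        raise ValueError("program-specific classification needs >=2 callers")
    trees: dict[str, dict[str, IntervalTree]] = {}
    for caller, singles in singletons_by_caller.items():
        per_chrom: dict[str, IntervalTree] = {}
        for c in singles:
            if c.state != cnv_class:
                raise ValueError(
                    f"{caller}: singleton of class {c.state} passed for {cnv_class}"
                )
            per_chrom.setdefault(c.interval.chrom, IntervalTree()).addi(
                c.interval.start, c.interval.end, None
            )
        trees[caller] = per_chrom

    rows = []
    for caller, singles in singletons_by_caller.items():
        shared = 0
        for c in singles:
            hit = any(
                other != caller
                and c.interval.chrom in trees[other]
                and trees[other][c.interval.chrom].overlap(c.interval.start, c.interval.end)
                for other in singletons_by_caller
            )
            shared += int(hit)
        total = len(singles)
        specific = total - shared
        rows.append(
            {
                "caller": caller,
                "cnv_class": cnv_class,
                "n_total": total,
                "n_shared": shared,
                "n_program_specific": specific,
                "pct_shared": 100.0 * shared / total if total else float("nan"),
                "pct_program_specific": 100.0 * specific / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# size profile


def size_profile(
    callsets: Mapping[str, CallSetTable] | CallSetTable,
    n_samples: int,
    size_bins: Sequence[tuple[float, float]] = DEFAULT_SIZE_BINS_KB,
) -> pd.DataFrame:
    """Mean number of CNVs per individual, per size stratum and caller.

    The denominator is the full cohort, including individuals without any
    call — the profile describes the caller's output volume, not the
    carriers'. Calls at copy number 2 are not CNVs and are excluded.
    """
    if n_samples <= 0:
        raise ValueError("cohort size must be positive")
    if isinstance(callsets, CallSetTable):
        callsets = {callsets.caller: callsets}
    rows = []
    overflow = f">{size_bins[-1][1]:g}"
    for caller, table in callsets.items():
        counts: dict[str, int] = {}
        for c in table:
            if c.state == NORMAL:
                continue
            label = _assign_size_bin(c.interval.length, size_bins) or overflow
            counts[label] = counts.get(label, 0) + 1
        labels = [_size_bin_label(lo, hi) for lo, hi in size_bins]
        if overflow in counts:
            labels.append(overflow)
        for label in labels:
            rows.append(
                {
                    "caller": caller,
                    "size_bin_kb": label,
                    "n_calls": counts.get(label, 0),
                    "mean_per_individual": counts.get(label, 0) / n_samples,
                }
            )
    return pd.DataFrame(rows)
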