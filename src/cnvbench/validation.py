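"""qPCR-based copy-number truth assignment and accuracy scoring, cross-program
common-CNV matching, and the plate-effect scan.

Relative quantification: for each sample the target-gene threshold cycle is
normalised against an endogenous control (dCt = Ct_target - Ct_control), and
then against a calibrator sample assumed to carry two copies
(ddCt = dCt_sample - dCt_calibrator). Because each PCR cycle doubles the
product, the quantity of starting template relative to the calibrator is
approximately 2^-ddCt, and the estimated copy number is 2 * 2^-ddCt.

Accuracy metrics take the qPCR state as truth. PPV = TP / (TP + FP) over
tested positive calls; the false-positive rate is FP / (FP + TN) over
qPCR-normal samples and the false-negative rate FN / (FN + TP) over
qPCR-variant samples (the standard confusion-matrix definitions, i.e.
sensitivity = 1 - FNR and specificity = 1 - FPR).

The plate-effect scan compares, for every array plate, carrier frequency of
a common CNV on the plate against all remaining plates with an exact 2x2
test; a locus whose frequency depends on the plate a sample was genotyped on
is a batch artifact, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .intervals import DELETION, DUPLICATION, NORMAL, CNVCall, overlap_fraction
from .io import PlateAssignment, QPCRMeasurement

DEFAULT_DEL_THRESHOLD = 1.5
DEFAULT_DUP_THRESHOLD = 2.5


@dataclass(frozen=True)
class CopyNumberEstimate:
    """qPCR-derived copy number for one sample at one assayed region."""

    sample_id: str
    assay: str
    ddct: float
    relative_quantity: float
    copy_number: float
    state: str


def ddct_copy_number(
    measurements: Sequence[QPCRMeasurement],
    t_del: float = DEFAULT_DEL_THRESHOLD,
    t_dup: float = DEFAULT_DUP_THRESHOLD,
) -> list[CopyNumberEstimate]:
    """Estimate copy numbers from Ct measurements by the 2^-ddCt method.

    Replicate wells of the same sample x assay are averaged before
    differencing; replicate calibrators are likewise averaged. A missing
    calibrator is fatal (nothing to anchor the scale); the estimate is
    classified into deletion/normal/duplication with :func:`classify_cn`.
    """
    by_assay: dict[str, list[QPCRMeasurement]] = {}
    for m in measurements:
        by_assay.setdefault(m.assay, []).append(m)

    out: list[CopyNumberEstimate] = []
    for assay in sorted(by_assay):
        group = by_assay[assay]
        cal = [m for m in group if m.is_calibrator]
        if not cal:
            raise ValueError(f"assay {assay!r} has no calibrator sample")
        cal_dct = float(np.mean([m.ct_target - m.ct_control for m in cal]))
        by_sample: dict[str, list[QPCRMeasurement]] = {}
        for m in group:
            by_sample.setdefault(m.sample_id, []).append(m)
        for sample in sorted(by_sample):
            reps = by_sample[sample]
            dct = float(np.mean([m.ct_target - m.ct_control for m in reps]))
            ddct = dct - cal_dct
            rq = float(2.0 ** (-ddct))
            cn = 2.0 * rq
            out.append(
                CopyNumberEstimate(
                    sample_id=sample,
                    assay=assay,
                    ddct=ddct,
                    relative_quantity=rq,
                    copy_number=cn,
                    state=classify_cn(cn, t_del, t_dup),
                )
            )
    return out


def classify_cn(
    copy_number: float,
    t_del: float = DEFAULT_DEL_THRESHOLD,
    t_dup: float = DEFAULT_DUP_THRESHOLD,
) -> str:
    """Classify an estimated copy number into deletion/normal/duplication.

    Strict inequalities: an estimate exactly on a boundary stays normal
    (boundary values are the most noise-prone, so the conservative call is
    the diploid one). Defaults 1.5 and 2.5 are midpoints between the integer
    copy-number states.
    """
    if not (0 < t_del < 2 < t_dup):
        raise ValueError(
            f"thresholds must satisfy 0 < t_del < 2 < t_dup, got {t_del}, {t_dup}"
        )
    if copy_number < t_del:
        return DELETION
    if copy_number > t_dup:
        return DUPLICATION
    return NORMAL


# ---------------------------------------------------------------------------
# accuracy metrics


@dataclass(frozen=True)
class ValidationOutcome:
    """Confusion counts of program calls against qPCR truth for one region."""

    region: str
    caller: str
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_tested(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float:
        tested = self.tp + self.fp
        return self.tp / tested if tested else float("nan")

    @property
    def fp_rate(self) -> float:
        normals = self.fp + self.tn
        return self.fp / normals if normals else float("nan")

    @property
    def fn_rate(self) -> float:
        variants = self.fn + self.tp
        return self.fn / variants if variants else float("nan")


def ppv(outcomes: Iterable[ValidationOutcome]) -> float:
    """Pooled positive predictive value TP / (TP + FP) over outcomes.

    NaN when no positive call was tested (the quantity is then undefined,
    not zero).
    """
    tp = fp = 0
    for o in outcomes:
        tp += o.tp
        fp += o.fp
    return tp / (tp + fp) if (tp + fp) else float("nan")


def fp_fn_rates(
    program_states: Mapping[str, str],
    qpcr_states: Mapping[str, str],
    region: str = "",
    caller: str = "",
    variant_states: frozenset[str] = frozenset({DELETION, DUPLICATION}),
) -> ValidationOutcome:
    """Confusion counts for one region, per-sample, with qPCR as truth.

    Both mappings are sample -> state; every sample must appear in both
    (the scored set is exactly those with a program call state *and* a qPCR
    state). A call is positive when its state is a variant state; direction
    is intentionally collapsed, since a single qPCR probe interrogates
    presence of a dosage change at the region.
    """
    missing = set(program_states) ^ set(qpcr_states)
    if missing:
        raise ValueError(
            f"samples present in only one of program/qPCR tables: {sorted(missing)[:5]}"
        )
    tp = fp = tn = fn = 0
    for sample, prog in program_states.items():
        truth = qpcr_states[sample]
        called = prog in variant_states
        real = truth in variant_states
        if called and real:
            tp += 1
        elif called and not real:
            fp += 1
        elif not called and real:
            fn += 1
        else:
            tn += 1
    return ValidationOutcome(region=region, caller=caller, tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# cross-program common-CNV matching


def match_common_cnv(
    calls_by_caller: Mapping[str, Sequence[CNVCall]],
    threshold: float = 0.5,
) -> list[list[tuple[str, int]]]:
    """Group calls of the same common CNV made by different programs.

    Pairwise matching at ``threshold`` of the combined span (default 0.5 —
    stricter than truth-set recovery because a single qPCR probe must
    interrogate every grouped call), then transitive closure into
    equivalence classes. Returns classes of ``(caller, index)`` pairs, each
    index into that caller's sequence.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    nodes: list[tuple[str, int]] = [
        (caller, i)
        for caller, calls in calls_by_caller.items()
        for i in range(len(calls))
    ]
    index = {node: k for k, node in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    callers = list(calls_by_caller)
    for ai, ca in enumerate(callers):
        for cb in callers[ai + 1:]:
            for i, x in enumerate(calls_by_caller[ca]):
                for j, y in enumerate(calls_by_caller[cb]):
                    if x.sample_id != y.sample_id:
                        continue
                    if overlap_fraction(x.interval, y.interval) >= threshold:
                        union(index[(ca, i)], index[(cb, j)])

    groups: dict[int, list[tuple[str, int]]] = {}
    for node, k in index.items():
        groups.setdefault(find(k), []).append(node)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


# ---------------------------------------------------------------------------
# plate-effect scan


@dataclass
class PlateEffectResult:
    """Per-plate exact-test results for one region, and the flag."""

    region: str
    per_plate: pd.DataFrame  # plate, n_plate, carriers_plate, n_rest, carriers_rest, p
    alpha: float
    flagged: bool

    @property
    def min_p(self) -> float:
        return float(self.per_plate["p"].min())


def plate_effect_scan(
    carrier_status: pd.DataFrame,
    plates: PlateAssignment,
    alpha: Optional[float] = None,
) -> list[PlateEffectResult]:
    """Scan regions for plate-restricted frequency artifacts.

    ``carrier_status`` is a boolean DataFrame, samples (index) x regions
    (columns). For every region and every plate, a two-sided Fisher exact
    test compares carriers/non-carriers on the plate against all other
    plates; a region is flagged when any plate's p-value falls below
    ``alpha`` (default 0.05 / number of plates — Bonferroni within region,
    since each region performs one test per plate).
    """
    plate_labels = plates.plates
    if len(plate_labels) < 2:
        raise ValueError("plate-effect scan needs >=2 plates")
    samples = list(carrier_status.index)
    unassigned = [s for s in samples if s not in plates.plate_of]
    if unassigned:
        raise ValueError(f"samples without a plate assignment: {unassigned[:5]}")
    plate_of = np.array([plates.plate_of[s] for s in samples])
    for p in plate_labels:
        if not np.any(plate_of == p):
            raise ValueError(f"plate {p!r} has no samples in the carrier table")
    if alpha is None:
        alpha = 0.05 / len(plate_labels)
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    results = []
    for region in carrier_status.columns:
        carrier = carrier_status[region].to_numpy(dtype=bool)
        rows = []
        for p in plate_labels:
            on = plate_of == p
            a = int(np.sum(carrier & on))
            b = int(np.sum(~carrier & on))
            c = int(np.sum(carrier & ~on))
            d = int(np.sum(~carrier & ~on))
            _, pval = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "plate": p,
                    "n_plate": a + b,
                    "carriers_plate": a,
                    "n_rest": c + d,
                    "carriers_rest": c,
                    "p": float(pval),
                }
            )
        df = pd.DataFrame(rows)
        results.append(
            PlateEffectResult(
                region=str(region),
                per_plate=df,
                alpha=alpha,
                flagged=bool((df["p"] < alpha).any()),
            )
        )
    return results
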