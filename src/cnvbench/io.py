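"""Readers and writers for call sets, truth sets, probe manifests, plate maps
and qPCR tables, plus call-set filtering.

Two coordinate dialects are supported and must be declared explicitly:

* ``"bed"`` — headerless BED3+ columns (chrom, start, end, sample, copy
  number, optional LOD), 0-based half-open, matching the internal convention.
* ``"tsv"`` — headered tab-separated table with 1-based inclusive
  coordinates, the convention of published CNV coordinate strings.

Auto-detecting the convention is deliberately not offered: a silent
off-by-one in CNV comparison shifts every overlap fraction and is the single
most damaging failure mode in this kind of benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .intervals import (
    DELETION,
    DUPLICATION,
    UNKNOWN,
    CNVCall,
    GenomicInterval,
    ProbeMap,
    ReferenceCNV,
)

logger = logging.getLogger(__name__)

DIALECTS = ("bed", "tsv")

#: truth-set state tokens accepted on input, lower-cased
STATE_SYNONYMS = {
    "deletion": DELETION, "del": DELETION, "loss": DELETION, "-1": DELETION,
    "0": DELETION, "1": DELETION,
    "duplication": DUPLICATION, "dup": DUPLICATION, "gain": DUPLICATION,
    "+1": DUPLICATION, "3": DUPLICATION, "4": DUPLICATION,
    "unknown": UNKNOWN, "na": UNKNOWN, ".": UNKNOWN, "cnv": UNKNOWN,
}


@dataclass
class CallSetTable:
    """An ordered collection of CNV calls with provenance.

    Exact duplicate records (same sample, caller, interval and copy number)
    are dropped at load time with a logged count; ``filter_history`` records
    every filter applied together with its input/output counts so that counts
    always reconcile.
    """

    calls: list[CNVCall]
    caller: str
    source_path: Optional[str] = None
    filter_history: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "sample_id": c.sample_id,
                "copy_number": c.copy_number,
                "lod": c.lod,
                "caller": c.caller,
                "state": c.state,
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "sample_id", "copy_number",
                     "lod", "caller", "state"],
        )


@dataclass(frozen=True)
class PlateAssignment:
    """Mapping sample id -> genotyping plate label; each sample on one plate."""

    plate_of: dict[str, str]

    @property
    def plates(self) -> list[str]:
        return sorted(set(self.plate_of.values()))

    def samples_on(self, plate: str) -> list[str]:
        return [s for s, p in self.plate_of.items() if p == plate]

    def __len__(self) -> int:
        return len(self.plate_of)


@dataclass(frozen=True)
class QPCRMeasurement:
    """One qPCR well: threshold cycles for target and endogenous control.

    The calibrator flag marks the sample assumed to carry two copies, the
    anchor of the relative-quantification (2^-ddCt) calculation.
    """

    sample_id: str
    assay: str
    ct_target: float
    ct_control: float
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("control", self.ct_control)):
            if not (ct > 0) or ct != ct or ct == float("inf"):
                raise ValueError(f"Ct ({name}) must be finite and > 0, got {ct}")


# ---------------------------------------------------------------------------
# call sets


def _dedupe(calls: list[CNVCall], context: str) -> list[CNVCall]:
    seen: set[tuple] = set()
    out = []
    for c in calls:
        key = (c.sample_id, c.caller, c.interval, c.copy_number)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    dropped = len(calls) - len(out)
    if dropped:
        logger.info("%s: dropped %d exact duplicate call(s)", context, dropped)
    return out


def read_callset(path, caller_label: str, dialect: str = "bed",
                 chrom_prefix: Optional[str] = None) -> CallSetTable:
    """Load a call set, converting coordinates to the internal 0-based
    half-open convention.

    ``chrom_prefix`` of ``"add"`` / ``"strip"`` normalises ``chr`` naming;
    any other chromosome label is kept verbatim.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    if dialect == "bed":
        try:
            df = pd.read_csv(
                path, sep=r"\s+", header=None, comment="#",
                names=["chrom", "start", "end", "sample_id", "copy_number", "lod"],
                dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(
                columns=["chrom", "start", "end", "sample_id", "copy_number", "lod"]
            )
        offset = 0
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "start", "end", "sample_id", "copy_number"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        if "lod" not in df.columns:
            df["lod"] = pd.NA
        offset = 1  # 1-based inclusive -> subtract 1 from start only

    calls: list[CNVCall] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1 + (dialect == "tsv")):
        try:
            chrom = _norm_chrom(str(row.chrom), chrom_prefix)
            lod = None if pd.isna(row.lod) else float(row.lod)
            calls.append(
                CNVCall(
                    interval=GenomicInterval(chrom, int(row.start) - offset, int(row.end)),
                    sample_id=str(row.sample_id),
                    copy_number=int(row.copy_number),
                    caller=caller_label,
                    lod=lod,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    calls = _dedupe(calls, str(path))
    return CallSetTable(calls=calls, caller=caller_label, source_path=str(path))


def write_callset(table: CallSetTable, path, dialect: str = "bed") -> None:
    """Write a call set in either dialect; inverse of :func:`read_callset`."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    df = table.to_dataframe().drop(columns=["caller", "state"])
    if dialect == "bed":
        df.to_csv(path, sep="\t", header=False, index=False, na_rep="")
    else:
        df = df.copy()
        df["start"] = df["start"] + 1
        df.to_csv(path, sep="\t", index=False, na_rep="")


def filter_by_lod(calls: CallSetTable, min_lod: float, strict: bool = False) -> CallSetTable:
    """Retain calls with LOD >= ``min_lod``.

    Calls lacking a LOD score pass by default (segmentation callers emit
    none); ``strict=True`` drops them instead. The filter is logged with
    reconciling input/output counts.
    """
    if min_lod < 0:
        raise ValueError(f"min_lod must be >= 0, got {min_lod}")
    kept, missing = [], 0
    for c in calls:
        if c.lod is None:
            missing += 1
            if not strict:
                kept.append(c)
        elif c.lod >= min_lod:
            kept.append(c)
    entry = (
        f"filter_by_lod(min_lod={min_lod}, strict={strict}): "
        f"in={len(calls)} out={len(kept)} removed={len(calls) - len(kept)} "
        f"missing_lod={missing}"
    )
    logger.info("%s", entry)
    return CallSetTable(
        calls=kept,
        caller=calls.caller,
        source_path=calls.source_path,
        filter_history=calls.filter_history + [entry],
    )


# ---------------------------------------------------------------------------
# auxiliary tables


def _norm_chrom(chrom: str, mode: Optional[str]) -> str:
    if mode == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    if mode == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def read_truthset(path, source: str, chrom_prefix: Optional[str] = None) -> list[ReferenceCNV]:
    """Load a truth set (headered TSV, 1-based inclusive coordinates).

    Columns: chrom, start, end, sample_id, state. State tokens are mapped
    through a synonym table (loss/del/deletion -> deletion, gain/dup ->
    duplication, na/. -> unknown).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str})
    required = {"chrom", "start", "end", "sample_id", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    refs = []
    for row in df.itertuples(index=False):
        token = str(row.state).strip().lower()
        if token not in STATE_SYNONYMS:
            raise ValueError(f"{path}: unrecognised state token {row.state!r}")
        refs.append(
            ReferenceCNV(
                interval=GenomicInterval(
                    _norm_chrom(str(row.chrom), chrom_prefix),
                    int(row.start) - 1, int(row.end),
                ),
                sample_id=str(row.sample_id),
                state=STATE_SYNONYMS[token],
                source=source,
            )
        )
    return refs


def write_truthset(refs: Iterable[ReferenceCNV], path) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start + 1,
            "end": r.interval.end,
            "sample_id": r.sample_id,
            "state": r.state,
        }
        for r in refs
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "state"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_manifest(path, chrom_prefix: Optional[str] = None) -> ProbeMap:
    """Load a probe manifest (TSV: chrom, position, probe_id; 1-based positions).

    Positions are sorted on load; duplicate probe ids are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    required = {"chrom", "position", "probe_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].head(3).tolist()
        raise ValueError(f"{path}: duplicate probe id(s), e.g. {dupes}")
    df["chrom"] = df["chrom"].map(lambda c: _norm_chrom(str(c), chrom_prefix))
    positions = {
        chrom: (grp["position"].astype(int) - 1).tolist()
        for chrom, grp in df.groupby("chrom", sort=True)
    }
    ids = {
        chrom: grp["probe_id"].tolist() for chrom, grp in df.groupby("chrom", sort=True)
    }
    return ProbeMap(positions, ids)


def write_probe_manifest(probes: ProbeMap, path) -> None:
    rows = []
    for chrom in probes.chromosomes:
        for i, p in enumerate(probes.positions(chrom)):
            rows.append({"chrom": chrom, "position": int(p) + 1,
                         "probe_id": f"{chrom}_p{i}"})
    pd.DataFrame(rows, columns=["chrom", "position", "probe_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_plate_map(path) -> PlateAssignment:
    """Load a sample -> plate table (TSV: sample_id, plate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "plate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].head(3).tolist()
        raise ValueError(f"{path}: sample(s) assigned to more than one plate: {dupes}")
    return PlateAssignment(plate_of=dict(zip(df["sample_id"], df["plate"])))


def write_plate_map(plates: PlateAssignment, path) -> None:
    pd.DataFrame(
        sorted(plates.plate_of.items()), columns=["sample_id", "plate"]
    ).to_csv(path, sep="\t", index=False)


def read_qpcr(path) -> list[QPCRMeasurement]:
    """Load qPCR Ct measurements (CSV: sample_id, assay, ct_target,
    ct_control, is_calibrator).

    Every assay must include at least one calibrator row (the assumed
    two-copy sample); a file without one is rejected outright because no
    copy number can be anchored.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "assay": str})
    required = {"sample_id", "assay", "ct_target", "ct_control", "is_calibrator"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        flag = str(row.is_calibrator).strip().lower() in ("1", "true", "yes")
        out.append(
            QPCRMeasurement(
                sample_id=str(row.sample_id),
                assay=str(row.assay),
                ct_target=float(row.ct_target),
                ct_control=float(row.ct_control),
                is_calibrator=flag,
            )
        )
    by_assay: dict[str, bool] = {}
    for m in out:
        by_assay[m.assay] = by_assay.get(m.assay, False) or m.is_calibrator
    lacking = [a for a, has in by_assay.items() if not has]
    if lacking:
        raise ValueError(f"{path}: assay(s) without a calibrator sample: {sorted(lacking)}")
    return out


def write_qpcr(measurements: Iterable[QPCRMeasurement], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "assay": m.assay,
            "ct_target": m.ct_target,
            "ct_control": m.ct_control,
            "is_calibrator": m.is_calibrator,
        }
        for m in measurements
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "assay", "ct_target", "ct_control", "is_calibrator"],
    ).to_csv(path, index=False)
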