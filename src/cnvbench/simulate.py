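"""Synthetic truth sets, probe maps, caller outputs, plate structures and
qPCR tables.

The generator produces data with the statistical structure the benchmarking
analyses assume, so the whole pipeline can run with no external data:

* a truth frequency spectrum mixing singletons with common variants
  (Beta-distributed carrier frequency) — real reference CNV lists are
  dominated by rare events;
* caller sensitivity that depends on the number of probes a variant spans
  and is optionally penalised for duplications (a deletion is a 2-fold
  intensity change, a duplication only 1.5-fold, so duplications are harder);
* breakpoint jitter, deletion/duplication state confusion, per-sample false
  calls with log-normal LOD scores, and optional plate-restricted artifact
  calls;
* qPCR threshold-cycle tables generated by inverting the 2^-ddCt law with
  Gaussian cycle noise.

Everything is deterministic under a fixed seed; each stage draws from its
own child stream of the master seed so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .intervals import (
    DELETION,
    DUPLICATION,
    CNVCall,
    CNVRegion,
    GenomicInterval,
    ProbeMap,
    ReferenceCNV,
    count_probes,
)
from .io import CallSetTable, PlateAssignment, QPCRMeasurement
from .recovery import DEFAULT_PROBE_BINS

#: copy number assigned to simulated deletion / duplication calls
_CN_OF_STATE = {DELETION: 1, DUPLICATION: 3}


@dataclass(frozen=True)
class PlateArtifact:
    """Extra carrier probability injected for one region on one plate."""

    plate: str
    region_index: int
    added_carrier_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.added_carrier_prob <= 1.0):
            raise ValueError("added_carrier_prob must be in [0, 1]")


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one virtual CNV caller.

    ``sensitivity`` holds one detection probability per probe-count stratum
    (same strata as the recovery tables). ``jitter_sd`` is the Gaussian SD
    of breakpoint displacement in bp; ``state_flip_prob`` the chance an
    emitted call reports the wrong direction; ``false_call_rate`` the
    Poisson mean of spurious calls per sample; LOD scores are log-normal.
    ``dup_penalty`` multiplies sensitivity for duplications.
    """

    name: str
    sensitivity: tuple[float, ...] = (0.1, 0.4, 0.6, 0.7, 0.8)
    jitter_sd: float = 0.0
    state_flip_prob: float = 0.0
    false_call_rate: float = 0.0
    lod_log_mean: float = 2.5
    lod_log_sd: float = 0.6
    dup_penalty: float = 1.0
    plate_artifact: Optional[PlateArtifact] = None

    def __post_init__(self) -> None:
        if len(self.sensitivity) != len(DEFAULT_PROBE_BINS):
            raise ValueError(
                f"profile needs {len(DEFAULT_PROBE_BINS)} per-bin sensitivities, "
                f"got {len(self.sensitivity)}"
            )
        for s in self.sensitivity:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"sensitivity out of [0, 1]: {s}")
        if not (0.0 <= self.state_flip_prob <= 1.0):
            raise ValueError("state_flip_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.false_call_rate < 0:
            raise ValueError("false_call_rate must be >= 0")
        if not (0.0 <= self.dup_penalty <= 1.0):
            raise ValueError("dup_penalty must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a simulated benchmark.

    Defaults describe a small SNP-array cohort: one 30 Mb chromosome probed
    every ~1.5 kb (genome-wide array density), 200 non-overlapping CNV loci
    of 1-200 kb (log-uniform), a rare-variant-dominated spectrum (80%
    singletons, the remainder at Beta(1, 3) carrier frequency), 40%
    duplications, and a 96-sample cohort on 48-sample plates (two plates,
    the minimum with a defined plate contrast).
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000}
    )
    probe_spacing: float = 1500.0
    n_regions: int = 200
    size_bounds: tuple[int, int] = (1_000, 200_000)
    frac_singleton: float = 0.8
    common_freq_beta: tuple[float, float] = (1.0, 3.0)
    frac_duplication: float = 0.4
    cohort_size: int = 96
    plate_size: int = 48

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_singleton <= 1.0):
            raise ValueError("frac_singleton must be in [0, 1]")
        if not (0.0 <= self.frac_duplication <= 1.0):
            raise ValueError("frac_duplication must be in [0, 1]")
        if self.cohort_size < 1 or self.plate_size < 1:
            raise ValueError("cohort_size and plate_size must be positive")
        if self.size_bounds[0] < 1 or self.size_bounds[0] > self.size_bounds[1]:
            raise ValueError(f"invalid size bounds {self.size_bounds}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "size_bounds" in raw:
            raw["size_bounds"] = tuple(raw["size_bounds"])
        if "common_freq_beta" in raw:
            raw["common_freq_beta"] = tuple(raw["common_freq_beta"])
        return cls(**raw)


@dataclass
class TruthSet:
    """Output of :func:`simulate_truth`: the ground truth of one benchmark."""

    refs: list[ReferenceCNV]
    regions: list[CNVRegion]
    probes: ProbeMap
    samples: list[str]
    config: SimulationConfig

    def region_state(self, i: int) -> str:
        return self.regions[i].members[0].state

    def carrier_matrix(self) -> "pd.DataFrame":
        """Boolean samples x regions truth carrier table."""
        import pandas as pd

        mat = np.zeros((len(self.samples), len(self.regions)), dtype=bool)
        idx = {s: i for i, s in enumerate(self.samples)}
        for j, region in enumerate(self.regions):
            for s in region.carriers:
                mat[idx[s], j] = True
        return pd.DataFrame(
            mat, index=self.samples,
            columns=[f"region{j}" for j in range(len(self.regions))],
        )


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    # named child stream: stable across runs, independent across stages
    tag = int.from_bytes(stage.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


def simulate_plates(config: SimulationConfig) -> PlateAssignment:
    """Assign the cohort to consecutive fixed-size plates (last may be short)."""
    plate_of = {}
    for i in range(config.cohort_size):
        plate_of[f"S{i:04d}"] = f"P{i // config.plate_size + 1:02d}"
    return PlateAssignment(plate_of=plate_of)


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Generate truth regions, carriers and a probe map.

    Regions are non-overlapping: each chromosome is divided into equal
    slots, one region per slot, sized log-uniformly within the configured
    bounds (clipped to 80% of the slot) and placed uniformly inside it.
    Carrier frequency follows the configured singleton/common mixture; every
    region keeps at least one carrier. Region state (deletion/duplication)
    is shared by all carriers of the region.
    """
    rng = _stage_rng(config.seed, "truth")
    samples = [f"S{i:04d}" for i in range(config.cohort_size)]

    # spread regions over chromosomes proportional to length
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(config.n_regions * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths):
        if alloc.sum() >= config.n_regions:
            break
        alloc[i] += config.n_regions - alloc.sum()

    lo, hi = config.size_bounds
    refs: list[ReferenceCNV] = []
    regions: list[CNVRegion] = []
    probe_positions: dict[str, np.ndarray] = {}

    for ci, chrom in enumerate(chroms):
        L = config.chrom_lengths[chrom]
        n_probe = max(1, int(L / config.probe_spacing))
        probe_positions[chrom] = np.unique(rng.integers(0, L, size=n_probe))

        k = int(alloc[ci])
        if k == 0:
            continue
        slot = L // k
        if lo > int(slot * 0.8):
            raise ValueError(
                f"cannot fit {k} non-overlapping regions of >= {lo} bp on "
                f"{chrom} ({L} bp); reduce n_regions or region size"
            )
        for j in range(k):
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            size = int(min(max(size, lo), slot * 0.8))
            start = slot * j + int(rng.integers(0, slot - size))
            interval = GenomicInterval(chrom, start, start + size)

            if rng.random() < config.frac_singleton:
                carriers = [samples[int(rng.integers(0, len(samples)))]]
            else:
                freq = float(rng.beta(*config.common_freq_beta))
                mask = rng.random(len(samples)) < freq
                carriers = [s for s, m in zip(samples, mask) if m]
                if not carriers:
                    carriers = [samples[int(rng.integers(0, len(samples)))]]
            state = DUPLICATION if rng.random() < config.frac_duplication else DELETION
            members = tuple(
                ReferenceCNV(interval=interval, sample_id=s, state=state, source="truth")
                for s in sorted(carriers)
            )
            refs.extend(members)
            regions.append(
                CNVRegion(
                    interval=interval,
                    members=members,
                    carriers=frozenset(carriers),
                    frequency=len(set(carriers)) / config.cohort_size,
                )
            )

    probes = ProbeMap(probe_positions)
    return TruthSet(refs=refs, regions=regions, probes=probes,
                    samples=samples, config=config)


def _probe_bin_index(n: int) -> int:
    # 0-probe truth regions fall back to the single-probe stratum
    for b, (blo, bhi) in enumerate(DEFAULT_PROBE_BINS):
        if n >= blo and (bhi is None or n <= bhi):
            return b
    return 0


def simulate_caller(
    truth: TruthSet,
    profile: CallerProfile,
    seed: int,
    plates: Optional[PlateAssignment] = None,
) -> CallSetTable:
    """Emit one virtual caller's output over the truth set.

    Each truth carrier's CNV is detected with probability
    ``sensitivity[probe-count stratum]`` (times ``dup_penalty`` for
    duplications); detected intervals are jittered, their direction flipped
    with ``state_flip_prob``, and LOD scores sampled. A jittered call that
    collapses below 1 bp is dropped (counted as a miss). False calls are
    placed at random non-truth loci; a configured plate artifact adds
    spurious carrier calls of one region on one plate.
    """
    rng = _stage_rng(seed, f"caller:{profile.name}")
    calls: list[CNVCall] = []

    region_bin = [
        _probe_bin_index(count_probes(r.interval, truth.probes)) for r in truth.regions
    ]
    ref_region = {}
    for j, region in enumerate(truth.regions):
        for m in region.members:
            ref_region[(m.sample_id, m.interval)] = j

    chrom_len = dict(truth.config.chrom_lengths)

    def _emit(interval: GenomicInterval, sample: str, state: str) -> None:
        # jitter, flip, score
        if profile.jitter_sd > 0:
            start = int(round(interval.start + rng.normal(0, profile.jitter_sd)))
            end = int(round(interval.end + rng.normal(0, profile.jitter_sd)))
            start, end = min(start, end), max(start, end)
            start = max(0, start)
            end = min(chrom_len[interval.chrom], end)
            if end - start < 1:
                return
            interval = GenomicInterval(interval.chrom, start, end)
        if rng.random() < profile.state_flip_prob:
            state = DELETION if state == DUPLICATION else DUPLICATION
        calls.append(
            CNVCall(
                interval=interval,
                sample_id=sample,
                copy_number=_CN_OF_STATE[state],
                caller=profile.name,
                lod=float(rng.lognormal(profile.lod_log_mean, profile.lod_log_sd)),
            )
        )

    for ref in truth.refs:
        j = ref_region[(ref.sample_id, ref.interval)]
        p = profile.sensitivity[region_bin[j]]
        if ref.state == DUPLICATION:
            p *= profile.dup_penalty
        if rng.random() < p:
            _emit(ref.interval, ref.sample_id, ref.state)

    if profile.false_call_rate > 0:
        chroms = sorted(chrom_len)
        weights = np.array([chrom_len[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        lo, hi = truth.config.size_bounds
        truth_by_chrom: dict[str, list[GenomicInterval]] = {}
        for region in truth.regions:
            truth_by_chrom.setdefault(region.interval.chrom, []).append(region.interval)
        for sample in truth.samples:
            for _ in range(int(rng.poisson(profile.false_call_rate))):
                for _attempt in range(8):
                    chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                    size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                    size = min(size, chrom_len[chrom] - 1)
                    start = int(rng.integers(0, chrom_len[chrom] - size))
                    iv = GenomicInterval(chrom, start, start + size)
                    if not any(
                        iv.start < t.end and t.start < iv.end
                        for t in truth_by_chrom.get(chrom, ())
                    ):
                        state = DELETION if rng.random() < 0.5 else DUPLICATION
                        _emit(iv, sample, state)
                        break

    art = profile.plate_artifact
    if art is not None:
        if plates is None:
            raise ValueError(f"{profile.name}: plate artifact configured but no plates given")
        region = truth.regions[art.region_index]
        state = truth.region_state(art.region_index)
        for sample in plates.samples_on(art.plate):
            if sample in region.carriers:
                continue
            if rng.random() < art.added_carrier_prob:
                _emit(region.interval, sample, state)

    return CallSetTable(calls=calls, caller=profile.name,
                        source_path=f"<simulated:{profile.name}>")


def simulate_qpcr(
    true_cn: Mapping[tuple[str, str], float],
    noise_sd: float,
    seed: int,
    calibrator_id: str = "CAL",
) -> list[QPCRMeasurement]:
    """Generate Ct tables whose 2^-ddCt quantification returns the true CN.

    For each (sample, assay) pair with true copy number ``cn``, the target
    Ct is offset from the control by the calibrator baseline plus
    ``-log2(cn / 2)`` plus Gaussian cycle noise; the calibrator itself is a
    noise-free two-copy anchor. A true CN of 0 cannot give a finite Ct and
    is floored at 0.25 copies (amplification at the detection limit).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _stage_rng(seed, "qpcr")
    ct_control = 20.0
    baseline = 5.0  # calibrator dCt
    out: list[QPCRMeasurement] = []
    assays = sorted({assay for (_, assay) in true_cn})
    for assay in assays:
        out.append(
            QPCRMeasurement(
                sample_id=calibrator_id,
                assay=assay,
                ct_target=ct_control + baseline,
                ct_control=ct_control,
                is_calibrator=True,
            )
        )
    for (sample, assay), cn in sorted(true_cn.items()):
        cn_eff = max(float(cn), 0.25)
        ddct = -np.log2(cn_eff / 2.0)
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(
            QPCRMeasurement(
                sample_id=sample,
                assay=assay,
                ct_target=ct_control + baseline + ddct + noise,
                ct_control=ct_control,
                is_calibrator=False,
            )
        )
    return out


def carrier_matrix_from_calls(
    callsets: Mapping[str, CallSetTable] | CallSetTable,
    regions: Sequence[CNVRegion],
    samples: Sequence[str],
):
    """Boolean samples x regions table of called carrier status.

    A sample carries a region according to a caller when any of its
    non-diploid calls overlaps the region interval by >= 1 bp. With a
    mapping of callers a dict of tables is returned.
    """
    import pandas as pd

    if isinstance(callsets, CallSetTable):
        single = True
        callsets = {callsets.caller: callsets}
    else:
        single = False
    out = {}
    for caller, table in callsets.items():
        mat = np.zeros((len(samples), len(regions)), dtype=bool)
        idx = {s: i for i, s in enumerate(samples)}
        for c in table:
            if c.copy_number == 2 or c.sample_id not in idx:
                continue
            for j, region in enumerate(regions):
                iv = region.interval
                if (c.interval.chrom == iv.chrom
                        and c.interval.start < iv.end and iv.start < c.interval.end):
                    mat[idx[c.sample_id], j] = True
        out[caller] = pd.DataFrame(
            mat, index=list(samples),
            columns=[f"region{j}" for j in range(len(regions))],
        )
    return out[next(iter(out))] if single else out
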