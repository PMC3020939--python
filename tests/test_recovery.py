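"""Truth-set recovery: matching criteria, stratified tables, per-region rates."""

import numpy as np
import pytest

from cnvbench import (
    CNVCall,
    GenomicInterval,
    ProbeMap,
    ReferenceCNV,
    match_reference,
    merge_into_regions,
    per_region_sensitivity,
    recovery_by_frequency_bin,
    recovery_by_probe_bin,
)
from conftest import oracle_recovered, random_calls, random_refs


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def ref(start, end, sample="S1", state="deletion"):
    return ReferenceCNV(iv(start, end), sample, state, "T")


def call(start, end, cn=1, sample="S1", lod=10.0):
    return CNVCall(iv(start, end), sample, cn, "X", lod)


class TestMatchReference:
    def test_identical_deletion_recovered_under_both(self):
        (m,) = match_reference([ref(0, 1000)], [call(0, 1000, cn=1)])
        assert m.recovered_korn_only and m.recovered_with_consistency
        assert m.best_overlap == pytest.approx(1.0)

    def test_small_overlap_not_recovered(self):
        (m,) = match_reference([ref(0, 1000)], [call(900, 2000, cn=1)])
        assert m.best_overlap == pytest.approx(100 / 2000)
        assert not m.recovered_korn_only

    def test_wrong_direction_recovered_korn_only(self):
        # a duplication call over a deletion reference: detected but
        # mislabelled, so the consistency criterion removes it
        (m,) = match_reference([ref(0, 1000)], [call(500, 1400, cn=3)])
        assert m.best_overlap == pytest.approx(500 / 1400)
        assert m.recovered_korn_only
        assert not m.recovered_with_consistency

    def test_diploid_calls_never_match(self):
        (m,) = match_reference([ref(0, 1000)], [call(0, 1000, cn=2)])
        assert not m.recovered_korn_only

    def test_matching_is_within_sample(self):
        (m,) = match_reference([ref(0, 1000, sample="S1")],
                               [call(0, 1000, cn=1, sample="S2")])
        assert not m.recovered_korn_only

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            match_reference([], [], threshold=0.0)
        with pytest.raises(ValueError):
            match_reference([], [], threshold=1.5)

    def test_unknown_state_rejected_with_consistency(self):
        unknown = ReferenceCNV(iv(0, 100), "S1", "unknown", "T")
        with pytest.raises(ValueError, match="unknown"):
            match_reference([unknown], [], require_state=True)
        # evaluable with the plain criterion
        (m,) = match_reference([unknown], [call(0, 100, cn=1)], require_state=False)
        assert m.recovered

    def test_agrees_with_exhaustive_oracle(self, rng):
        """On small random sets the tree-accelerated matcher reproduces an
        all-pairs per-basepair comparison for both criteria."""
        for trial in range(20):
            refs = random_refs(rng, int(rng.integers(1, 50)))
            calls = random_calls(rng, int(rng.integers(0, 50)))
            thr = float(rng.choice([0.1, 0.25, 0.5]))
            matches = match_reference(refs, calls, threshold=thr)
            for m in matches:
                assert m.recovered_korn_only == oracle_recovered(
                    m.ref, calls, thr, require_state=False
                )
                assert m.recovered_with_consistency == oracle_recovered(
                    m.ref, calls, thr, require_state=True
                )

    def test_monotone_in_threshold_and_consistency(self, rng):
        refs = random_refs(rng, 120)
        calls = random_calls(rng, 120)
        rates = []
        for thr in (0.1, 0.25, 0.5, 0.9):
            matches = match_reference(refs, calls, threshold=thr)
            korn = np.mean([m.recovered_korn_only for m in matches])
            cons = np.mean([m.recovered_with_consistency for m in matches])
            assert cons <= korn  # consistency can only remove matches
            rates.append(korn)
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestRecoveryByProbeBin:
    probes = ProbeMap({"chr1": list(range(0, 10_000, 10))})  # 1 probe / 10 bp

    def match(self, refs, calls):
        return match_reference(refs, calls, require_state=True)

    def test_bins_partition_and_rates(self):
        # probe counts: 1, 4, 25 -> bins "1", "2-5", ">20"
        refs = [ref(0, 10), ref(100, 140), ref(1000, 1250)]
        calls = [call(1000, 1250, cn=1)]
        table = recovery_by_probe_bin(self.match(refs, calls), self.probes)
        t = table.table.set_index("bin")
        assert t.loc["1", "n_reference"] == 1 and t.loc["1", "n_recovered"] == 0
        assert t.loc["2-5", "n_reference"] == 1
        assert t.loc[">20", "n_recovered"] == 1
        assert t["n_reference"].sum() + table.n_excluded == len(refs)

    def test_zero_probe_reference_excluded(self):
        sparse = ProbeMap({"chr1": [5000]})
        table = recovery_by_probe_bin(self.match([ref(0, 100)], []), sparse)
        assert table.n_excluded == 1
        assert table.total_reference == 0

    def test_empty_bin_rate_is_nan(self):
        table = recovery_by_probe_bin(self.match([ref(0, 15)], []), self.probes)
        assert np.isnan(table.rate(">20"))

    def test_all_recovered_rates_one(self):
        refs = [ref(0, 55), ref(1000, 1300)]
        calls = [call(0, 55, cn=1), call(1000, 1300, cn=1)]
        table = recovery_by_probe_bin(self.match(refs, calls), self.probes)
        populated = table.table.dropna(subset=["rate"])
        assert (populated["rate"] == 1.0).all()

    def test_overlapping_user_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            recovery_by_probe_bin([], self.probes, bins=((1, 10), (10, 20)))


class TestRecoveryByFrequencyBin:
    def test_binning_by_region_frequency(self):
        # region A: 1/8 carriers (low bin); region B: 6/8 (0.6-0.8 bin)
        refs_a = [ref(0, 100, sample="S1")]
        refs_b = [ref(5000, 5100, sample=f"S{i}") for i in range(1, 7)]
        refs = refs_a + refs_b
        regions = merge_into_regions(refs, total_samples=8)
        calls = [call(0, 100, cn=1, sample="S1")]
        matches = match_reference(refs, calls)
        table = recovery_by_frequency_bin(matches, regions).table.set_index("bin")
        assert table.loc["0<a<=0.2", "n_reference"] == 1
        assert table.loc["0<a<=0.2", "rate"] == pytest.approx(1.0)
        assert table.loc["0.6<a<=0.8", "n_reference"] == 6
        assert table.loc["0.6<a<=0.8", "n_recovered"] == 0

    def test_uniform_sensitivity_uniform_rates(self, rng):
        """A caller detecting every reference with probability s gives bin
        rates within 3 binomial SDs of s in every populated bin."""
        s = 0.7
        samples = [f"S{i}" for i in range(40)]
        refs, calls = [], []
        pos = 0
        for region_i in range(80):
            n_car = int(rng.integers(1, 30))
            carriers = rng.choice(samples, size=n_car, replace=False)
            for smp in carriers:
                refs.append(ref(pos, pos + 100, sample=str(smp)))
                if rng.random() < s:
                    calls.append(call(pos, pos + 100, cn=1, sample=str(smp)))
            pos += 1000
        regions = merge_into_regions(refs, total_samples=len(samples))
        matches = match_reference(refs, calls)
        table = recovery_by_frequency_bin(matches, regions).table
        for _, row in table.iterrows():
            n = row["n_reference"]
            if n < 30:
                continue
            sd = np.sqrt(s * (1 - s) / n)
            assert abs(row["rate"] - s) < 3 * sd


class TestPerRegionSensitivity:
    def test_hand_counts(self):
        refs_a = [ref(0, 100, sample=f"S{i}") for i in range(2)]
        refs_b = [ref(5000, 5100, sample=f"S{i}") for i in range(8)]
        refs = refs_a + refs_b
        regions = merge_into_regions(refs, total_samples=8)
        calls = [call(0, 100, cn=1, sample=f"S{i}") for i in range(2)]
        calls += [call(5000, 5100, cn=1, sample=f"S{i}") for i in range(6)]
        matches = match_reference(refs, calls)
        result = per_region_sensitivity(matches, regions)
        sens = dict(zip(result.per_region["interval"], result.per_region["sensitivity"]))
        assert sens["chr1:1-100"] == pytest.approx(1.0)
        assert sens["chr1:5001-5100"] == pytest.approx(6 / 8)
        assert result.share_high == pytest.approx(0.5)  # one of two regions > 0.9

    def test_all_missed_goes_to_low_class(self):
        refs = [ref(i * 1000, i * 1000 + 100) for i in range(5)]
        regions = merge_into_regions(refs, total_samples=4)
        matches = match_reference(refs, [])
        result = per_region_sensitivity(matches, regions)
        assert result.share_low == pytest.approx(1.0)
        assert result.share_high == pytest.approx(0.0)
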