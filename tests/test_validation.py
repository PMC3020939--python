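"""qPCR quantification, accuracy metrics, common-CNV matching, plate scan."""

import numpy as np
import pandas as pd
import pytest

from cnvbench import (
    CNVCall,
    GenomicInterval,
    QPCRMeasurement,
    ValidationOutcome,
    classify_cn,
    ddct_copy_number,
    fp_fn_rates,
    match_common_cnv,
    plate_effect_scan,
    ppv,
)
from cnvbench.io import PlateAssignment


def qm(sample, ct_target, ct_control=20.0, assay="a1", cal=False):
    return QPCRMeasurement(sample, assay, ct_target, ct_control, cal)


class TestDdct:
    def estimates(self, rows):
        return {e.sample_id: e for e in ddct_copy_number(rows)}

    def test_calibrator_identity_and_doubling_law(self):
        rows = [qm("CAL", 25.0, cal=True), qm("S1", 25.0), qm("S2", 26.0)]
        est = self.estimates(rows)
        assert est["CAL"].copy_number == pytest.approx(2.0)
        assert est["S1"].copy_number == pytest.approx(2.0)
        # one extra cycle = half the template = one copy
        assert est["S2"].ddct == pytest.approx(1.0)
        assert est["S2"].copy_number == pytest.approx(1.0)

    def test_three_copies(self):
        rows = [qm("CAL", 25.0, cal=True), qm("S1", 25.0 - 0.5849625007211562)]
        est = self.estimates(rows)
        assert est["S1"].copy_number == pytest.approx(3.0, abs=1e-9)

    def test_replicates_averaged_before_differencing(self):
        rows = [qm("CAL", 25.0, cal=True),
                qm("S1", 25.5), qm("S1", 26.5)]  # mean dCt 6 -> ddct 1
        est = self.estimates(rows)
        assert est["S1"].copy_number == pytest.approx(1.0)

    def test_missing_calibrator_fatal(self):
        with pytest.raises(ValueError, match="no calibrator"):
            ddct_copy_number([qm("S1", 25.0)])

    def test_monotone_decreasing_and_exact_halving(self, rng):
        ddcts = np.sort(rng.uniform(-3, 3, 20))
        rows = [qm("CAL", 25.0, cal=True)] + [
            qm(f"S{i}", 25.0 + d) for i, d in enumerate(ddcts)
        ]
        by_sample = {e.sample_id: e.copy_number for e in ddct_copy_number(rows)}
        cns = [by_sample[f"S{i}"] for i in range(len(ddcts))]  # increasing ddct
        assert all(a >= b for a, b in zip(cns, cns[1:]))
        # doubling law to machine precision
        pair = [qm("CAL", 25.0, cal=True), qm("A", 25.7), qm("B", 26.7)]
        ea, eb = (e for e in ddct_copy_number(pair) if e.sample_id in "AB")
        assert eb.copy_number * 2 == pytest.approx(ea.copy_number, rel=1e-15)


class TestClassifyCn:
    @pytest.mark.parametrize(
        "cn,expect",
        [
            (2.0, "normal"),
            (1.0, "deletion"),
            (3.2, "duplication"),
            (1.5, "normal"),  # strict inequality at the boundary
            (2.5, "normal"),
            (4.0, "duplication"),
        ],
    )
    def test_default_thresholds(self, cn, expect):
        assert classify_cn(cn) == expect

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_cn(2.0, t_del=2.5, t_dup=1.5)


class TestAccuracyMetrics:
    def test_ppv_examples(self):
        confirmed_3_of_5 = ValidationOutcome("r", "p", tp=3, fp=2, tn=0, fn=0)
        assert ppv([confirmed_3_of_5]) == pytest.approx(0.60)
        none_confirmed = ValidationOutcome("r", "p", tp=0, fp=5, tn=0, fn=0)
        assert ppv([none_confirmed]) == 0.0
        all_confirmed = ValidationOutcome("r", "p", tp=5, fp=0, tn=0, fn=0)
        assert ppv([all_confirmed]) == 1.0

    def test_ppv_undefined_without_positives(self):
        assert np.isnan(ppv([ValidationOutcome("r", "p", 0, 0, 4, 0)]))

    def test_fp_fn_hand_count(self):
        # 10 qPCR-normal samples, 3 called variant; 8 qPCR-variant, 2 missed
        program = {f"N{i}": ("deletion" if i < 3 else "normal") for i in range(10)}
        program |= {f"V{i}": ("normal" if i < 2 else "deletion") for i in range(8)}
        truth = {f"N{i}": "normal" for i in range(10)}
        truth |= {f"V{i}": "deletion" for i in range(8)}
        out = fp_fn_rates(program, truth)
        assert out.fp_rate == pytest.approx(0.30)
        assert out.fn_rate == pytest.approx(0.25)
        assert out.n_tested == 18

    def test_perfect_and_degenerate_programs(self):
        truth = {"A": "deletion", "B": "normal", "C": "duplication"}
        out = fp_fn_rates(dict(truth), truth)
        assert out.fp_rate == 0.0 and out.fn_rate == 0.0
        all_variant = {s: "deletion" for s in truth}
        out2 = fp_fn_rates(all_variant, truth)
        assert out2.fp_rate == 1.0 and out2.fn_rate == 0.0

    def test_empty_truth_stratum_is_nan(self):
        out = fp_fn_rates({"A": "deletion"}, {"A": "deletion"})
        assert np.isnan(out.fp_rate) and out.fn_rate == 0.0

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="only one"):
            fp_fn_rates({"A": "normal"}, {"B": "normal"})

    def test_counts_against_random_confusion_oracle(self, rng):
        states = ["deletion", "normal", "duplication"]
        for _ in range(20):
            samples = [f"S{i}" for i in range(int(rng.integers(2, 40)))]
            prog = {s: str(rng.choice(states)) for s in samples}
            truth = {s: str(rng.choice(states)) for s in samples}
            out = fp_fn_rates(prog, truth)
            tp = sum(prog[s] != "normal" and truth[s] != "normal" for s in samples)
            fp = sum(prog[s] != "normal" and truth[s] == "normal" for s in samples)
            fn = sum(prog[s] == "normal" and truth[s] != "normal" for s in samples)
            tn = sum(prog[s] == "normal" and truth[s] == "normal" for s in samples)
            assert (out.tp, out.fp, out.fn, out.tn) == (tp, fp, fn, tn)
            assert out.n_tested == len(samples)


class TestMatchCommonCnv:
    def call(self, start, end, sample="S1", caller="X", cn=1):
        return CNVCall(GenomicInterval("chr1", start, end), sample, cn, caller, 10.0)

    def test_identical_calls_matched(self):
        groups = match_common_cnv({
            "A": [self.call(0, 100_000, caller="A")],
            "B": [self.call(0, 100_000, caller="B")],
        })
        assert groups == [[("A", 0), ("B", 0)]]

    def test_half_union_rule(self):
        # 40/160 = 0.25 < 0.5 -> unmatched; 75/125 = 0.6 >= 0.5 -> matched
        a = self.call(0, 100_000, caller="A")
        weak = self.call(60_000, 160_000, caller="B")
        strong = self.call(25_000, 125_000, caller="B")
        assert len(match_common_cnv({"A": [a], "B": [weak]})) == 2
        assert len(match_common_cnv({"A": [a], "B": [strong]})) == 1

    def test_transitive_closure(self):
        # A-B and B-C each pass 50%, so all three group even if A-C does not
        a = self.call(0, 100, caller="A")
        b = self.call(30, 130, caller="B")
        c = self.call(60, 160, caller="C")
        groups = match_common_cnv({"A": [a], "B": [b], "C": [c]})
        assert len(groups) == 1 and len(groups[0]) == 3


class TestPlateEffectScan:
    def scan(self, carrier, plate_of, alpha=None):
        return plate_effect_scan(carrier, PlateAssignment(plate_of=plate_of), alpha)

    def build(self, n_plates, per_plate, carriers_per_plate):
        samples, plate_of, flags = [], {}, []
        for p in range(n_plates):
            for i in range(per_plate):
                s = f"P{p}S{i}"
                samples.append(s)
                plate_of[s] = f"P{p}"
                flags.append(i < carriers_per_plate[p])
        carrier = pd.DataFrame({"region0": flags}, index=samples)
        return carrier, plate_of

    def test_uniform_frequency_not_flagged(self):
        carrier, plate_of = self.build(5, 48, [5] * 5)
        (res,) = self.scan(carrier, plate_of)
        assert not res.flagged
        assert (res.per_plate["p"] >= res.alpha).all()

    def test_gross_excess_flagged_with_hypergeometric_p(self):
        from scipy.stats import hypergeom

        carrier, plate_of = self.build(11, 48, [24] + [1] * 10)
        (res,) = self.scan(carrier, plate_of)
        assert res.flagged
        # one-sided hypergeometric tail bounds the two-sided exact p
        n_total, n_carrier, n_plate = 11 * 48, 34, 48
        tail = hypergeom.sf(23, n_total, n_carrier, n_plate)
        assert res.min_p <= 2 * tail + 1e-12
        assert res.min_p < 1e-12

    def test_default_alpha_is_bonferroni_per_plate(self):
        carrier, plate_of = self.build(4, 10, [2] * 4)
        (res,) = self.scan(carrier, plate_of)
        assert res.alpha == pytest.approx(0.05 / 4)

    def test_single_plate_rejected(self):
        carrier, plate_of = self.build(1, 10, [2])
        with pytest.raises(ValueError, match=">=2 plates"):
            self.scan(carrier, plate_of)

    def test_unassigned_sample_rejected(self):
        carrier, plate_of = self.build(2, 5, [1, 1])
        del plate_of["P0S0"]
        with pytest.raises(ValueError, match="without a plate"):
            self.scan(carrier, plate_of)
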