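"""Robustness diagnostics and the superenhancer caller."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from encoop.annotation import Enhancer
from encoop.diagnostics import (ContingencyTable, call_superenhancers,
                                class_overlap, dual_target_concordance,
                                elbow_cutoff, fisher_exact,
                                inflation_robustness, stitch_regions,
                                strongest_fraction)
from tests.conftest import make_activity


def hypergeom_p_greater(a, b, c, d):
    """Exhaustive fixed-margin oracle for the one-sided Fisher test."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = comb(n, c1)
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if x >= a:
            p += comb(r1, x) * comb(r2, c1 - x) / denom
    return p


class TestFisher:
    def test_perfect_association(self):
        _, p = fisher_exact(ContingencyTable(5, 0, 0, 5), "greater")
        assert p == pytest.approx(1 / comb(10, 5))     # 1/252

    def test_no_association(self):
        odds, p = fisher_exact(ContingencyTable(5, 5, 5, 5), "greater")
        assert odds == 1
        assert p > 0.5

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_matches_enumeration_oracle_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            assert p == pytest.approx(hypergeom_p_greater(a, b, c, d),
                                      rel=1e-9)


class TestClassOverlap:
    def test_identical_classifications(self):
        cls = pd.Series(["synergistic"] * 5 + ["additive"] * 5,
                        index=[f"g{i}" for i in range(10)])
        t, odds, p = class_overlap(cls, cls)
        assert (t.b, t.c) == (0, 0)
        assert p == pytest.approx(1 / comb(10, 5))

    def test_independent_labels_not_enriched(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(200)]
        a = pd.Series(rng.choice(["synergistic", "additive"], 200), index=idx)
        b = pd.Series(rng.choice(["synergistic", "additive"], 200), index=idx)
        _, _, p = class_overlap(a, b)
        assert p > 0.01

    def test_known_overlap_table(self):
        # 57 synergistic under A; 33 of them synergistic under B
        idx = [f"g{i}" for i in range(120)]
        a = pd.Series("additive", index=idx)
        b = pd.Series("additive", index=idx)
        a.iloc[:57] = "synergistic"
        b.iloc[:33] = "synergistic"
        b.iloc[57:62] = "synergistic"
        t, _, p = class_overlap(a, b)
        assert (t.a, t.b, t.c, t.d) == (33, 24, 5, 58)
        assert p < 1e-6

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            class_overlap(pd.Series(["x"], index=["a"]),
                          pd.Series(["x"], index=["b"]))


class TestStrongestFraction:
    def _setup(self, trajs):
        pairs = pd.DataFrame({"enhancer_id": list(trajs), "gene_id": "G"})
        return pairs, make_activity(dict(trajs, G=[1] * 7))

    def test_single_enhancer_is_one(self):
        pairs, act = self._setup({"E1": [1, 2, 3, 4, 5, 6, 7]})
        assert strongest_fraction("G", pairs, act) == 1.0

    def test_equal_trajectories_split_evenly(self):
        pairs, act = self._setup({"E1": [2] * 7, "E2": [2] * 7})
        assert strongest_fraction("G", pairs, act) == pytest.approx(0.5)

    def test_three_to_one_ratio(self):
        pairs, act = self._setup({"E1": [30 / 7] * 7, "E2": [10 / 7] * 7})
        assert strongest_fraction("G", pairs, act) == pytest.approx(0.75)

    def test_zero_activity_is_nan(self):
        pairs, act = self._setup({"E1": [0] * 7})
        assert np.isnan(strongest_fraction("G", pairs, act))


class TestConcordance:
    def test_all_concordant_binomial_tail(self):
        pairs = pd.DataFrame(
            [(f"E{i}", f"G{2 * i + j}") for i in range(20) for j in (0, 1)],
            columns=["enhancer_id", "gene_id"])
        classes = pd.Series("additive", index=[f"G{i}" for i in range(40)])
        n_dual, n_conc, p = dual_target_concordance(pairs, classes, null_p=0.5)
        assert (n_dual, n_conc) == (20, 20)
        assert p == pytest.approx(0.5 ** 20)

    def test_null_level_concordance_not_significant(self):
        rng = np.random.default_rng(1)
        pairs = pd.DataFrame(
            [(f"E{i}", f"G{2 * i + j}") for i in range(100) for j in (0, 1)],
            columns=["enhancer_id", "gene_id"])
        labels = rng.choice(["additive", "synergistic"], 200)
        classes = pd.Series(labels, index=[f"G{i}" for i in range(200)])
        _, _, p = dual_target_concordance(pairs, classes)
        assert p > 0.05

    def test_no_dual_targets_reports_counts_only(self):
        pairs = pd.DataFrame({"enhancer_id": ["E1"], "gene_id": ["G1"]})
        classes = pd.Series(["additive"], index=["G1"])
        assert dual_target_concordance(pairs, classes) == (0, 0, None)


class TestInflation:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(2)
        t = np.array([0, 12, 24, 30, 36, 72, 96.0])
        traj, pairs = {}, []
        for g in range(12):
            S = np.zeros(7)
            for e in range(2):
                a = 1 + 25 / (1 + np.exp(-(t - rng.uniform(20, 50)) / 10))
                traj[f"E{g}_{e}"] = a
                S += a
                pairs.append((f"E{g}_{e}", f"G{g}"))
            if g < 6:
                traj[f"G{g}"] = 2 * S + 1
            else:
                traj[f"G{g}"] = np.exp(3 * (S - S.min()) / np.ptp(S) + 1)
        enh_ids = [k for k in traj if k.startswith("E")]
        return (pd.DataFrame(pairs, columns=["enhancer_id", "gene_id"]),
                make_activity(traj), enh_ids)

    def test_identity_factor_keeps_everything(self, cohort):
        pairs, act, enh = cohort
        assert inflation_robustness(pairs, act, enh, factor=1.0, seed=0) == 1.0

    def test_doubling_preserves_synergistic_set(self, cohort):
        pairs, act, enh = cohort
        assert inflation_robustness(pairs, act, enh, factor=2.0, seed=0) == 1.0

    def test_invalid_factor(self, cohort):
        pairs, act, enh = cohort
        with pytest.raises(ValueError):
            inflation_robustness(pairs, act, enh, factor=0.0)


def peaks_df(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


ENH = [Enhancer("E1", "chr1", 0, 500), Enhancer("E2", "chr1", 5_200, 5_700),
       Enhancer("E3", "chr1", 40_000, 40_500)]


class TestStitch:
    def test_gap_4kb_stitches_into_one_region(self):
        peaks = peaks_df(("chr1", 0, 1000, 10.0), ("chr1", 5000, 6000, 30.0))
        out = stitch_regions(peaks, ENH)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 6000)
        assert out.loc[0, "signal"] == pytest.approx(40.0 / 2000)

    def test_peak_beyond_1kb_of_enhancers_excluded(self):
        peaks = peaks_df(("chr1", 20_000, 21_000, 99.0))   # >= 2 kb from all
        assert len(stitch_regions(peaks, ENH)) == 0

    def test_gap_13kb_stays_two_regions(self):
        peaks = peaks_df(("chr1", 0, 1000, 5.0), ("chr1", 39_500, 40_000, 7.0))
        out = stitch_regions(peaks, ENH)
        assert len(out) == 2

    def test_order_invariance_and_signal_conservation(self):
        rng = np.random.default_rng(3)
        rows = [("chr1", s, s + 400, float(rng.uniform(1, 9)))
                for s in range(0, 42_000, 700)]
        fwd = stitch_regions(peaks_df(*rows), ENH)
        rev = stitch_regions(peaks_df(*rows[::-1]), ENH)
        pd.testing.assert_frame_equal(fwd, rev)
        kept = peaks_df(*rows)
        widths = fwd["end"] - fwd["start"]
        # signal density x summed peak width conserves total kept peak signal
        total = (fwd["signal"] * [  # per-region sum of constituent widths
            400 * n for n in fwd["n_peaks"]]).sum()
        near = [r for r in rows if any(
            max(e.start - r[2], r[1] - e.end, 0) <= 1000 for e in ENH)]
        assert total == pytest.approx(sum(r[3] for r in near))


class TestElbow:
    def test_quadratic_signals_cut_at_25(self):
        cutoff, flags = elbow_cutoff([i ** 2 for i in range(11)])
        assert cutoff == 25
        assert flags.sum() == 5                     # signals 36..100

    def test_linear_ramp_flags_nothing(self):
        cutoff, flags = elbow_cutoff(list(range(10)))
        assert flags.sum() == 0

    def test_single_outlier_only_flagged(self):
        sig = [1.0] * 9 + [100.0]
        cutoff, flags = elbow_cutoff(sig)
        assert flags.sum() == 1 and flags[-1]

    def test_constant_signals_flag_nothing(self):
        _, flags = elbow_cutoff([3.0, 3.0, 3.0, 3.0])
        assert flags.sum() == 0

    def test_flagged_set_is_upward_closed_in_signal(self):
        rng = np.random.default_rng(5)
        sig = rng.exponential(5, 50)
        cutoff, flags = elbow_cutoff(sig)
        if flags.any():
            assert sig[flags].min() > sig[~flags].max() or not (~flags).any()

    def test_super_caller_end_to_end(self):
        rows = [("chr1", 100 * i, 100 * i + 50, float(i ** 2))
                for i in range(1, 8)]
        enh = [Enhancer(f"E{i}", "chr1", 100 * i, 100 * i + 50)
               for i in range(1, 8)]
        out = call_superenhancers(peaks_df(*rows), enh, stitch_dist=10)
        assert out["is_super"].sum() >= 1
        assert (out.loc[out["is_super"], "signal"] >
                out["cutoff_signal"].iloc[0]).all()
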