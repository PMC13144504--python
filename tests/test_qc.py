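"""The replicate QC filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonosim import (
    CloneProfile,
    CountMatrix,
    FilterConfig,
    drop_discordant_replicates,
    drop_low_depth_samples,
    drop_sporadic_barcodes,
    pool_and_normalize,
    reconstruct_whole_tumor,
    restrict_to_tumor_barcodes,
    run_filter_chain,
    zero_low_counts,
)
from clonosim.synth import make_sample_sheet

CFG = FilterConfig()


def matrix(data, groups=None, classes="tumor_piece", index=None):
    df = pd.DataFrame(data)
    if index is not None:
        df.index = index
    samples = list(df.columns)
    sheet = make_sample_sheet(
        samples,
        replicate_group=groups or samples,
        sample_class=classes,
    )
    return CountMatrix(df, sheet)


class TestZeroLowCounts:
    def test_boundary_at_threshold(self):
        m = matrix({"s1": [10, 11, 0, 200]})
        z = zero_low_counts(m, CFG)
        assert list(z.counts["s1"]) == [0, 11, 0, 200]

    def test_idempotent(self):
        m = matrix({"s1": [3, 10, 11, 50]})
        once = zero_low_counts(m, CFG)
        twice = zero_low_counts(once, CFG)
        assert once.counts.equals(twice.counts)

    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=30)
    )
    def test_never_increases_and_clears_at_most_threshold(self, values):
        m = matrix({"s1": values})
        z = zero_low_counts(m, CFG)
        assert (z.counts.values <= m.counts.values).all()
        kept = z.counts.values[z.counts.values > 0]
        assert (kept > CFG.low_count_zero_threshold).all()


class TestDepthFilter:
    def test_boundary_9999_dropped_10000_kept(self):
        m = matrix({"low": [9999], "ok": [10_000]})
        out, report = drop_low_depth_samples(m, CFG)
        assert list(out.counts.columns) == ["ok"]
        assert report.steps[0]["sample"] == "low"

    def test_all_pass_unchanged(self):
        m = matrix({"a": [20_000], "b": [50_000]})
        out, report = drop_low_depth_samples(m, CFG)
        assert out.counts.equals(m.counts) and not report.steps

    def test_empty_matrix(self):
        m = matrix({"a": []})
        out, report = drop_low_depth_samples(m, CFG)
        assert out.counts.empty


class TestReplicateConcordance:
    # constructed so Pearson r is exactly 0.6 (kept: the rule is strict)
    X = [4000, 8000, 12_000, 16_000]
    Y_AT_060 = [8000, 4000, 16_000, 12_000]
    Y_BELOW = [7400, 3400, 16_000, 11_400]  # r ~= 0.588

    def test_r_below_threshold_removed(self):
        m = matrix({"r1": self.X, "r2": self.Y_BELOW}, groups=["g", "g"])
        assert np.corrcoef(self.X, self.Y_BELOW)[0, 1] < 0.6
        out, report = drop_discordant_replicates(m, CFG)
        assert out.counts.columns.empty
        assert {s["sample"] for s in report.steps} == {"r1", "r2"}

    def test_r_at_threshold_kept(self):
        m = matrix({"r1": self.X, "r2": self.Y_AT_060}, groups=["g", "g"])
        out, _ = drop_discordant_replicates(m, CFG)
        assert list(out.counts.columns) == ["r1", "r2"]

    def test_identical_replicates_kept(self):
        m = matrix({"r1": [1, 5, 9], "r2": [1, 5, 9]}, groups=["g", "g"])
        out, _ = drop_discordant_replicates(m, CFG)
        assert len(out.counts.columns) == 2

    def test_cfdna_exempt_but_flagged(self):
        m = matrix(
            {"c1": [100, 0, 0], "c2": [0, 100, 0]},
            groups=["g", "g"],
            classes="cfDNA",
        )
        out, report = drop_discordant_replicates(m, CFG)
        assert len(out.counts.columns) == 2
        assert report.steps[0]["step"] == "replicate_concordance_exempt"

    def test_singleton_group_warned_and_kept(self):
        m = matrix({"only": [5, 6, 7]}, groups=["g"])
        with pytest.warns(UserWarning, match="single replicate"):
            out, _ = drop_discordant_replicates(m, CFG)
        assert list(out.counts.columns) == ["only"]

    def test_quintuplicate_mean_pairwise_rule(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 1000, size=20)
        cols = {f"r{i}": base + rng.integers(0, 20, size=20) for i in range(1, 5)}
        cols["bad"] = rng.permutation(base)  # scrambled: low r to all others
        m = matrix(cols, groups=["g"] * 5)
        out, report = drop_discordant_replicates(m, CFG)
        assert "bad" not in out.counts.columns
        assert set(out.counts.columns) == {"r1", "r2", "r3", "r4"}


class TestSporadicBarcodes:
    def test_one_of_two_replicates_discarded(self):
        m = matrix({"r1": [50, 40], "r2": [0, 45]}, groups=["g", "g"])
        out, report = drop_sporadic_barcodes(m, CFG)
        assert list(out.counts["r1"]) == [0, 40]
        assert report.steps[0]["barcodes_discarded"] == 1

    def test_two_of_five_kept(self):
        cols = {f"r{i}": [30 if i <= 2 else 0] for i in range(1, 6)}
        m = matrix(cols, groups=["g"] * 5)
        out, report = drop_sporadic_barcodes(m, CFG)
        assert out.counts.loc[0, "r1"] == 30 and not report.steps

    def test_present_everywhere_unchanged(self):
        m = matrix({"r1": [5, 6], "r2": [7, 8]}, groups=["g", "g"])
        out, _ = drop_sporadic_barcodes(m, CFG)
        assert out.counts.equals(m.counts)


class TestPoolAndNormalize:
    def test_pooling_sums_replicates(self):
        m = matrix({"r1": [5, 100], "r2": [7, 300]}, groups=["g", "g"], index=[7, 9])
        (profile,) = pool_and_normalize(m)
        assert profile.counts == {7: 12, 9: 400}
        assert profile.label == "g"

    def test_explicit_frequencies(self):
        m = matrix({"r1": [60, 40]}, groups=["g"], index=[1, 2])
        (profile,) = pool_and_normalize(m)
        assert profile.frequencies == {1: 0.6, 2: 0.4}

    def test_zero_total_group_yields_empty_profile(self):
        m = matrix({"r1": [0, 0]}, groups=["g"])
        (profile,) = pool_and_normalize(m)
        assert not profile


class TestReconstruction:
    def test_single_piece_identity(self):
        piece = CloneProfile("A", {1: 30, 2: 70})
        tumor = reconstruct_whole_tumor([piece])
        assert tumor.frequencies == piece.frequencies

    def test_two_piece_sum(self):
        a = CloneProfile("A", {1: 100})
        b = CloneProfile("B", {1: 100, 2: 200})
        tumor = reconstruct_whole_tumor([a, b])
        assert tumor.frequencies == {1: 0.5, 2: 0.5}
        assert abs(sum(tumor.frequencies.values()) - 1) < 1e-9

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_whole_tumor([])


class TestRestrictToTumor:
    def test_subset_sample_unchanged(self):
        tumor = CloneProfile("t", {1: 5, 2: 5})
        sample = CloneProfile("s", {1: 3})
        (out,) = restrict_to_tumor_barcodes([sample], tumor)
        assert out.frequencies == {1: 1.0}

    def test_foreign_barcode_removed_and_renormalized(self):
        tumor = CloneProfile("t", {1: 5, 2: 5})
        sample = CloneProfile("s", {1: 30, 99: 10})
        (out,) = restrict_to_tumor_barcodes([sample], tumor)
        assert out.frequencies == {1: 1.0}
        assert out.meta["mass_outside_tumor"] == 10

    def test_empty_tumor_empties_samples_with_warning(self):
        tumor = CloneProfile("t", {})
        sample = CloneProfile("s", {1: 3})
        with pytest.warns(UserWarning):
            (out,) = restrict_to_tumor_barcodes([sample], tumor)
        assert not out


class TestFullChain:
    def build(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3000, size=40)
        cols = {
            "t_r1": base + rng.integers(0, 50, size=40),
            "t_r2": base + rng.integers(0, 50, size=40),
            "shallow_r1": rng.integers(0, 40, size=40),  # low depth
        }
        return matrix(cols, groups=["t", "t", "shallow"])

    def test_chain_is_idempotent_on_its_output(self):
        m = self.build()
        once, _ = run_filter_chain(m, CFG)
        twice, _ = run_filter_chain(once, CFG)
        assert once.counts.equals(twice.counts)

    def test_no_step_increases_counts_and_mass_accounts(self):
        m = self.build()
        out, report = run_filter_chain(m, CFG)
        shared = [c for c in out.counts.columns]
        assert (out.counts[shared].values <= m.counts[shared].values).all()
        accounting = report.steps[-1]
        assert (
            accounting["input_reads"]
            == accounting["output_reads"] + report.total_mass_removed
        )

    def test_order_is_logged(self):
        _, report = run_filter_chain(self.build(), CFG)
        steps = [s["step"] for s in report.steps]
        assert steps[0] == "zero_low_counts"
        assert steps[-1] == "mass_accounting"
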