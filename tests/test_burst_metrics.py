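import math

import numpy as np
import pandas as pd
import pytest

from meaburst import (
    BurstRecord,
    BurstTable,
    TimeWindow,
    compare_with_reference,
    filter_window,
    mean_burst_isi,
    parse_electrode_id,
    summarize_electrode,
    summarize_table,
    summarize_well,
)
from meaburst.datasets import SINGLE_BURST_ELECTRODES, load_b6_baseline_reference
from meaburst.errors import ValidationError

E11 = parse_electrode_id("B6_11")


class TestTimeWindow:
    def test_half_open_membership(self):
        w = TimeWindow("w", 120.0, 240.0)
        assert w.contains(120.0) and not w.contains(240.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValidationError):
            TimeWindow("w", 10.0, 10.0)


class TestFilterWindow:
    def test_boundary_inclusion(self, layout):
        recs = (
            BurstRecord(E11, 120.0, 5, 0.05),
            BurstRecord(E11, 240.0, 5, 0.05),
        )
        table = BurstTable(recs, layout=layout)
        kept = filter_window(table, TimeWindow("w", 120.0, 240.0))
        assert [r.start_time_s for r in kept] == [120.0]

    def test_partition_conserves_counts(self, rng, layout):
        """Counts over consecutive windows covering [0, T) sum to the total."""
        starts = rng.uniform(0, 600, size=400)
        recs = tuple(BurstRecord(E11, float(t), 5, 0.01) for t in set(starts))
        table = BurstTable(recs, layout=layout)
        edges = np.sort(np.concatenate([[0, 600], rng.uniform(0, 600, size=7)]))
        windows = [
            TimeWindow(f"w{i}", float(a), float(b))
            for i, (a, b) in enumerate(zip(edges, edges[1:]))
        ]
        per_window = sum(len(filter_window(table, w)) for w in windows)
        assert per_window == len(table)


class TestMeanBurstISI:
    @pytest.mark.parametrize(
        "duration,size,expected",
        [
            (0.09216, 17, 0.00576),
            (0.08424, 22, 0.004011429),
            (0.08328, 22, 0.003965714),
            (0.11192, 24, 0.004866087),
            (0.1028, 19, 0.005711111),
        ],
    )
    def test_single_burst_worked_examples(self, duration, size, expected):
        # duration / (size - 1), checked at the 9 printed decimals
        assert round(mean_burst_isi(duration, size), 9) == expected

    def test_two_spike_identity(self):
        assert mean_burst_isi(0.1, 2) == 0.1

    def test_single_spike_is_domain_error(self):
        with pytest.raises(ValidationError):
            mean_burst_isi(0.1, 1)


class TestSummarizeElectrode:
    def test_zero_bursts_gives_undefined_means(self, b6_like_table, two_windows):
        s = summarize_electrode(
            b6_like_table, parse_electrode_id("B6_44"), two_windows[0]
        )
        assert s.n_bursts == 0
        assert math.isnan(s.mean_duration_s)
        assert math.isnan(s.mean_spikes_per_burst)
        assert math.isnan(s.mean_burst_isi_s)

    def test_single_burst_electrode(self, layout):
        table = BurstTable(
            (BurstRecord(parse_electrode_id("B6_13"), 10.0, 17, 0.09216),),
            layout=layout,
        )
        s = summarize_electrode(
            table, parse_electrode_id("B6_13"), TimeWindow("w", 0, 597)
        )
        assert s.n_bursts == 1
        assert s.mean_duration_s == 0.09216
        assert s.mean_spikes_per_burst == 17
        assert s.mean_burst_isi_s == 0.00576

    def test_means_match_direct_arithmetic(self, rng, layout):
        durs = rng.uniform(0.05, 0.2, size=50)
        sizes = rng.integers(5, 40, size=50)
        recs = tuple(
            BurstRecord(E11, float(i), int(n), float(d))
            for i, (d, n) in enumerate(zip(durs, sizes))
        )
        table = BurstTable(recs, layout=layout)
        s = summarize_electrode(table, E11, TimeWindow("w", 0, 100))
        assert s.n_bursts == 50
        assert s.mean_duration_s == pytest.approx(durs.mean(), abs=1e-15)
        assert s.mean_spikes_per_burst == pytest.approx(sizes.mean(), abs=1e-12)
        assert s.mean_burst_isi_s == pytest.approx(
            np.mean(durs / (sizes - 1)), abs=1e-15
        )

    def test_per_burst_mean_not_ratio_of_means(self, layout):
        """Heterogeneous bursts: mean of duration/(size-1) differs from
        mean_duration/(mean_size-1) — the same discrepancy pattern the
        B6_12 reference row exhibits (0.1212651/10.2 != 0.012609743)."""
        recs = (
            BurstRecord(E11, 0.0, 5, 0.2),
            BurstRecord(E11, 1.0, 41, 0.08),
        )
        table = BurstTable(recs, layout=layout)
        s = summarize_electrode(table, E11, TimeWindow("w", 0, 10))
        per_burst = (0.2 / 4 + 0.08 / 40) / 2
        ratio = s.mean_duration_s / (s.mean_spikes_per_burst - 1)
        assert s.mean_burst_isi_s == per_burst
        assert abs(per_burst - ratio) > 1e-3

    def test_scale_equivariance(self, b6_like_table, two_windows):
        c = 3.5
        scaled = BurstTable(
            tuple(
                BurstRecord(r.electrode, r.start_time_s, r.size_spikes, r.duration_s * c)
                for r in b6_like_table.records
            ),
            layout=b6_like_table.layout,
        )
        a = summarize_electrode(b6_like_table, E11, two_windows[0])
        b = summarize_electrode(scaled, E11, two_windows[0])
        assert b.n_bursts == a.n_bursts
        assert b.mean_spikes_per_burst == a.mean_spikes_per_burst
        assert b.mean_duration_s == pytest.approx(c * a.mean_duration_s, rel=1e-12)
        assert b.mean_burst_isi_s == pytest.approx(c * a.mean_burst_isi_s, rel=1e-12)


class TestSummarizeWell:
    def test_uniform_counts_have_zero_sem(self, layout):
        recs = tuple(
            BurstRecord(e, 1.0, 5, 0.05) for e in layout.electrodes("B6")
        )
        table = BurstTable(recs, layout=layout)
        s = summarize_well(table, "B6", TimeWindow("w", 0, 10))
        assert s.mean_n_bursts == 1.0 and s.sem_n_bursts == 0.0
        assert s.n_electrodes_active == 16

    def test_sem_worked_example(self, layout):
        # electrode-level counts {1, 2, 3} -> SEM = sd / sqrt(3) = 0.5774
        recs = []
        for i, tok in enumerate(["B6_11", "B6_12", "B6_13"], start=1):
            e = parse_electrode_id(tok)
            recs += [BurstRecord(e, float(j), 5, 0.05) for j in range(i)]
        table = BurstTable(tuple(recs), layout=layout)
        s = summarize_well(table, "B6", TimeWindow("w", 0, 10), count_policy="active_only")
        assert round(s.sem_n_bursts, 4) == 0.5774

    def test_inactive_electrodes_zero_in_counts_excluded_from_means(self, layout):
        e = parse_electrode_id("B6_11")
        table = BurstTable((BurstRecord(e, 1.0, 5, 0.08),), layout=layout)
        s = summarize_well(table, "B6", TimeWindow("w", 0, 10))
        assert s.n_electrodes_active == 1
        assert s.mean_n_bursts == pytest.approx(1 / 16)
        assert s.mean_duration_s == 0.08  # over the single active electrode
        assert s.sem_duration_s == 0.0

    def test_unknown_well_is_error(self, b6_like_table, two_windows):
        with pytest.raises(ValidationError):
            summarize_well(b6_like_table, "Z9", two_windows[0])

    def test_matches_brute_force_mean_sem(self, rng, layout):
        electrodes = layout.electrodes("C3")
        recs = []
        counts = {}
        for e in electrodes:
            k = int(rng.integers(0, 6))
            counts[str(e)] = k
            recs += [
                BurstRecord(e, float(rng.uniform(0, 10)), 5, float(rng.uniform(0.01, 0.2)))
                for _ in range(k)
            ]
        table = BurstTable(tuple(recs), layout=layout)
        s = summarize_well(table, "C3", TimeWindow("w", 0, 10))
        vals = np.array([counts[str(e)] for e in electrodes], float)
        assert s.mean_n_bursts == pytest.approx(vals.mean())
        assert s.sem_n_bursts == pytest.approx(vals.std(ddof=1) / np.sqrt(16))


class TestSummarizeTable:
    def test_tidy_shape_and_missing_values(self, b6_like_table, two_windows):
        df = summarize_table(b6_like_table, two_windows, level="electrode")
        assert len(df) == 16 * 2
        inactive = df[(df.electrode == "B6_44") & (df.window == "w1")]
        assert inactive.n_bursts.item() == 0
        assert inactive.mean_duration_s.isna().all()

    def test_well_level(self, b6_like_table, two_windows):
        df = summarize_table(b6_like_table, two_windows, level="well")
        assert list(df.well.unique()) == ["B6"]
        assert len(df) == 2


class TestCompareWithReference:
    def test_self_comparison_passes_at_any_tol(self, b6_like_table, two_windows):
        summaries = [
            summarize_electrode(b6_like_table, e, two_windows[0])
            for e in b6_like_table.electrodes()
        ]
        report = compare_with_reference(summaries, pd.DataFrame(
            {
                "electrode": [str(s.electrode) for s in summaries],
                "n_bursts": [s.n_bursts for s in summaries],
                "mean_duration_s": [s.mean_duration_s for s in summaries],
                "mean_spikes_per_burst": [s.mean_spikes_per_burst for s in summaries],
                "mean_burst_isi_s": [s.mean_burst_isi_s for s in summaries],
            }
        ), tol=0.0)
        assert report.passed

    def test_pair_within_tol(self):
        a = pd.DataFrame({"electrode": ["B6_13"], "mean_duration_s": [0.09216]})
        b = pd.DataFrame({"electrode": ["B6_13"], "mean_duration_s": [0.09224]})
        assert compare_with_reference(a, b, tol=1e-3).passed

    def test_pair_beyond_tol(self):
        a = pd.DataFrame({"electrode": ["B6_13"], "mean_duration_s": [0.09216]})
        b = pd.DataFrame({"electrode": ["B6_13"], "mean_duration_s": [0.094]})
        assert not compare_with_reference(a, b, tol=1e-3).passed

    def test_one_sided_electrodes_flagged_not_fatal(self):
        a = pd.DataFrame({"electrode": ["B6_11", "B6_12"], "n_bursts": [1, 2]})
        b = pd.DataFrame({"electrode": ["B6_11", "B6_13"], "n_bursts": [1, 9]})
        report = compare_with_reference(a, b)
        assert report.only_in_summaries == ("B6_12",)
        assert report.only_in_reference == ("B6_13",)
        assert report.passed  # only the shared electrode is compared

    def test_reference_well_cross_software_agreement(self):
        """The two independent pipelines agree to 3 decimals everywhere
        except the documented B6_23 spikes-per-burst cell."""
        mea = load_b6_baseline_reference("r_pipeline")
        axion = load_b6_baseline_reference("axion")
        report = compare_with_reference(mea, axion, tol=1e-3)
        assert [(m.electrode, m.parameter) for m in report.mismatches] == [
            ("B6_23", "mean_spikes_per_burst")
        ]

    def test_reference_single_burst_isi_consistency(self):
        """For single-burst electrodes the tabulated mean ISI equals
        duration / (size - 1) at the printed precision."""
        mea = load_b6_baseline_reference("r_pipeline").set_index("electrode")
        for tok in SINGLE_BURST_ELECTRODES:
            row = mea.loc[tok]
            assert row["n_bursts"] == 1
            got = mean_burst_isi(row["mean_duration_s"], int(row["mean_spikes_per_burst"]))
            assert round(got, 9) == row["mean_burst_isi_s"]
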