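import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from eqtm_kit import (
    DifferentialMethylation,
    FeatureMatrix,
    ProbeAnnotation,
    SampleInfo,
    bh_adjust,
    chromosome_table,
    compute_m_value,
    filter_probes,
    reconstruct_counts_from_densities,
    region_distribution,
    test_dmp,
    top_k_sites,
    window_summary,
)


def _samples(n_case, n_control):
    out = []
    for i in range(n_case + n_control):
        out.append(
            SampleInfo(
                f"S{i}", "case" if i < n_case else "control",
                30.0 + i, "female" if i % 2 else "male", f"b{i % 2 + 1}",
            )
        )
    return out


def _dmp_row(probe_id, delta_m, call, fdr=0.01):
    return {
        "probe_id": probe_id, "mean_case": delta_m, "mean_control": 0.0,
        "delta_m": delta_m, "t_stat": 0.0, "p_value": fdr, "fdr": fdr,
        "call": call,
    }


def _ann(probe_id, chrom="chr1", pos=0, region="body", snp=False, gene=None):
    return ProbeAnnotation(probe_id, chrom, pos, region, snp, gene)


class TestMValue:
    @pytest.mark.parametrize(
        "meth,unmeth,offset,expected",
        [
            (1000, 1000, 0, 0.0),
            (4000, 1000, 0, 2.0),
            (0, 1000, 1, math.log2(1 / 1001)),
        ],
    )
    def test_log_ratio(self, meth, unmeth, offset, expected):
        assert compute_m_value(meth, unmeth, offset) == pytest.approx(expected, abs=1e-10)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_m_value(0, 0, 0)
        with pytest.raises(ValueError):
            compute_m_value(0, 1000, 0)


class TestFilterProbes:
    def test_flagged_probes_removed(self):
        ann = [_ann("a"), _ann("b", snp=True), _ann("c")]
        assert filter_probes(ann) == {"a", "c"}

    def test_identity_when_none_flagged(self):
        ann = [_ann("a"), _ann("c", chrom="chrX")]
        assert filter_probes(ann) == {"a", "c"}


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_direct_step_up_and_dominates_input(self, p):
        """Cross-check against a direct evaluation of the step-up formula:
        q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            expected[order[rank]] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(np.diff(expected[order]) >= -1e-12)


class TestDifferentialMethylation:
    def test_constant_probe_is_not_significant(self):
        samples = _samples(3, 3)
        m = FeatureMatrix(
            ["p1"], [s.sample_id for s in samples],
            [[1.0] * 6], "m_value",
        )
        res = test_dmp(m, samples)
        row = res.iloc[0]
        assert row["t_stat"] == 0.0 and row["p_value"] == 1.0
        assert row["call"] == "not_significant"

    def test_welch_p_matches_textbook_oracle(self):
        """On a small instance, per-probe p-values must match an
        independently coded Welch test to 1e-10."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 8))
        samples = _samples(4, 4)
        m = FeatureMatrix(
            [f"p{i}" for i in range(20)],
            [s.sample_id for s in samples], values, "m_value",
        )
        res = test_dmp(m, samples)
        for i in range(20):
            a, b = values[i, :4], values[i, 4:]
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / 4 + vb / 4
            t = (a.mean() - b.mean()) / math.sqrt(se2)
            df = se2**2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
            p = 2 * stats.t.sf(abs(t), df)
            assert res["t_stat"][i] == pytest.approx(t, abs=1e-10)
            assert res["p_value"][i] == pytest.approx(p, abs=1e-10)

    def test_strict_delta_threshold_boundary(self):
        # group means differ by exactly -0.3: |dM| > 0.3 strictly fails
        samples = _samples(4, 4)
        jitter = np.array([-0.01, 0.01, -0.01, 0.01])
        case = -0.3 + jitter
        ctrl = 0.0 + jitter
        m = FeatureMatrix(
            ["p1"], [s.sample_id for s in samples],
            np.concatenate([case, ctrl])[None, :], "m_value",
        )
        res = test_dmp(m, samples)
        assert res["delta_m"][0] == pytest.approx(-0.3)
        assert res["p_value"][0] < 0.05
        assert res["call"][0] == "not_significant"

    def test_label_swap_antisymmetry(self, default_dataset):
        _, m, _, annotation, samples, _ = default_dataset
        kept = sorted(filter_probes(annotation))[:300]
        swapped = [
            SampleInfo(s.sample_id,
                       "control" if s.group == "case" else "case",
                       s.age, s.sex, s.batch)
            for s in samples
        ]
        res = test_dmp(m, samples, kept)
        res_sw = test_dmp(m, swapped, kept)
        np.testing.assert_allclose(res_sw["delta_m"], -res["delta_m"], atol=1e-12)
        np.testing.assert_allclose(res_sw["t_stat"], -res["t_stat"], atol=1e-10)
        np.testing.assert_allclose(res_sw["p_value"], res["p_value"], atol=1e-12)
        swap = {"hypo": "hyper", "hyper": "hypo", "not_significant": "not_significant"}
        assert list(res_sw["call"]) == [swap[c] for c in res["call"]]

    def test_power_on_planted_hypomethylation(self):
        """Planted dM = -0.8 against within-group noise sd 0.2 at 12 vs 12
        must be recalled as hypo for >= 90% of planted probes."""
        from eqtm_kit import SimConfig, generate_dataset

        recalls = []
        for seed in (4, 14):
            cfg = SimConfig(seed=seed, n_latent=0)
            m, _, annotation, samples, truth = generate_dataset(cfg)
            res = test_dmp(m, samples, filter_probes(annotation)).set_index("probe_id")
            hypo = [p for p, v in truth.dmp_probes.items() if v < 0]
            recalls.append((res.loc[hypo, "call"] == "hypo").mean())
        assert min(recalls) >= 0.90

    def test_every_probe_has_exactly_one_call(self, default_dataset):
        _, m, _, annotation, samples, _ = default_dataset
        res = test_dmp(m, samples, filter_probes(annotation))
        counts = res["call"].value_counts()
        assert set(res["call"]) <= {"hypo", "hyper", "not_significant"}
        assert counts.sum() == len(res)

    def test_group_too_small_rejected(self):
        samples = _samples(1, 3)
        m = FeatureMatrix(
            ["p1"], [s.sample_id for s in samples], [[1, 2, 3, 4.0]], "m_value"
        )
        with pytest.raises(ValueError, match="at least 2"):
            test_dmp(m, samples)

    def test_sklearn_param_interface(self):
        est = DifferentialMethylation(fdr_threshold=0.1)
        assert est.get_params()["fdr_threshold"] == 0.1
        est.set_params(delta_m_threshold=0.5)
        assert est.delta_m_threshold == 0.5


class TestWindows:
    LENGTHS = {"chr1": 20.0}

    def _run(self, calls, positions):
        dmps = pd.DataFrame(
            [_dmp_row(f"p{i}", -1.0 if c == "hypo" else 1.0, c)
             for i, c in enumerate(calls)]
        )
        ann = [_ann(f"p{i}", pos=p) for i, p in enumerate(positions)]
        return window_summary(dmps, ann, self.LENGTHS)

    def test_three_to_one_is_hypo_domain(self):
        win = self._run(["hypo"] * 3 + ["hyper"], [10, 20, 30, 40])
        assert win.iloc[0]["domain_call"] == "hypo_domain"

    def test_three_to_two_boundary_is_none(self):
        win = self._run(["hypo"] * 3 + ["hyper"] * 2, [10, 20, 30, 40, 50])
        assert win.iloc[0]["domain_call"] == "none"

    def test_empty_window_is_none(self):
        win = self._run(["hypo"], [10])
        assert list(win["domain_call"])[1] == "none"
        assert win.iloc[1][["n_hypo", "n_hyper"]].sum() == 0

    def test_zero_hyper_with_hypo_is_domain(self):
        win = self._run(["hypo"], [10])
        assert win.iloc[0]["domain_call"] == "hypo_domain"

    def test_windows_tile_half_open_from_zero(self):
        win = self._run(["hypo"], [10])
        assert list(win["start"]) == [0, 10_000_000]
        assert list(win["end"]) == [10_000_000, 20_000_000]

    def test_position_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            self._run(["hypo"], [25_000_000])

    def test_window_counts_conserve_chromosome_totals(self, default_dataset):
        cfg, m, _, annotation, samples, _ = default_dataset
        dmps = test_dmp(m, samples, filter_probes(annotation))
        win = window_summary(dmps, annotation, cfg.chrom_lengths_mb)
        tab = chromosome_table(dmps, annotation, cfg.chrom_lengths_mb)
        for col in ("n_hypo", "n_hyper"):
            by_chrom = win.groupby("chrom")[col].sum()
            for _, row in tab.iterrows():
                assert by_chrom[row["chrom"]] == row[col]


class TestChromosomeTable:
    def test_densities_and_ratio(self):
        dmps = pd.DataFrame(
            [_dmp_row(f"h{i}", 1.0, "hyper") for i in range(5)]
            + [_dmp_row(f"l{i}", -1.0, "hypo") for i in range(5)]
        )
        ann = [_ann(f"h{i}", pos=i) for i in range(5)] + [
            _ann(f"l{i}", pos=100 + i) for i in range(5)
        ]
        tab = chromosome_table(dmps, ann, {"chr1": 100.0})
        row = tab.iloc[0]
        assert row["hyper_per_mb"] == pytest.approx(0.05)
        assert row["hypo_hyper_ratio"] == pytest.approx(1.0)

    def test_zero_hyper_gives_undefined_sentinel(self):
        dmps = pd.DataFrame([_dmp_row(f"l{i}", -1.0, "hypo") for i in range(10)])
        ann = [_ann(f"l{i}", pos=i) for i in range(10)]
        tab = chromosome_table(dmps, ann, {"chr1": 100.0})
        assert math.isnan(tab.iloc[0]["hypo_hyper_ratio"])

    def test_total_density_additivity(self, default_dataset):
        cfg, m, _, annotation, samples, _ = default_dataset
        dmps = test_dmp(m, samples, filter_probes(annotation))
        tab = chromosome_table(dmps, annotation, cfg.chrom_lengths_mb)
        np.testing.assert_allclose(
            tab["total_per_mb"], tab["hyper_per_mb"] + tab["hypo_per_mb"]
        )

    def test_missing_length_rejected(self):
        dmps = pd.DataFrame([_dmp_row("p0", -1.0, "hypo")])
        with pytest.raises(ValueError, match="chr9"):
            chromosome_table(dmps, [_ann("p0", chrom="chr9")], {"chr1": 100.0})


class TestReconstruct:
    def test_symmetric_case(self):
        assert reconstruct_counts_from_densities(100, 0.05, 0.05) == (5, 5, 1.0)

    def test_zero_hyper_sentinel(self):
        n_hyper, n_hypo, ratio = reconstruct_counts_from_densities(100, 0.0, 0.1)
        assert (n_hyper, n_hypo) == (0, 10)
        assert math.isnan(ratio)


class TestRegionDistribution:
    def test_all_promoter(self):
        dmps = pd.DataFrame([_dmp_row("p0", -1.0, "hypo")])
        dist = region_distribution(dmps, [_ann("p0", region="promoter")])
        assert dist == {"promoter_region": 1.0, "other": 0.0}

    def test_half_and_half(self):
        dmps = pd.DataFrame(
            [_dmp_row("p0", -1.0, "hypo"), _dmp_row("p1", -1.0, "hypo")]
        )
        ann = [_ann("p0", region="utr5"), _ann("p1", region="body")]
        dist = region_distribution(dmps, ann)
        assert dist["promoter_region"] == pytest.approx(0.5)

    def test_no_calls_warns_empty(self):
        dmps = pd.DataFrame([_dmp_row("p0", 0.0, "not_significant")])
        with pytest.warns(UserWarning):
            assert region_distribution(dmps, [_ann("p0")]) == {}

    def test_fraction_recovers_annotation_composition(self):
        """Calls independent of region: promoter fraction must fall in the
        99% binomial interval around the planted 40%."""
        rng = np.random.default_rng(3)
        n = 2000
        regions = rng.choice(["promoter", "body"], size=n, p=[0.4, 0.6])
        dmps = pd.DataFrame([_dmp_row(f"p{i}", -1.0, "hypo") for i in range(n)])
        ann = [_ann(f"p{i}", pos=i, region=r) for i, r in enumerate(regions)]
        frac = region_distribution(dmps, ann)["promoter_region"]
        lo, hi = stats.binom.interval(0.99, n, 0.4)
        assert lo / n <= frac <= hi / n


class TestTopK:
    def test_returns_all_when_fewer_than_k(self):
        dmps = pd.DataFrame(
            [_dmp_row(f"p{i}", -1.0, "hypo", fdr=0.01 * (i + 1)) for i in range(100)]
        )
        assert len(top_k_sites(dmps, k=500)) == 100

    def test_tie_broken_by_effect_size_then_id(self):
        dmps = pd.DataFrame(
            [
                _dmp_row("pA", -0.5, "hypo", fdr=0.01),
                _dmp_row("pB", -0.9, "hypo", fdr=0.01),
                _dmp_row("pC", -0.5, "hypo", fdr=0.01),
            ]
        )
        assert top_k_sites(dmps, k=3) == ["pB", "pA", "pC"]

    def test_k_one_returns_smallest_fdr(self):
        dmps = pd.DataFrame(
            [
                _dmp_row("pA", -0.5, "hypo", fdr=0.04),
                _dmp_row("pB", -0.9, "hypo", fdr=0.001),
            ]
        )
        assert top_k_sites(dmps, k=1) == ["pB"]
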