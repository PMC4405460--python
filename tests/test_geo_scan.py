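import numpy as np
import pytest

import steppescan as ss
from steppescan.errors import ConfigError
from conftest import make_scan_config


def matrix_from_values(vals, n):
    vals = np.asarray(vals, float)
    vals = (vals + vals.T) / 2  # symmetrize hand-set values
    ids = [f"P{i}" for i in range(vals.shape[0])]
    return ss.SharingMatrix(ids, [ss.LengthBin(1, 2)], vals[:, :, None], n), ids


class TestSharingVector:
    def test_single_population_is_matrix_row(self):
        S, ids = matrix_from_values(np.arange(16).reshape(4, 4), [3, 3, 3, 3])
        v = ss.sharing_vector(S, "P0", ["P1", "P2", "P3"], ss.LengthBin(1, 2))
        np.testing.assert_allclose(v, S.values[0, 1:, 0])

    def test_singleton_set_equals_single(self):
        S, ids = matrix_from_values(np.arange(16).reshape(4, 4), [3, 4, 5, 6])
        refs = ["P1", "P2"]
        v1 = ss.sharing_vector(S, "P0", refs, ss.LengthBin(1, 2))
        v2 = ss.sharing_vector(S, ["P0"], refs, ss.LengthBin(1, 2))
        np.testing.assert_allclose(v1, v2)

    def test_reference_order_contract(self):
        S, ids = matrix_from_values(np.arange(16).reshape(4, 4), [3, 3, 3, 3])
        v = ss.sharing_vector(S, "P0", ["P3", "P1"], ss.LengthBin(1, 2))
        w = ss.sharing_vector(S, "P0", ["P1", "P3"], ss.LengthBin(1, 2))
        np.testing.assert_allclose(v, w[::-1])

    def test_pooled_matches_direct_segment_pooling(self):
        """Pooling two neighbor populations through the matrix algebra equals
        recomputing the statistic with their individuals merged."""
        rng = np.random.default_rng(3)
        pops = ss.PopulationTable.from_records(
            [("A", 50, 40, "x"), ("B", 50, 41, "x"), ("C", 50, 42, "x")]
        )
        sizes = {"A": 4, "B": 6, "C": 5}
        cfg = ss.SharingSimConfig(pops, sizes, baseline_rate_cM=3.0,
                                  decay_scale_km=5000.0,
                                  bins=[ss.LengthBin(1, 2)], seed=8)
        segs, _ = ss.simulate_sharing_network(cfg)
        S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
        pooled = ss.sharing_vector(S, ["A", "B"], ["C"], cfg.bins[0])[0]
        # direct: merge A and B into one super-population and recompute
        merged_map = {s: ("AB" if p in ("A", "B") else p)
                      for s, p in cfg.sample_map().items()}
        mpops = ss.PopulationTable.from_records(
            [("AB", 50, 40.5, "x"), ("C", 50, 42, "x")]
        )
        msegs = ss.IBDSegmentTable.from_frame(
            segs.frame.assign(
                population_a=segs.frame["sample_a"].map(merged_map),
                population_b=segs.frame["sample_b"].map(merged_map),
            )
        )
        MS = ss.sharing_matrix(msegs, mpops, cfg.bins, {"AB": 10, "C": 5})
        assert pooled == pytest.approx(MS.value("AB", "C", cfg.bins[0]), rel=1e-12)

    def test_empty_references_rejected(self):
        S, _ = matrix_from_values(np.arange(16).reshape(4, 4), [3, 3, 3, 3])
        with pytest.raises(ConfigError, match="empty reference"):
            ss.sharing_vector(S, "P0", [], ss.LengthBin(1, 2))


class TestFlagQuantile:
    def test_type7_quantile_example(self):
        threshold, flagged = ss.flag_quantile(np.arange(10.0), 0.90)
        assert threshold == pytest.approx(8.1)
        assert flagged.tolist() == [9]

    def test_ties_do_not_flag(self):
        threshold, flagged = ss.flag_quantile(np.full(8, 3.0), 0.90)
        assert flagged.size == 0

    def test_q_one_flags_nothing(self):
        _, flagged = ss.flag_quantile(np.arange(10.0), 1.0)
        assert flagged.size == 0

    def test_too_few_values(self):
        with pytest.raises(ConfigError):
            ss.flag_quantile(np.arange(4.0), 0.9)


class TestSubtractAccumulate:
    def hand_fixture(self):
        # 3 focal (P0..P2) with singleton neighbor sets (P3..P5) and
        # 5 references (P6..P10); hand-set sharing values
        rng = np.random.default_rng(42)
        P = 11
        vals = rng.uniform(0.5, 3.0, size=(P, P))
        S, ids = matrix_from_values(vals, [4] * P)
        config = ss.ScanConfig(
            focal_ids=["P0", "P1", "P2"],
            neighbor_sets={"P0": ["P3"], "P1": ["P4"], "P2": ["P5"]},
            reference_ids=[f"P{k}" for k in range(6, 11)],
            bin=ss.LengthBin(1, 2),
        )
        return S, config

    def test_arithmetic_oracle(self):
        S, config = self.hand_fixture()
        res = ss.subtract_accumulate(S, config)
        # independent loop-based accumulation over the same hand-set values
        pairs = {"P0": "P3", "P1": "P4", "P2": "P5"}
        for k, ref in enumerate(res.reference_ids):
            expected = sum(
                S.value(f, ref, config.bin) - S.value(n, ref, config.bin)
                for f, n in pairs.items()
            )
            assert res.accumulated[k] == pytest.approx(expected, rel=1e-12)

    def test_per_focal_rows_sum_to_accumulated(self):
        S, config = self.hand_fixture()
        res = ss.subtract_accumulate(S, config)
        np.testing.assert_allclose(
            res.per_focal.to_numpy().sum(axis=0), res.accumulated
        )

    def test_flagging_is_strict_quantile_exceedance(self):
        S, config = self.hand_fixture()
        res = ss.subtract_accumulate(S, config)
        for k, ref in enumerate(res.reference_ids):
            assert (ref in res.flagged) == (res.accumulated[k] > res.threshold)

    def test_translation_invariance(self):
        S, config = self.hand_fixture()
        res = ss.subtract_accumulate(S, config)
        shifted = ss.SharingMatrix(S.pop_ids, S.bins, S.values + 1.7, S.n)
        res2 = ss.subtract_accumulate(shifted, config)
        np.testing.assert_allclose(res.accumulated, res2.accumulated, atol=1e-9)

    def test_focal_removed_from_other_neighbor_sets(self):
        S, config = self.hand_fixture()
        config.neighbor_sets["P0"] = ["P3", "P1"]  # P1 is focal
        cleaned = config.cleaned_neighbor_sets()
        assert cleaned["P0"] == ["P3"]

    def test_short_reference_list_rejected(self):
        S, config = self.hand_fixture()
        config.reference_ids = ["P6", "P7", "P8", "P9"]
        with pytest.raises(ConfigError, match="quantile"):
            ss.subtract_accumulate(S, config)


class TestInjectedSourceRecovery:
    def test_source_flagged_with_expected_accumulation(self, scan_study):
        pops, sizes, neighbor_sets = scan_study
        cfg = make_scan_config(pops, sizes, seed=1, delta=2.0)
        segs, _ = ss.simulate_sharing_network(cfg)
        S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
        scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(12)],
                             neighbor_sets=neighbor_sets, bin=cfg.bins[0])
        res = ss.subtract_accumulate(S, scan)
        assert "SRC" in res.flagged
        a_src = res.accumulated[res.reference_ids.index("SRC")]
        assert a_src == pytest.approx(12 * 2.0, rel=0.25)

    def test_null_replicates_flag_source_rarely(self, scan_study):
        pops, sizes, neighbor_sets = scan_study
        cfg = make_scan_config(pops, sizes, seed=1, delta=2.0)
        segs, _ = ss.simulate_sharing_network(cfg)
        S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
        scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(12)],
                             neighbor_sets=neighbor_sets, bin=cfg.bins[0],
                             n_null_replicates=20, seed=5)
        reps = ss.null_scan_replicates(S, scan)
        assert len(reps) == 20
        freq = ss.flag_frequency(reps)
        assert freq.get("SRC", 0.0) < 0.30

    def test_null_replicates_deterministic(self, scan_study):
        pops, sizes, neighbor_sets = scan_study
        cfg = make_scan_config(pops, sizes, seed=2, delta=0.0)
        segs, _ = ss.simulate_sharing_network(cfg)
        S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
        scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(12)],
                             neighbor_sets=neighbor_sets, bin=cfg.bins[0],
                             n_null_replicates=5, seed=11)
        r1 = ss.null_scan_replicates(S, scan)
        r2 = ss.null_scan_replicates(S, scan)
        for a, b in zip(r1, r2):
            assert a.reference_ids == b.reference_ids
            np.testing.assert_array_equal(a.accumulated, b.accumulated)

    def test_zero_replicates_empty(self, scan_study):
        pops, sizes, neighbor_sets = scan_study
        cfg = make_scan_config(pops, sizes, seed=2, delta=0.0)
        segs, _ = ss.simulate_sharing_network(cfg)
        S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
        scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(12)],
                             neighbor_sets=neighbor_sets, bin=cfg.bins[0],
                             n_null_replicates=0)
        assert ss.null_scan_replicates(S, scan) == []


class TestExchangeableNull:
    def test_accumulations_centered_at_zero(self):
        """Under the exchangeable null (focals and neighbors drawn from the
        same generative parameters) the per-reference accumulated sums are
        centered at zero across independent generator replicates."""
        records, neighbor_sets = [], {}
        for k in range(6):
            records.append((f"F{k}", 50.0, 40.0 + 5 * k, "focal"))
            ns = []
            for j in range(2):
                records.append((f"N{k}_{j}", 50.0, 40.0 + 5 * k, "neighbor"))
                ns.append(f"N{k}_{j}")
            neighbor_sets[f"F{k}"] = ns
        for r in range(6):
            records.append((f"R{r}", 50.0, 70.0 + 5 * r, "reference"))
        pops = ss.PopulationTable.from_records(records, neighbor_sets)
        sizes = {p: 10 for p in pops.population_ids}
        scan = ss.ScanConfig(focal_ids=[f"F{k}" for k in range(6)],
                             neighbor_sets=neighbor_sets,
                             bin=ss.LengthBin(1, 2))
        rows = []
        for rep in range(50):
            cfg = ss.SharingSimConfig(
                populations=pops, sample_sizes=sizes, baseline_rate_cM=1.0,
                decay_scale_km=2000.0, bins=[ss.LengthBin(1, 2)],
                seed=30_000 + rep,
            )
            segs, _ = ss.simulate_sharing_network(cfg)
            S = ss.sharing_matrix(segs, pops, cfg.bins, sizes)
            rows.append(ss.subtract_accumulate(S, scan).accumulated)
        A = np.stack(rows)
        mean = A.mean(axis=0)
        se = A.std(axis=0, ddof=1) / np.sqrt(A.shape[0])
        within = np.abs(mean) < 2 * se
        assert within.mean() >= 0.9  # ~5% excursions expected by chance
        grand = A.mean()
        grand_se = A.mean(axis=1).std(ddof=1) / np.sqrt(A.shape[0])
        assert abs(grand) < 2 * grand_se + 1e-12
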