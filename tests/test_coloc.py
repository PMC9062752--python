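import numpy as np
import pandas as pd
import pytest

from methscore.coloc import (
    ColocResult,
    classify_evidence,
    coloc_abf,
    extract_region,
    log_abf,
    lookup_ms_cpgs,
)
from methscore.io import AssocSummaryStats, MwasSummary
from methscore.simulate import simulate_coloc_region


def enumeration_oracle(l1, l2, p1, p2, p12):
    """Direct probability-space sum over all single-causal configurations."""
    abf1 = np.exp(l1)
    abf2 = np.exp(l2)
    h0 = 1.0
    h1 = p1 * abf1.sum()
    h2 = p2 * abf2.sum()
    h3 = p1 * p2 * sum(
        abf1[i] * abf2[j] for i in range(len(l1)) for j in range(len(l2)) if i != j
    )
    h4 = p12 * float((abf1 * abf2).sum())
    tot = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / tot


def region_from_stats(betas1, ses1, betas2, ses2):
    n = len(betas1)
    snps = [f"rs{i}" for i in range(n)]
    base = {
        "snp": snps,
        "chr": "1",
        "pos": [1000 + i for i in range(n)],
        "ea": "A",
        "oa": "G",
        "n": 1000,
    }
    gwas = AssocSummaryStats(pd.DataFrame({**base, "beta": betas1, "se": ses1}), "gwas")
    mqtl = AssocSummaryStats(
        pd.DataFrame({**base, "beta": betas2, "se": ses2, "cpg": "cg1"}), "mqtl"
    )
    return extract_region(gwas, mqtl, "rs0", window_bp=10_000)


class TestLogAbf:
    def test_null_shrinkage(self):
        # z = 0 and V = W: log ABF = 0.5 log 0.5
        assert log_abf(0.0, 0.1, 0.1) == pytest.approx(0.5 * np.log(0.5), abs=1e-12)

    def test_prior_collapse(self):
        # W -> 0: no evidence either way
        assert log_abf(0.5, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_worked_value(self):
        # V=0.01, W=0.04, z=5: 0.5 log(0.2) + 12.5 * 0.8
        val = log_abf(0.5, 0.1, 0.2)
        assert val == pytest.approx(0.5 * np.log(0.2) + 10.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log_abf(np.nan, 0.1, 0.2)
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0, 0.2)


class TestColocAbf:
    def test_all_null_favours_h0(self):
        n = 50
        reg = region_from_stats(
            np.zeros(n), np.full(n, 0.05), np.zeros(n), np.full(n, 0.05)
        )
        res = coloc_abf(reg)
        assert res.pp["PP0"] > 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        """Posteriors equal brute-force configuration enumeration, <= 6 SNPs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        b1 = rng.normal(0, 0.2, n)
        s1 = rng.uniform(0.02, 0.1, n)
        b2 = rng.normal(0, 0.2, n)
        s2 = rng.uniform(0.02, 0.1, n)
        reg = region_from_stats(b1, s1, b2, s2)
        res = coloc_abf(reg)
        l1 = np.array([log_abf(b, s, 0.2) for b, s in zip(b1, s1)])
        l2 = np.array([log_abf(b, s, 0.15) for b, s in zip(b2, s2)])
        expected = enumeration_oracle(l1, l2, 1e-4, 1e-4, 1e-5)
        got = np.array([res.pp[f"PP{i}"] for i in range(5)])
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_posteriors_and_per_snp_sum_to_one(self):
        gwas, mqtl, _ = simulate_coloc_region("H4", 30, effect=0.2, seed=1)
        reg = extract_region(gwas, mqtl, "rs15")
        res = coloc_abf(reg)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-10)
        assert res.per_snp_h4.sum() == pytest.approx(1.0, abs=1e-10)

    def test_h4_simulation_recovers_shared_signal(self):
        hits = 0
        for seed in range(20):
            gwas, mqtl, _ = simulate_coloc_region("H4", 50, effect=0.15, seed=seed)
            reg = extract_region(gwas, mqtl, "rs25")
            res = coloc_abf(reg)
            hits += res.pp["PP4"] > 0.95
        assert hits >= 18

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        n = 8
        b1, s1 = rng.normal(0, 0.3, n), rng.uniform(0.05, 0.1, n)
        b2, s2 = rng.normal(0, 0.3, n), rng.uniform(0.05, 0.1, n)
        base = coloc_abf(region_from_stats(b1, s1, b2, s2))
        c = 3.7
        scaled = coloc_abf(
            region_from_stats(c * b1, c * s1, b2, s2), prior_sd_gwas=0.2 * c
        )
        for k in base.pp:
            assert scaled.pp[k] == pytest.approx(base.pp[k], abs=1e-10)


class TestExtractRegion:
    def _stats(self, rows, kind="gwas"):
        df = pd.DataFrame(
            rows, columns=["snp", "chr", "pos", "ea", "oa", "beta", "se", "n", "cpg"]
        )
        if kind == "gwas":
            df = df.drop(columns="cpg")
        return AssocSummaryStats(df, kind)

    def test_intersection_only(self):
        gwas = self._stats(
            [[f"rs{i}", "1", 100 + i, "A", "G", 0.1, 0.05, 100, None] for i in range(7)]
        )
        mqtl = self._stats(
            [[f"rs{i}", "1", 100 + i, "A", "G", 0.1, 0.05, 100, "cg1"] for i in range(5)],
            "mqtl",
        )
        reg = extract_region(gwas, mqtl, "rs0", window_bp=1000)
        assert reg.n_snps == 5

    def test_swapped_alleles_flip_beta(self):
        gwas = self._stats([["rs1", "1", 100, "A", "G", 0.2, 0.05, 100, None]])
        mqtl = self._stats([["rs1", "1", 100, "G", "A", 0.3, 0.05, 100, "cg1"]], "mqtl")
        reg = extract_region(gwas, mqtl, "rs1", window_bp=1000)
        assert reg.mqtl["beta"].iloc[0] == pytest.approx(-0.3)

    def test_ambiguous_snp_dropped(self):
        gwas = self._stats(
            [
                ["rs1", "1", 100, "A", "T", 0.2, 0.05, 100, None],
                ["rs2", "1", 110, "A", "G", 0.2, 0.05, 100, None],
            ]
        )
        mqtl = self._stats(
            [
                ["rs1", "1", 100, "A", "T", 0.3, 0.05, 100, "cg1"],
                ["rs2", "1", 110, "A", "G", 0.3, 0.05, 100, "cg1"],
            ],
            "mqtl",
        )
        reg = extract_region(gwas, mqtl, "rs1", window_bp=1000)
        assert reg.n_ambiguous_dropped == 1 and reg.n_snps == 1

    def test_absent_index_snp(self):
        gwas = self._stats([["rs1", "1", 100, "A", "G", 0.2, 0.05, 100, None]])
        mqtl = self._stats([["rs1", "1", 100, "A", "G", 0.3, 0.05, 100, "cg1"]], "mqtl")
        with pytest.raises(KeyError):
            extract_region(gwas, mqtl, "rs99")


class TestClassifyAndLookup:
    def _result(self, pp4, pp3, cpg="cg1"):
        rest = 1 - pp4 - pp3
        return ColocResult(
            pp={"PP0": rest, "PP1": 0.0, "PP2": 0.0, "PP3": pp3, "PP4": pp4},
            per_snp_h4=pd.Series([0.7, 0.3], index=["rsA", "rsB"]),
            n_snps=2,
            priors=(1e-4, 1e-4, 1e-5),
            index_snp="rsIdx",
            cpg=cpg,
        )

    @pytest.mark.parametrize(
        "pp4,pp3,tier",
        [(0.85, 0.10, "strong"), (0.71, 0.20, "suggestive"), (0.30, 0.10, "none")],
    )
    def test_tiers(self, pp4, pp3, tier):
        res = self._result(pp4, pp3)
        assert classify_evidence(res) == tier

    def test_ratio_rule_blocks_strong(self):
        res = self._result(0.82, 0.17)  # ratio 4.8 < 5
        assert classify_evidence(res) == "suggestive"

    def test_lookup_reports_traits_containing_cpg(self):
        recipes = [
            MwasSummary("smoking", pd.DataFrame({"cpg": ["cg1", "cg2"], "weight": [1, 1], "p": [0.01, 0.2]})),
            MwasSummary("bmi", pd.DataFrame({"cpg": ["cg1"], "weight": [1.0], "p": [0.5]})),
            MwasSummary("hdl", pd.DataFrame({"cpg": ["cg9"], "weight": [1.0], "p": [0.5]})),
        ]
        res = self._result(0.71, 0.1)
        classify_evidence(res)
        report = lookup_ms_cpgs([res], recipes)
        assert len(report) == 1
        assert report["traits_containing_cpg"].iloc[0] == "bmi,smoking"

    def test_lookup_empty_when_no_evidence(self):
        res = self._result(0.3, 0.1)
        classify_evidence(res)
        report = lookup_ms_cpgs([res], [])
        assert report.empty
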