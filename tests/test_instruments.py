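"""Instrument strength formulas, greedy LD pruning, and harmonisation."""

import numpy as np
import pandas as pd
import pytest

from mrpath import AnalysisError, FormatError, f_statistic, harmonize, ld_prune, variant_r2
from mrpath.instruments import instrument_strength, pairs_to_tables, variant_r2_eaf
from conftest import random_sumstats


class TestStrength:
    def test_r2_boundaries(self):
        assert variant_r2(0.0, 0.1, 1_000) == 0.0
        n = 1_000
        t = np.sqrt(n - 2)  # t^2 = n - 2 -> R2 = 0.5 exactly
        assert variant_r2(t * 0.1, 0.1, n) == pytest.approx(0.5)
        with pytest.raises(AnalysisError):
            variant_r2(0.1, 0.1, 2)

    def test_r2_recovers_planted_share(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.binomial(2, 0.3, n).astype(float)
        b = np.sqrt(0.01 / np.var(x))  # 1% of unit-variance outcome
        y = b * x + rng.normal(0, np.sqrt(0.99), n)
        xc = x - x.mean()
        beta = xc @ (y - y.mean()) / (xc @ xc)
        se = np.sqrt((np.sum((y - y.mean() - beta * xc) ** 2) / (n - 2)) / (xc @ xc))
        assert variant_r2(beta, se, n) == pytest.approx(0.01, abs=0.003)

    def test_f_statistic_identities(self):
        assert f_statistic(0.0, 100) == 0.0
        n = 500
        r2 = 0.5  # t^2 = n - 2 case
        assert f_statistic(r2, n) == pytest.approx(n - 2)
        # smallest r2 with F >= 10 at n = 1,000 is 10/1008
        r2_star = 10 / 1008
        assert f_statistic(r2_star, 1_000) == pytest.approx(10.0)
        assert f_statistic(r2_star * 0.999, 1_000) < 10.0

    def test_eaf_form_cross_check(self):
        # standardised-trait variant: both forms agree on the variance share
        rng = np.random.default_rng(1)
        n, maf, b = 200_000, 0.3, 0.05
        x = rng.binomial(2, maf, n).astype(float)
        share = b * b * np.var(x)
        y = b * x + rng.normal(0, np.sqrt(1 - share), n)
        xc = x - x.mean()
        beta = xc @ (y - y.mean()) / (xc @ xc)
        se = np.sqrt((np.sum((y - y.mean() - beta * xc) ** 2) / (n - 2)) / (xc @ xc))
        assert variant_r2(beta, se, n) == pytest.approx(
            variant_r2_eaf(beta, maf), rel=0.15)

    def test_weak_instruments_labelled(self):
        table = random_sumstats(np.random.default_rng(2), 6)
        table["BETA"] = [1.0, 0.001, 1.0, 0.002, 1.0, 0.001]
        table["SE"] = 0.05
        stats = instrument_strength(table, f_min=10)
        assert stats["kept"].tolist() == [True, False, True, False, True, False]
        assert set(stats.loc[~stats["kept"], "reason"]) == {"weak"}


def _ld(ids, r2_map):
    m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for (a, b), v in r2_map.items():
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestPrune:
    def _stats(self, ids, p, f):
        return pd.DataFrame({"SNP": ids, "P": p, "f_stat": f,
                             "kept": True, "reason": ""})

    def test_uncorrelated_all_kept(self):
        ids = ["a", "b", "c"]
        stats = self._stats(ids, [0.01, 0.02, 0.03], [30, 20, 10])
        out = ld_prune(stats, _ld(ids, {}))
        assert out["kept"].all()

    def test_tie_break_prefers_larger_f(self):
        ids = ["a", "b"]
        stats = self._stats(ids, [0.01, 0.01], [10, 50])
        out = ld_prune(stats, _ld(ids, {("a", "b"): 0.5}))
        assert out.set_index("SNP")["kept"].to_dict() == {"a": False, "b": True}

    def test_threshold_boundary_drops_at_exactly_point_one(self):
        ids = ["a", "b"]
        stats = self._stats(ids, [0.01, 0.02], [50, 40])
        out = ld_prune(stats, _ld(ids, {("a", "b"): 0.1}))
        assert out.set_index("SNP")["kept"].to_dict() == {"a": True, "b": False}

    def test_two_blocks_keep_one_each(self):
        ids = [f"v{i}" for i in range(10)]
        r2 = {}
        for block in (ids[:5], ids[5:]):
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    r2[(a, b)] = 0.8
        ld = _ld(ids, r2)
        rng = np.random.default_rng(3)
        stats = self._stats(ids, rng.uniform(1e-8, 1e-4, 10), rng.uniform(20, 80, 10))
        out = ld_prune(stats, ld)
        kept = out.loc[out["kept"], "SNP"].tolist()
        assert len(kept) == 2
        # brute-force oracle: the kept variant of each block is its best-priority one
        order = stats.sort_values(["P", "f_stat", "SNP"],
                                  ascending=[True, False, True])["SNP"].tolist()
        expected = {next(s for s in order if s in ids[:5]),
                    next(s for s in order if s in ids[5:])}
        assert set(kept) == expected
        assert (out.loc[~out["kept"], "reason"] == "ld_pruned").all()

    def test_kept_set_is_maximal(self):
        rng = np.random.default_rng(4)
        ids = [f"v{i}" for i in range(15)]
        raw = rng.uniform(0, 0.4, (15, 15))
        m = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        ld = pd.DataFrame(m, index=ids, columns=ids)
        stats = self._stats(ids, rng.uniform(0, 1, 15), rng.uniform(5, 50, 15))
        out = ld_prune(stats, ld, threshold=0.2)
        kept = out.loc[out["kept"], "SNP"].tolist()
        for snp in out.loc[~out["kept"], "SNP"]:
            assert (ld.loc[snp, kept] >= 0.2).any()

    def test_missing_variant_errors(self):
        stats = self._stats(["a", "zzz"], [0.1, 0.2], [20, 20])
        with pytest.raises(AnalysisError, match="zzz"):
            ld_prune(stats, _ld(["a"], {}))


def _joint_tables(seed, n=15):
    """Exposure/outcome tables over shared variants with random re-labelling."""
    rng = np.random.default_rng(seed)
    exp = random_sumstats(rng, n)
    exp.loc[: n // 3, ["A1", "A2"]] = ["A", "T"]  # a few palindromic variants
    out = exp.copy()
    out["BETA"] = 0.3 * exp["BETA"] + rng.normal(0, 0.05, n)
    out["SE"] = rng.uniform(0.01, 0.1, n)
    out["EAF"] = np.clip(exp["EAF"] + rng.normal(0, 0.01, n), 0.01, 0.99)
    out["N"] = 30_000
    # randomly swap allele order in the outcome table
    swap = rng.random(n) < 0.5
    out.loc[swap, ["A1", "A2"]] = out.loc[swap, ["A2", "A1"]].to_numpy()
    out.loc[swap, "BETA"] = -out.loc[swap, "BETA"]
    out.loc[swap, "EAF"] = 1.0 - out.loc[swap, "EAF"]
    return exp, out


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        exp, _ = _joint_tables(0, 6)
        exp = exp.iloc[3:]  # non-palindromic rows
        pairs, dropped = harmonize(exp, exp)
        assert len(dropped) == 0
        assert (~pairs["flipped"]).all()
        np.testing.assert_allclose(np.abs(pairs["beta_exp"]), np.abs(exp["BETA"]))

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = random_sumstats(np.random.default_rng(1), 1)
        exp.loc[0, ["A1", "A2", "EAF", "BETA"]] = ["A", "G", 0.2, 0.5]
        out = exp.copy()
        out.loc[0, ["A1", "A2", "EAF", "BETA"]] = ["G", "A", 0.8, 0.3]
        pairs, _ = harmonize(exp, out)
        assert pairs.loc[0, "flipped"]
        assert pairs.loc[0, "beta_out"] == pytest.approx(-0.3)
        assert pairs.loc[0, "eaf_out"] == pytest.approx(0.2)

    def test_strand_complement_resolved(self):
        exp = random_sumstats(np.random.default_rng(2), 1)
        exp.loc[0, ["A1", "A2", "EAF", "BETA"]] = ["A", "G", 0.2, 0.5]
        out = exp.copy()
        out.loc[0, ["A1", "A2"]] = ["T", "C"]  # same orientation, other strand
        pairs, dropped = harmonize(exp, out)
        assert len(pairs) == 1 and not pairs.loc[0, "flipped"]
        assert pairs.loc[0, "beta_out"] == pytest.approx(0.5)

    def test_palindromic_near_half_dropped(self):
        exp = random_sumstats(np.random.default_rng(3), 1)
        exp.loc[0, ["A1", "A2", "EAF"]] = ["A", "T", 0.48]
        pairs, dropped = harmonize(exp, exp.copy())
        assert len(pairs) == 0
        assert dropped.loc[0, "reason"] == "unharmonizable"

    def test_palindromic_clear_eaf_kept(self):
        exp = random_sumstats(np.random.default_rng(4), 1)
        exp.loc[0, ["A1", "A2", "EAF", "BETA"]] = ["C", "G", 0.2, 0.4]
        out = exp.copy()
        out.loc[0, "EAF"] = 0.22
        pairs, dropped = harmonize(exp, out)
        assert len(pairs) == 1
        assert pairs.loc[0, "palindromic"]

    def test_duplicate_ids_rejected(self):
        exp = random_sumstats(np.random.default_rng(5), 3)
        exp.loc[2, "SNP"] = exp.loc[0, "SNP"]
        with pytest.raises(FormatError, match="duplicate"):
            harmonize(exp, random_sumstats(np.random.default_rng(5), 3))

    @pytest.mark.parametrize("which", ["exposure", "outcome"])
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_allele_relabelling_involution(self, which, seed):
        """Swapping A1/A2 with beta negation in either input leaves pairs unchanged."""
        exp, out = _joint_tables(seed)
        pairs, dropped = harmonize(exp, out)
        tab = exp if which == "exposure" else out
        relab = tab.copy()
        relab[["A1", "A2"]] = relab[["A2", "A1"]].to_numpy()
        relab["BETA"] = -relab["BETA"]
        relab["EAF"] = 1.0 - relab["EAF"]
        if which == "exposure":
            pairs2, dropped2 = harmonize(relab, out)
        else:
            pairs2, dropped2 = harmonize(exp, relab)
        pd.testing.assert_frame_equal(
            pairs.drop(columns="flipped"), pairs2.drop(columns="flipped"))
        pd.testing.assert_frame_equal(dropped, dropped2)

    @pytest.mark.parametrize("seed", [20, 21])
    def test_idempotence(self, seed):
        """Re-harmonising a harmonised pair set reproduces it field for field.

        The ``flipped`` flag is relative to the immediate source records, so a
        re-harmonised (already aligned) set is legitimately all-unflipped.
        """
        exp, out = _joint_tables(seed)
        pairs, _ = harmonize(exp, out)
        exp2, out2 = pairs_to_tables(pairs)
        pairs2, dropped2 = harmonize(exp2, out2)
        assert len(dropped2) == 0
        assert (~pairs2["flipped"]).all()
        pd.testing.assert_frame_equal(
            pairs.drop(columns="flipped").reset_index(drop=True),
            pairs2.drop(columns="flipped").reset_index(drop=True),
            check_dtype=False,
        )
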