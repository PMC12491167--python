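"""Instrument-strength arithmetic, LD clumping and the filter chain."""

import itertools

import numpy as np
import pytest

from medmr.instruments import (
    InstrumentCriteria,
    LDMatrix,
    NoInstrumentsError,
    clump,
    f_statistic,
    select_instruments,
    variance_explained,
)
from tests.conftest import make_pair, make_record


class TestVarianceExplained:
    def test_hand_evaluated_value(self):
        # 2*0.25*0.01 / (2*0.25*0.01 + 2*0.25*10000*0.0001) = 0.01/1.01
        assert variance_explained(0.5, 0.1, 0.01, 10_000) == pytest.approx(0.009901, abs=5e-7)

    def test_zero_beta_gives_zero(self):
        assert variance_explained(0.3, 0.0, 0.01, 10_000) == 0.0

    def test_eaf_cancels(self):
        a = variance_explained(0.2, 0.1, 0.01, 10_000)
        b = variance_explained(0.4, 0.1, 0.01, 10_000)
        assert a == pytest.approx(b, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.3, 0.1, 0.01, 1)


class TestFStatistic:
    def test_zero_r2(self):
        assert f_statistic(0.0, 100) == 0.0

    def test_hand_arithmetic(self):
        assert f_statistic(0.009901, 10_000) == pytest.approx(99.98, rel=1e-3)

    def test_monotone_in_r2(self):
        assert f_statistic(0.01, 5000) < f_statistic(0.02, 5000)

    def test_r2_of_one_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 5000)


def _clump_oracle(records, ld, r2_thresh, window_kb):
    """Step-by-step greedy simulation, written independently of the
    implementation: repeatedly take the smallest-p remaining SNP and delete
    its correlated neighbours."""
    remaining = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top.snp_id)
        survivors = []
        for r in remaining:
            same_region = (r.chrom == top.chrom
                           and abs(r.pos - top.pos) <= window_kb * 1000)
            if same_region and ld.get(top.snp_id, r.snp_id) >= r2_thresh:
                continue
            survivors.append(r)
        remaining = survivors
    return kept


class TestClump:
    def test_independent_snps_all_retained(self):
        recs = [make_record(f"rs{i}", pos=i * 1000, pvalue=10 ** -(i + 3)) for i in range(5)]
        retained, log = clump(recs, LDMatrix.identity(), 0.01, 10_000)
        assert len(retained) == 5 and not log.entries

    def test_correlated_neighbour_removed(self):
        a = make_record("rs1", pos=1000, pvalue=1e-8)
        b = make_record("rs2", pos=2000, pvalue=1e-6)
        ld = LDMatrix({("rs1", "rs2"): 0.5})
        retained, log = clump([a, b], ld, 0.01, 10_000)
        assert [r.snp_id for r in retained] == ["rs1"]
        assert log.entries[0].stage == "ld_clump"

    def test_chain_matches_bruteforce_oracle(self, rng):
        recs = [make_record(f"rs{i}", pos=1000 * (i + 1), pvalue=float(p))
                for i, p in enumerate(rng.uniform(1e-10, 1e-5, size=5))]
        ld = LDMatrix()
        ids = [r.snp_id for r in recs]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ld.set(a, b, float(rng.choice([0.0, 0.005, 0.02, 0.5, 0.95])))
        retained, _ = clump(recs, ld, 0.01, 10_000)
        assert [r.snp_id for r in retained] == _clump_oracle(recs, ld, 0.01, 10_000)

    def test_order_invariance(self, rng):
        recs = [make_record(f"rs{i}", pos=1000 * (i + 1), pvalue=float(p))
                for i, p in enumerate(rng.uniform(1e-10, 1e-5, size=8))]
        ld = LDMatrix()
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                ld.set(a.snp_id, b.snp_id, float(rng.uniform(0, 1)))
        ref = [r.snp_id for r in clump(recs, ld, 0.3, 10_000)[0]]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert [r.snp_id for r in clump(shuffled, ld, 0.3, 10_000)[0]] == ref

    def test_window_limits_removal(self):
        # same r2 but 20,000 kb apart: outside the window, both kept
        a = make_record("rs1", pos=1_000, pvalue=1e-8)
        b = make_record("rs2", pos=20_001_000, pvalue=1e-6)
        ld = LDMatrix({("rs1", "rs2"): 0.9})
        retained, _ = clump([a, b], ld, 0.01, 10_000)
        assert len(retained) == 2


class TestSelectInstruments:
    def base_pairs(self):
        return [
            make_pair("rs_ok", pos=1_000),
            make_pair("rs_weak_p", pos=200_000, pval_exp=1e-5),
            make_pair("rs_rare", pos=400_000, eaf=0.005),
            make_pair("rs_weak_f", pos=600_000, beta_exp=0.003, se_exp=0.005),
        ]

    def test_stage_labels(self):
        retained, log = select_instruments(self.base_pairs(), InstrumentCriteria())
        stages = {e.snp_id: e.stage for e in log.entries}
        assert stages == {"rs_weak_p": "p_exposure", "rs_rare": "maf",
                          "rs_weak_f": "weak_instrument"}
        assert [p.snp_id for p in retained] == ["rs_ok"]

    def test_conservation(self):
        pairs = self.base_pairs()
        retained, log = select_instruments(pairs, InstrumentCriteria())
        assert len(retained) + len(log) == len(pairs)

    def test_f_boundary_excluded_at_10(self):
        # F = 9.9 => excluded (rule is F <= 10 out)
        n = 50_000
        r2 = 9.9 / (n - 2 + 9.9)
        beta = 0.01
        se = beta * np.sqrt((1 - r2) / (n * r2))
        p = make_pair("rs_f", beta_exp=beta, se_exp=float(se))
        with pytest.raises(NoInstrumentsError) as err:
            select_instruments([p], InstrumentCriteria())
        assert err.value.stage_counts == {"weak_instrument": 1}

    def test_outcome_p_policy_directions(self):
        assoc = make_pair("rs_assoc", pval_out=0.01)
        null = make_pair("rs_null", pos=50_000, pval_out=0.5)
        crit_default = InstrumentCriteria()  # exclude_below: drop outcome-associated
        retained, log = select_instruments([assoc, null], crit_default)
        assert [p.snp_id for p in retained] == ["rs_null"]
        assert log.entries[0].stage == "outcome_p"
        crit_literal = InstrumentCriteria(outcome_p_policy="exclude_above")
        retained2, _ = select_instruments([assoc, null], crit_literal)
        assert [p.snp_id for p in retained2] == ["rs_assoc"]
        retained3, _ = select_instruments([assoc, null],
                                          InstrumentCriteria(outcome_p_policy="off"))
        assert len(retained3) == 2

    def test_empty_set_raises_with_counts(self):
        with pytest.raises(NoInstrumentsError) as err:
            select_instruments([make_pair("rs1", pval_exp=0.5)], InstrumentCriteria())
        assert err.value.stage_counts == {"p_exposure": 1}

    def test_filter_order_permutation_invariance(self, rng):
        """{exposure-p, MAF, F} applied in any order give the same final set."""
        pairs = []
        for i in range(30):
            pairs.append(make_pair(
                f"rs{i}", pos=(i + 1) * 1_000_000,
                pval_exp=float(rng.choice([1e-8, 1e-4])),
                eaf=float(rng.choice([0.005, 0.3])),
                beta_exp=float(rng.choice([0.002, 0.1])),
            ))
        crit = InstrumentCriteria(outcome_p_policy="off")
        try:
            ref, _ = select_instruments(pairs, crit)
            ref_ids = {p.snp_id for p in ref}
        except NoInstrumentsError:
            ref_ids = set()

        def p_filter(ps):
            return [p for p in ps if p.pval_exp < crit.p_exposure_max]

        def maf_filter(ps):
            return [p for p in ps if min(p.eaf_exp, 1 - p.eaf_exp) >= crit.maf_min]

        def f_filter(ps):
            from medmr.instruments import instrument_strength
            return [p for p in ps if instrument_strength(p).f_stat > crit.f_min]

        for order in itertools.permutations([p_filter, maf_filter, f_filter]):
            result = list(pairs)
            for f in order:
                result = f(result)
            assert {p.snp_id for p in result} == ref_ids


class TestLDMatrix:
    def test_square_and_pairlist_agree(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        arr = np.array([[1, 0.5, 0.0], [0.5, 1, 0.2], [0.0, 0.2, 1]])
        import pandas as pd
        square = tmp_path / "square.tsv"
        pd.DataFrame(arr, index=ids, columns=ids).to_csv(square, sep="\t")
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.5\nrs2\trs3\t0.2\n")
        m1, m2 = LDMatrix.from_file(square), LDMatrix.from_file(pairs)
        for a in ids:
            for b in ids:
                assert m1.get(a, b) == pytest.approx(m2.get(a, b))

    def test_symmetric_completion_and_missing_default(self):
        m = LDMatrix({("rs1", "rs2"): 0.7})
        assert m.get("rs2", "rs1") == 0.7
        assert m.get("rs1", "rs9") == 0.0  # missing treated as independent
        assert m.get("rs1", "rs1") == 1.0

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            LDMatrix({("a", "b"): 1.5})
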