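import numpy as np
import pandas as pd
import pytest

from tcrdyn.genomics import (
    CCF_GRID,
    burden_metrics,
    classify_strong_binders,
    estimate_ccf,
    expected_vaf,
    ith_index,
    median_ccf_baseline,
    neoantigen_depletion_test,
    signature_score,
    wgii,
)


def estimate_ccf_oracle(vaf, purity, cn_tumor, cn_normal=2):
    """Independently coded exhaustive loop with the same tie-break."""
    best = None
    for cn_mut in range(1, cn_tumor + 1):
        for step in range(1, 101):
            ccf = step / 100.0
            exp = cn_mut * ccf * purity / (cn_normal * (1 - purity) + cn_tumor * purity)
            resid = abs(exp - vaf)
            if best is None or resid < best[0] - 1e-12:
                best = (resid, cn_mut, ccf)
    return best[2], best[1], best[0]


class TestExpectedVaf:
    def test_half_purity_symmetric_case(self):
        assert expected_vaf(1.0, 1, 0.5, 2, 2) == pytest.approx(0.25)

    def test_vanishing_purity_limit(self):
        assert expected_vaf(1.0, 1, 1e-9, 2, 2) == pytest.approx(0.0, abs=1e-9)

    def test_hand_case(self):
        assert expected_vaf(0.5, 2, 0.8, 3, 2) == pytest.approx(0.8 / 2.8)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf(1.0, 1, 0.0, 0, 0)


class TestEstimateCcf:
    def test_clonal_heterozygous_case(self):
        fit = estimate_ccf(0.25, 0.5, 2)
        assert (fit.ccf, fit.cn_mut) == (1.0, 1)
        # (ccf=0.5, cn_mut=2) fits equally well: ambiguity must be flagged
        assert fit.is_ambiguous

    def test_forward_inverse_round_trip(self):
        vaf = expected_vaf(0.37, 1, 0.6, 2, 2)
        fit = estimate_ccf(vaf, 0.6, 2)
        assert abs(fit.ccf - 0.37) <= 0.01 + 1e-12

    def test_zero_vaf_hits_grid_boundary(self):
        fit = estimate_ccf(0.0, 0.5, 2)
        assert (fit.ccf, fit.cn_mut) == (0.01, 1)
        assert fit.residual == pytest.approx(expected_vaf(0.01, 1, 0.5, 2, 2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(0.5, 0.5, 0)
        with pytest.raises(ValueError):
            estimate_ccf(1.5, 0.5, 2)

    def test_matches_independent_exhaustive_loop(self, rng):
        for _ in range(100):
            vaf = float(rng.uniform(0, 0.8))
            purity = float(rng.uniform(0.1, 1.0))
            cn_t = int(rng.integers(1, 5))
            fit = estimate_ccf(vaf, purity, cn_t)
            o_ccf, o_cnm, o_resid = estimate_ccf_oracle(vaf, purity, cn_t)
            assert fit.residual == pytest.approx(o_resid, abs=1e-12)
            if not fit.is_ambiguous:
                assert (fit.ccf, fit.cn_mut) == (o_ccf, o_cnm)

    def test_noise_free_recovery_on_random_grid_draws(self, rng):
        n_checked = 0
        for _ in range(200):
            ccf = float(CCF_GRID[rng.integers(0, 100)])
            cn_t = int(rng.integers(1, 5))
            cn_mut = int(rng.integers(1, cn_t + 1))
            purity = float(rng.uniform(0.2, 1.0))
            vaf = expected_vaf(ccf, cn_mut, purity, cn_t)
            fit = estimate_ccf(vaf, purity, cn_t)
            if fit.is_ambiguous:
                continue
            n_checked += 1
            assert abs(fit.ccf - ccf) <= 0.01 + 1e-12
            assert fit.cn_mut == cn_mut
        assert n_checked > 100  # injective cases dominate


class TestBurdens:
    def _muts(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "mutation_id", "sample_id", "mutation_class", "is_exonic",
                "is_neoantigen_encoding", "ccf",
            ],
        )

    def test_tmb_per_megabase(self):
        rows = [(f"m{i}", "S1", "nsSNV", True, False, 1.0) for i in range(30)]
        out = burden_metrics(self._muts(rows), exome_mb=30.0)
        assert out.loc[0, "tmb"] == pytest.approx(1.0)

    def test_no_mutations_gives_zeros(self):
        out = burden_metrics(self._muts([("m0", "S1", "other", False, False, 1.0)]), 30.0)
        assert out.loc[0, "tmb"] == 0.0
        assert out.loc[0, "fsindel_count"] == 0

    def test_single_region_clonal_uses_ccf_threshold(self):
        rows = [
            ("m0", "S1", "nsSNV", True, False, 0.9),
            ("m1", "S1", "nsSNV", True, False, 0.4),
        ]
        out = burden_metrics(self._muts(rows), exome_mb=1.0)
        assert out.loc[0, "clonal_tmb"] == pytest.approx(1.0)  # only CCF > 0.5

    def test_multiregion_clonal_uses_ubiquitous_mutations(self):
        rows = [
            ("shared", "S1", "nsSNV", True, False, 1.0),
            ("shared", "S2", "nsSNV", True, False, 1.0),
            ("private", "S1", "nsSNV", True, False, 1.0),
        ]
        out = burden_metrics(self._muts(rows), exome_mb=1.0).set_index("sample_id")
        assert out.loc["S1", "tmb"] == pytest.approx(2.0)
        assert out.loc["S1", "clonal_tmb"] == pytest.approx(1.0)
        assert out.loc["S2", "clonal_tmb"] == pytest.approx(1.0)

    def test_missing_exome_size_is_config_error(self):
        with pytest.raises(ValueError):
            burden_metrics(self._muts([]), exome_mb=None)


class TestWgii:
    def _segments(self, cn_by_chrom, length=10_000):
        rows = []
        for chrom, cn in cn_by_chrom.items():
            rows.append({"chromosome": str(chrom), "start": 0, "end": length, "total_cn": cn})
        return pd.DataFrame(rows)

    def test_all_segments_at_ploidy(self):
        segs = self._segments({c: 2 for c in range(1, 23)})
        assert wgii(segs, ploidy=2.0) == 0.0

    def test_every_segment_aberrant(self):
        segs = self._segments({c: 3 for c in range(1, 23)})
        assert wgii(segs, ploidy=2.0) == 1.0

    def test_single_aberrant_chromosome(self):
        cn = {c: 2 for c in range(1, 23)}
        cn[1] = 5
        assert wgii(self._segments(cn), ploidy=2.0) == pytest.approx(1 / 22)

    def test_split_invariance(self):
        whole = pd.DataFrame(
            [{"chromosome": "1", "start": 0, "end": 100, "total_cn": 3},
             {"chromosome": "1", "start": 100, "end": 300, "total_cn": 2}]
        )
        split = pd.DataFrame(
            [{"chromosome": "1", "start": 0, "end": 50, "total_cn": 3},
             {"chromosome": "1", "start": 50, "end": 100, "total_cn": 3},
             {"chromosome": "1", "start": 100, "end": 300, "total_cn": 2}]
        )
        assert wgii(whole, 2.0) == pytest.approx(wgii(split, 2.0))

    def test_no_autosomal_segments_is_undefined(self):
        assert wgii(pd.DataFrame(columns=["chromosome", "start", "end", "total_cn"]), 2.0) is None


class TestIthIndex:
    @pytest.mark.parametrize(
        "subclonal,clonal,expected", [(2, 4, 0.5), (0, 3, 0.0), (3, 0, None)]
    )
    def test_ratio_and_undefined_flag(self, subclonal, clonal, expected):
        assert ith_index(subclonal, clonal) == expected


class TestStrongBinders:
    def test_rank_filter(self):
        preds = pd.DataFrame(
            {
                "peptide": ["p1", "p2", "p3"],
                "rank_mutant": [0.3, 0.3, 0.6],
                "rank_wildtype": [0.7, 0.4, 0.7],
            }
        )
        assert classify_strong_binders(preds).tolist() == [True, False, False]


class TestDepletion:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["mutation_id", "ccf", "is_neoantigen_encoding"])

    def test_ccf_drop_of_ten_points_contracts(self):
        pre = self._df([("m", 0.80, True)])
        post = self._df([("m", 0.70, True)])
        res = neoantigen_depletion_test(pre, post)
        assert res.labels.loc[0, "contracted"]

    def test_smaller_drop_does_not_contract(self):
        res = neoantigen_depletion_test(self._df([("m", 0.80, True)]), self._df([("m", 0.75, True)]))
        assert not res.labels.loc[0, "contracted"]

    def test_disappearance_contracts(self):
        res = neoantigen_depletion_test(self._df([("m", 0.30, False)]), self._df([]))
        assert res.labels.loc[0, "contracted"]

    def test_balanced_table_shows_no_association(self):
        rows = []
        # 5 contracted + 5 stable in each class
        for i in range(10):
            rows.append((f"n{i}", 0.9, True))
            rows.append((f"o{i}", 0.9, False))
        pre = self._df(rows)
        post = self._df(
            [(f"n{i}", 0.9 - (0.2 if i < 5 else 0.0), True) for i in range(10)]
            + [(f"o{i}", 0.9 - (0.2 if i < 5 else 0.0), False) for i in range(10)]
        )
        res = neoantigen_depletion_test(pre, post, alternative="two-sided")
        assert res.table == ((5, 5), (5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        one_sided = neoantigen_depletion_test(pre, post)
        assert one_sided.p_value > 0.05

    def test_empty_margin_reports_table_without_p(self):
        res = neoantigen_depletion_test(
            self._df([("m1", 0.9, True), ("m2", 0.9, True)]),
            self._df([("m1", 0.9, True), ("m2", 0.9, True)]),
        )
        assert res.p_value is None
        assert res.table[0][1] == 2

    def test_relative_drop_mode(self):
        pre = self._df([("m", 0.40, True)])
        post = self._df([("m", 0.35, True)])
        absolute = neoantigen_depletion_test(pre, post)
        relative = neoantigen_depletion_test(pre, post, relative=True)
        assert not absolute.labels.loc[0, "contracted"]  # drop 0.05 < 0.10
        assert relative.labels.loc[0, "contracted"]  # drop 12.5% of baseline

    def test_median_baseline_across_pre_samples(self):
        pre = pd.DataFrame(
            {
                "mutation_id": ["m", "m", "m"],
                "sample_id": ["S1", "S2", "S3"],
                "ccf": [0.2, 0.6, 0.9],
                "is_neoantigen_encoding": [True, True, True],
            }
        )
        base = median_ccf_baseline(pre)
        assert base.loc[0, "ccf"] == pytest.approx(0.6)


class TestSignatureScore:
    def test_all_zero_z_scores(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=["g1", "g2", "g3"])
        scores = signature_score(expr, ["g1", "g2"])
        assert np.allclose(scores, 0.0)

    def test_symmetric_genes_cancel(self):
        expr = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["up", "down"], columns=["s1", "s2"])
        scores = signature_score(expr, ["up", "down"])
        assert np.allclose(scores, 0.0)

    def test_matches_hand_computation(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 6.0], [0.0, 1.0, 1.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=list("abcd"),
        )
        scores = signature_score(expr, ["g1", "g2", "g3"])
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        assert np.allclose(scores, z.mean(axis=0))

    def test_missing_genes_logged_and_absent_set_undefined(self):
        expr = pd.DataFrame(np.ones((1, 2)), index=["g1"])
        assert signature_score(expr, ["gX"]) is None
        assert signature_score(expr, ["g1", "gX"]) is not None
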