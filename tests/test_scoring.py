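"""Weight estimation against grid-search oracles and score arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.special import expit

from adenoma_prs.core_io import MISSING, CohortTable, GenotypeMatrix, SnpDef, SnpPanel
from adenoma_prs.scoring import (
    EstimationError,
    WeightEstimate,
    compute_scores,
    estimate_weights,
    orient_to_weights,
    read_weights,
    score_distribution_stats,
    write_weights,
)

from conftest import make_matrix


def logit_grid_mle(x: np.ndarray, y: np.ndarray, tol: float = 1e-6) -> float:
    """Independent maximiser of the Bernoulli log-likelihood over
    (intercept, slope) by iterative grid refinement."""

    def loglik(a, b):
        eta = a + b * x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    a0, b0, half = 0.0, 0.0, 8.0
    while half > tol / 4:
        grid_a = np.linspace(a0 - half, a0 + half, 33)
        grid_b = np.linspace(b0 - half, b0 + half, 33)
        vals = np.array([[loglik(a, b) for b in grid_b] for a in grid_a])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        a0, b0 = grid_a[i], grid_b[j]
        half /= 2.0
    return b0


def table_to_data(ctrl_counts, case_counts):
    """2x3 genotype-count table -> (dosage, label) arrays."""
    x, y = [], []
    for dose, (nc, na) in enumerate(zip(ctrl_counts, case_counts)):
        x += [dose] * (nc + na)
        y += [0] * nc + [1] * na
    return np.array(x, float), np.array(y, float)


class TestEstimateWeights:
    def test_null_distribution_gives_zero_beta(self):
        # identical genotype tables in cases and controls: MLE is exactly 0
        x, y = table_to_data((30, 40, 30), (30, 40, 30))
        g = make_matrix(x[:, None].astype(np.int8), rsids=["rs1"])
        (w,) = estimate_weights(g, y)
        assert w.beta == pytest.approx(0.0, abs=1e-6)
        assert not w.oriented_flip

    def test_matches_grid_search_oracle(self):
        x, y = table_to_data((20, 30, 10), (10, 25, 25))
        g = make_matrix(x[:, None].astype(np.int8), rsids=["rs1"])
        (w,) = estimate_weights(g, y)
        assert w.beta == pytest.approx(logit_grid_mle(x, y), abs=1e-4)

    def test_protective_snp_is_flipped(self):
        x, y = table_to_data((10, 25, 25), (20, 30, 10))  # risk allele depleted in cases
        g = make_matrix(x[:, None].astype(np.int8), rsids=["rs1"])
        (w,) = estimate_weights(g, y)
        assert w.oriented_flip and w.beta > 0
        assert w.beta == pytest.approx(-logit_grid_mle(x, y), abs=1e-4)

    def test_recovers_true_log_odds_ratio(self):
        """Large simulated reference panel: beta-hat near ln(1.54)."""
        from adenoma_prs.core_io import STUDY_PANEL
        from adenoma_prs.synthetic_data import (
            SimulationConfig,
            ma_association_odds_ratios,
            simulate_reference_panel,
        )

        cfg = SimulationConfig(
            seed=2,
            n_ref_cases=5000,
            n_ref_controls=5000,
            odds_ratios=ma_association_odds_ratios(STUDY_PANEL),
        )
        g, labels = simulate_reference_panel(cfg)
        weights = {w.rsid: w for w in estimate_weights(g, labels)}
        assert weights["rs6983267"].beta == pytest.approx(np.log(1.54), abs=0.05)
        assert not weights["rs6983267"].oriented_flip
        # protective stated risk allele: flipped, magnitude ln(1/0.64)
        assert weights["rs10795668"].oriented_flip
        assert weights["rs10795668"].beta == pytest.approx(np.log(1 / 0.64), abs=0.05)

    def test_monomorphic_snp_raises_naming_it(self):
        g = make_matrix(np.zeros((40, 1), dtype=np.int8), rsids=["rs_mono"])
        with pytest.raises(EstimationError, match="rs_mono"):
            estimate_weights(g, np.r_[np.ones(20), np.zeros(20)])

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.full(20, 2)].astype(np.int8)
        y = np.r_[np.zeros(20), np.ones(20)]
        g = make_matrix(x[:, None], rsids=["rs_sep"])
        with pytest.raises(EstimationError, match="rs_sep"):
            estimate_weights(g, y)

    def test_self_consistency_loop(self):
        """Weights estimated from data simulated at the fitted weights
        re-recover them within sampling tolerance."""
        from adenoma_prs.synthetic_data import SimulationConfig, simulate_reference_panel

        cfg1 = SimulationConfig(seed=13, n_ref_cases=4000, n_ref_controls=4000)
        g1, l1 = simulate_reference_panel(cfg1)
        w1 = estimate_weights(g1, l1)
        signed1 = np.array([-w.beta if w.oriented_flip else w.beta for w in w1])
        cfg2 = SimulationConfig(
            seed=14, n_ref_cases=4000, n_ref_controls=4000, odds_ratios=np.exp(signed1)
        )
        g2, l2 = simulate_reference_panel(cfg2)
        w2 = estimate_weights(g2, l2)
        signed2 = np.array([-w.beta if w.oriented_flip else w.beta for w in w2])
        assert np.abs(signed2 - signed1).max() < 4 * 0.035  # ~4 SE at n=4000/4000


class TestComputeScores:
    def test_bounds(self, toy_panel):
        zeros = make_matrix(np.zeros((1, 2), dtype=np.int8), rsids=toy_panel.rsids)
        twos = make_matrix(np.full((1, 2), 2, dtype=np.int8), rsids=toy_panel.rsids)
        (lo,) = compute_scores(zeros, toy_panel)
        (hi,) = compute_scores(twos, toy_panel)
        assert lo.score == 0.0 and lo.risk_allele_count == 0
        assert hi.score == pytest.approx(2 * toy_panel.sum_beta)
        assert hi.risk_allele_count == 4

    def test_study_panel_maximum_is_478(self):
        from adenoma_prs.core_io import STUDY_PANEL

        g = make_matrix(np.full((1, 18), 2, dtype=np.int8), rsids=STUDY_PANEL.rsids)
        (r,) = compute_scores(g, STUDY_PANEL)
        assert r.score == pytest.approx(4.78, abs=1e-9)

    def test_missing_imputed_by_twice_frequency(self):
        panel = SnpPanel((SnpDef("rs1", "1", 1, "A", "G", "G", 0.2, 0.5),))
        g = make_matrix(np.array([[MISSING]], dtype=np.int8), rsids=["rs1"])
        (r,) = compute_scores(g, panel, "impute")
        assert r.score == pytest.approx(0.2 * (2 * 0.5))
        assert r.n_missing == 1

    def test_rescale_policy(self, toy_panel):
        g = make_matrix(np.array([[2, MISSING]], dtype=np.int8), rsids=toy_panel.rsids)
        (r,) = compute_scores(g, toy_panel, "rescale")
        # observed score 0.4 on observed weight 0.2, rescaled by 0.7/0.2
        assert r.score == pytest.approx(0.4 * 0.7 / 0.2)

    def test_omit_policy(self, toy_panel):
        g = make_matrix(np.array([[2, MISSING]], dtype=np.int8), rsids=toy_panel.rsids)
        (r,) = compute_scores(g, toy_panel, "omit")
        assert r.score == pytest.approx(0.4) and r.risk_allele_count == 2

    def test_unknown_policy_rejected(self, toy_panel, toy_matrix):
        with pytest.raises(ValueError, match="policy"):
            compute_scores(toy_matrix, toy_panel, "drop_sample")

    @settings(max_examples=50, deadline=None)
    @given(hst.integers(0, 1), hst.integers(0, 2))
    def test_monotonicity_single_dosage_step(self, snp_idx, start_dose):
        """Raising one dosage by 1 raises the score by exactly that beta."""
        panel = SnpPanel(
            (
                SnpDef("rs1", "1", 1, "A", "G", "G", 0.17, 0.5),
                SnpDef("rs2", "2", 2, "C", "T", "T", 0.31, 0.4),
            )
        )
        if start_dose == 2:
            return
        base = np.array([[1, 1]], dtype=np.int8)
        base[0, snp_idx] = start_dose
        bumped = base.copy()
        bumped[0, snp_idx] += 1
        (r0,) = compute_scores(make_matrix(base, rsids=panel.rsids), panel)
        (r1,) = compute_scores(make_matrix(bumped, rsids=panel.rsids), panel)
        assert r1.score - r0.score == pytest.approx(panel.snps[snp_idx].beta)

    def test_score_is_additive_over_panel_split(self):
        """Score over a concatenated panel equals the sum of sub-panel scores."""
        from adenoma_prs.core_io import STUDY_PANEL

        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(25, 18)).astype(np.int8)
        g = make_matrix(dosage, rsids=STUDY_PANEL.rsids)
        full = compute_scores(g, STUDY_PANEL)
        left = STUDY_PANEL.subset(STUDY_PANEL.rsids[:9])
        right = STUDY_PANEL.subset(STUDY_PANEL.rsids[9:])
        gl = make_matrix(dosage[:, :9], rsids=left.rsids)
        gr = make_matrix(dosage[:, 9:], rsids=right.rsids)
        sl = compute_scores(gl, left)
        sr = compute_scores(gr, right)
        for f, a, b in zip(full, sl, sr):
            assert f.score == pytest.approx(a.score + b.score, abs=1e-12)

    def test_weighted_and_unweighted_correlate(self):
        """Similar-magnitude weights: score and allele count nearly collinear."""
        from adenoma_prs.core_io import STUDY_PANEL
        from adenoma_prs.synthetic_data import SimulationConfig, simulate_study_cohorts

        g, _ = simulate_study_cohorts(SimulationConfig(seed=0, missing_rate=0.0))
        res = compute_scores(g, STUDY_PANEL)
        r = np.corrcoef([x.score for x in res], [x.risk_allele_count for x in res])[0, 1]
        assert r > 0.9


class TestOrientToWeights:
    def test_flip_recodes_dosage_and_panel(self, toy_panel):
        g = make_matrix(np.array([[0, 2], [1, MISSING]], dtype=np.int8), rsids=toy_panel.rsids)
        weights = [
            WeightEstimate("rs1", 0.25, 0.1, False),
            WeightEstimate("rs2", 0.4, 0.1, True),
        ]
        g2, panel2 = orient_to_weights(g, toy_panel, weights)
        assert g2.dosage[:, 1].tolist() == [0, MISSING]
        assert panel2["rs2"].risk_allele == "C"
        assert panel2["rs2"].freq == pytest.approx(0.7)
        assert panel2.betas.tolist() == [0.25, 0.4]
        # original matrix untouched
        assert g.dosage[0, 1] == 2


class TestDistributionStats:
    def _cohort(self, ids, group="MA"):
        return CohortTable(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "group": group,
                    "adenoma_count": pd.array([12] * len(ids), dtype="Int64"),
                    "crc_history": False,
                    "age": 55.0,
                    "sex": "M",
                }
            )
        )

    def test_hand_computed_mean_and_sd(self, toy_panel):
        from adenoma_prs.scoring import ScoreResult

        scores = [ScoreResult("a", 2.0, 10, 0), ScoreResult("b", 3.0, 12, 0)]
        (row,) = score_distribution_stats(scores, self._cohort(["a", "b"]))
        assert row.mean_score == pytest.approx(2.5)
        assert row.sd_score == pytest.approx(np.sqrt(0.5), abs=1e-12)  # 0.7071
        assert row.n == 2

    def test_degenerate_identical_scores_raise(self):
        from adenoma_prs.scoring import ScoreResult

        scores = [ScoreResult("a", 2.0, 10, 0), ScoreResult("b", 2.0, 10, 0)]
        with pytest.raises(ValueError):
            score_distribution_stats(scores, self._cohort(["a", "b"]))

    def test_single_member_group_raises(self):
        from adenoma_prs.scoring import ScoreResult

        with pytest.raises(ValueError, match="fewer than 2"):
            score_distribution_stats(
                [ScoreResult("a", 2.0, 10, 0)], self._cohort(["a"])
            )


class TestWeightsIO:
    def test_round_trip(self, toy_panel, tmp_path):
        weights = [
            WeightEstimate("rs1", 0.123456789012, 0.05, False),
            WeightEstimate("rs2", 0.4, 0.1, True),
        ]
        path = tmp_path / "w.tsv"
        write_weights(weights, toy_panel, path)
        assert read_weights(path) == weights
        # flipped SNP reports the other allele as effective risk allele
        df = pd.read_csv(path, sep="\t")
        assert df.loc[1, "risk_allele"] == "C"
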