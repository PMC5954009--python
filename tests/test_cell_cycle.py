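"""Phase scoring, reference-quantile calibration and phase calls."""

import numpy as np
import pandas as pd
import pytest

from scfate import (
    ExpressionMatrix,
    GenePanel,
    SyntheticConfig,
    calibrate_threshold,
    classify_phase,
    concat_matrices,
    generate_cells,
    max_normalize,
    phase_foldchange,
    phase_scores,
)
from scfate.cell_cycle import PhaseThreshold


def _mk(vals, genes, cells=None):
    cells = cells or [f"c{i}" for i in range(len(vals))]
    return ExpressionMatrix(pd.DataFrame(vals, index=cells, columns=genes))


class TestMaxNormalize:
    def test_linear_scaling(self):
        m = _mk([[0.0], [2.0], [4.0]], ["g1"])
        out = max_normalize(m)
        assert out.values["g1"].tolist() == [0.0, 0.5, 1.0]

    def test_all_zero_gene_stays_zero(self):
        m = _mk([[0.0, 1.0], [0.0, 2.0]], ["dead", "live"])
        out = max_normalize(m)
        assert (out.values["dead"] == 0).all()

    def test_every_detected_gene_reaches_one(self, random_matrix):
        out = max_normalize(random_matrix)
        detected_any = random_matrix.detected.any(axis=0)
        maxima = out.values.max(axis=0)
        assert np.allclose(maxima[detected_any], 1.0)
        assert (out.values.to_numpy() >= 0).all()
        assert (out.values.to_numpy() <= 1.0).all()


class TestPhaseScores:
    @pytest.fixture()
    def tiny_panel(self):
        return GenePanel({"a1": "cc_g1", "a2": "cc_g1",
                          "b1": "cc_sg2m", "b2": "cc_sg2m",
                          "x": "other"})

    def test_extreme_cell_scores(self, tiny_panel):
        # cell0 at per-gene max of both S/G2/M genes and zero G1 expression
        m = _mk([[0.0, 0.0, 4.0, 6.0, 1.0],
                 [2.0, 3.0, 2.0, 3.0, 1.0]],
                ["a1", "a2", "b1", "b2", "x"])
        scores = phase_scores(m, tiny_panel)
        assert scores.loc["c0", "g1_score"] == 0.0
        assert scores.loc["c0", "sg2m_score"] == 1.0
        assert (scores["call"] == "uncalled").all()

    def test_scores_equal_brute_force_recomputation(self, tiny_panel):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 8, (20, 5))
        vals[rng.random((20, 5)) < 0.3] = 0
        m = _mk(vals, ["a1", "a2", "b1", "b2", "x"])
        scores = phase_scores(m, tiny_panel)
        for i, cell in enumerate(m.cell_ids):
            g1 = np.mean([vals[i, j] / vals[:, j].max() for j in (0, 1)])
            sg2m = np.mean([vals[i, j] / vals[:, j].max() for j in (2, 3)])
            assert scores.loc[cell, "g1_score"] == pytest.approx(g1)
            assert scores.loc[cell, "sg2m_score"] == pytest.approx(sg2m)

    def test_normalization_scope_is_whole_cohort(self, tiny_panel):
        m = _mk([[1.0, 1.0, 1.0, 1.0, 0.0],
                 [2.0, 2.0, 2.0, 2.0, 0.0]],
                ["a1", "a2", "b1", "b2", "x"])
        base = phase_scores(m, tiny_panel)
        # appending a duplicate of an existing cell changes no maxima
        dup = concat_matrices(m, _mk([[2.0, 2.0, 2.0, 2.0, 0.0]],
                                     ["a1", "a2", "b1", "b2", "x"], ["c9"]))
        same = phase_scores(dup, tiny_panel)
        assert np.allclose(same.loc[["c0", "c1"], ["g1_score", "sg2m_score"]],
                           base[["g1_score", "sg2m_score"]])
        # appending a new per-gene maximum rescales everyone
        louder = concat_matrices(m, _mk([[4.0, 4.0, 4.0, 4.0, 0.0]],
                                        ["a1", "a2", "b1", "b2", "x"], ["c9"]))
        rescaled = phase_scores(louder, tiny_panel)
        assert rescaled.loc["c0", "g1_score"] == pytest.approx(0.25)

    def test_missing_category_rejected(self):
        m = _mk([[1.0]], ["a1"])
        with pytest.raises(ValueError, match="cc_sg2m"):
            phase_scores(m, GenePanel({"a1": "cc_g1"}))


class TestCalibration:
    def _scores(self, values):
        return pd.DataFrame({"sg2m_score": values,
                             "g1_score": 0.0, "call": "uncalled"},
                            index=[f"r{i}" for i in range(len(values))])

    def test_fraction_one_keeps_all_reference_in_g0g1(self):
        rng = np.random.default_rng(2)
        scores = self._scores(rng.uniform(0, 1, 50))
        th = calibrate_threshold(scores, 1.0)
        assert th.sg2m_cutoff >= scores["sg2m_score"].max()
        called = classify_phase(scores, th)
        assert (called["call"] == "G0G1").all()

    def test_ties_resolved_to_smallest_achieving_cutoff(self):
        rng = np.random.default_rng(3)
        for frac in (0.5, 0.75, 0.9):
            vals = rng.integers(0, 5, 40) / 4.0  # heavy ties
            scores = self._scores(vals)
            th = calibrate_threshold(scores, frac)
            # oracle: exhaustive scan over candidate cutoffs
            candidates = np.unique(vals)
            achieved = [(c, (vals <= c).mean()) for c in candidates]
            best = min(c for c, f in achieved if f >= frac)
            assert th.sg2m_cutoff == pytest.approx(best)

    def test_too_few_reference_cells_rejected(self):
        with pytest.raises(ValueError, match="reference cells"):
            calibrate_threshold(self._scores(np.linspace(0, 1, 9)), 0.9)

    def test_calibration_then_classification_hits_requested_fraction(self):
        rng = np.random.default_rng(4)
        n, frac = 50, 0.8
        scores = self._scores(rng.normal(0.4, 0.1, n))
        th = calibrate_threshold(scores, frac)
        called = classify_phase(scores, th)
        achieved = (called["call"] == "G0G1").mean()
        assert frac <= achieved <= frac + 1.0 / n


class TestClassify:
    def test_tie_goes_to_quiescent_side(self):
        scores = pd.DataFrame({"g1_score": [0.1], "sg2m_score": [0.5],
                               "call": "uncalled"}, index=["c0"])
        th = PhaseThreshold(sg2m_cutoff=0.5, reference_fraction=0.9,
                            reference_n=100)
        assert classify_phase(scores, th)["call"].iloc[0] == "G0G1"

    def test_all_zero_cell_called_g0g1(self, panel):
        genes = panel.genes("cc_g1") + panel.genes("cc_sg2m")
        m = _mk(np.vstack([np.zeros(15), np.ones(15)]), genes)
        scores = phase_scores(m, panel)
        th = PhaseThreshold(0.3, 0.9, 100)
        assert classify_phase(scores, th).loc["c0", "call"] == "G0G1"

    def test_sg2m_call_fraction_monotone_in_generator_phase_fraction(self, panel):
        """More cycling cells in, more S/G2/M calls out (5-point grid)."""
        ref_m, ref_ann = generate_cells(
            SyntheticConfig.reference_hsc(300, seed=41), is_reference=True)
        ref_scores = phase_scores(ref_m, panel)
        th = calibrate_threshold(ref_scores, 0.9)
        called_fracs = []
        for f in [0.1, 0.3, 0.5, 0.7, 0.9]:
            cfg = SyntheticConfig.default(seed=42)
            cfg.populations = ["PreMeg"]
            cfg.cells_per_population = [300]
            cfg.phase_fractions["PreMeg"] = {"G0G1": 1 - f, "SG2M": f}
            m, _ = generate_cells(cfg)
            scores = phase_scores(m, panel)
            called_fracs.append(
                (classify_phase(scores, th)["call"] == "SG2M").mean())
        assert all(b >= a for a, b in zip(called_fracs, called_fracs[1:]))


class TestPhaseFoldchange:
    def _setup(self):
        rng = np.random.default_rng(8)
        panel = GenePanel({"m1": "mep_platelet", "m2": "mep_platelet",
                           "x": "other"})
        vals = rng.uniform(1, 5, (12, 3))
        m = _mk(vals, ["m1", "m2", "x"])
        ann = pd.DataFrame(
            {"population": ["HSC"] * 6 + ["PreMeg"] * 6},
            index=m.cell_ids)
        calls = pd.DataFrame(
            {"call": (["G0G1", "SG2M"] * 6)}, index=m.cell_ids)
        return m, ann, calls, panel

    def test_reference_stratum_is_one(self):
        m, ann, calls, panel = self._setup()
        table = phase_foldchange(m, ann, calls, panel)
        assert table.loc["HSC", "G0G1"] == pytest.approx(1.0)

    def test_doubling_one_stratum_doubles_only_its_fold(self):
        m, ann, calls, panel = self._setup()
        base = phase_foldchange(m, ann, calls, panel)
        stratum = (ann["population"] == "PreMeg") & (calls["call"] == "SG2M")
        m2 = ExpressionMatrix(m.values.copy())
        m2.values.loc[stratum.values, :] *= 2.0
        table = phase_foldchange(m2, ann, calls, panel)
        assert table.loc["PreMeg", "SG2M"] == pytest.approx(
            2 * base.loc["PreMeg", "SG2M"])
        assert table.loc["PreMeg", "G0G1"] == pytest.approx(
            base.loc["PreMeg", "G0G1"])

    def test_matches_brute_force_stratified_means(self):
        m, ann, calls, panel = self._setup()
        table = phase_foldchange(m, ann, calls, panel)
        mep = m.values[["m1", "m2"]].mean(axis=1)
        ref = mep[(ann["population"] == "HSC") & (calls["call"] == "G0G1")].mean()
        for pop in ("HSC", "PreMeg"):
            for ph in ("G0G1", "SG2M"):
                mask = (ann["population"] == pop) & (calls["call"] == ph)
                assert table.loc[pop, ph] == pytest.approx(mep[mask].mean() / ref)

    def test_empty_stratum_warns_nan(self):
        m, ann, calls, panel = self._setup()
        calls.loc[ann["population"] == "PreMeg", "call"] = "G0G1"
        with pytest.warns(UserWarning, match="empty stratum"):
            table = phase_foldchange(m, ann, calls, panel)
        assert np.isnan(table.loc["PreMeg", "SG2M"])
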