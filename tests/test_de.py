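import numpy as np
import pandas as pd
import pytest

from cotarget.de import (
    DEConfig,
    ExpressionMatrix,
    concordant_dependent_genes,
    log2_fold_change,
    replicate_test,
)
from cotarget.simulate import PlantedTruth, SimConfig, generate_annotation, \
    generate_knockdown_expression, plant_dependent_genes, generate_cooccupied_peaks


def matrix(rows: dict[str, list[float]], n_reps=3) -> ExpressionMatrix:
    """rows: gene -> 9 values (ctrl x3, kdA x3, kdB x3)."""
    cols = [f"{c}_{r}" for c in ("control", "kdA", "kdB") for r in range(1, n_reps + 1)]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    conditions = {c: c.rsplit("_", 1)[0] for c in cols}
    return ExpressionMatrix(values, conditions)


class TestFoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change(7.3, 7.3) == 0.0

    def test_exact_power_of_two(self):
        # (4+1)/(9+1) = 1/2
        assert log2_fold_change(4, 9, pseudocount=1.0) == pytest.approx(-1.0)

    def test_double_zero_guarded_by_pseudocount(self):
        assert log2_fold_change(0.0, 0.0, pseudocount=1.0) == 0.0

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 2.0)


class TestReplicateTest:
    def test_identical_groups_p_one(self):
        assert replicate_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_strong_separation(self):
        # Welch t on log2(x+1), worked independently from the t formula:
        # t = 58.076, Welch df = 2.132, two-sided p = 1.8959e-4
        p = replicate_test([10, 10.1, 9.9], [1, 1.1, 0.9])
        assert p == pytest.approx(1.8959e-4, rel=1e-3)
        assert p < 0.001

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            replicate_test([5.0], [1.0, 2.0])

    def test_zero_variance_unequal_means(self):
        assert replicate_test([5.0, 5.0], [2.0, 2.0]) == 0.0


class TestConcordance:
    def test_concordant_down_is_dependent(self):
        expr = matrix({"g1": [40, 42, 38, 9, 10, 11, 10, 9, 11],
                       "null": [20, 21, 19, 20, 19, 21, 21, 20, 19]})
        calls = {c.gene_id: c for c in concordant_dependent_genes(expr)}
        assert calls["g1"].dependent and calls["g1"].direction == "down"
        assert not calls["null"].dependent and calls["null"].direction is None

    def test_discordant_directions_rejected(self):
        expr = matrix({"g1": [20, 21, 19, 45, 44, 46, 9, 10, 11]})
        (call,) = concordant_dependent_genes(expr)
        assert not call.dependent

    def test_subthreshold_fold_change_rejected_despite_tiny_p(self):
        # ~1.38-fold with pseudocount: below the >1.5 gate
        expr = matrix({"g1": [30, 30.1, 29.9, 21.4, 21.5, 21.3, 21.5, 21.4, 21.6]})
        (call,) = concordant_dependent_genes(expr)
        assert call.p_a < 0.001 and call.p_b < 0.001
        assert not call.dependent

    def test_missing_condition_rejected(self):
        values = pd.DataFrame({"control_1": [1.0], "control_2": [1.0],
                               "kdA_1": [1.0], "kdA_2": [1.0]}, index=["g1"])
        conditions = {c: c.rsplit("_", 1)[0] for c in values.columns}
        with pytest.raises(ValueError, match="two knockdown"):
            concordant_dependent_genes(ExpressionMatrix(values, conditions))

    def test_hairpin_relabeling_symmetry(self):
        rng = np.random.default_rng(8)
        rows = {f"g{i}": list(rng.lognormal(3, 0.5, 9)) for i in range(40)}
        expr = matrix(rows)
        swapped_conditions = {
            c: {"kdA": "kdB", "kdB": "kdA"}.get(cond, cond)
            for c, cond in expr.conditions.items()
        }
        swapped = ExpressionMatrix(expr.values, swapped_conditions)
        dep1 = {c.gene_id for c in concordant_dependent_genes(expr) if c.dependent}
        dep2 = {c.gene_id for c in concordant_dependent_genes(swapped) if c.dependent}
        assert dep1 == dep2

    def test_dependent_set_monotone_in_thresholds(self):
        rng = np.random.default_rng(13)
        rows = {}
        for i in range(60):
            base = rng.lognormal(3, 0.8)
            fold = rng.uniform(1.0, 4.0)
            ctrl = base * rng.lognormal(0, 0.2, 3)
            kd = (base / fold) * rng.lognormal(0, 0.2, 6)
            rows[f"g{i}"] = list(np.concatenate([ctrl, kd]))
        expr = matrix(rows)

        def dep(fc, alpha):
            calls = concordant_dependent_genes(expr, DEConfig(fc, alpha))
            return {c.gene_id for c in calls if c.dependent}

        assert dep(2.0, 0.05) <= dep(1.5, 0.05) <= dep(1.2, 0.05)
        assert dep(1.5, 0.01) <= dep(1.5, 0.05) <= dep(1.5, 0.2)

    def test_transcript_collapse_sums_per_gene(self):
        cols = [f"{c}_{r}" for c in ("control", "kdA", "kdB") for r in (1, 2)]
        values = pd.DataFrame(
            [[1.0] * 6, [2.0] * 6, [5.0] * 6],
            index=["tx1", "tx2", "tx3"], columns=cols,
        )
        conditions = {c: c.rsplit("_", 1)[0] for c in cols}
        em = ExpressionMatrix(values, conditions)
        collapsed = em.collapse_transcripts({"tx1": "gA", "tx2": "gA", "tx3": "gB"})
        assert collapsed.values.loc["gA"].tolist() == [3.0] * 6
        assert collapsed.values.loc["gB"].tolist() == [5.0] * 6


class TestPlantedPower:
    @pytest.mark.parametrize("seed", [101, 202])
    def test_sensitivity_and_false_positive_rate(self, seed):
        """Planted 3-fold effects (CV 20%, n=3) are recovered at >=90%
        sensitivity with a false-positive rate within 2x the alpha gate."""
        cfg = SimConfig(seed=seed, n_genes=400, n_bound_genes=200,
                        n_planted_activated=40, n_planted_repressed=40,
                        n_dependent_unbound=20)
        annotation = generate_annotation(cfg)
        *_rest, truth = generate_cooccupied_peaks(cfg, annotation)
        truth = plant_dependent_genes(cfg, annotation, truth)
        expr = generate_knockdown_expression(cfg, annotation, truth)
        calls = {c.gene_id: c for c in concordant_dependent_genes(expr)}

        planted = set(truth.dependent_genes)
        nulls = set(expr.genes) - planted
        hit = [g for g in planted if calls[g].dependent
               and calls[g].direction == truth.dependent_genes[g]]
        fp = [g for g in nulls if calls[g].dependent]
        assert len(hit) / len(planted) >= 0.9
        assert len(fp) / len(nulls) <= 2 * DEConfig().alpha

    def test_null_effect_gives_alpha_level_calls(self):
        """With effect_fold -> 1 (no planted effect), dependent-call rate on
        planted genes collapses to chance level."""
        cfg = SimConfig(seed=5, n_genes=300, n_bound_genes=150,
                        n_planted_activated=30, n_planted_repressed=30,
                        n_dependent_unbound=0, effect_fold=1.0 + 1e-9)
        annotation = generate_annotation(cfg)
        *_rest, truth = generate_cooccupied_peaks(cfg, annotation)
        truth = plant_dependent_genes(cfg, annotation, truth)
        expr = generate_knockdown_expression(cfg, annotation, truth)
        calls = concordant_dependent_genes(expr)
        rate = sum(c.dependent for c in calls) / len(calls)
        # both-hairpin concordance at alpha=0.05 plus the FC gate: well below alpha
        assert rate <= 0.05


class TestExpressionIO:
    def test_tsv_and_sidecar_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        rows = {f"g{i}": list(rng.lognormal(2, 1, 9)) for i in range(10)}
        expr = matrix(rows)
        expr.write_tsv(tmp_path / "e.tsv", tmp_path / "d.yaml")
        back = ExpressionMatrix.read_tsv(tmp_path / "e.tsv", tmp_path / "d.yaml")
        assert back.conditions == expr.conditions
        pd.testing.assert_frame_equal(back.values, expr.values, rtol=1e-5)

    def test_negative_rpkm_rejected(self):
        values = pd.DataFrame({"control_1": [-1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(values, {"control_1": "control"})
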