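"""CE scoring, deterministic ranking, quantile selection and stratification."""

import numpy as np
import pandas as pd
import pytest

from cerank.ce_rank import (
    QuantileRule,
    ce_scores,
    rank_from_matrix,
    rank_molecules,
    select_top_quantile,
    stratified_rank,
)
from cerank.evidence_model import DetectionMatrix, EvidenceLayer, build_detection_matrix
from cerank.pipeline import prioritize
from cerank.scoring import score_all_layers


def loop_oracle(matrix: DetectionMatrix, weights: dict) -> dict:
    """Per-molecule brute-force weighted mean, independent of the vectorized path."""
    total = sum(weights[l] for l in matrix.layers)
    out = {}
    for mol in matrix.molecules:
        s = 0.0
        for layer in matrix.layers:
            s += weights[layer] * int(matrix.data.loc[layer, mol])
        out[mol] = s / total
    return out


def random_matrix(rng, n_layers, n_molecules, density=0.1):
    values = (rng.random((n_layers, n_molecules)) < density).astype(np.int8)
    frame = pd.DataFrame(
        values,
        index=[f"l{i}" for i in range(n_layers)],
        columns=[f"m{j}" for j in range(n_molecules)],
    )
    return DetectionMatrix(frame)


class TestCEScores:
    def test_full_and_zero_support_attain_bounds(self):
        layers = [
            EvidenceLayer("l1", "s", "expression", frozenset({"ALL", "SOME"})),
            EvidenceLayer("l2", "s", "expression", frozenset({"ALL"})),
        ]
        m = build_detection_matrix(layers, ["ALL", "SOME", "NONE"])
        scores = ce_scores(m, {"l1": 0.9, "l2": 0.6})
        assert scores["ALL"] == pytest.approx(1.0)
        assert scores["SOME"] == pytest.approx(0.9 / 1.5)
        assert "NONE" not in scores  # never detected: no column

    def test_hand_computed_weighted_mean(self):
        layers = [
            EvidenceLayer("l1", "s", "expression", frozenset({"X"})),
            EvidenceLayer("l2", "s", "expression", frozenset({"X"})),
            EvidenceLayer("l3", "s", "expression", frozenset({"Y"})),
        ]
        m = build_detection_matrix(layers, ["X", "Y"])
        scores = ce_scores(m, {"l1": 1.0, "l2": 0.8, "l3": 0.5})
        assert scores["X"] == pytest.approx(1.8 / 2.3)

    def test_missing_weight_and_zero_total_are_errors(self):
        layers = [EvidenceLayer("l1", "s", "expression", frozenset({"X"}))]
        m = build_detection_matrix(layers, ["X"])
        with pytest.raises(KeyError):
            ce_scores(m, {})
        with pytest.raises(ValueError, match="positive"):
            ce_scores(m, {"l1": 0.0})

    def test_matches_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = random_matrix(rng, int(rng.integers(2, 30)), int(rng.integers(2, 60)))
            weights = {l: float(rng.uniform(0.5, 1.0)) for l in m.layers}
            expected = loop_oracle(m, weights)
            got = ce_scores(m, weights)
            for mol, val in expected.items():
                assert got[mol] == pytest.approx(val, abs=1e-12)

    def test_uniform_weights_reduce_to_vote_fraction(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 20, 40, density=0.3)
        scores = ce_scores(m, {l: 0.7 for l in m.layers})
        counts = m.detection_counts()
        for mol in m.molecules:
            assert scores[mol] == pytest.approx(counts[mol] / 20)

    def test_adding_a_detection_never_lowers_score(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 15, 20, density=0.2)
        weights = {l: float(rng.uniform(0.5, 1.0)) for l in m.layers}
        scores = ce_scores(m, weights)
        mol = m.molecules[0]
        layer_off = next(l for l in m.layers if m.data.loc[l, mol] == 0)
        bumped = m.data.copy()
        bumped.loc[layer_off, mol] = 1
        assert ce_scores(DetectionMatrix(bumped), weights)[mol] > scores[mol]


class TestRanking:
    def test_tie_break_by_count_then_identifier(self):
        ranked = rank_molecules(
            {"A": 0.5, "B": 0.5, "C": 0.2, "X": 0.2, "Y": 0.2},
            detection_counts={"A": 3, "B": 2, "X": 1, "Y": 1},
        )
        assert [r.molecule for r in ranked] == ["A", "B", "X", "Y", "C"]
        assert [r.rank for r in ranked] == [1, 2, 3, 4, 5]

    def test_singleton_ranks_first(self):
        assert rank_molecules({"only": 0.1})[0].rank == 1

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_molecules({})


class TestQuantile:
    @pytest.mark.parametrize(
        "n, q, expected", [(7895, 0.995, 40), (200, 0.995, 1), (1000, 0.95, 50)]
    )
    def test_selected_count(self, n, q, expected):
        assert QuantileRule(q).selected_count(n) == expected

    def test_selection_takes_ranking_prefix(self):
        ranked = rank_molecules({f"m{i}": 1.0 - i / 100 for i in range(100)})
        top = select_top_quantile(ranked, 0.95)
        assert [r.molecule for r in top] == [f"m{i}" for i in range(5)]

    def test_invalid_quantile_rejected(self):
        ranked = rank_molecules({"a": 0.5})
        with pytest.raises(ValueError):
            select_top_quantile(ranked, 1.0)


class TestStratification:
    def test_multi_class_study_appears_in_both_strata(self, tiny_studies, tiny_layers):
        weighted, _ = score_all_layers(tiny_studies, tiny_layers)
        result = prioritize(tiny_studies, tiny_layers)
        weights = result.weights
        # hex1 carries {listening, practice}: its molecules rank in both
        for cls in ("listening", "practice"):
            strat = stratified_rank(tiny_studies, result.layers, result.matrix, weights, cls)
            assert "cortisol" in {r.molecule for r in strat}

    def test_molecule_absent_without_subset_support(self, tiny_studies, tiny_layers):
        result = prioritize(tiny_studies, tiny_layers)
        listening = stratified_rank(
            tiny_studies, result.layers, result.matrix, result.weights, "listening"
        )
        # SNCA is detected only by hgm1 (ability): absent from listening stratum
        assert "SNCA" not in {r.molecule for r in listening}

    def test_single_class_database_reduces_to_global_ranking(self, tiny_studies, tiny_layers):
        import dataclasses

        mono = [
            dataclasses.replace(s, phenotype_classes=frozenset({"practice"}))
            for s in tiny_studies
        ]
        result = prioritize(mono, tiny_layers)
        strat = stratified_rank(mono, result.layers, result.matrix, result.weights, "practice")
        assert [(r.molecule, r.rank, r.score) for r in strat] == [
            (r.molecule, r.rank, r.score) for r in result.ranking
        ]

    def test_empty_class_is_an_error(self, tiny_studies, tiny_layers):
        result = prioritize(tiny_studies, tiny_layers)
        import dataclasses

        no_listening = [
            dataclasses.replace(s, phenotype_classes=frozenset({"ability"}))
            for s in tiny_studies
        ]
        with pytest.raises(ValueError, match="listening"):
            stratified_rank(no_listening, result.layers, result.matrix, result.weights, "listening")

    def test_subset_denominator_recomputed(self, tiny_studies, tiny_layers):
        result = prioritize(tiny_studies, tiny_layers)
        strat = stratified_rank(
            tiny_studies, result.layers, result.matrix, result.weights, "ability"
        )
        # ability stratum = hgm1's two layers only; EGR1 detected in 1 of 2
        w_assoc = result.weights["hgm1:association:1"]
        w_link = result.weights["hgm1:linkage:1"]
        egr1 = next(r for r in strat if r.molecule == "EGR1")
        assert egr1.score == pytest.approx(w_assoc / (w_assoc + w_link))
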