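import numpy as np
import pandas as pd
import pytest

from droughtdex.expression import ExpressionMatrix, SampleDesign, normalize, aggregate_isoforms
from droughtdex.selection import (
    SelectionConfig,
    SelectionError,
    round1_filter,
    round2_rank,
    round3_confirm,
    select_stable_genes,
    run_pipeline,
)
from droughtdex.simulate import SimConfig, simulate_experiment, simulate_orthogonal


CFG = SelectionConfig()


def _null_row():
    return (10.0, 10.0, 0.0, 0.9, 0.95)


class TestRound1:
    def test_definition_case_selected_up(self, de_table_factory):
        day0 = de_table_factory({"g1": (10, 10, 0.1, 0.8, 0.9)})
        t06 = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        t010 = de_table_factory({"g1": _null_row()})
        x6 = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        x10 = de_table_factory({"g1": _null_row()})
        out = round1_filter(day0, t06, t010, x6, x10, CFG)
        assert out["up"] == ["g1"] and out["down"] == []

    def test_day0_difference_excludes(self, de_table_factory):
        day0 = de_table_factory({"g1": (50, 10, 2.3, 0.001, 0.002)})
        strong = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        out = round1_filter(day0, strong, strong, strong, strong, CFG)
        assert out["up"] == [] and out["down"] == []

    def test_equivalence_needs_small_fold_change_too(self, de_table_factory):
        # insignificant day-0 p but a large day-0 fold change fails equivalence
        day0 = de_table_factory({"g1": (40, 10, 2.0, 0.2, 0.4)})
        strong = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        out = round1_filter(day0, strong, strong, strong, strong, CFG)
        assert out["up"] == []

    def test_conflicting_day_signs_ambiguous(self, de_table_factory):
        day0 = de_table_factory({"g1": (10, 10, 0.1, 0.8, 0.9)})
        temp = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        x6 = de_table_factory({"g1": (80, 10, 3.0, 0.0005, 0.001)})
        x10 = de_table_factory({"g1": (2, 20, -3.0, 0.0005, 0.001)})
        out = round1_filter(day0, temp, temp, x6, x10, CFG)
        assert out["ambiguous"] == ["g1"]
        assert out["up"] == [] and out["down"] == []

    def test_mismatched_universes_rejected(self, de_table_factory):
        t1 = de_table_factory({"g1": _null_row()})
        t2 = de_table_factory({"g2": _null_row()})
        with pytest.raises(SelectionError, match="universe"):
            round1_filter(t1, t2, t1, t1, t1, CFG)


def _gene_matrix_and_design(gene_means: dict[str, dict[tuple[str, int], float]]):
    """Constant-replicate gene matrix over 2 cultivars x 3 days x 2 reps."""
    cultivars = [("A", "tolerant"), ("B", "sensitive")]
    rows, cols = {}, []
    design_rows = []
    for cultivar, cls in cultivars:
        for day in (0, 6, 10):
            for rep in (1, 2):
                sid = f"{cultivar}_{day}_{rep}"
                cols.append(sid)
                design_rows.append(
                    {"sample_id": sid, "cultivar": cultivar, "pair_id": "P1",
                     "tolerance_class": cls, "day": day, "replicate": rep}
                )
    frame = pd.DataFrame(
        {sid: [gene_means[g][(sid.split("_")[0], int(sid.split("_")[1]))] for g in gene_means]
         for sid in cols},
        index=list(gene_means),
    )
    m = ExpressionMatrix(frame, normalized=True, norm_method="cpm")
    return m, SampleDesign(pd.DataFrame(design_rows))


class TestStableGenes:
    def test_flat_gene_is_stable(self):
        means = {"g1": {(c, d): 50.0 for c in "AB" for d in (0, 6, 10)}}
        m, design = _gene_matrix_and_design(means)
        assert select_stable_genes(m, design) == ["g1"]

    def test_boundary_ratio_excluded_strictly(self):
        # pseudocounted ratio hits exactly 1.2 on one cell -> excluded
        means = {"g1": {(c, d): 9.5 for c in "AB" for d in (0, 6, 10)}}
        means["g1"][("A", 6)] = 11.5  # (11.5+0.5)/(9.5+0.5) = 1.2
        m, design = _gene_matrix_and_design(means)
        assert select_stable_genes(m, design) == []

    def test_ratios_inside_window_stable(self):
        rng = np.random.default_rng(0)
        means = {}
        for i in range(20):
            base = 100.0
            cell = {}
            for c in "AB":
                cell[(c, 0)] = base
                for d in (6, 10):
                    cell[(c, d)] = base * rng.uniform(0.92, 1.08)
            means[f"g{i:02d}"] = cell
        m, design = _gene_matrix_and_design(means)
        assert select_stable_genes(m, design) == sorted(means)

    def test_zero_day0_mean_excluded(self):
        means = {"g1": {(c, d): 0.0 if (c, d) == ("A", 0) else 50.0
                        for c in "AB" for d in (0, 6, 10)}}
        # force day-0 zero mean in cultivar A only
        means["g1"][("A", 0)] = 0.0
        m, design = _gene_matrix_and_design(means)
        assert select_stable_genes(m, design) == []


class TestRound2:
    def test_top_k_by_score(self, de_table_factory):
        x6 = de_table_factory({"g1": (170, 10, 4.0, 1e-5, 1e-4), "g2": (21, 10, 1.0, 0.01, 0.02)})
        x10 = de_table_factory({"g1": _null_row(), "g2": _null_row()})
        assert round2_rank(["g1", "g2"], x6, x10, CFG, k=1) == ["g1"]

    def test_k_larger_than_input_sorts_all(self, de_table_factory):
        x6 = de_table_factory({"g1": (170, 10, 4.0, 1e-5, 1e-4), "g2": (21, 10, 1.0, 0.01, 0.02)})
        x10 = de_table_factory({"g1": _null_row(), "g2": _null_row()})
        assert round2_rank(["g2", "g1"], x6, x10, CFG, k=10) == ["g1", "g2"]

    def test_tie_broken_by_smaller_q(self, de_table_factory):
        x6 = de_table_factory({"g1": (80, 10, 3.0, 0.01, 0.05), "g2": (80, 10, 3.0, 0.001, 0.004)})
        x10 = de_table_factory({"g1": _null_row(), "g2": _null_row()})
        assert round2_rank(["g1", "g2"], x6, x10, CFG, k=2) == ["g2", "g1"]

    def test_nonpositive_k_rejected(self, de_table_factory):
        x6 = de_table_factory({"g1": _null_row()})
        with pytest.raises(SelectionError, match="positive"):
            round2_rank(["g1"], x6, x6, CFG, k=0)

    def test_empty_input_empty_output(self, de_table_factory):
        x6 = de_table_factory({"g1": _null_row()})
        assert round2_rank([], x6, x6, CFG) == []


class TestRound3:
    def _profiles(self, entries):
        return pd.DataFrame.from_dict(entries, orient="index", columns=[6, 10])

    def test_matching_directions_confirmed(self):
        rna = self._profiles({"g1": ["up", "up"]})
        pcr = self._profiles({"g1": ["up", "up"]})
        assert round3_confirm(["g1"], rna, pcr)["confirmed"] == ["g1"]

    def test_one_day_disagreement_rejected(self):
        rna = self._profiles({"g1": ["up", "up"]})
        pcr = self._profiles({"g1": ["up", "down"]})
        assert round3_confirm(["g1"], rna, pcr)["confirmed"] == []

    def test_zero_change_orthogonal_rejected(self):
        rna = self._profiles({"g1": ["up", "up"]})
        pcr = self._profiles({"g1": ["none", "none"]})
        assert round3_confirm(["g1"], rna, pcr)["confirmed"] == []

    def test_missing_profile_dropped_with_warning(self):
        rna = self._profiles({"g1": ["up", "up"]})
        pcr = self._profiles({"gX": ["up", "up"]})
        with pytest.warns(UserWarning, match="g1"):
            out = round3_confirm(["g1"], rna, pcr)
        assert out["confirmed"] == [] and out["missing_orthogonal"] == ["g1"]


@pytest.fixture(scope="module")
def pipeline_run(small_experiment, small_orthogonal):
    _, matrix, tmap, design, truth = small_experiment
    report = run_pipeline(matrix, design, tmap, small_orthogonal, seed=7)
    return report, truth


class TestPipeline:
    def test_round_nesting(self, pipeline_run):
        report, _ = pipeline_run
        for pair in report.pairs.values():
            assert set(pair.round3) <= set(pair.round2) <= set(pair.round1)
            assert not (set(pair.round1_up) & set(pair.round1_down))
            assert len(pair.round1_up) + len(pair.round1_down) == len(pair.round1)

    def test_shared_gene_counted_once_in_union(self, small_experiment, small_orthogonal):
        # keep every round-1 gene through ranking so the gene planted in both
        # pairs reaches both final rounds and must be de-duplicated in the union
        _, matrix, tmap, design, truth = small_experiment
        report = run_pipeline(
            matrix, design, tmap, small_orthogonal,
            cfg=SelectionConfig(round2_fraction=1.0), seed=7,
        )
        shared = set(truth.table.index[truth.table["shared"]])
        per_pair = [set(p.round3) for p in report.pairs.values()]
        union = set(report.overall_selected)
        assert union == set().union(*per_pair)
        both = per_pair[0] & per_pair[1]
        assert shared <= both
        assert len(union) == sum(len(s) for s in per_pair) - len(both)

    def test_stable_set_disjoint_from_round1(self, pipeline_run):
        report, _ = pipeline_run
        stable = set(report.stable_genes)
        for pair in report.pairs.values():
            assert not (stable & set(pair.round1))

    def test_planted_stable_genes_recovered(self, pipeline_run):
        report, truth = pipeline_run
        assert set(truth.genes("stable")) <= set(report.stable_genes)

    def test_deterministic_reports(self, small_experiment, small_orthogonal):
        _, matrix, tmap, design, _ = small_experiment
        r1 = run_pipeline(matrix, design, tmap, small_orthogonal, seed=7)
        r2 = run_pipeline(matrix, design, tmap, small_orthogonal, seed=7)
        assert r1.to_json() == r2.to_json()

    def test_sample_order_invariance(self, small_experiment, small_orthogonal):
        _, matrix, tmap, design, _ = small_experiment
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.data.columns)
        shuffled = ExpressionMatrix(matrix.data[perm], level=matrix.level)
        shuffled_design = SampleDesign(
            design.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        r1 = run_pipeline(matrix, design, tmap, small_orthogonal, seed=7)
        r2 = run_pipeline(shuffled, shuffled_design, tmap, small_orthogonal, seed=7)
        assert r1.to_json() == r2.to_json()

    def test_empty_candidate_set_is_valid(self):
        cfg = SimConfig(n_genes=150, n_responsive=2, n_stable=2, n_shared=0,
                        responsive_log2fc=0.0, seed=5)
        matrix, tmap, design, truth = simulate_experiment(cfg)
        strict = SelectionConfig(alpha=1e-12)
        report = run_pipeline(matrix, design, tmap, None, cfg=strict, seed=5)
        for pair in report.pairs.values():
            assert pair.round1 == [] and pair.round2 == [] and pair.round3 == []
        assert report.overall_selected == []

    def test_mismatched_design_rejected(self, small_experiment):
        _, matrix, tmap, design, _ = small_experiment
        bad = design.table.copy()
        bad.loc[0, "sample_id"] = "ghost_sample"
        with pytest.raises(SelectionError, match="absent"):
            run_pipeline(matrix, SampleDesign(bad), tmap, None)


class TestConfig:
    def test_alpha_bounds(self):
        with pytest.raises(SelectionError):
            SelectionConfig(alpha=0.0)

    def test_window_must_bracket_one(self):
        with pytest.raises(SelectionError):
            SelectionConfig(stable_low=1.1, stable_high=1.2)
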