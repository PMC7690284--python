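"""Assay normalization: array quantification, ΔΔCt, delta gMFI, migration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypoxiaquant.assays import (
    CytokineRecord,
    correct_migration,
    delta_gmfi,
    filter_candidates,
    fold_induction,
    qpcr_relative_expression,
    quantify_membrane,
)
from hypoxiaquant.errors import LayoutError, ValidationError
from hypoxiaquant.phantoms import ArrayLayout, generate_array_table


def make_grid(spot_map, pos=(1000.0, 1000.0), neg=(0.0, 0.0)):
    rows = []
    for analyte, intensities in spot_map.items():
        for rep, val in enumerate(intensities):
            rows.append((analyte, rep, val, False, False))
    for rep, val in enumerate(pos):
        rows.append(("POS", rep, val, True, False))
    for rep, val in enumerate(neg):
        rows.append(("NEG", rep, val, False, True))
    return pd.DataFrame(rows, columns=["analyte", "replicate", "intensity",
                                       "is_pos_ctrl", "is_neg_ctrl"])


class TestQuantifyMembrane:
    def test_spot_at_positive_control_normalizes_to_one(self):
        out = quantify_membrane(make_grid({"A": (1000.0, 1000.0)}))
        assert np.allclose(out["normalized"], 1.0)

    def test_spot_at_negative_control_normalizes_to_zero(self):
        out = quantify_membrane(make_grid({"A": (50.0, 50.0)}, neg=(50.0, 50.0)))
        assert np.allclose(out["normalized"], 0.0)

    def test_random_grid_matches_direct_recompute(self, rng):
        vals = rng.uniform(10, 900, size=4)
        out = quantify_membrane(make_grid({"A": vals[:2], "B": vals[2:]},
                                          pos=(800.0, 900.0), neg=(20.0, 40.0)))
        expected = np.clip((vals - 30.0) / (850.0 - 30.0), 0, None)
        assert np.allclose(np.sort(out["normalized"]), np.sort(expected))

    def test_affine_rescaling_invariance(self, rng):
        """A common gain/offset on all raw intensities cancels out."""
        grid = make_grid({"A": (300.0, 350.0)}, pos=(900.0, 950.0), neg=(10.0, 30.0))
        out1 = quantify_membrane(grid)
        grid2 = grid.assign(intensity=grid.intensity * 3.7 + 12.0)
        out2 = quantify_membrane(grid2)
        assert np.allclose(out1["normalized"], out2["normalized"])

    def test_unusable_membrane_rejected(self):
        with pytest.raises(ValidationError):
            quantify_membrane(make_grid({"A": (1.0, 2.0)}, pos=(5.0, 5.0), neg=(9.0, 9.0)))

    def test_missing_controls_rejected(self):
        grid = make_grid({"A": (1.0, 2.0)})
        with pytest.raises(LayoutError):
            quantify_membrane(grid[~grid.is_pos_ctrl])


class TestFoldInduction:
    def test_identical_membranes_fold_one_p_large(self):
        m = quantify_membrane(make_grid({"A": (200.0, 220.0)}))
        recs = fold_induction(m, m.copy())
        assert recs[0].fold_induction == pytest.approx(1.0)
        assert recs[0].p_value >= 0.5

    def test_noiseless_generator_fold_recovered_exactly(self):
        layout = ArrayLayout(base_intensity={"X": 250.0, "Y": 125.0})
        table = generate_array_table(layout, {"X": 4.0}, noise_sd=0.0)
        hps = quantify_membrane(table[table.membrane == "HPS"])
        nps = quantify_membrane(table[table.membrane == "NPS"])
        recs = {r.analyte: r for r in fold_induction(hps, nps)}
        assert recs["X"].fold_induction == pytest.approx(4.0)
        assert recs["Y"].fold_induction == pytest.approx(1.0)

    def test_t_statistic_matches_closed_form(self, rng):
        """Pooled-variance unpaired t with one-tailed p, 3v3 replicates."""
        h = rng.normal(2.0, 0.3, 3)
        n = rng.normal(1.0, 0.3, 3)
        hps = pd.DataFrame({"analyte": "A", "replicate": range(3), "normalized": h})
        nps = pd.DataFrame({"analyte": "A", "replicate": range(3), "normalized": n})
        rec = fold_induction(hps, nps)[0]
        sp2 = (2 * h.var(ddof=1) + 2 * n.var(ddof=1)) / 4
        t = (h.mean() - n.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert rec.p_value == pytest.approx(float(stats.t.sf(t, df=4)), rel=1e-10)

    def test_mismatched_analyte_sets_rejected(self):
        a = pd.DataFrame({"analyte": ["A"], "replicate": [0], "normalized": [1.0]})
        b = pd.DataFrame({"analyte": ["B"], "replicate": [0], "normalized": [1.0]})
        with pytest.raises(ValidationError):
            fold_induction(a, b)


class TestFilterCandidates:
    def _rec(self, analyte, p=0.01, fold=3.0, mw=60.0):
        return CytokineRecord(analyte, 1.0, fold, fold, p, mw)

    def test_passing_candidate_retained(self):
        assert filter_candidates([self._rec("A", mw=65.0)], {"A"}) == ["A"]

    def test_small_protein_excluded_by_size(self):
        assert filter_candidates([self._rec("A", mw=12.0)], {"A"}) == []

    def test_mw_endpoints_inclusive(self):
        recs = [self._rec("A", mw=30.0), self._rec("B", mw=100.0)]
        assert filter_candidates(recs, {"A", "B"}) == ["A", "B"]

    def test_requires_qpcr_confirmation(self):
        assert filter_candidates([self._rec("A")], set()) == []

    def test_monotone_in_alpha_and_mw_window(self, rng):
        recs = [self._rec(f"C{i}", p=rng.uniform(0, 0.2), fold=rng.uniform(0.5, 5),
                          mw=rng.uniform(5, 150)) for i in range(30)]
        confirmed = {r.analyte for r in recs if rng.random() < 0.7}
        narrow = set(filter_candidates(recs, confirmed, 30, 100, 0.05))
        wide = set(filter_candidates(recs, confirmed, 20, 120, 0.10))
        assert narrow <= wide


class TestQpcr:
    def _table(self, gene_folds, n_per_arm=3, ct_ref=18.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gene, fold in gene_folds.items():
            for cond in ("control", "treated"):
                for i in range(n_per_arm):
                    dct = rng.uniform(3, 8) if cond == "control" else None
                    rows.append((f"{cond}{i}", gene, 0.0, ct_ref, cond))
        df = pd.DataFrame(rows, columns=["sample", "gene", "ct_target", "ct_reference",
                                         "condition"])
        # program ΔΔCt = −log2(fold) on top of a per-gene control ΔCt of 5
        for gene, fold in gene_folds.items():
            sel_c = (df.gene == gene) & (df.condition == "control")
            sel_t = (df.gene == gene) & (df.condition == "treated")
            df.loc[sel_c, "ct_target"] = ct_ref + 5.0
            df.loc[sel_t, "ct_target"] = ct_ref + 5.0 - math.log2(fold)
        return df

    def test_zero_ddct_gives_fold_one(self):
        folds = qpcr_relative_expression(self._table({"G": 1.0}))
        assert folds["G"] == pytest.approx(1.0)

    def test_ddct_minus_one_gives_fold_two(self):
        folds = qpcr_relative_expression(self._table({"G": 2.0}))
        assert folds["G"] == pytest.approx(2.0)

    def test_programmed_folds_roundtrip_to_machine_precision(self):
        targets = {"A": 0.25, "B": 1.0, "C": 2.0, "D": 8.0}
        folds = qpcr_relative_expression(self._table(targets))
        for gene, f in targets.items():
            assert folds[gene] == pytest.approx(f, rel=1e-12)

    def test_random_table_matches_independent_recompute(self, rng):
        df = pd.DataFrame({
            "sample": [f"s{i}" for i in range(6)],
            "gene": "G",
            "ct_target": rng.uniform(20, 30, 6),
            "ct_reference": rng.uniform(15, 20, 6),
            "condition": ["control"] * 3 + ["treated"] * 3,
        })
        fold = qpcr_relative_expression(df)["G"]
        dct = df.ct_target - df.ct_reference
        ddct = dct[3:].mean() - dct[:3].mean()
        assert fold == pytest.approx(2.0 ** (-ddct))

    def test_missing_reference_dropped_with_warning(self):
        df = self._table({"G": 2.0})
        df.loc[0, "ct_reference"] = np.nan
        with pytest.warns(UserWarning):
            qpcr_relative_expression(df)


class TestDeltaGmfi:
    def test_identical_distributions_give_zero(self):
        x = np.array([1.0, 2.0, 4.0])
        assert delta_gmfi(x, x) == pytest.approx(0.0)

    def test_worked_example(self):
        assert delta_gmfi([2.0, 8.0], [1.0, 1.0]) == pytest.approx(3.0)

    def test_lognormal_samples_match_oracle(self, rng):
        s = rng.lognormal(2.0, 0.5, 200)
        i = rng.lognormal(1.0, 0.5, 200)
        expected = stats.gmean(s) - stats.gmean(i)
        assert delta_gmfi(s, i) == pytest.approx(expected)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValidationError):
            delta_gmfi([1.0, 0.0], [1.0])


class TestCorrectMigration:
    def test_identical_curves_cancel(self):
        t = np.arange(0, 180, 2.0)
        s = np.sin(t / 30.0) + 2
        out = correct_migration(t, s, s)
        assert np.allclose(out["corrected_signal"], 0.0)

    def test_constant_offset_preserved(self):
        t = np.arange(0, 10, 2.0)
        out = correct_migration(t, np.full_like(t, 7.0), np.full_like(t, 4.0))
        assert np.allclose(out["corrected_signal"], 3.0)

    def test_random_curves_match_elementwise_oracle(self, rng):
        t = np.arange(0, 180, 2.0)
        w, wo = rng.random(t.size), rng.random(t.size)
        out = correct_migration(t, w, wo)
        assert np.allclose(out["corrected_signal"], [a - b for a, b in zip(w, wo)])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValidationError):
            correct_migration([0, 2], [1.0, 2.0, 3.0], [0.0, 0.0])
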