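"""Filters and normalized sum-of-ranks ordering against hand enumeration."""

import numpy as np
import pandas as pd
import pytest

from molmoo.triage import (FilterSpec, apply_filters, export_top_k,
                           rank_sum_of_ranks)


@pytest.fixture
def candidates():
    # hand-built 10-candidate table; expected survivors worked out by hand
    return pd.DataFrame({
        "smiles": [f"M{i}" for i in range(10)],
        "logP":    [2.0, 6.0, -1.0, 3.5, 2.0, 5.6, -0.4, 2.0, 4.0, 1.0],
        "SAS":     [2.5, 2.0, 2.0, 3.0, 3.1, 2.9, 1.5, 2.0, 2.5, np.nan],
        "binding": [-8.0, -9.0, -8.5, -7.1, -8.0, -7.0, -7.2, -6.0, -7.5, -8.0],
    })


class TestFilters:
    def test_survivors_match_hand_enumeration(self, candidates):
        # by hand: M0 passes all; M1 fails Ghose (logP 6.0 > 5.6);
        # M2 fails Ghose (logP -1.0 < -0.4); M3 passes (all at bounds,
        # inclusive); M4 fails SAS (3.1); M5 fails binding (-7.0 > -7.1);
        # M6 passes; M7 fails binding (-6.0); M8 passes; M9 dropped (no SAS)
        survivors, counts = apply_filters(candidates)
        assert list(survivors["smiles"]) == ["M0", "M3", "M6", "M8"]
        assert counts["survivors"] == 4
        assert counts["missing_values"] == 1

    def test_interior_point_passes(self):
        frame = pd.DataFrame({"smiles": ["x"], "logP": [2.0], "SAS": [2.5],
                              "binding": [-8.0]})
        survivors, _ = apply_filters(frame)
        assert len(survivors) == 1

    def test_high_logp_fails_ghose(self):
        frame = pd.DataFrame({"smiles": ["x"], "logP": [6.0], "SAS": [2.0],
                              "binding": [-9.0]})
        survivors, _ = apply_filters(frame)
        assert survivors.empty

    def test_tightening_thresholds_is_monotone(self, candidates):
        base, _ = apply_filters(candidates, FilterSpec())
        for spec in (FilterSpec(sas_max=2.4),
                     FilterSpec(binding_max=-8.0),
                     FilterSpec(logp_window=(0.0, 3.0)),
                     FilterSpec(logp_window=(0.5, 2.5), sas_max=2.0,
                                binding_max=-8.5)):
            tightened, _ = apply_filters(candidates, spec)
            assert len(tightened) <= len(base)
            assert set(tightened["smiles"]) <= set(base["smiles"])

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            apply_filters(pd.DataFrame({"smiles": ["x"]}))


class TestSumOfRanks:
    def test_five_candidate_ordering_matches_hand_ranks(self):
        table = pd.DataFrame({
            "smiles": ["a", "b", "c", "d", "e"],
            "f1": [1.0, 2.0, 3.0, 4.0, 5.0],   # ranks 1..5
            "f2": [5.0, 1.0, 2.0, 3.0, 4.0],   # ranks 5,1,2,3,4
            "f3": [2.0, 2.0, 1.0, 5.0, 4.0],   # ranks 2.5,2.5,1,5,4
        })
        ranked = rank_sum_of_ranks(table, ["f1", "f2", "f3"])
        # normalized scores: a=(1+5+2.5)/5=1.7, b=(2+1+2.5)/5=1.1,
        # c=(3+2+1)/5=1.2, d=(4+3+5)/5=2.4, e=(5+4+4)/5=2.6
        assert list(ranked["smiles"]) == ["b", "c", "a", "d", "e"]
        assert np.allclose(ranked["rank_score"],
                           [1.1, 1.2, 1.7, 2.4, 2.6])

    def test_single_candidate_scores_m(self):
        table = pd.DataFrame({"smiles": ["only"], "f1": [3.0], "f2": [9.0]})
        ranked = rank_sum_of_ranks(table, ["f1", "f2"])
        assert ranked["rank_score"].iloc[0] == 2.0      # m ranks of 1/1

    def test_dominant_candidate_ranks_first(self, rng):
        F = rng.normal(size=(6, 3)) + 5.0
        F[2] = -1.0                                     # best everywhere
        table = pd.DataFrame(F, columns=["f1", "f2", "f3"])
        table["smiles"] = [f"m{i}" for i in range(6)]
        ranked = rank_sum_of_ranks(table, ["f1", "f2", "f3"])
        assert ranked["smiles"].iloc[0] == "m2"

    def test_invariant_to_affine_rescaling(self, rng):
        F = rng.normal(size=(8, 3))
        table = pd.DataFrame(F, columns=["f1", "f2", "f3"])
        table["smiles"] = [f"m{i}" for i in range(8)]
        a = rank_sum_of_ranks(table, ["f1", "f2", "f3"])
        table2 = table.copy()
        table2["f2"] = table2["f2"] * 7.0 + 100.0
        b = rank_sum_of_ranks(table2, ["f1", "f2", "f3"])
        assert list(a["smiles"]) == list(b["smiles"])

    def test_score_ties_break_by_smiles(self):
        table = pd.DataFrame({"smiles": ["zz", "aa"],
                              "f1": [1.0, 2.0], "f2": [2.0, 1.0]})
        ranked = rank_sum_of_ranks(table, ["f1", "f2"])
        assert list(ranked["smiles"]) == ["aa", "zz"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_of_ranks(pd.DataFrame(columns=["smiles", "f1"]), ["f1"])


class TestExportTopK:
    def _ranked(self):
        table = pd.DataFrame({
            "smiles": ["a", "b", "a", "c", "d"],
            "f1": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        return rank_sum_of_ranks(table, ["f1"])

    def test_duplicates_collapse_before_cutoff(self, tmp_path):
        top = export_top_k(self._ranked(), 3,
                           csv_path=str(tmp_path / "top.csv"))
        assert list(top["smiles"]) == ["a", "b", "c"]
        assert (tmp_path / "top.csv").exists()

    def test_row_count_is_min_of_k_and_unique(self):
        assert len(export_top_k(self._ranked(), 25)) == 4

    def test_warns_when_fewer_than_k(self):
        with pytest.warns(UserWarning):
            export_top_k(self._ranked(), 25)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            export_top_k(self._ranked(), 0)

    def test_structure_grid_written(self, tmp_path):
        table = pd.DataFrame({"smiles": ["CCO", "c1ccccc1", "CC(=O)O"],
                              "f1": [1.0, 2.0, 3.0]})
        ranked = rank_sum_of_ranks(table, ["f1"])
        path = tmp_path / "grid.png"
        export_top_k(ranked, 3, image_path=str(path))
        assert path.exists() and path.stat().st_size > 0
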