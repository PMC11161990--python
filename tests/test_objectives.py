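"""Objective registry: orientation, caching, sentinels, adapters."""

import subprocess
from types import SimpleNamespace

import numpy as np
import pytest

from molmoo import objectives as obj
from molmoo.molecules import compute_properties


def sas_registry():
    return obj.build_registry([
        {"name": "sas", "direction": "minimize", "evaluator": "sas"},
        {"name": "qed", "direction": "maximize", "evaluator": "property:QED"},
    ])


class TestRegistry:
    def test_sas_in_natural_range(self, small_library):
        registry = sas_registry()
        for smi in small_library[:20]:
            value = registry.evaluate(smi).values[0]
            assert 1.0 <= value <= 10.0

    def test_maximization_negated_exactly_once(self, small_library):
        registry = sas_registry()
        smi = small_library[0]
        vec = registry.evaluate(smi)
        qed = compute_properties(smi)["QED"]
        assert np.isclose(vec.values[1], -qed)
        display = registry.to_display(vec.as_array())
        assert np.isclose(display[1], qed)

    def test_cache_serves_repeat_evaluations(self, small_library):
        registry = sas_registry()
        smi = small_library[3]
        first = registry.evaluate(smi)
        calls = registry.backend_calls
        second = registry.evaluate(smi)
        assert registry.backend_calls == calls
        assert first.values == second.values

    def test_cache_keys_on_canonical_form(self):
        registry = sas_registry()
        registry.evaluate("OCC")
        calls = registry.backend_calls
        registry.evaluate("CCO")          # same molecule, different spelling
        assert registry.backend_calls == calls

    def test_evaluator_crash_maps_to_failure_sentinel(self):
        def boom(_):
            raise RuntimeError("backend down")

        registry = obj.ObjectiveRegistry([
            obj.ObjectiveSpec("broken", "minimize", boom, 1e6),
            obj.ObjectiveSpec("good", "maximize",
                              lambda s: compute_properties(s)["QED"], 0.0),
        ])
        vec = registry.evaluate("CCO")
        assert vec.values[0] == 1e6
        assert np.isfinite(vec.values[1])

    def test_empty_smiles_gets_worst_case_vector(self):
        registry = sas_registry()
        vec = registry.evaluate("")
        assert vec.values[0] == 10.0        # worst SAS
        assert vec.values[1] == 0.0         # worst (negated) QED

    def test_duplicate_names_rejected(self):
        spec = obj.ObjectiveSpec("x", "minimize", lambda s: 0.0, 1.0)
        with pytest.raises(ValueError):
            obj.ObjectiveRegistry([spec, spec])


class TestSurrogateAdmet:
    def test_all_six_objectives_present(self):
        preds = obj.surrogate_admet("CC(=O)Nc1ccc(O)cc1")
        assert set(preds) == {"binding_affinity", "sas", "bioavailability",
                              "solubility", "ld50", "clintox"}

    def test_deterministic(self):
        a = obj.surrogate_admet("c1ccccc1CCN")
        assert a == obj.surrogate_admet("c1ccccc1CCN")

    def test_finite_over_fixture_sweep(self, fixture_library):
        for smi in fixture_library:
            preds = obj.surrogate_admet(smi)
            assert all(np.isfinite(v) for v in preds.values()), smi

    def test_default_registry_matches_panel(self):
        registry = obj.default_surrogate_registry()
        assert registry.names == list(obj.SURROGATE_DIRECTIONS)
        vec = registry.evaluate("CCO")
        assert len(vec) == 6 and np.all(np.isfinite(vec.as_array()))


class TestDockingAdapter:
    def test_unconfigured_executable_raises(self):
        with pytest.raises(obj.DockingUnavailableError):
            obj.docking_adapter("CCO", obj.DockingConfig())

    def test_registry_build_fails_fast_without_executable(self):
        with pytest.raises(obj.DockingUnavailableError):
            obj.build_registry([{"name": "binding", "direction": "minimize",
                                 "evaluator": "docking"}])

    def test_mocked_process_score_propagates(self):
        def fake_run(cmd, **kwargs):
            return SimpleNamespace(returncode=0,
                                   stdout="mode | affinity\n   1   -7.5  0\n")

        config = obj.DockingConfig(executable="qvina-mock",
                                   receptor_path="receptor.pdbqt")
        assert obj.docking_adapter("CCO", config, runner=fake_run) == -7.5

    def test_malformed_ligand_returns_invalid_value(self):
        def fake_run(cmd, **kwargs):                    # pragma: no cover
            return SimpleNamespace(returncode=0, stdout="1 -5.0")

        config = obj.DockingConfig(executable="qvina-mock",
                                   receptor_path="receptor.pdbqt")
        value = obj.docking_adapter("not_a_molecule", config, runner=fake_run)
        assert value == obj.INVALID_DOCKING_VALUE

    def test_failing_process_returns_invalid_value(self):
        def fake_run(cmd, **kwargs):
            return SimpleNamespace(returncode=1, stdout="")

        config = obj.DockingConfig(executable="qvina-mock",
                                   receptor_path="receptor.pdbqt")
        assert obj.docking_adapter("CCO", config, runner=fake_run) \
            == obj.INVALID_DOCKING_VALUE

    def test_box_must_be_positive(self):
        with pytest.raises(ValueError):
            obj.DockingConfig(size=(0.0, 20.0, 20.0))
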