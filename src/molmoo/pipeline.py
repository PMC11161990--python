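"""End-to-end orchestration of the desk-scale drug-design pipeline.

Stages: fixture generation → latent problem construction → one optimization
run per (algorithm, seed) → cross-run metric report → candidate triage.
Each stage writes its outputs under the configured directory and is skipped
on re-run when they already exist, so the pipeline is resumable; the exact
configuration snapshot lives alongside the outputs.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .config import RunConfig, save_config
from .fixtures import FixtureSpec, generate_molecules, toy_problem
from .metrics import make_report
from .molecules import compute_properties
from .optimizers import ALGORITHMS, initialize_population
from .triage import FilterSpec, apply_filters, export_top_k, rank_sum_of_ranks

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the run directory."""


def run_pipeline(config: RunConfig, fixtures_n: int = 500,
                 toy_objectives: int = 4, codec=None) -> dict:
    from .cli import write_run_directory  # thin IO helper shared with the CLI
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    save_config(config, os.path.join(out_dir, "config.yaml"))

    stage = "fixtures"
    try:
        library_path = os.path.join(out_dir, "library.smi")
        if os.path.exists(library_path):
            with open(library_path) as fh:
                library = [l.strip() for l in fh if l.strip()]
        else:
            library = generate_molecules(
                FixtureSpec(n_molecules=fixtures_n, seed=config.seeds[0]))
            with open(library_path, "w") as fh:
                fh.write("\n".join(library) + "\n")

        stage = "optimize"
        histories = []
        problems = {}
        for algorithm in config.algorithms:
            if algorithm not in ALGORITHMS:
                raise PipelineError(f"unknown algorithm {algorithm!r}")
            for seed in config.seeds:
                run_dir = os.path.join(out_dir, f"{algorithm}_seed{seed}")
                problem = toy_problem(toy_objectives, codec=codec,
                                      library=library, seed=config.seeds[0])
                initial = initialize_population(
                    library, problem, config.search.population_size, seed)
                history = ALGORITHMS[algorithm](problem, config.search,
                                                initial, seed)
                write_run_directory(history, problem, run_dir)
                histories.append(history)
                problems[(algorithm, seed)] = problem

        stage = "metrics"
        any_problem = next(iter(problems.values()))
        report = make_report(histories, library,
                             os.path.join(out_dir, "report"),
                             objective_names=any_problem.registry.names)

        stage = "triage"
        names = any_problem.registry.names
        rows = []
        for history in histories:
            final = history.final
            for smi, f in zip(final.smiles, final.objectives):
                if not smi:
                    continue
                row = {"smiles": smi, "algorithm": history.algorithm,
                       "seed": history.seed}
                row.update({n: float(v) for n, v in zip(names, f)})
                rows.append(row)
        table = pd.DataFrame(rows)
        props = table["smiles"].apply(compute_properties)
        table["logP"] = props.apply(lambda p: p["logP"])
        table["SAS"] = props.apply(lambda p: p["SAS"])
        binding = "binding_affinity" if "binding_affinity" in table.columns \
            else names[0]
        table["binding"] = table[binding]
        survivors, counts = apply_filters(table, config.filters)
        triage_dir = os.path.join(out_dir, "triage")
        os.makedirs(triage_dir, exist_ok=True)
        pd.DataFrame([counts]).to_csv(
            os.path.join(triage_dir, "filter_counts.csv"), index=False)
        top = None
        if not survivors.empty:
            ranked = rank_sum_of_ranks(survivors, names)
            ranked.to_csv(os.path.join(triage_dir, "ranking.csv"), index=False)
            top = export_top_k(ranked, 25,
                               csv_path=os.path.join(triage_dir, "top.csv"))
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    return {"histories": histories, "report": report,
            "triage_counts": counts, "top": top, "library": library}
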