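"""Reproducible desk-scale experiment presets.

These bundle fixture generation, preprocessing, model construction and a
training recipe into single calls so that tests, the acceptance script and
the command line all run the *same* experiment.  Problem sizes are chosen
to exercise every pathway of the system on a single CPU in minutes; the
full-scale hyperparameters remain available through the plain
:class:`~molmoo.autoencoder.ModelConfig` / ``TrainConfig`` defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import (AutoencoderService, LossWeights, ModelConfig,
                          MolecularAutoencoder, TrainConfig,
                          _PropertyScaler, reconstruction_accuracy, train)
from .fixtures import FixtureSpec, generate_molecules
from .molecules import DatasetSplit, MoleculeRecord, Vocabulary, preprocess_dataset

__all__ = ["OverfitResult", "tiny_overfit_experiment", "desk_dataset",
           "desk_optimization_experiment"]


def desk_dataset(n_molecules: int, seed: int, max_tokens: int = 30
                 ) -> list[MoleculeRecord]:
    """Compact fixture records (token length capped for desk-scale models)."""
    raw = generate_molecules(FixtureSpec(n_molecules=4 * n_molecules, seed=seed))
    records = []
    for smi in raw:
        rec = MoleculeRecord.from_smiles(smi)
        if len(rec.tokens) <= max_tokens:
            records.append(rec)
        if len(records) == n_molecules:
            break
    if len(records) < n_molecules:
        raise RuntimeError("fixture pool too small for requested dataset")
    return records


@dataclass
class OverfitResult:
    service: AutoencoderService
    accuracy: float
    history: list
    records: list[MoleculeRecord]


def tiny_overfit_experiment(n_molecules: int = 50, seed: int = 42,
                            joint_epochs: int = 400,
                            polish_epochs: int = 150,
                            architecture: str = "relso") -> OverfitResult:
    """Memorize a small fixture set with the scaled-down configuration.

    Two stages on the desk preset (32-dim embedding, 2 encoder layers,
    64-dim latent): first the full joint objective — contrastive pairs
    from SMILES enumeration, canonical reconstruction targets, cosine
    learning-rate decay — which organizes the latent space; then a short
    low-rate polish on canonical views only (augmentation noise and the
    contrastive term off), which settles the last few token errors of pure
    memorization.  Reports end-to-end greedy reconstruction accuracy on
    the memorized set.
    """
    records = desk_dataset(n_molecules, seed)
    max_len = max(len(r.tokens) for r in records) + 2
    vocab = Vocabulary.from_records(records)
    config = ModelConfig.desk(architecture, contrastive_enabled=True,
                              max_len=max_len)
    model = MolecularAutoencoder(config, vocab, seed=seed)
    service = AutoencoderService(model, _PropertyScaler.fit(records))
    split = DatasetSplit(train=records,
                         validation=records[: max(4, n_molecules // 6)],
                         test=records)
    history = train(service, split, LossWeights(),
                    TrainConfig(learning_rate=6e-3, batch_size=16,
                                max_epochs=joint_epochs, patience=10 ** 9,
                                lr_decay="cosine", seed=seed))
    if polish_epochs:
        model.config.contrastive_enabled = False
        history += train(service, split, LossWeights(),
                         TrainConfig(learning_rate=5e-4, batch_size=16,
                                     max_epochs=polish_epochs,
                                     patience=10 ** 9, seed=seed + 1))
        model.config.contrastive_enabled = True
    return OverfitResult(service=service,
                         accuracy=reconstruction_accuracy(service, records),
                         history=history, records=records)


def desk_optimization_experiment(library: list[str] | None = None,
                                 codec=None, algorithms=None,
                                 seeds=(42, 182), population: int = 40,
                                 evaluations: int = 800,
                                 m_objectives: int = 4,
                                 library_size: int = 2000,
                                 library_seed: int = 42) -> list[dict]:
    """One desk-scale optimization run per (algorithm, seed).

    By default the decision space is the identity embedding of a
    2000-molecule fixture library in descriptor space (a library this size
    leaves per-objective headroom: a 40-molecule initial sample essentially
    never contains the library's optima, so improvement is measurable);
    pass ``codec`` to search a trained latent space instead.  The initial
    population is sampled from ``library``, so its novelty against the
    library is zero by construction.  Returns one summary row per run:
    budget use, per-objective best values of the initial and final
    populations, whether any objective's best strictly improved, and
    initial/final novelty.
    """
    from .fixtures import FixtureSpec, generate_molecules, toy_problem
    from .metrics import novelty
    from .optimizers import ALGORITHMS, AlgorithmParams, initialize_population

    algorithms = list(algorithms or ALGORITHMS)
    if library is None:
        library = generate_molecules(FixtureSpec(n_molecules=library_size,
                                                 seed=library_seed))
    dataset = list(library)
    rows = []
    for name in algorithms:
        for seed in seeds:
            problem = toy_problem(m_objectives, codec=codec, library=library)
            params = AlgorithmParams(population_size=population,
                                     max_evaluations=evaluations)
            initial = initialize_population(dataset, problem, population, seed)
            history = ALGORITHMS[name](problem, params, initial, seed)
            # Novelty reference: the molecules the run started from.  With a
            # trained codec the library doubles as its training set, so the
            # whole library is the reference; the identity embedding trains
            # on nothing, so the initial sample is.
            reference = dataset if codec is not None \
                else [ind.smiles for ind in initial]
            F0 = history.generations[0].objectives
            FF = history.final.objectives
            rows.append({
                "algorithm": name, "seed": seed,
                "evaluations_used": history.evaluations_used,
                "budget": params.max_evaluations,
                "best_initial": F0.min(axis=0), "best_final": FF.min(axis=0),
                "improved": bool(np.any(FF.min(axis=0)
                                        < F0.min(axis=0) - 1e-12)),
                "novelty_initial": novelty(history.generations[0].smiles,
                                           reference),
                "novelty_final": novelty(history.final.smiles, reference),
                "history": history,
            })
    return rows
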