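# Methods

`molmoo` implements a complete drug-design loop: molecules are represented
as SELFIES strings, embedded into a fixed-length latent space by a
Transformer autoencoder trained with a joint reconstruction / property /
contrastive objective, and optimized in that latent space by six
many-objective metaheuristics against a panel of minimization-oriented
objectives, followed by quality metrics and candidate triage. This note
records the models, the parameters that matter, the numerical choices, and
what the desk-scale experiments do and do not demonstrate.

## Molecular representation

SMILES is the interchange format; SELFIES is the model-facing notation.
The package ships its own SELFIES codec (version-2 grammar, neutral
organic-subset molecules: B, C, N, O, P, S, halogens; no charges, isotopes
or stereocentres). Two properties carry the whole design:

* **Totality.** Any sequence of alphabet symbols decodes to a valid
  molecule: bond orders are capped by remaining valences, branch lengths
  and ring distances are read from explicit index symbols and clipped to
  what exists. A greedy argmax decode of *any* latent vector therefore
  always yields a molecule; there is no validity filter anywhere in the
  search loop.
* **Determinism.** Encoding mirrors the atom order of the input SMILES
  (RDKit preserves input order), so a molecule's canonical SMILES maps to
  one SELFIES string.

RDKit is the chemistry authority: parsing, kekulization, canonical SMILES
(the identity key for deduplication, caching, uniqueness and novelty),
logP (Crippen), QED, and SAS (the Ertl–Schuffenhauer synthetic
accessibility score from RDKit's contrib tree, scale 1–10, lower =
easier).

Decoder edge cases: a branch or ring symbol in a state without free
valences is skipped; an atom symbol arriving when the current chain atom is
saturated terminates that derivation scope; ring distances count back from
the current attachment atom in derivation order, so branch atoms derived in
between do not shift the reference point. These choices keep decode total
and exactly invert the encoder on encoder-produced strings.

## Dataset preprocessing

Input molecule lists are deduplicated by canonical SMILES, then filtered:
tokenization length at most 198 symbols (configurable), and at least two
unique alternative SMILES spellings within 10 enumeration attempts
("augmentations", the canonical spelling itself excluded — a molecule that
cannot be re-spelled, such as methane, provides no contrastive positive
pair). Survivors are split 70/10/20 by a seeded shuffle *of molecules*, so
no molecule's spellings straddle splits. SMILES enumeration renumbers
atoms with a seeded permutation and writes the molecule non-canonically;
this is deterministic per seed, unlike backend-global randomized output.

## Autoencoders

Both architectures share: token + learned positional embeddings,
post-norm Transformer encoder (self-attention with key padding masks),
a four-linear-layer ReLU projection into the latent space, and 2-layer
property heads (logP, SAS, QED, trained on z-scored targets; predictions
are un-scaled on output).

* **ReLSO-style** (`relso`, the default): the encoder output is
  mean-pooled over non-pad positions ("applies pooling" is unspecified in
  the source architecture; mean is length-invariant and standard).
  The decoder is convolutional and non-autoregressive: a linear layer
  expands the latent vector to one channel vector per target position,
  positional embeddings are added, and three same-padded 1-D conv blocks
  (kernel 5, ReLU) feed a per-position softmax. A broadcast-only entry
  (the same latent vector at every position) was tried first and could not
  exceed ~45 % token accuracy even on a 50-molecule memorization task —
  the decoder settles for per-position marginals; the per-position linear
  expansion removes that bottleneck.
* **FragNet-style** (`fragnet`): the start-token encoder state is
  projected to the latent vector; decoding is autoregressive through a
  Transformer decoder (teacher forcing during training, greedy argmax at
  inference) cross-attending to the un-projected latent as a single
  memory position.

**Joint loss.** total = 1·CE + 0.25·(MSE_logP + MSE_SAS + MSE_QED)
+ 1·NT-Xent + 0.1·mean‖z‖². Reconstruction is token cross-entropy
(padding excluded); the latent penalty is the batch mean of squared
Euclidean norms. NT-Xent uses cosine similarity at temperature τ = 0.1
over 2N latent vectors with exactly two positives per molecule (the
denominator runs over the 2N−1 non-self entries); a zero-norm latent
raises rather than silently producing NaN.

**Contrastive pairs and reconstruction targets.** Positive pairs are two
enumerated SMILES spellings of the same molecule, converted to SELFIES and
tokenized. Reconstruction targets are always the *canonical* SELFIES:
augmented spellings act as input noise. This is deliberate — if each view
must reconstruct its own spelling, the contrastive pull (make the two
views' latents identical) and reconstruction (make them decode to
*different* strings) are in direct conflict, and joint training stalls;
with canonical targets the two terms cooperate (measured on the
memorization task: ~45 % vs ≥ 99 % token accuracy).

**Initialization.** Linear layers inside ReLU stacks (projection,
unprojection, property heads, the latent-to-sequence expansion) use He
initialization; attention projections use uniform fan-in scaling. With
small uniform init everywhere, the latent pathway starts nearly
uninformative (inter-molecule latent s.d. ~0.005) and training collapses
into the marginal fit described above.

**Training.** Adam (the optimizer family is a documented assumption;
only learning rates are inherited from the full-scale setting: 2e−5 ReLSO
/ 1e−5 FragNet). A validation pass runs every 20 % of an epoch's steps;
training stops after four consecutive validation-loss increases or at the
epoch cap. Optional cosine learning-rate decay to a configurable floor.
All arithmetic is float64 numpy on a purpose-built reverse-mode autodiff
core (`molmoo.autograd`), so runs are bit-reproducible given a seed.

**Desk preset.** 32-dim embedding, 2 encoder layers, 2 heads, 64-dim
feedforward, 64-dim latent, dropout 0. The memorization experiment
(`molmoo.presets.tiny_overfit_experiment`) trains this preset on 50
fixture molecules (SELFIES length ≤ 30 tokens) with learning rate 6e−3,
batch 16, cosine decay to a 2 % floor, 500 epochs — chosen as the point
where end-to-end greedy reconstruction accuracy reliably exceeds 99 % in a
few CPU-minutes. The full-scale preset (256/6/8/1024/512, dropout 0.2) is
shipped as configuration and is not exercised by the tests.

## Objectives

A registry maps a decoded molecule to a minimization-oriented objective
vector: maximization objectives are negated on entry (exactly once;
reports un-negate for display). Evaluations are cached by canonical
SMILES. Failures — evaluator exceptions, non-finite values, the empty
molecule — are replaced by each objective's declared worst-case sentinel
and participate in dominance as ordinary (bad) values; the docking
sentinel is 10⁶, matching the convention for invalid dockings.

External predictors enter through adapters. The docking adapter shells
out to a Vina-style executable with a configurable box (defaults: center
(14.444, 5.250, −18.278) Å, size (20, 20, 20) Å — the LPA1 pocket);
a missing executable fails at registry *construction*, so offline runs
must use the surrogate. `surrogate_admet` is a synthetic, deterministic
descriptor-based stand-in producing the same six endpoints
(binding affinity, SAS, bioavailability, solubility, LD50, clinical
toxicity) with the right orientations and rough scales; it models no
predictor quality and claims no pharmacological accuracy — it exists so
the whole system runs offline and its tests are meaningful about the
*machinery*, not about chemistry.

## Latent-space search

The decision space is a box: per-dimension min/max of the encoded initial
sample, expanded by a 10 % margin. Data-driven bounds keep search inside
decoder-meaningful territory; nothing in the model defines natural bounds.

All algorithms share SBX crossover (p_c = 1) and polynomial mutation
(p_m = 1/D), both with distribution index 20, and the **repair loop**:
offspring vector → decode → molecule → re-encode → clip → evaluate; the
individual carries the re-encoded vector. Every decoded offspring counts
as one function evaluation (cache hits included — the budget measures
search effort, not backend load). Initial populations are seeded samples
(without replacement) from the training molecules, encoded and evaluated;
their novelty against that dataset is 0 by construction.

The six algorithms are compact, faithful implementations of the published
selection mechanisms (not ports of any reference framework):

* **GrEA** — grid with div = 8 per objective; grid ranking, grid crowding
  degree, grid coordinate point distance; front-wise filling with the
  punishment scheme on the critical front.
* **HypE** — Monte Carlo hypervolume contributions (nSample = 10 000 in
  search; the removal count parameterizes the HypE weights); critical
  front pruned by smallest estimated contribution.
* **KnEA** — extreme-point hyperplane distances; adaptive neighbourhood
  with target knee ratio T = 0.5; knees preferred in tournaments and
  truncation.
* **MOEA/DD** — Das–Dennis weight regions, neighbourhood mating
  (T = 200 clipped to the population, δ = 0.9), steady-state update
  removing the largest-PBI member (θ = 5) of the most crowded region of
  the worst front.
* **A-NSGA-III** — NSGA-III normalization (ASF extreme points →
  intercepts), reference-ray association, niche preservation; adaptive
  insertion of simplices around niches holding ≥ 2 solutions and deletion
  of inserted points whose niches empty.
* **NMPSO** — three-guide velocity update (personal, global, random
  archive; ω ∈ [0.1, 0.5], c₁..c₃ ∈ [1.5, 2.5] redrawn per particle per
  iteration), balanceable fitness estimation (normalized convergence
  distance + shift-based density), polynomial mutation on positions, and
  a BFE-truncated nondominated archive. Positions, not velocities, are
  repaired.

For six objectives the reference/weight lattice is two-layer Das–Dennis
(boundary H = 3, inner layer H = 2 shrunk toward the centroid); for up to
four objectives a single layer sized to the population is used.
Truncation ties break by a seeded uniform draw, so runs are reproducible.

## Metrics

GD and IGD are mean nearest-neighbour Euclidean distances (arithmetic
mean, unnormalized objectives — both documented, configurable choices),
computed against a reference front approximated by the dominance-filtered,
deduplicated union across all runs. Uniqueness = distinct canonical
SMILES fraction; novelty = fraction absent from the training set (both
computed on post-selection populations). 1-Wasserstein distances use the
sorted-sample formulation via scipy. The exact hypervolume oracle (used
to validate HypE's sampling) is a coordinate-sweep computation for 2–3
objectives at oracle scale. Kernel density plots use Scott's rule; the
plots are qualitative, the annotated distances are the tested quantities.

## Synthetic fixtures and the toy problem

The fixture generator assembles molecules from five scaffold families
(alkanes, aromatics, heteroaromatics, amides, sulfonamides) with a
substituent pool, deterministically per seed; products are valid, distinct,
charge-free, and span > 2 logP units with wide QED/SAS spread — enough
conflict to give the toy objective space real Pareto structure. It makes
no attempt to mimic real screening libraries.

The toy problem is QED (maximized), SAS, distance of logP from the
drug-like window [−0.4, 5.6], and heavy-atom count (minimized), with
surrogate ADMET endpoints appended for m > 4. Two codecs serve it: a
trained autoencoder, or the training-free `DescriptorCodec` — library
molecules embedded at standardized 8-descriptor vectors, decoded by
nearest neighbour, so decode∘encode is exactly the identity on the
library and repair is exactly idempotent.

The end-to-end experiments (population 40, 800 evaluations, seeds 42 and
182) use the descriptor codec over a 2000-molecule fixture library, a
size chosen so the instrument can measure what it is meant to measure.
Two failure modes of smaller setups motivated it. A *small* library
(a few hundred molecules) saturates: the 40-molecule initial sample
frequently already contains the library's optimum in most objectives
(logP-window distance is 0 for most drug-like fixtures, plain alkanes all
sit near the SAS floor), so "did the search improve on the initial best"
degenerates into finding one needle molecule. And an autoencoder *overfit
to 50 molecules* — the memorization experiment's model — partitions its
latent space into 50 attractor basins: SBX offspring of two memorized
parents decode straight back to a parent, the repair loop snaps them
there, and the evolutionary algorithms never leave the training set
(novelty stays 0; only the particle swarm's larger steps escape). A
2000-molecule identity-embedded library avoids both: the initial sample
essentially never contains a per-objective optimum, recombination in
descriptor space decodes to genuinely different molecules, and all six
algorithms improve at least one objective and reach positive novelty at
every seed tried (42, 182 and four others). Searching a *well-trained*
large-corpus latent space the same way is exactly what the full-scale
configuration describes; desk-scale training cannot produce such a space,
and the identity embedding is the honest stand-in.

## Triage

Filters (inclusive bounds): Ghose lipophilicity window −0.4 ≤ logP ≤ 5.6,
binding affinity ≤ −7.1, SAS ≤ 3. Survivors are ordered by normalized
sum of ranks: per minimization-oriented objective, rank best-first with
average ranks on ties, divide by the candidate count, sum across
objectives; exact score ties break by canonical SMILES. "Normalized" is
interpreted as rank/count (a min–max alternative is configurable); all
objectives in the candidate vectors feed the sum. Filtering reuses values
recorded during the runs — no re-docking at triage.

## Problem sizes

Tests and the acceptance script run: 50-molecule memorization (500
epochs, a few CPU-minutes), twelve optimization runs (6 algorithms × 2
seeds) at population 40 / 800 evaluations, metric and triage checks on
constructed instances, and a mini pipeline (80 fixtures, 2 algorithms,
population 12, 60 evaluations). The full-scale setting (population 2000,
25 000 evaluations, 5 seeds, 4M-molecule corpora, GPU docking) is
expressible in configuration but deliberately not executed.

## Known limitations

* The SELFIES codec covers the neutral organic subset; charged species,
  isotopes and stereochemistry are rejected at encoding (real screening
  data would need a grammar extension).
* The ADMET surrogate is synthetic; conclusions about *chemistry* (as
  opposed to the optimization machinery) require plugging in a real
  predictor and docking engine through the adapters.
* Desk-scale populations make metric curves noisy; the reference front is
  itself an approximation from the same runs, as in the underlying method.
* The autodiff core is single-threaded float64 numpy: exactly
  reproducible, but not suitable for corpus-scale training.
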