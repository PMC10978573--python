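# Methods

`vhhlm` is a desk-scale workbench for nanobody (VHH) sequence modeling. Every
stage — repertoire simulation, IMGT numbering, masked-language-model (MLM)
training, positional infilling, nativeness scoring, fine-tuning, and germline
diagnostics — runs on a single CPU in minutes, with ground truth supplied by
the simulator rather than by external corpora. This note records the models,
the defaults and why, the numerical choices, and what the package does and
does not demonstrate.

## Synthetic repertoires

A repertoire is drawn from a set of IMGT-numbered germline scaffolds by
(i) sampling a germline (optionally with mixing weights), (ii) applying
somatic hypermutation (SHM) as independent per-position substitutions, and
(iii) replacing CDR3 wholesale.

**Scaffolds.** Ten hand-built VH-like scaffolds ship with the package, five
per species. Species `vhh` carries the camelid hallmark F/E/R/F at IMGT
42/49/50/52 plus several additional framework differences from species
`human` (V/G/L/W at the hallmarks), mirroring the fact that camelid and human
frameworks differ beyond the hallmark positions. They are invented sequences,
not real IGHV alleles: tests stay self-contained, with no download or license
questions. Scaffold length is 117 residues: full frameworks (FW1 1–26,
FW2 39–55, FW3 66–104, FW4 118–128) and middle-gapped loops (CDR1 8 of 12
positions, CDR2 7 of 10, CDR3 9 of 13), following the IMGT convention of
filling loop positions from both ends inward.

**SHM.** Each non-CDR3 position mutates independently with probability
`base_rate × hotspot_multiplier(region)`; the replacement is drawn from a
row-stochastic 20×20 matrix with zero diagonal (a mutation always changes the
residue; uniform off-diagonal by default). Defaults: `base_rate = 0.03`,
CDR1/CDR2 hotspot multiplier 4 — framework mutation counts of a few per
sequence with visibly elevated loop diversity, a plausible caricature of an
NGS repertoire. There is no clonal lineage structure and there are no indels;
the evaluations downstream need marginal and pairwise statistics, not
genealogy.

**CDR3.** A length is sampled (default: 8–16, peaked at 12) and residues are
drawn i.i.d. from a loop-like composition (G/S/Y-rich, C/M-poor). This models
junctional diversity without D/J bookkeeping, making CDR3 the maximally
diverse, essentially unpredictable region — the role it plays in the
infilling analyses.

**Thermostability.** The property generator is additive: value = intercept +
Σ effect_weights[(IMGT position, residue)] + Gaussian noise. The default
model puts weights on CDR3 positions (aromatics and proline stabilize,
glycine and acidic residues destabilize; intercept 62 °C, noise SD 1.5 °C),
so the signal is carried by sequence content that actually varies across a
repertoire and is recoverable from mean-pooled representations. Insertion
labels ("109A") contribute through their base position.

**What the simulator does not emulate:** clonal expansion and phylogeny,
indel SHM, paired light chains, sequencing error, real germline gene
diversity, and real thermostability physics. Tests passing on simulated data
show the machinery is correct and that the statistical contrasts (context
advantage, species separation, pre-training benefit) behave as designed;
they do not certify performance on natural repertoires.

## IMGT numbering by alignment transfer

Queries are numbered by global alignment (Needleman–Wunsch, linear gaps,
match 2 / mismatch −1 / gap −2) to each scaffold's *framework-only* view; the
best-scoring scaffold wins. Aligning against frameworks only prevents loop
content from pairing with — and displacing — framework columns. Aligned
framework columns in runs of ≥ 3 consecutive columns become anchors (isolated
pairings are usually chance matches against loop content); residues between
anchors are assigned the free IMGT positions between the anchor positions,
filling from both ends inward, with lettered insertions ("111A") at the
midpoint when a loop exceeds its positions. Sequences whose best framework
identity falls below 0.5 are rejected as unnumberable, mirroring how NGS
pipelines drop truncated chains.

Traceback ties are broken deterministically: diagonal on a match, then gap in
the reference, then diagonal on a mismatch, then gap in the query. Preferring
the match-diagonal first keeps substituted residues paired adjacent to their
match runs, which materially improves number transfer.

**Stability and its limits.** Renumbering after a single *interior* framework
mutation (≥ 3 positions from a region edge) reproduces the original
assignment in ≥ 99% of simulated records at SHM base rate 0.05. Mutations at
framework positions *adjacent to a CDR* can re-register against chance
matches in loop content (any content-independent scoring gains
match − mismatch = 3 by doing so), and whole-sequence stability under
unrestricted mutation placement is ≈ 94%. Position-specific scoring (an HMM)
would remove this failure mode; it is deliberately out of scope, and the
package treats boundary-adjacent renumbering as a known limitation.

## Masked language model

Residues are words, sequences are sentences: vocabulary of 20 residues plus
[MASK]/[PAD]/[CLS]/[SEP]/[UNK], learned token and position embeddings, and a
pre-LayerNorm transformer encoder with a BERT-style MLM head, implemented
directly in numpy with hand-written backpropagation (forward/backward for
embeddings, multi-head attention, layernorm, GELU feed-forward) and Adam with
linear warmup. The implementation is exact (gradients verified against finite
differences in float64) and fast enough at desk scale; float32 is used
throughout.

Masking follows the BERT-standard policy: ceil(15%) of residue positions per
sequence (at least one), of which 80% become [MASK], 10% a random residue,
10% stay. Special tokens are never masked. `predict_position` masks one
position, runs one forward pass, and softmaxes over the 20 residue logits
(special-token mass excluded and renormalized); per-sequence queries batch
all L masked variants into one forward pass.

Presets: `tiny` (2 layers, 4 heads, embedding 32, FF 128) for all tests and
experiments; `small` (12 layers, 8 heads, embedding 320, FF 1280; ≈ 15.0M
parameters) and `big` (12 layers, 12 heads, embedding 768, FF 3072; ≈ 85.8M)
match published antibody-LM scales. Twelve layers — not six — are needed at
embedding 320 to reach the ~14M-parameter budget with the conventional 4×
feed-forward width. Optimizer defaults (Adam 1e-3, batch 64, 100 warmup
steps, 1% held-out validation) are exposed in the estimator's parameters.

Training runs used by the tests and the acceptance script: 20 000 length-40
PSSM-sampled sequences × 3 epochs for distribution recovery; 6 000 length-30
sequences × 8 epochs at learning rate 2e-3 for the context-advantage
experiment (learning a long-range deterministic dependency is a
feature-learning transition — shorter schedules succeed only at some seeds);
6 000 repertoire sequences × 3 epochs per species model. These sizes were
chosen as the smallest at which the contrasts of interest are comfortably
reproducible.

## Infilling benchmark

Each position is obscured in turn; the top predicted residue (ties broken
alphabetically and flagged) is compared with the truth. Per-sequence
accuracies are matches ÷ region length, for each IMGT region and for the
composites V (all positions), FW (FW1–4) and CDRs (CDR1–3); report-level
means are unweighted across sequences with a non-empty region (regions empty
in every sequence are omitted). Unnumberable sequences are skipped and
counted. The mean-over-sequences aggregation (rather than pooled positions)
is a documented choice; with near-constant sequence lengths the two agree
closely.

The PSSM baseline predictor returns the row for a position's IMGT label —
exactly the information a gene-based mutational map provides — falling back
to the base position for insertion labels and to uniform for unseen
positions. It is the context-free contrast for the MLM's context advantage:
on a corpus where one position deterministically copies another (both
marginals 50/50), the PSSM baseline cannot exceed ~0.5 there while the
trained MLM approaches 1.0.

## Nativeness

For each position i, the observed residue's final-layer logit z_i is taken
under masking of i, and the score is Σ_i exp(−z_i); lower means closer to the
training distribution. A pseudo-log-likelihood variant (Σ_i −log p_i) is
available behind `variant="pll"`; both are monotone-decreasing in the
observed-residue logit and neither is claimed to be byte-identical to any
published score. Length normalization is off by default (the statistic is a
sum) with a normalized variant available, since raw sums confound length with
nativeness. Separation between repertoires is summarized as the probability
that a random native sequence scores lower than a random foreign one
(rank-sum AUC; ties count half). Because the sum is dominated by the
inherently unpredictable CDR3 positions — which carry no species signal —
the separation AUC of a freshly trained tiny model varies with training
seed (roughly 0.87–1.0 on the simulated species pair).

## Fine-tuning

A four-layer dense head (hidden dims d, d/2, d/4 with ReLU, He-initialized;
linear or sigmoid output paired with MSE or binary cross-entropy) is trained
on mean-pooled final hidden states (CLS pooling available). Mean pooling
shrinks the feature scale by roughly 1/sqrt(sequence length), so a LayerNorm
sits between the pooled vector and the head — without it the head's
gradients start orders of magnitude too small and training stalls at the
target mean. By default the whole encoder is fine-tuned, preceded by ten
epochs of head-only warmup on frozen features so that early encoder updates
are not driven by a random head's gradients (omitting the warmup lets
roughly one repeat in five fall into a non-learning basin);
`freeze_encoder=True` trains the head on frozen features (and precomputes
them once). The no-pretraining control uses a randomly initialized frozen
encoder of the same shape. Regression targets are min-max scaled to [0, 1]
on the training split only and predictions inverse-scaled.

Data are split 8:1:1 (shuffled, seeded); validation/test records with ≥ 90%
global-alignment identity to any training record are dropped (between train
and evaluation only — the minimal reading of an identity restriction).
Regression experiments run five repeats that re-seed training on the fixed
split and report mean/SD of test Pearson r, alongside a uniform-[0,1] random
baseline. Training regimes differ by what moves: whole-encoder fine-tuning
uses Adam at 5e-4 with up to 40 epochs, the frozen-feature (head-only)
control 2e-3 with up to 200 epochs; both early-stop on the validation split
(patience 8, best-epoch weights restored). The lower rate for whole-encoder
updates is a stability requirement — at 1e-3, individual repeats occasionally
diverge to negative test correlations, which early stopping alone does not
rescue. The expected ordering on the synthetic thermostability fixture
(n = 400, noise SD 1.5 °C) is pre-trained > head-only > random band; note
that species classification on hallmark-separable data is nearly trivial and
does not isolate the value of pre-training — the classifier test asserts
separation, not pre-training benefit.

## Germline diagnostics

Gene assignment picks the germline with the highest identity over its
framework positions (ties to the lexicographically first gene id, flagged).
Edit distances are unit-cost Levenshtein (delegated to edlib; a brute-force
DP oracle verifies it in tests). The distance-curve analysis extracts each
record's concatenated FW2+FW3, takes the most frequent clone as the germline
proxy (lexicographically smallest on ties, flagged), and reports, per edit
distance, the total frequency of all chains and the frequency of the most
frequent unique clone. Both per-read and per-unique-clone views are
computable because both series are first-class. On a clean single-germline
simulation the curve is unimodal and descending; planting a second,
unassigned germline produces a secondary density bump at the inter-germline
distance — the diagnostic signature of missing gene references. PSSMs are
per-IMGT-position frequency tables (no smoothing by default; add-k
available), with rows only where positions are observed.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; identical (config, seed) reproduces outputs byte-identically
  on the same platform.
- Evaluation-mode forward passes are deterministic (dropout only acts in
  training mode; default dropout 0 at desk scale).
- Probability-vector invariants are enforced at 1e-9 (configs) and 1e-6
  (predicted distributions); target-scaler round trips are exact to 1e-9.
- Ranking ties: alphabetical for residues, lexicographic for clones, gene-id
  order for assignments — every tie-break is deterministic and flagged where
  it matters.
- Sequence-identity filtering skips alignments that provably cannot reach
  the threshold (length-ratio bound) for speed.
- Degenerate inputs fail loudly: empty corpora, zero-variance targets,
  single-class splits, non-stochastic matrices, and unnumberable sequences
  all raise typed errors or are counted, never silently dropped.

## Known limitations

- Alignment-transfer numbering is not an HMM: boundary-adjacent framework
  mutations can re-register (see above), and fragmentary or highly divergent
  chains are rejected rather than rescued.
- The simulator's independence assumptions (positions, sequences) make some
  tasks easier than nature would: hallmark-based species classification is
  nearly linearly separable, and the thermostability signal is genuinely
  additive.
- The numpy transformer is single-threaded beyond BLAS and is not intended
  for the `small`/`big` presets at real corpus sizes; those presets exist to
  instantiate and sanity-check the published parameter budgets.
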