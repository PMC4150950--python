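# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `peplife`. It is the place where genuinely open design
decisions are written down; nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The quantity modelled is the half-life, in seconds, of a short peptide
(typically a 10mer or 16mer of the 20 standard L-amino acids) incubated in
a concentrated crude intestinal protease preparation. Because the assay
uses undiluted protease at far above physiological concentration, the
values rank peptides *relative* to one another rather than predicting
physiological residence times; all modelling choices below treat the
half-life as a positive, heavily right-skewed response spanning several
orders of magnitude (published ranges: 0.0008–40.1296 s for 10mers,
0.0008–6.4211 s for 16mers).

## Sequence model and encoders

Sequences are strictly the 20 standard residues; B/J/O/U/X/Z and modified
residues are rejected rather than imputed, because every downstream model
is calibrated on unmodified L-peptides and silently imputing would produce
confident nonsense. C-terminal windows keep N→C orientation (a suffix, not
a reversal).

k-mer composition uses overlapping windows with denominator N − k + 1 and
reports **fractions summing to 1** rather than percentages. Nothing
upstream fixes this normalization; fractions were chosen because they are
scale-free for the learners and make the row-sum invariant exact. Feature
order is fixed lexicographic (A, C, D, … Y and their products), which also
satisfies the convention that alanine occupies the first cell of each
binary one-hot block. Binary (positional) encoding requires all peptides
in a matrix to share one length; mixed lengths are an error, not a
truncation.

## Physicochemical panel

Seventeen properties per peptide. Mean-scale properties average a pinned
published per-residue table over the sequence:

| property | scale | units |
|---|---|---|
| hydropathy | Kyte & Doolittle (1982) | dimensionless |
| hydrophobicity | Eisenberg consensus (1984) | dimensionless |
| hydrophilicity | Hopp & Woods (1981) | dimensionless |
| flexibility | Bhaskaran & Ponnuswamy (1988) | dimensionless |
| side-chain volume | Zamyatnin (1972) | Å³ |

Molecular weight is the average isotopic mass (Biopython ProtParam). Net
charge is a Henderson–Hasselbalch sum over the termini and the ionizable
side chains (C, D, E, H, K, R, Y) with the EMBOSS pKa set; the isoelectric
point is its unique zero on (0, 14), found by bisection to interval width
1e-9 (net charge at the result is below 1e-4 elementary charges). Class
fractions use standard memberships: positive {K,R,H}, negative {D,E},
tiny {A,C,G,S,T}, small {A,C,D,G,N,P,S,T,V}, aromatic {F,W,Y,H},
aliphatic {I,L,V}, polar {C,D,E,H,K,N,Q,R,S,T,W,Y}, amphipathic
{K,M,R,W,Y}. The original server's exact property list and scales are not
recoverable; this panel is a documented superset of the four named ones
(hydrophobicity, volume, isoelectric point, flexibility), and the method's
logic is scale-agnostic — swapping a table changes values, not behaviour.

## Learners

The regression target is the raw half-life in seconds by default, matching
the convention under which the historical MAE magnitudes (≈1.9 s for
10mers, ≈0.2 s for 16mers) are stated; a `log_target` option fits log
half-life instead and exponentiates predictions, which is the right choice
when the response is known to be multiplicative.

* **SVR** — scikit-learn's ε-insensitive SVR. When `tune=True`, a small
  inner-CV grid (C ∈ {0.1, 1, 10, 100}, γ ∈ {2⁻⁷…2³}, ε ∈ {0.01, 0.1,
  0.5}, 3 folds, Pearson-R criterion) picks hyperparameters; the grid is a
  package choice since only "tuned" is on record historically.
* **kNN** — Euclidean distance on the encoded features; k ∈ {1…10} when
  tuned, and k is clipped to the training size so k ≥ n degrades to the
  training mean. Inverse-distance weighting is offered as the documented
  stand-in for entropic instance-based learners (KStar-style), which are
  under-specified for regression and not reproduced.
* **Decision table** — a concrete realization of an under-specified
  rule-table learner: each selected feature is discretized, rows grouped
  by their joint bin pattern, each cell predicting its members' mean
  half-life. Discretization is zero-aware — exact 0 ("k-mer absent") is
  its own category and the nonzero values get 3 equal-frequency bins —
  which suits sparse composition descriptors and makes "a peptide lacking
  a k-mer all training peptides contain" fall into an empty cell, hence
  the global-mean fallback. An empty feature subset also predicts the
  global training mean.

kNN and the decision table are exactly scale-equivariant: training on
c·y multiplies every prediction by c and leaves cross-validated Pearson R
unchanged, which is the computational content of the ×10/×1000
scale-robustness experiment. SVR shares the property only after rescaling
(C, ε, and the solver tolerance) by c.

## Feature selection

CFS merit with Pearson correlations throughout (the numeric-target
behaviour of the original implementation; constant features get
correlation 0, not NaN), searched forward best-first from the empty set
with termination after 5 consecutive non-improving expansions — the
historical protocol values. Ties are broken by lexicographic feature-name
order, making the search fully deterministic.

Two caveats are deliberate:

* The early-termination depth makes the search a heuristic: on strongly
  collinear designs it can stop before backtracking to the global
  optimum. The search itself is complete — with a large stale limit it
  provably enumerates all subsets and the unit tests verify it then
  matches brute force exactly — and on planted-model problems (informative
  features among independent noise) the default depth reaches the global
  optimum on all 100 randomized test fixtures.
* Selection runs on the **full training set**, as the historical protocol
  specifies. This leaks target information into any subsequent
  cross-validation on the same data, so CV metrics computed after full-set
  selection are optimistic; run selection inside each fold (the building
  blocks support it) when unbiased estimates matter. The optional
  "locally predictive" post-processing step of the original selector is
  not implemented.

The published selected sets for 10mers and 16mers (4 and 4 residues, 8 and
3 dipeptides, 38 and 5 tripeptides) ship as named configurations so the
published model shapes can be reconstructed on user data without
re-running selection.

## Evaluation

Five-fold cross-validation: a seeded uniform shuffle (no stratification —
nothing on record suggests stratifying, and a stratified option would
change fold composition silently), near-equal folds, pooled out-of-fold
metrics. R² is anchored at the *training* mean of each fold — SD =
Σ(xᵢ − ȳ_train)² — which permits negative values whenever a model
underperforms that baseline; this reconstruction follows the stated SD
definition and is consistent with negative R² values appearing alongside
positive R in the historical benchmark grids. Constant predictions are
assigned R = 0 (no linear association) rather than an error, so a
mean-predicting baseline is comparable.

The stable-vs-unstable analysis contrasts the 20 longest- and 20
shortest-lived peptides (shrinking to ⌊n/2⌋ below 40 records); per-residue
composition differences use a two-sided Welch t-test — no test is on
record, and Welch avoids assuming equal variances between tails of a
skewed distribution. Residues constant in both groups get p = 1.0. Tie
handling makes group membership a function of (half-life, sequence) only,
independent of record order.

## Design workflows

Mutant design enumerates all 19N single-point substitutions
(position-major, residue-alphabetical), scores them with the supplied
model and reports 1-based positions, predicted half-life, whether each
mutant beats the parent, and the full panel of physicochemical deltas so
"better half-life *and* acceptable properties" stays a user decision —
the package ranks, it does not auto-accept. Protein scanning scores all
L − w + 1 windows at step 1 (1-based inclusive coordinates). Batch
filtering keeps peptides above a half-life threshold and inside optional
per-property bounds, sorted by prediction; the operation is idempotent.
Only single-point mutants are generated (the granularity of the original
service); iterative application covers multi-point exploration.

## Synthetic data

The experimental datasets are not redistributable, so the generator
produces datasets of their shape with known ground truth: i.i.d. peptides
over a residue distribution, half-life = clip(link(intercept +
w·features) + N(0, σ), lo, hi).

Defaults (chosen once, as the package's study conditions):

* **Link**: exponential, so half-lives are right-skewed across orders of
  magnitude like the published ranges; an identity link is available for
  tests that need the response exactly linear in the features.
* **Weights**: the eight published 10mer dipeptides (or the three 16mer
  ones), weight 18 each for 10mers — one motif occurrence (feature value
  1/9) multiplies the half-life by e² ≈ 7.4 — with intercept ln(0.02) s,
  spanning roughly the published 10mer range under the clip.
* **Residue distribution**: enriched 5:1 for the nine residues occurring
  in the planted dipeptides, so each motif appears in a learnable fraction
  of 189 peptides. This mirrors the real data, where exactly these
  dipeptides carried enough signal to be selected; under a uniform
  distribution a specific dipeptide appears in only ~5% of 10mers and no
  method could recover it at n = 189.
* **Noise**: σ = 5% of the standard deviation of the clean half-lives
  ("spread" is read as SD; it is not defined more precisely anywhere).
* **Clip**: the published ranges, keeping half-lives strictly positive.

The planted-single-residue variant makes half-life exponential in one
residue's composition with log-normal noise; at effect size 0 it is the
exchangeable null used for false-positive-rate checks.

What the generator does **not** emulate: the real assay's measurement
error structure, position-specific cleavage preferences, any dependence
beyond additive k-mer effects, and the exact empirical half-life
distribution. Passing recovery tests therefore show the pipeline is
correct and well-calibrated on data of this shape — not that the
published correlation values are reproduced, which is impossible without
the original measurements.

## Problem sizes and determinism

All stochastic components take explicit integer seeds (numpy Generator);
identical seeds give bitwise-identical datasets, folds and reports. The
test suite and the acceptance script use desk-scale problems — n = 189
simulated 10mers, 100 subset-search fixtures of ≤ 12 features, 50-seed
null batches — sizes at which every check runs in seconds on one CPU
while still exercising the full pipeline.

## Known limitations

* Not applicable to chemically modified residues, D-amino acids, cyclic
  peptides or disulphide-bonded peptides.
* Predictions rank peptides relatively; absolute seconds reflect the
  concentrated-protease assay, not physiology.
* The published benchmark correlations cannot be reproduced or refuted
  here (training data not redistributable); the built-in "published"
  configurations reconstruct model *shapes*, and must be trained on user
  or simulated data.
* Full-training-set feature selection (the faithful default) biases
  subsequent cross-validation optimistically, as noted above.
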