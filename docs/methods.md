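# Methods

## The sequence model

The generator is a character-level language model over a fixed 22-token
vocabulary: the 20 canonical amino acids at indices 0–19 (alphabetical by
one-letter code), the padding token `X` at index 20 and the end token `$`
at index 21. `X` doubles as the start-of-sequence primer, which keeps the
vocabulary at exactly 22 symbols while still giving sampling a termination
signal; a window is rendered as `X` + residues + `$` + `X`-padding.

The network is a stack of unidirectional LSTM layers (fused gate layout
input/forget/cell/output) followed by a dense 22-way softmax head. Training
minimises masked categorical cross-entropy in nats over next-token pairs:
the input at step *t* is the token at position *t*, the target the token at
*t + 1*. Positions whose target is the padding token are masked out by
default (otherwise the pad class dominates the loss on short peptides); the
`include_pad_loss` flag restores them for parity experiments.

Defaults follow the production configuration: two 256-unit layers with 30%
and 45% dropout (inverted dropout on each layer's output, resampled per
time step, training only), Adam at learning rate 0.02, a 200-epoch budget,
and a fixed forget-gate bias of 1.0 — the standard remedy for vanishing
forget-gate gradients on short sequences. Everything is implemented in
numpy with explicit backpropagation through time; sequence windows are
short (≤ 17 tokens for 9–15-mers) and corpora small, so full-batch CPU
training takes seconds at the sizes used here. All randomness flows through
`numpy.random.Generator` seeded from the config, making weights, loss
traces and samples bit-reproducible.

Cross-validation shuffles the corpus once (seeded), splits it into *k*
contiguous folds and re-initialises the weights with `base_seed + fold` for
every fold so no fold inherits knowledge from a previous one. The selected
architecture minimises the mean, over folds, of each trace's best-epoch
validation loss.

Sampling is autoregressive: prime with `X`, divide logits by the
temperature (default 1.0), draw, stop at `$` or `max_len`. A temperature of
0 is treated as greedy argmax decoding. Duplicate draws and exact training
matches are removed downstream by `dedupe_against`, mirroring the
generate-then-filter workflow.

### Memorization as a capacity check

The capacity test trains a 2×64-unit model on a 10-sequence corpus and asks
for (a) final training loss < 0.1 nats and (b) greedy reconstruction of
≥ 9/10 sequences. Two details make this well-posed. First, greedy decoding
from the bare start token is deterministic and can only ever emit one
sequence, so "reconstruction" is defined as greedy completion primed with
each sequence's first residue, and the fixture gives the 10 sequences
pairwise-distinct first residues. Second, a corpus of *n* distinct
sequences has an irreducible total loss of about *n*·ln *n* nats (each
sequence pays the branch entropy once), so the achievable mean loss is
floor ≈ *n*·ln *n* / total-targets. For 10 distinct 9–15-mers that floor is
≈ 0.19 nats — above 0.1 regardless of training. The fixture therefore uses
30-residue sequences (floor ≈ 0.074), which the model reaches within 500
epochs while reconstructing 10/10.

## Descriptors

* **Net charge**: Henderson–Hasselbalch sums over ionizable side chains
  (D, E, C, Y negative; K, R, H positive) plus the termini, at pH 7.4
  (physiological) by default. The pKa set shipped in `data/pka.yaml` is the
  Bjellqvist table used by common pI calculators; it is an editable data
  file so other conventions can be swapped in.
* **Isoelectric point**: bisection of the net charge on pH ∈ [0, 14] to
  |charge| < 1e-4. Net charge is strictly decreasing in pH, so the root is
  unique.
* **Eisenberg hydrophobicity / hydrophobic moment**: the consensus scale in
  `data/eisenberg.yaml`; μH is the magnitude of the vector sum of residue
  hydrophobicities placed at 100° helical intervals, divided by length —
  the standard amphipathicity measure.
* **Aromaticity** (F/W/Y fraction), **aliphatic index**
  (X_A + 2.9·X_V + 3.9·(X_I + X_L) in mole percent), **instability index**
  ((10/L)·Σ Guruprasad DIWV dipeptide weights, with length-1 sequences 0 by
  convention; the DIWV table comes from Biopython), **hydrophobic ratio**
  (fraction in {A,C,F,I,L,M,V,W,Y}, configurable) and **charge density**
  (net charge per Dalton of average molecular weight).

The "combined descriptor space" for distance comparisons is the six-feature
panel reported side by side for training vs generated sets: charge,
Eisenberg hydrophobicity, hydrophobic moment, length, isoelectric point and
aromaticity. Distances use min-max scaling fit on the reference (training)
table — constant columns are dropped with a warning, scaled values outside
the reference range are not clipped — and the summary statistic is each
row's L2 distance to the reference centroid (a single well-defined
summary; a nearest-neighbour variant would also be defensible but the
centroid is what the package reports). Welch's t statistic and
Welch–Satterthwaite degrees of freedom are computed directly from the
textbook formulas, with the two-sided p-value from Student's t; the
comparison report runs on raw feature values by default (scaled tables can
be passed explicitly).

Baselines: `random_baseline` draws residues uniformly; `helical_baseline`
places residues on a 100°-per-residue helical wheel, drawing from a
hydrophobic pool when the wheel angle falls in a 180° arc and from a
polar/charged pool otherwise, which guarantees a large hydrophobic moment.
Both resample lengths from the supplied distribution (typically the
empirical training lengths) and are fully seeded.

## Calculated CD spectra

A spectrum is a linear combination of per-class basis spectra weighted by
secondary-structure fractions, θ(λ) = Σ_j f_j B_j(λ), in mean-residue
ellipticity units on a common ascending nanometre grid — the basis-set
approach of structure-based empirical CD calculators. Basis files are
whitespace-delimited text (class-name header, then wavelength + one value
per class), so published basis sets can be dropped in; the default class
scheme is helix/sheet/coil but any class count is supported.

The filter reads the 220 nm band as the helical marker: a candidate
survives when its ellipticity there is at least as negative as the
reference's (boundary included). "Lower ellipticity" is sign-ambiguous in
prose, so the opposite reading is available behind an `invert` flag. Which
single summary (220 nm, 195 nm, or whole-curve) best reproduces a given
experimental protocol is an open choice; 220 nm is the primary helix/strand
marker and is the default.

Secondary-structure compositions are inputs: from DSSP-style strings
(`ss_from_string`, H/G/I → helix, E/B → sheet, rest coil) or user data.
The demo pipeline, which has no 3-D structure predictor in scope, assigns
each candidate a composition from a simple helix-propensity heuristic (the
fraction of residues in a helix-former set {A,E,L,M,Q,K,R,H}, plus a small
fixed sheet share). This is a stand-in that gives the CD stage realistic
variation between candidates; it is not a structure prediction, and passing
the demo says nothing about real peptides' spectra.

## Contact analysis and screening

Trajectories are multi-model PDB files (one MODEL per frame); the parser
enforces an identical atom roster across frames and names the offending
model on mismatch. Interface residue pairs are those with any heavy-atom
pair within a closed 4.0 Å threshold (hydrogens can be included by flag;
4.0 Å is a heavy-atom convention). The contact series is the per-frame
count of such pairs, optionally restricted to positively charged
peptide-side residues {R, K, H} — both selections are provided because
either can be the relevant statistic depending on the control analysis.

The screening statistic is the *unbiased sample variance* (divisor n − 1;
population variance by flag) of the contact count: low variance means the
peptide holds a stable contact footprint on the receptor. A record passes
when variance ≤ 3 (closed cut-off) and when the magnitude of its binding
free energy is ≥ 17 kcal/mol — i.e. ΔG ≤ −17 kcal/mol under the usual
MM-PBSA sign convention; energies are consumed from CSV, never computed.
Records missing an energy are flagged and fail the energy criterion rather
than being dropped. Ranking of the double-passers orders by most favorable
energy, ties by lower variance, then id, and returns the top 20 by default.
`distance_stats` (mean and SD over frames of the minimum heavy-atom
distance of a residue pair) supports the accompanying distance-fluctuation
analysis. The selected sequences are fused N-terminally with penetratin —
a pure string operation.

## Synthetic fixtures

The fixture module emulates the statistical structure each stage needs and
nothing more:

* `synth_corpus` — uniform-length peptides with an optional motif implanted
  at a random position in every sequence (gives the LSTM learnable
  structure) and optional composition bias.
* `synth_contact_records` — defaults to the production pool shape of 127
  records with exactly 57 below the variance cut-off of 3; each series'
  variance is verified by direct recomputation at generation time and
  resampled until it lands on the intended side, so downstream screen tests
  are exact, not probabilistic. Energies straddle the 17 kcal/mol magnitude
  threshold.
* `synth_trajectory` — a two-chain toy system whose frame-*t* contact count
  equals a prescribed schedule (contacting pairs at 3.5 Å, others at 8 Å,
  pairs spaced 50 Å apart so cross-pair contacts cannot occur).
* `synth_basis` — smooth Gaussian-band toy basis curves (helix-like double
  negative band near 208/222 nm, sheet-like band near 218 nm, coil-like
  band near 198 nm).

These fixtures are statistically structured but biologically arbitrary:
passing tests demonstrates the correctness and determinism of the
machinery, not that the pipeline would select active NLRP3 inhibitors from
real data.

## Pipeline and problem sizes

The demo pipeline runs every stage on synthetic data with a deliberately
small model (one 32–48-unit layer, ~100 epochs, 60–150 draws); these sizes
were chosen so the full demo completes in seconds on one CPU core while
exercising identical code paths to the production configuration (2×256
units, 200 epochs, 1018 draws), which is selected simply by omitting the
overrides. The screening stage maps synthetic contact records onto the
CD-surviving candidate ids, truncating at the configured pool size (127)
and scaling the planted low-variance count proportionally (57/127) when
fewer candidates exist — the linkage between generation and the MD pool is
a workflow hand-off (docking and MD themselves are out of scope), so the
demo keeps the pool shape rather than inventing structure data.

Determinism is end-to-end: a config fully determines every artifact, and
re-running produces byte-identical outputs (the manifest records seeds,
thresholds and the candidate funnel).

## Known limitations

* The LSTM is CPU/numpy; it is not intended for corpora beyond a few
  thousand short sequences.
* Greedy-decoding capacity checks require distinguishing prefixes; they are
  a memorization probe, not a generative-quality metric.
* The redundancy reducer is O(n²) in pairwise alignments — fine for
  thousands of short peptides, not for large databases.
* CD calculation inherits the basis-set approximation: non-secondary
  structure contributions and intensity-scaling errors are not modelled.
* The contact-variance screen consumes trajectories and energies; it cannot
  detect problems upstream of them (force field, sampling, docking pose).
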