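# pepgen

A toolkit for de novo design of short inhibitory peptides targeting
protein–protein interfaces — built around the NLRP3-inflammasome use case,
where candidate peptides are designed to disrupt the PYD–PYD interactions
between the NLRP3 sensor and the ASC adaptor.

The pipeline couples a generative sequence model with a cascade of
physics- and property-based screens:

1. **Corpus preparation** — read short peptides (9–15 residues) from FASTA,
   drop redundant sequences by greedy CD-HIT-style clustering at >90%
   global-alignment identity, and encode them over a 22-token vocabulary
   (20 amino acids + pad/start `X` + end `$`).
2. **Generative model** — a character-level LSTM language model (two
   256-unit layers, 30%/45% dropout, Adam at learning rate 0.02, fixed
   forget-gate bias) trained with masked categorical cross-entropy
   `L(t, y) = −Σ_k t_k log y_k` over next-token predictions; five-fold
   cross-validation over a unit-count grid selects the architecture, and
   novel peptides are sampled autoregressively with temperature-scaled
   softmax.
3. **Descriptor screening** — global physicochemical descriptors (net
   charge at pH 7.4, Eisenberg hydrophobicity and hydrophobic moment μH,
   isoelectric point, aromaticity, aliphatic and instability indices),
   min-max scaled to the training set; generated peptides are compared to
   random and amphipathic-helical baselines via Welch's t-tests and
   Euclidean distances to the training centroid in the scaled space.
4. **Calculated CD spectra** — mean-residue ellipticity as a linear
   combination of secondary-structure basis spectra,
   `θ(λ) = Σ_j f_j B_j(λ)`; candidates whose 220 nm helical band is weaker
   than a reference spectrum are removed.
5. **Contact-variance screen** — from multi-model PDB trajectories,
   peptide–receptor residue contacts at a closed 4.0 Å heavy-atom cutoff;
   candidates pass when the unbiased sample variance of the per-frame
   contact count is ≤ 3 and the magnitude of their binding free energy
   (consumed from MM-PBSA output) is ≥ 17 kcal/mol. The top 20 survivors
   are ranked by binding energy and fused N-terminally with penetratin
   (`RQIKIWFQNRRMKWKK`) for cell delivery.

A synthetic-fixture module generates motif-bearing corpora, toy basis
spectra, contact series with a planted number of low-variance records, and
two-chain toy trajectories, so the whole pipeline runs and is tested
without any external data.

## Worked example

Run the fully synthetic demo pipeline:

```bash
cat > demo.yaml <<'YAML'
seed: 11
out_dir: demo_run
corpus: {synth_n: 60, synth_motif: KRLWK}
model: {units: 48, layers: 1, dropout: [0.1], epochs: 100}
sampling: {n_draws: 120}
compare: {n_random: 80, n_helical: 80}
YAML
pepgen pipeline --config demo.yaml
cat demo_run/distances.json
```

which prints (numbers from this exact config and seed):

```
{
  "gen": {"mean": 0.628183, "sd": 0.341992},
  "helical": {"mean": 1.048078, "sd": 0.301881},
  "random": {"mean": 1.115086, "sd": 0.303385}
}
```

Generated peptides sit markedly closer to the training centroid in the
scaled descriptor space (0.63) than uniform-random (1.12) or idealised
helical (1.05) baselines — the signature that the language model has
absorbed the training distribution rather than emitting arbitrary
sequences. `demo_run/` also contains the cleaned corpus, model checkpoint,
loss trace, sampled and deduplicated FASTA files, the per-feature Welch
comparison table, the CD pass list, the screening report with variance and
energy flags, and the ranked, penetratin-fused top candidates
(`top_candidates.csv`), plus a `manifest.json` recording every threshold
and the candidate funnel.

Individual stages are exposed as subcommands (`pepgen prepare`, `train`,
`cv`, `sample`, `describe`, `compare`, `cdfilter`, `screen`,
`pepgen synth …`); see `pepgen --help`.

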