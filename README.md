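# ethosyntax

Analysis of behavioral bout-sequence "syntax" in frame-labeled ethograms:

- **ethogram** — run-length encode frame label streams into (action, duration)
  bouts, delete sub-threshold artifact bouts (default 167 ms), drop standing,
  and bin bout durations into per-action equal-occupancy categories
  (short/medium/long).
- **markov** — action×duration-category state spaces (6/12/18 states),
  maximum-likelihood transition matrices (row-normalized pooled counts with
  same-action blocks identically zero), log-likelihoods, BIC
  (`ln(n)·k − 2·lnL`), early/late phase splitting, and matrix residual
  comparison.
- **nulls** — duration-permuted and order-permuted null transition models,
  both in closed form (the infinite-permutation limit) and by explicit
  within-fly Monte-Carlo permutation with per-entry standard errors.
- **mrp** — nonstationary Markov renewal process simulation: a time-varying
  transition matrix interpolates linearly from an early to a late matrix over
  a switch time (default 13 min), while bout durations are drawn from
  state-specific empirical pools.
- **motifs** — anterior/posterior motif segmentation, body-vs-leg time
  coupling, intra-motif transition fractions, and sliding-window behavioral
  progression curves.
- **synth** — ground-truth synthetic cohorts (block-structured matrices with
  configurable within-motif mass, duration-category coupling, anterior→
  posterior drift, and injectable sub-threshold label noise) for end-to-end
  validation of every stage.

## CLI

```sh
# generate a synthetic cohort (frame files + ground-truth manifest)
ethosyntax synth --seed 7 --n-flies 3 --out-dir cohort/

# frame labels -> de-noised bout ethogram
ethosyntax discretize cohort/synth-000.frames.txt -o fly0.bouts.csv

# MLE transition matrix over 18 states (6 actions x 3 duration bins)
ethosyntax fit fly*.bouts.csv --n-bins 3 -o matrix.csv

# analytic null matrices and BIC model comparison
ethosyntax nulls fly*.bouts.csv --n-bins 3 -o null_
ethosyntax bic fly*.bouts.csv --n-bins 3 -o scores.json

# motif table, progression curve, MRP simulation
ethosyntax motifs fly*.bouts.csv -o motifs.csv
ethosyntax progression cohort/*.frames.txt -o progression.csv
ethosyntax simulate --model cohort/truth_model.json --seed 5 -o sim.bouts.csv
```

All file formats are plain text (label-per-line frame files with `#` headers,
bout CSVs, matrix CSVs with `action.category` labels such as `h.s`, JSON for
schemes/models/scores).

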