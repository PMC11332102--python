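# infoflow

Directed-influence analysis for coupled daily count time series —
built for the question "does national media coverage drive local public
sentiment?", and applicable to any small panel of count series where
directed, possibly confounded influence is at stake.

The package implements a four-stage causal analysis over panels of
daily counts (one national media series MPB, and per-area local-crime
coverage MLC, positive tweets PT, negative tweets NT):

1. **Preprocessing** — additive seasonal-trend adjustment by locally
   weighted regression (weekly / monthly / yearly seasons), a one-day
   backward shift for print-media series, and a sparsity/concentration
   screen for area inclusion.
2. **Conditional transfer entropy** — series are symbolized into
   rank-based tertiles and the plug-in estimate

   TE(Y→X | Z) = H(X_{t+1} | X_t, Z_t) − H(X_{t+1} | X_t, Y_t, Z_t)

   is computed in bits.  Significance comes from a grouped-permutation
   surrogate: source symbols are shuffled *within* strata defined by
   the joint (target, conditioner) state, preserving every nuisance
   dependence while destroying the tested one; a link is significant
   when the observed value exceeds the 95th percentile of B = 20,000
   surrogates.  Conditioning on the third series removes common-driver
   and cascade confounds.
3. **Sign and dynamics** — significant links are signed by lagged
   partial Spearman correlation (source past vs target present,
   controlling target and conditioner pasts), and independently probed
   by convergent cross mapping (CCM): simplex projection on delay
   embeddings, with skill that converges in library length only for a
   true causal direction.
4. **Event study** — at minute resolution, paired pre/post posting
   rates around media events compared by a one-tailed Wilcoxon
   signed-rank test, swept over window semi-widths of 30–720 minutes.

Because raw social-media data cannot be redistributed, every stage
ships with synthetic generators of known causal structure
(`infoflow.synth`, `infoflow.dynpanel`): coupled 3-state Markov chains
in direct / common-driver / cascade motifs with Poisson count
emissions, seasonal count series, coupled logistic maps, and
baseline-plus-excitation point processes.

## Worked example

Generate a study-shaped panel (3745 days, six areas) in which the
national series drives each area's negative-tweet counts with copy
probability 0.3, then run the transfer-entropy stage:

```bash
python analysis/01_simulate_panel.py
python analysis/03_te_surrogates.py
```

prints (seeds fixed in the scripts):

```
[coupled] 6 areas, B=20000, 322s
  MPB->NT|MLC significant: 6/6 (median TE 0.0524 bits, median q95 0.0099)
  other links significant: 0/12
  sign analysis: all MPB->NT partial correlations positive: True
[null] 6 areas, B=20000, 290s
  MPB->NT|MLC significant: 0/6 (median TE 0.0063 bits, median q95 0.0099)
  other links significant: 1/12
```

Reading: in the coupled panel the true link MPB→NT∣MLC clears the
surrogate threshold in every area (0.05 bits against a null 95%
quantile of 0.0099 bits — the analytic chi-square null for tertile
symbols at 3744 transitions is χ²₃₆(0.95)/(2·3744·ln 2) ≈ 0.0098), the
twelve uncoupled links are never flagged, and the sign analysis
recovers the positive association.  On the null panel the one false
positive out of eighteen tests matches the 5% nominal level.  The
remaining drivers (`02` screening/adjustment diagnostics, `04` CCM
convergence, `05` event study) write their tables under `results/`.

The same stages are scriptable via the CLI:

```bash
infoflow simulate --n-areas 6 --coupling 0.3 --out panel.csv
infoflow te --panel panel.csv --seed 1 --out results/
infoflow ccm --panel panel.csv --seed 1 --out results/
```

## Layout

- `src/infoflow/` — the library: `preprocess`, `infocore`,
  `surrogates`, `partialcorr`, `ccm`, `events`, `synth`, `dynpanel`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, estimators, parameter choices, and what
  the synthetic benchmarks do and do not establish.
- `tests/` — unit, property and end-to-end statistical tests.
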