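# Methods

## Estimators

Let a score cutoff define an accepted set containing `T` target and `D`
decoy rank-1 PSMs. The classical target-decoy estimate is
`FDR_TDS = (D + 1)/T`, optionally multiplied by a database-size correction
`factor`, estimated as the ratio of target to decoy PSMs at a fixed low
rank (default rank 5, configurable), where essentially all matches are
incorrect.

The candidate-weighted estimate uses the per-spectrum candidate counts.
For spectrum *i* with `target_i` target and `decoy_i` decoy candidate
peptides inside the precursor tolerance, an incorrect match is a target
with probability `P(t_i) = target_i/(target_i + decoy_i)`. Modelling
repeated incorrect matching as Bernoulli draws, the number of draws until
a target (decoy) hit is geometric with expectation `1/P(t_i)`
(`1/P(d_i)`), and

```
FDR_cTDS = Σ_{i ∈ D} 1/P(d_i)  /  Σ_{i ∈ T} 1/P(t_i).
```

Design choices, all of which a caller can override or inspect:

* **Pseudocount.** TDS carries its customary `+1` in the numerator; cTDS
  is implemented without one, exactly as defined. A `plus_one` switch
  (`as-paper` default / `none` / `both`) exists for sensitivity analysis;
  `both` adds one unit (one expected decoy draw) to the cTDS numerator.
* **Thresholding.** Acceptance at level α uses q-values — the running
  minimum of the estimated FDR over all cutoffs at least as permissive —
  so accepted sets are nested in α. FDR columns are reported uncapped;
  q-values are capped at 1.
* **Ties.** Equal-score PSMs are ordered decoy-before-target
  (conservative: the decoy penalises the tied block before any tied
  target is counted), then by spectrum id for determinism. The accepted
  count is therefore invariant to input permutation.
* **Undefined probabilities.** Spectra with zero candidates have
  undefined `P`; they are excluded from the cTDS sums and counted in a
  diagnostic. A target-labelled PSM always has `target_i ≥ 1` (the matched
  peptide is itself a candidate), so its weight is always defined.
* **Correction factor and cTDS.** cTDS is invariant to the factor by
  construction. Where a corrected view of the `P(t_i)` distribution is
  wanted (the candidate-count analogue of correcting TDS), the package
  uses `target_i/(target_i + decoy_i·factor)`; the exact transformation is
  not standardised, and this choice reduces to the plain probability at
  factor 1 and recentres count-imbalanced databases at 0.5.

The false match rate of an entrapment experiment — reference database plus
known-absent entrapment sequences as the target side — is
`FMR = #accepted targets matching entrapment / #accepted targets matching
reference`, computed on the same accepted sets.

## Decoy constructions

`reverse` reverses the whole protein. The segment-based methods split the
protein so that every K or R ends a segment and stays at its position
(no proline exception in segmentation), and rearrange only the residues
before each anchor: `pseudo_reverse` reverses each segment,
`pseudo_shuffle` permutes it uniformly (Fisher–Yates). The trailing
anchor-free segment is treated like any other. Consequences: anchors and
per-segment composition are always preserved, and pseudo-reverse leaves
the multiset of 0-missed-cleavage tryptic peptide masses identical between
target and decoy, so reverse/pseudo-reverse give target and decoy peptide
sets of equal size while the stochastic methods generally do not — which
is what motivates the correction factor for TDS.

`de_bruijn` regenerates each segment by a random Eulerian walk on the
segment's order-k de Bruijn multigraph (k ≥ 2, default 2): nodes are the
segment's (k−1)-mers, each k-mer contributes one edge emitting its last
letter, and the walk starts at the segment's first (k−1)-mer and consumes
every edge exactly once, choosing among available edges with probability
proportional to the database amino-acid frequency of the emitted letter.
A completed walk preserves the segment's length, residue multiset and
k-mer multiset. Segments shorter than k, or for which no complete walk is
found within 32 restarts, fall back to a pseudo-shuffle of that segment
(logged). The walk-based construction is this package's own; published
descriptions of de Bruijn decoys leave k, the traversal and composition
handling open, so the known worked instances are treated as admissible
outcomes (length/anchor/composition constraints), not byte targets.

Stochastic methods draw from a per-protein stream seeded by
`(seed, SHA-256(accession))`, making databases reproducible and each
protein's decoy independent of the rest of the database.

## Digestion and candidate counting

Digestion is fully tryptic: cleavage C-terminal to K/R, by default not
before proline (the default trypsin of common search engines; the proline
rule is a flag). Database digestion uses up to 2 missed cleavages and
length bounds 7–50 (the bounds are conventional search-engine defaults,
each disable-able; `tryptic_digest` itself applies no bounds unless asked).
Masses are neutral monoisotopic: the sum of residue masses plus water,
with fixed carbamidomethyl-C (+57.02146 Da) and variable oxidation-M
(+15.99491 Da, up to 3 per peptide) as the default modifications. The
residue-mass table is embedded and unit-tested against an independent
calculator. Peptides containing B/J/O/U/X/Z have no defined monoisotopic
mass and are excluded from indexing with a logged count.

The candidate unit is a distinct (peptide sequence, modification variant)
pair per database side, deduplicated across parent proteins — mirroring
how a search engine enumerates scoring candidates. The index is a sorted
mass array with an origin prefix-sum; a query at tolerance `t` ppm counts
entries in the closed window ±(mass·t·10⁻⁶), single window, no
isotope-error offsets. Default tolerance: 20 ppm.

## The simulator

`simulate_search` draws, per spectrum: an incorrect-match indicator
(probability `frac_incorrect`, default 0.3); candidate counts
`target_i ~ 1 + Poisson(λ_t)`, `decoy_i ~ 1 + Poisson(λ_d)` (the `1 +`
keeps both sides ≥ 1, consistent with the matched peptide being a
candidate); a label — always target for correct matches, target with
probability `P(t_i)` otherwise; and a score from a two-component Gaussian
mixture (correct `N(4, 1)`, incorrect `N(0, 1)`; only the ordering
matters to the estimators). Incorrect targets are classed as entrapment
matches and correct ones as reference (flipped to entrapment with
probability `entrap_frac`, default 0 — i.e. the reference covers every
truly present peptide), so the simulated FMR is directly comparable to
the nominal threshold. Ranks 2–5 are always incorrect and generated the
same way, ordered by score, to exercise the rank-5 correction factor.

Defaults are the package's study conditions: `n_spectra = 50,000`,
`frac_incorrect = 0.3`, and `λ_t = λ_d = 40`. The rate 40 was chosen so
the `P(t_i)` distribution matches the qualitative shape seen in
protein-level searches — most mass near 0.5 with a heavy-tailed
minority, and an exactly-0.5 fraction of `Σ_k P(K=k)² ≈ 1/(2√(πλ)) ≈
4.5%`, inside the few-percent range reported for real data. The
asymmetric benchmark condition (`λ_t = 1, λ_d = 3`) makes incorrect
matches land on decoys about twice as often as on targets, the regime
where plain TDS is strongly conservative.

What the simulator does **not** emulate: spectra and fragment matching
(scores are exchangeable mixture draws, not search-engine scores),
correlation between a spectrum's candidate count and its score, shared
peptides between target and decoy databases, and the very large candidate
counts (hundreds to thousands) of full-proteome searches. Passing tests
therefore show that the estimators behave as designed under their own
sampling assumptions — calibration under symmetry, accuracy advantage
under count asymmetry — not that real-data FDR differences will have any
particular magnitude. The end-to-end synthetic database runs use small
proteomes (hundreds of proteins), so candidate counts per spectrum are
small and the exactly-0.5 fraction is correspondingly much larger than in
a full-proteome search; these runs validate the plumbing and the
qualitative behaviour, not proteome-scale percentages.

## Numerical and degenerate-input choices

* cTDS sums use float64 cumulative sums over score-sorted arrays; the
  two-pass reference summation agrees to 1e-12 relative in tests.
* A cutoff prefix with `T = 0` has undefined FDR (reported as infinite in
  curves; point estimators raise).
* `correction_factor` raises when no decoys exist at the chosen rank,
  suggesting a different rank.
* Empty FASTA files, malformed entries, unknown residues and candidate
  counts that are neither embedded in the PSM table nor computable all
  raise with the offending item named. Embedded counts take precedence
  over computed ones, with disagreements logged.

## Problem sizes

The test suite and the acceptance script use 5×10⁴ spectra per simulated
search, 10–20 replicate seeds for the Monte-Carlo comparisons, 10³
proteins for decoy-invariant checks and a few hundred proteins for
end-to-end runs — sizes at which every Monte-Carlo band in the tests
(3 binomial standard errors, Bonferroni-adjusted where many bins are
tested) is meaningful while a full run stays in the minutes range on a
single CPU.

## Known limitations

* Protein-level decoys only; peptide-level decoy databases (where the
  two estimators coincide by construction) are out of scope.
* No peptide- or protein-level FDR roll-up, rescoring, or posterior error
  probabilities.
* Candidate counting is precursor-mass-only; fragment tolerance is
  accepted in configuration for provenance but unused.
* The de Bruijn construction is one principled reading of an
  under-specified method; other implementations may differ byte-wise
  while satisfying the same constraints.
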