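# Methods

## Scope and model

`tmcensus` quantifies the membrane-proteome contrast between prokaryotic
dsDNA viruses and their bacterial/archaeal hosts. The quantities of
interest are per-genome TM-protein fractions, the distribution of
TM-segment counts per protein, the virus-specificity (Viral Quotient) of
orthologous gene families, and the association of TM content with virion
lipid association and host domain. Orthogroup membership, prophage
coordinates and lipid-class labels are consumed as inputs; building them
(homology clustering, prophage detection, virion annotation) is out of
scope.

## TM segment calling

The built-in predictor is a deterministic hydropathy sliding-window
caller, not an HMM. Rules, in order:

1. **Seeding.** Every window of `window` residues (default 19 — the
   classic hydropathy-plot width, matching the ~20 residues needed to span
   a bilayer) whose mean Kyte–Doolittle hydropathy is ≥ `threshold`
   (default 1.6 scale units) marks all residues it covers.
2. **Merging.** Maximal seeded runs separated by fewer than `merge_gap`
   (default 3) residues are merged.
3. **Boundary trimming.** Run ends are trimmed while the terminal
   residue's hydropathy is below `trim_threshold` (default 0.0). The union
   of qualifying windows systematically overshoots into flanking loops by
   several residues per side; trimming restores helix-scale boundaries, as
   boundary-refinement steps do in classical window-based callers. Without
   it, called lengths run ~4–5 aa long per side and the ~20 aa
   characteristic length is unrecoverable.
4. **Splitting.** Runs longer than `max_len` (default 35) are split at the
   lowest-hydropathy interior residue, recursively, and re-trimmed. This is
   what separates two planted helices whose seed runs bridge a short loop.
5. **Length filter.** Runs shorter than `min_len` (default 15) are
   dropped.

The scale is pluggable (`HydropathyScale`); Kyte–Doolittle is the default
because it is the standard, reproducible choice. Defaults were fixed so
that planted-helix recovery on the generator's study conditions meets its
design targets (≥ 95 % exact-count recovery); they are deliberately
ordinary values for this family of methods. Sequences shorter than one
window yield a zero-segment prediction rather than an error.

**Orientation.** The positive-inside rule: Lys+Arg are counted in the
alternating inter-segment loops under both orientations and the N-terminal
side is set so the richer loops face inside. Ties break to N-in, the
topology dominant in nearly all organisms.

**Signal guard.** A heuristic tripartite n/h/c detector: ≥ 1 Lys/Arg in
the first 5 residues, a hydrophobic run of 7–15 residues (each ≥ 1.5 KD)
starting by position 10, then an A-X-A-style small-residue motif within 6
residues of the run end (the motif search starts just before the run end,
since Ala in the motif is itself hydrophobic). When a signal is detected,
called segments **starting** inside the signal region are removed. The
start-based rule (rather than "wholly contained") is deliberate: a
segment seeded jointly by the signal's h-region and early mature residues
belongs to the export signal, and removing only wholly-contained segments
would let a planted signal *create* TM calls. A protein with ≥ 1 remaining
segment counts as a TM protein regardless of the signal flag.

## Census

Per-genome rows keep the raw (uncapped) TM-count histogram; the capped
view (`0..cap-1` plus a `cap+` overflow bucket, cap 15 by default, 4 in
figure-style summaries) is derived on demand. Invariants enforced at
construction: histogram sums to the protein count, TM mass at k ≥ 1 equals
the TM-protein count, cross-tab margins match.

**Redundancy reduction.** Virus genome pairs sharing ≥ `threshold`
(default 0.9) of their genes are linked and each single-linkage component
keeps one seeded-random representative. The shared fraction divides the
common orthogroup count by the smaller genome's orthogroup-assigned gene
count (`mode="min"`); a Jaccard alternative is provided since the
literature phrase "share at least 90 % of their genes" does not fix the
denominator. Min-denominator is the default because it makes a subset
genome maximally redundant with its superset. Genomes with no
orthogroup-assigned genes cannot be judged and are kept with a warning.
Cellular genomes keep the largest genome (most proteins) per genus, ties
to the lexicographically smallest id.

## Viral Quotient

With genome-frequencies f_V (virus genomes containing ≥ 1 member), f_C
(cellular genomes containing ≥ 1 member anywhere) and f_P (cellular
genomes with ≥ 1 member inside a prophage region):

    VQ = (f_V + f_P) / (f_V + f_P + f_C)

"Frequency" is per-genome presence, not protein counts, which makes VQ
invariant under proportional scaling of the universe. The prophage term
credits integrated phage copies to the viral side while the cellular term
still counts every cellular genome containing matches; this algebra
reproduces all three boundary behaviours that define the statistic
(virus-only → 1, cellular-only non-prophage → 0, prophage-only → 0.5).
The phrase "added to both fractions" admits a second reading in which the
prophage frequency also enters the denominator twice; it is available as
`prophage_mode="double"` but is not the default because it breaks the
prophage-only = 0.5 anchor. Exactly VQ = 0.5 classifies as predominantly
viral, consistent with the prophage-only case.

## Statistical tests

- **Mann–Whitney–Wilcoxon**: two-sided. The exact permutation distribution
  of U (midranks for ties) is enumerated whenever C(n+m, n) ≤ 100 000; the
  two-sided p is the probability of a U at least as far from nm/2 as
  observed. Tie-free samples up to n·m ≤ 400 use the exact rank-sum
  distribution; everything else uses the normal approximation with midrank
  tie correction. Exactness with ties beyond the enumeration cap is not
  attempted — no closed form exists — so large tied samples are
  approximate. Reported p-values below 2e-16 print as a floor (`< 2e-16`),
  since values at that magnitude are floating-point floors, not
  measurements.
- **Chi-squared**: Pearson statistic without continuity correction.
  Histogram comparisons align count maps on the union of keys; columns
  whose minimum expected count falls below 5 are merged rightward (a
  deficient last column folds left) until adequate or only two columns
  remain; fewer than two usable bins is an error.
- **Correlation**: Pearson product-moment; binary covariates (lipid
  association with tentative labels inheriting their class; host domain
  with Archaea = 1 so archaeal enrichment is positive) give point-biserial
  values. Zero variance on either side is an error, not a NaN.

No multiple-testing correction is applied across a report; the report is a
small fixed panel of planned comparisons.

## Synthetic data generator

The generator emulates the census's study conditions:

- **Class structure.** Virus-like genomes (default 40, ~80 genes each,
  negative-binomial) target a mean TM fraction of 0.08; cell-like genomes
  (default 12, ~300 genes) target 0.22 — the 20–25 % band with sampling
  spread. Lipid-associated virus families (default 15 % of genomes,
  assigned by a deterministic stride so genome counts don't reshuffle the
  labels) get a 7× TM-target multiplier, renormalized so the class mean
  stays 0.08; this plants the lipid/TM-content association the group
  comparisons measure. Families, host domains and (tentative) lipid
  classes come from a fixed table of real family names.
- **TM-count distributions.** Virus-like TM proteins carry 1–3 segments;
  cell-like ones follow a heavy-tailed distribution with secondary modes
  at 6 and 12 segments, the signature of cellular transporter families.
- **Protein anatomy.** Helix lengths ~ N(21, 1.5) truncated to [19, 25]
  and rounded; loops ≥ 10 aa (N(16, 3)); helices sampled from a
  hydrophobic-enriched composition, loops from a hydrophilic K/R-free
  composition plus explicitly placed Lys/Arg: `round(0.15·len)` per loop
  with a planted excess of 3 on 'in'-side loops (placing the counts
  deterministically rather than binomially is what makes the
  positive-inside signal reliably recoverable at bias 3). Soluble proteins
  use a surface-biased hydrophilic composition so hydrophobic windows stay
  rare, as in real soluble proteins; ~4 % of proteins get a signal peptide
  (Met + 2 basic, 8–12 aa hydrophobic core, A-X-A motif).
- **Orthogroups.** Each conserved gene (60 % default) joins a group in a
  viral or cellular pool keyed by its TM count; the group's prototype
  protein is generated from a group-specific substream and members are
  loop-only perturbations (substitutions at non-K/R loop positions, rare
  single-residue loop indels), so orthologs retain the planted TM count by
  construction. A small cross-pool rate (5 %) puts some families in both
  viruses and cells; prophage blocks (20 genes, half of cellular genomes)
  draw from the viral pool, exercising the VQ prophage correction.
- **Determinism.** All randomness flows from one seed through
  fixed-purpose substreams (`default_rng([seed, stream, index, ...])`):
  per-genome streams mean adding genomes never shifts existing ones, and
  prototypes are independent of which genome first uses them. Same spec +
  seed → byte-identical outputs.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: real sequence composition (planted helices and
loops are compositionally cleaner than real ones, so recovery rates here
are upper bounds), homology at realistic divergence (orthologs are
near-identical copies), genome organisation and gene order, the
Lipothrixviridae-style exceptions where lipid association and TM content
decouple, and the long tail of partial/fragmented proteins in real
annotation. Statistical behaviour of the census and tests transfers; raw
recovery percentages do not.

## Problem sizes

Default test and acceptance runs use the default spec (≈ 6 500 proteins
across 52 genomes) and 1000-protein predictor benchmarks; these sizes give
binomial standard errors well inside the asserted tolerances while keeping
the full suite fast. Reference quantities in `scripts/acceptance.py` are
computed at the same sizes.

## Known limitations

- The caller is single-scale and windowed; it does not model helix
  probability sequence context as Phobius's HMM does, and marginal helices
  (mean hydropathy near the threshold) can be missed or split differently.
- Signal-peptide detection is a motif heuristic, weaker than SignalP;
  its role here is the guard invariant, not standalone accuracy.
- MWW exactness with heavy ties is bounded by the enumeration cap.
- `select_representatives` is O(n²) in genomes with orthogroup sets held
  in memory; adequate for thousands of genomes, not for millions.
- Coordinates are 1-based inclusive everywhere; interoperating code using
  0-based half-open conventions must convert at the boundary.
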