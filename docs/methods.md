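# Methods

This note documents the models and conventions implemented in
`paretarget`: what is assumed, what is tunable, and which choices were
genuinely open design decisions.

## Cleavage geometry and duplex alignment

Plant AGO slicing cuts the target between the nucleotides paired to
miRNA positions 10 and 11. The degradome read's 5′ nucleotide therefore
marks the transcript coordinate *t* paired to miRNA position 10, and in
an ungapped duplex the partner of miRNA position *p* (1-based, 5′→3′)
sits at transcript coordinate *t* + 10 − *p*. Target-site windows are
extracted as [*t* − (*L* − 10) − *g*, *t* + 9 + *g*] for a miRNA of
length *L* with a bulge budget of *g*; windows clipped by transcript
ends are flagged truncated, and truncated sites are not scored as
duplexes.

Alignment assigns exactly one state per miRNA position — Watson–Crick
`match`, `gu` wobble, `mismatch`, or `gap` — and allows up to
`max_gaps` single-nucleotide bulges on either strand (default 1),
with position 10 pinned opposite the cleavage nucleotide (no bulge may
attach there). Two bulge types exist:

* an unpaired miRNA nucleotide carries the `gap` state itself;
* an unpaired target nucleotide attaches its `gap` state to the miRNA
  position processed outward from the anchor just after the bulge —
  the 3′-adjacent position in the 3′ half (positions 11..*L*), the
  5′-adjacent one in the 5′ half (9..1), since the other neighbour has
  already been consumed toward the anchor and every position carries
  exactly one state. Some indexed-reporting convention is required
  here; this one keeps the state vector a total function of miRNA
  coordinates.

The aligner is a small dynamic program over each anchor half,
minimizing the position-weighted penalty score below; ties prefer fewer
bulges, then bulges closer to the miRNA 3′ end. Positions that fall off
the transcript end pair nothing and are scored as mismatches. The DP is
tested for exact score-and-state agreement against brute-force
enumeration of every single-bulge placement.

## Alignment score

The classic plant-targeting score: per position, penalty 0 for a
Watson–Crick pair, 0.5 for G:U, 1.0 for a mismatch, 1.0 for a bulge;
penalties are doubled in the core region, miRNA positions 2–13. The
score's atom is therefore 0.5, which is why score caps are half-integers.

## Hybridization strength (MFE ratio)

A duplex's hybridization strength is summarized as
ΔG(duplex) / ΔG(perfect duplex), both from the same backend, so a
perfect duplex scores exactly 1.0 and anything weaker scores less. The
default backend is a self-contained nearest-neighbour model over the
fixed alignment:

* Turner-style 37 °C stacking free energies for consecutive paired
  positions (Watson–Crick and G:U), closed under strand-exchange
  symmetry; the rare destabilizing wobble–wobble steps are treated as
  unstacked so that breaking a pair can never stabilize the duplex —
  this keeps the ratio monotone under any match→mismatch conversion;
* helix initiation +4.09 kcal/mol and +0.45 per AU/GU pair closing the
  duplex ends;
* every unpaired miRNA position is charged 0.5 kcal/mol (terminal runs
  included), a constant-loop surrogate for internal-loop and bulge
  initiation;
* isolated end pairs with no stacked neighbour contribute nothing (an
  optimal fold would leave them open);
* duplexes whose energy is non-negative report ratio 0.0.

The per-nucleotide loop charge was calibrated once against ViennaRNA's
RNAduplex on seeded random near-complementary duplexes (0–3 edits) and
then frozen. On that population the two backends' ratios agree to ~0.02
on average, with ~90% of duplexes within 0.05; the residual spread is
the sequence dependence of internal-loop energetics, which a
fixed-alignment constant-loop model intentionally does not express.
RNAduplex (through the ViennaRNA Python bindings) is available as a
pluggable backend behind the same interface and serves as the
independent cross-check in the test suite; it is not a dependency of
the default path.

## Degradome peaks

Per transcript, degradome reads contribute their full abundance at the
1-based coordinate of every exact, full-length, sense-strand occurrence
(multi-mapping reads are counted per occurrence, without apportioning —
the simplest reproducible rule). Positions with abundance > 1 are
categorized: 0 = unique transcript maximum, 1 = tied maximum,
2 = above the mean, 3 = at/below the mean. The mean is taken over the
*occupied* (nonzero) positions: averaging over transcript length would
push nearly every occupied position above the mean and empty category 3.
Ties at the mean fall to category 3 so the categories partition.
Categories 0/1 are high-confidence (HC), 2/3 low-confidence (LC); peaks
below the abundance floor (default 5) are dropped because such weak
signals cannot be distinguished from random degradation.

## miRNA candidates and conservation

Homology matching of sRNA reads to known mature miRNAs is ungapped,
sense-strand sequence identity with ≤ 2 mismatches; G:U counts as a
mismatch here (identity, not pairing). Reads differing in length by ≤ 2
slide along the longer sequence with unpenalized overhangs and take the
minimum Hamming distance — equal-length-only matching would discard
ordinary isomiR-like length variants; > 2 nt difference never matches.
A candidate whose homology matches span more than one clade is
*conserved*; matches confined to one clade, or no match at all, make it
*species-specific*. Clades come from a species-prefix→clade map shipped
as package data and user-overridable. Abundance floor: 5 reads, also
for user-supplied miRNA lists (which bypass homology only).

## Criteria inference and the retain rate

From the duplex population (HC interactions by default), criteria are
inferred to retain at least a fraction *r* (default 0.85):

1. rank duplexes by (score ascending, MFE ratio descending, then a full
   deterministic tie-break); the first ceil(*r*·*n*) form the retained
   quantile subpopulation;
2. positional allowances at 10/11 open only if a *retained* duplex has a
   non-Watson–Crick state there, so outliers cannot unlock them;
3. each count cap is the smallest integer covering a fraction *r* of
   duplexes marginally (type-1 lower empirical quantile — thresholds
   must be achievable values); the score cap is the *r*-quantile of
   scores rounded up to 0.5 (the score atom); the MFE floor is the
   (1−*r*)-quantile of ratios rounded down to 0.01 (two-decimal
   convention for reported cutoffs);
4. marginal thresholds alone can under-retain jointly (different
   duplexes fail different rules), so every threshold is widened to the
   fieldwise envelope of the retained subpopulation.

Step 4 makes the retention guarantee exact by construction, is
order-invariant, and — because the retained set only grows with *r* —
criteria inferred at a higher retain rate always pass a superset of the
duplexes passed at a lower one. An iterative relax-one-threshold
variant was evaluated and rejected: its relaxation path depends on
which duplexes happen to fail, which breaks that monotonicity.

The default retain rate is chosen by sweeping *r* from 0.50 to 1.00 in
0.05 steps, evaluating Se/PPV at each grid point, and taking the lower
endpoint of the first increment whose |ΔSe|/|ΔPPV| drops below 1 (the
point where precision lost outweighs sensitivity gained); if no
increment loses more than it gains, the final grid value is used. The
biological reading: stronger complementarity earns more confidence, and
0.85 is where admitting weaker duplexes stops paying for itself.

## Evaluation conventions

Validation classes are used in the loose sense standard for
degradome-supported prediction: TP = predictions with experimental
validation, FP = predictions currently lacking it, P = validated
interactions observable in the dataset (HC peak and miRNA abundance
≥ 5). Se = 100·TP/P, PPV = 100·TP/(TP+FP). Specificity is deliberately
not computed: validation-driven data cannot enumerate true negatives.
Matching is on (miRNA sequence, transcript id, cleavage position) with
a ±1 nt tolerance by default, because published validation tables mix
conventions for which side of the cleaved bond is recorded; predictions
are deduplicated by key before counting. Zero denominators yield
flagged undefined values (`None`/`NA`), never exceptions. Percentages
are displayed half-up to one decimal; full precision is kept
internally.

## Statistics

* **Offset χ² per position**: observed {mismatch, G:U, gap, match}
  counts against expected counts from the reference subset's
  proportions scaled to the observed total; expected cells of 0 are
  stabilized with +0.5 (the "offset", configurable) and the vector is
  rescaled; df = 3. The match category is included so the cells
  partition the duplexes. A pooled all-positions variant per property
  is also provided (df = positions − 1).
* **Fisher exact per position and property**: two-sided, each position
  against the summed counts of the remaining positions.
* **KS on MFE ratios**: the larger sample is first subsampled without
  replacement (seeded) to the smaller's size, then a two-sided
  two-sample KS test is applied; identical same-size samples give
  p = 1 exactly, and a fixed seed makes repeated calls bit-identical.

Raw p-values are reported (the conventional 0.05 threshold belongs to
the reporting layer); a Benjamini–Hochberg option exists, off by
default.

## Synthetic fixtures

The generator emulates a paired sRNA + degradome experiment at desk
scale: random-sequence transcripts (default 25, 250–400 nt), ~21-nt
miRNAs, and planted interactions whose target sites realize a planned
per-position state vector (reverse complement with planned mismatches,
wobbles and bulges) under the same cleavage geometry the aligner
assumes. Planted degradome reads (20 nt) start exactly at the cleavage
coordinate with planned abundance (default 50, well above the floor of
5); background degradation reads start at uniform random coordinates
with abundance 1 + Geometric(0.5) — random degradation dominated by the
lowest abundances. sRNA samples express every miRNA (default abundance
30) plus random 19–24-nt noise reads. The default interaction plan
rotates through perfect, 3′-wobble, position-1-mismatch + wobble and
3′-bulge duplexes — the edit diversity typical of real plant
interactions. A two-subset mode plants property-disjoint populations
(a no-mismatch/multi-wobble subset versus a core-mismatch subset) to
exercise criteria portability. Same seed and config give byte-identical
files.

Deliberately not emulated: realistic base composition and repeats,
sequencing errors, ligation/sequencing bias, splice variants,
multi-site transcripts by default, and translational repression.
Passing the recovery tests therefore demonstrates the pipeline's
correctness on its own assumptions (exact mapping, anchored duplexes,
abundance-dominant true peaks), not robustness to artefacts real
libraries contain.

## Cross-validation recipe

Stability of inferred criteria against overfitting is assessed by a
driver loop over existing operations rather than a core operation:
repeatedly split the HC duplex population at random into a 75% training
and 25% testing group, infer criteria on the training group, and
evaluate them on the held-out group (50 repeats is a reasonable
default). In code:

```python
rng = np.random.default_rng(0)
for _ in range(50):
    idx = rng.permutation(len(duplexes))
    cut = int(0.75 * len(duplexes))
    train = [duplexes[i] for i in idx[:cut]]
    test = [duplexes[i] for i in idx[cut:]]
    criteria = infer_criteria(train, retain_rate=0.85)
    kept = [d for d in test if passes(d, criteria)]
    result = evaluate(kept, validated, positives_in(test))
```

Held-out sensitivity is expected to sit below within-sample retention:
the criteria summarize the training population's property envelope, and
interaction subsets genuinely differ (see the two-subset fixture and
the portability tests).

## Problem sizes and numerical conventions

Test and validation workloads are sized for a desk run: fixtures of
20–40 transcripts, retention checked over 1000 random populations of
5–60 duplexes, alignment verified on 500 random sites, categorization
on 1000 random profiles, Fisher tables with margins ≤ 50. Quantiles are
type-1 (no interpolation); score caps round up to 0.5 and MFE cutoffs
down to 0.01; float comparisons against caps use a 1e-9 slack;
deterministic orderings (sorted sequences/keys) are used everywhere an
iteration order could leak into output.

## Known limitations

* Degradome mapping is exact and transcriptome-based; SNPs, sequencing
  errors and genome-coordinate analyses are out of scope.
* The energy model evaluates the aligner's fixed duplex; it does not
  re-fold, so its absolute energies are approximate even though the
  consumed ratio is well-behaved.
* De-novo (hairpin-validated) miRNA discovery is not implemented; the
  candidate catalogue comes from homology plus user-supplied lists.
* Criteria are global per run — per-miRNA or per-family rule sets are
  not inferred.
* The conservation call depends on the completeness of the known-miRNA
  catalogue and its clade map; absent annotations bias toward
  species-specific.
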