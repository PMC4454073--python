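# Methods

`ampyscan` identifies and classifies AMPylation-related enzyme domains
(Fic/Doc-type AMPylators and their relatives) from protein sequence alone.
Two complementary classifiers are implemented end to end — a k-mer
composition support vector machine and per-family profile hidden Markov
models — together with motif-level consensus patterns and residue-level
decision rules for three special cases (AnkX-type phosphocholinators,
the AR/AT domains of glutamine synthetase adenylyl transferase, and
DrrA-substrate Rab GTPases). A synthetic-family generator provides a
fully reproducible benchmark.

## Sequence handling (`ampyscan.seqio`)

Sequences use the 20 standard amino acids plus `X` for anything unknown;
out-of-alphabet characters are replaced by `X` with a warning on input.
Pairwise global alignment uses Biopython's `PairwiseAligner` with
BLOSUM62 (extended with zero-scoring `X` rows), gap open −10 and
extension −1. Each alignment yields a *reference map* from 1-based
reference positions to query positions (or `None` where the reference
faces a gap), which is the coordinate machinery behind all residue-level
rules.

Percent identity is matches divided by alignment columns. The
redundancy filter greedily keeps the longest sequence of any group whose
pairwise identity exceeds the threshold — a desk-scale stand-in for
cluster-based redundancy removal.

Multiple alignments for profile training are built by *star alignment*:
every member is aligned to the longest member and the pairwise
alignments are merged column-wise, with insertions relative to the
centre padded per position.

## Features and SVM (`ampyscan.features`, `ampyscan.svm`)

The k-mer composition of a sequence is the normalised count vector of
its overlapping k-mers in lexicographic order over the 20-letter
alphabet: 20, 400, 8000 and 160000 dimensions for k = 1..4. Windows
containing `X` are excluded from both numerator and denominator. The
hybrid feature concatenates the k ∈ {1, 2, 4} blocks (160420
dimensions); matrices are stored sparse (CSR).

The multiclass SVM is one-vs-rest over binary polynomial-kernel SVCs
(kernel (x·y + 1)^d, γ = 1). After training, each class keeps its
support vectors, dual coefficients and intercept explicitly, so the
decision function is computed directly as
`((X @ SV^T) + 1)^d @ α + b` and the model serialises losslessly to
JSON. Prediction takes the arg-max of the per-class decision values.

## Profile hidden Markov models (`ampyscan.phmm`)

The architecture is the standard match/insert/delete chain M_1..M_L
with B = M_0 and E after M_L, wrapped in N- and C-terminal flanking
states that emit background residues on self-loops (loop probability
0.99). The model is global in the profile and local in the sequence:
a domain is traversed exactly once, anywhere in the query.

`build_profile` estimates the model from a seed alignment: columns with
gap fraction ≤ 0.5 become match states; emissions use
background-weighted pseudocounts `(counts + α·q)/(total + α)`;
transitions are counted from the observed per-row state paths with
Laplace (+1) pseudocounts over the allowed targets. A reference map
records which match state carries each position of the designated
reference row.

Scoring is in log space. The forward recursion gives
ln P(seq | model); the bit score is
log2(P(seq|model) / P(seq|null)) with an i.i.d. background null. `X`
residues emit with probability 1 under every state and under the null,
contributing zero log-odds. Viterbi is the max-product analogue with
explicit traceback (tie preference match > delete > insert), returning
the match-state-to-query-position correspondence and the aligned span.

E-values are calibrated per profile by scoring ≥50 background-sampled
sequences of the family's typical length and fitting a Gumbel
(extreme-value) distribution to the bit scores;
E = n_targets · SF(score). Scans keep hits with E below a cutoff —
1e-3 for conservative family assignment, 1 for permissive
remote-homolog screens. Family classification takes the minimum-E hit;
sequences with no passing hit are *unclassified*.

Both the forward and Viterbi implementations are verified in the test
suite against an independent brute-force enumeration of all complete
state paths on small models (agreement within 1e-9 in log space).

## Motif patterns (`ampyscan.motifs`)

Motif windows are 12 residues anchored at the catalytic His (Gln in one
divergent clade). Patterns use a PROSITE-like grammar: fixed residues,
`x` wildcards, `[D|E]` allowed sets and `[!R]` forbidden sets. Five
isofunctional classes are shipped:

| class | pattern |
|---|---|
| doc-GNKR | `Hxxx[D|E]GNKRxx[!R]` |
| doc-N-GNKR | `HxxxN[A|G]NKRxx[!R]` |
| fic-GNGR | `Hxxx[D|E]GNGRxxR` |
| fic-GNTR | `Hxxx[D|E]GNTRxx[!R]` |
| doc-Q-GNKR | `Qx[F|Y]x[D|E][G|V]NKR` |

The five classes are pairwise mutually exclusive by construction
(anchor H vs Q; position 5 N vs D/E; position 8 G/K/T; position 12 R vs
not-R), and `assign_motif_class` assigns exactly one class or
"unassigned". A broader canonical pattern `HxFx[D|E]GN[G|K]R` is
shipped for prescreening only. Windows are extracted from queries by
profile alignment: the window starts at the query residue aligned to
the anchor match state. `consensus_motif` rebuilds a pattern from a
stack of windows by per-position frequency thresholds (fixed ≥0.8,
two-residue set ≥0.7 jointly, curated forbidden discriminators, free
positions forced to wildcard).

## Residue-level rules (`ampyscan.rules`)

* **AnkX screen** — positive iff at least 3 of the 4 CDP-choline
  binding residues (D28, R30, Y41, R44 in AnkX numbering, read through
  the CMP-profile correspondence) are conserved *and* a Fic-domain hit
  co-occurs. Unmappable positions count as not conserved.
* **AR/AT assignment** — the lower-E profile hit makes the primary
  call; Asn at the AR-169-equivalent position supports AR and Gly at
  the AT-697-equivalent supports AT. Disagreement between profile call
  and residue evidence is a first-class `conflict` verdict.
* **Rab compatibility** — the query is mapped onto Rab1b numbering by
  global alignment; compatible iff position 77 is Tyr and the 53–58
  stretch has net charge ≥ +1 (K/R = +1, D/E = −1, all else 0).

## Metrics and cross-validation (`ampyscan.metrics`)

The multiclass confusion matrix carries an extra "unclassified" column;
unclassified predictions count as errors for the true class. Per-class
statistics are one-vs-rest collapses: sensitivity, specificity,
accuracy, Matthews correlation coefficient and F1. The aggregate score
`S = 100·(ACC% − 100/k)/(100 − 100/k)` rescales overall accuracy so
uniform-random = 0 and perfect = 100. Cross-validation is stratified
k-fold (default 5); the HMM trainer re-aligns and re-calibrates each
class's profile within every training fold, so held-out sequences never
influence their own model.

## Synthetic benchmark (`ampyscan.synth`)

Each synthetic family derives from a random 200-residue template
carrying one class motif at anchor position 90. Members accumulate
i.i.d. substitutions (rate 0.2 by default) at unconstrained positions
— pattern-constrained motif positions are preserved exactly, wildcard
positions mutate — and geometric-length indels (rate 0.02, never inside
the motif window). The true alignment is recorded during generation and
doubles as the seed MSA; everything regenerates bit-identically from
the JSON provenance. The shipped benchmark has three families
(fic-GNGR-, doc-GNKR- and Q-class-carrying) of 60 members each.

On this benchmark, 5-fold cross-validation reaches 100% accuracy for
both classifiers at the default divergence, and the HMM classifier at
least matches the SVM when the indel rate is raised to 0.08 — the
regime where alignment-aware models are expected to hold their
advantage over composition features.
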