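# Methods

## Problem and labels

A residue is *disordered* (D) when its backbone Cα atom is missing from the
reference structure, *ordered* (O) otherwise. This operational definition is
the only one supported; propensity-based or order-to-disorder-transition
definitions are out of scope. All evaluation is against this two-state
annotation.

Training and inference use a third state, *near-disorder* (N): in every
maximal ordered run, the K residues at each terminus are relabeled N. Runs
of length ≤ 2K have no interior, so the whole run becomes N — the symmetric
choice; partial overlap of the two boundary windows has no natural
semantics. The widening is applied to every ordered run, including runs
abutting the chain termini. K defaults to 5 residues. With ~5% disorder the
relabeling moves the class ratio from roughly 14.5:1 to the order of
7:1:0.6 (O:N:D), which is the imbalance reduction the third state exists
for.

## MCS profiles

Hits are high-scoring local alignments (HSPs) of the query against the
MCSbase. Selection: keep hits with e-value strictly below the threshold
(default 10), sort ascending, truncate to the top S (default 10). Ties in
e-value are broken by (subject_id, query_start) so selection is a pure
function of the hit set. Each HSP counts as one matched sequence; several
HSPs from one subject may all enter the top S — selection ranks alignments,
not subjects.

Accumulation walks alignment columns with two residue cursors. Only columns
with residues on both sides contribute: the subject residue's state is
counted at the query position. Gap columns advance one cursor and add
nothing. Normalizing the three per-position boxes gives the profile;
positions with zero coverage emit (0, 0, 0) rather than uniform 1/3, so the
tagger can tell "no homology evidence" apart from "balanced evidence". This
zero-vector convention pairs with zero padding outside the chain in the CRF
window expansion: both mean "no observation".

Coordinates are 1-based inclusive throughout, matching BLAST tabular
output; the adapter reads `outfmt "6 qseqid sseqid evalue qstart qend
sstart send qseq sseq"`. A documented external search protocol (six
PSI-BLAST iterations, 500 max target sequences) produces compatible input,
but nothing in the package or its tests runs BLAST.

## Features

12 columns per residue: the 3 MCS probabilities and a 9-symbol one-hot
encoding of predicted secondary structure. The SS alphabet defaults to
`HGIEBTSC-` (DSSP eight states plus a no-prediction dash) and is
configurable — SS prediction is an external input and only the cardinality
of its alphabet is structural. A PSSM block is deliberately absent: adding
PSSM features to MCS+SS is known to leave performance essentially
unchanged, and dropping them keeps the external-input surface minimal.

## CRF

Linear-chain CRF over (O, N, D). State potentials are linear in the
windowed features — weight × value — because the features are probabilities
and indicator bits, not discrete tokens; this is the continuous analogue of
unigram feature templates. The window spans offsets −4…+4 (nine positions)
over every feature column, plus one bias weight per label: 3 × (12·9 + 1)
state weights. Transitions are 3×3 label-pair weights with no feature
conditioning; no bigram feature templates, no semi-Markov extension.

Forward-backward and Viterbi run in the log domain; the forward and
backward log-partitions agree to ~1e−8 and are cross-checked in tests
against exhaustive 3^L enumeration for L ≤ 6. Viterbi breaks ties toward
the earlier label in (O, N, D) at every backtracking step — deterministic
and conservative, since order is the majority class (an all-zero model
yields an all-O path).

Training minimizes the negative conditional log-likelihood plus
‖w‖²/(2σ²), σ² = 10 by default, with scipy's L-BFGS-B (`maxiter` 200,
`ftol` 1e−6). The gradient is observed-minus-expected feature counts, with
pairwise expectations from forward-backward; it matches central finite
differences to better than 1e−4 relative. Initialization is all-zeros, so
training is deterministic — the seed in the training configuration is
reserved for future randomized variants (restarts, subsampling) and
currently affects nothing. The objective is convex, so the zero start is
also a global-optimum start. Models serialize to versioned JSON with
bit-exact round trip (floats survive JSON via `repr`).

## Decision schemes

The base per-residue determination is the argmax of the posterior
marginals, not the Viterbi path: both schemes are defined on per-residue
probabilities, and using marginals keeps a single probability object per
residue. Ties in the argmax resolve D > N > O (prefer the rarer, positive
class). Scheme I promotes a non-D residue to disorder when P(N) > τ
(default τ = 0.4); scheme II calls disorder when P(D) > τ (default
τ = 0.03). Comparisons are strict. The schemes are alternatives and are
never composed. The sweep grid defaults to 0.00–1.00 in steps of 0.01;
the Sw-maximizing τ reports the smallest grid point on ties. Under scheme
II the swept (Sn, 1−Sp) pairs trace the ROC of the P(D) score. The default
τ values are sensible operating points inherited from benchmark tuning on
external crystallographic data; re-deriving them requires that data, which
is why the package ships the sweep machinery rather than fixed claims.

## Metrics

Disorder positive. Sn = 100·TP/N_d, Sp = 100·TN/N_o, ACC = (Sn+Sp)/2, MCC
with the convention that a zero denominator factor yields 0.0 plus a
defined-flag (keeping report tables numeric where a dash would otherwise
appear). Sw is computed from its weighted-count form with W_d = ordered
fraction and W_o = disordered fraction — the cross-assignment is what makes
Sw ≡ Sn + Sp − 100 hold exactly, a property-tested identity. AUC is the
tie-corrected rank statistic of P(D) (delegated to scikit-learn, verified
against brute-force pair counting in tests). Bootstrap standard errors
resample chains — the prediction targets — without replacement, 80% of
chains per replicate, and report the ddof=1 standard deviation across
replicates. Percentages are reported to 2 decimals, MCC and AUC to 4.

## Synthetic study conditions

The generator emulates crystallographic disorder data at desk scale:

| parameter | default | meaning |
|---|---|---|
| n_families | 30 | query chains, each with its own homolog family |
| length_range | 80–300 | uniform chain length (residues) |
| disorder_target | 0.05 | intended pooled disorder fraction |
| terminal_disorder_prob | 0.6 | per-terminus chance of a disordered segment |
| internal_segment_rate | 0.0008 | per-residue start rate of internal segments |
| segment_length_mean | 8 | geometric mean segment length (residues) |
| n_homologs | 15 | mutated database homologs per family |
| substitution_prob | 0.15 | per-residue substitution rate in homologs |
| indel_prob | 0.01 | per-residue single-residue indel rate |
| label_flip_prob | 0.05 | per-residue two-state label flip in homologs |
| ss_noise | 0.2 | per-residue SS corruption to a random symbol |

Two terminal segments at 0.6 × mean 8 on a mean-190 chain contribute
≈ 5.05% disorder; the internal rate adds ≈ 0.6%, so the pooled fraction
lands near the 5% target (tested band 3–7% over 200 chains). Disordered
positions draw amino acids from a composition table enriched in P, E, S,
K, G, Q and depleted in W, C, F, I, Y, V, mirroring the low-hydrophobicity
bias of real disordered segments. Homolog labels are flipped *before*
near-disorder widening, as real database annotations would be. Secondary
structure derives from the truth labels (ordered runs emit H/E/T blocks,
disordered residues '-' or C) before symbol-level corruption. The toy
aligner scores match +2 / mismatch −1 / gap open −5 / gap extend −1
(open = score of the first gap residue), reports the best local alignment
per subject above score 10, and assigns the pseudo e-value m·n·2^(−score/4)
— monotone in score and scaled by search-space size, which is all the
selection stage consumes; full extreme-value statistics would add nothing
downstream. Indels are kept rare so labels transfer positionally with
little projection noise. The corpus writers emit exactly the file formats
the production parsers read, so synthetic runs exercise the real I/O paths.

**What passing on this corpus does and does not show.** The homolog
families carry near-clean copies of the truth labels, so the MCS profile is
close to an oracle and end-to-end runs typically reach token accuracy and
AUC at or near 1.0. That validates the machinery — counting, inference,
training, thresholding, scoring — not real-world accuracy. Real queries
have homologs at much lower identity, MCSbase coverage gaps, genuinely
noisy SS predictions, and disorder that is not compositionally separable;
none of these regimes is represented at the defaults.

## Problem sizes

The shipped test suite and the acceptance run use the default corpus
(30 families, ≈ 5,700 residues, 450 database homologs), which trains in
tens of seconds on one CPU; smaller corpora (6–8 families, 60–120 residues)
back the unit and integration tests. Exhaustive CRF oracles run at L ≤ 6
(≤ 729 paths), AUC pair-counting oracles at ≤ 200 residues.

## Known limitations

- The near-disorder widening is uniform in K; no distinction between N- and
  C-terminal boundaries and no length-adaptive K.
- Hit selection treats every HSP independently; a single subject can
  occupy several of the S slots.
- The CRF has no feature-conditioned transitions and no per-position
  regularization weighting; heavily imbalanced corpora rely entirely on the
  N-state device and the decision thresholds.
- The toy aligner reports one best alignment per subject, so co-optimal
  alignments are resolved by the underlying aligner's deterministic
  preference, not enumerated.
- `exclude_matches` removes exact full-sequence duplicates only; near-exact
  redundancy control (identity culling) is a dataset-preparation concern
  outside the package.
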