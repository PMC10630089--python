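# Methods

This note records the models implemented by `corona-evo`, the defaults that
matter, and what the synthetic data do and do not establish.

## CAAX-motif inference

A protein is called CAAX-positive when the residue at offset −4 from the
C-terminus is a cysteine, with the terminal residue counted as −1 (so on a
sequence of length L the acceptor sits at 1-based position L − 3). Only the
cysteine rule is enforced: the three downstream residues are deliberately
unconstrained, because the operational definition of the motif in
comparative scans is positional, and the biochemical preferences of the A/X
positions vary between substrates. Trailing `*` (stop) characters are
stripped before scanning; an `X` at −4 yields *unknown*.

Calls are three-state because predicted proteomes contain fragments. A
record is judged fragmentary when (in order of precedence): its FASTA
`partial=true` flag says so; it ends in an ambiguity residue after stop
stripping; or, with the flag unstated, its length is below a configurable
fraction (default 0.5) of the family median. The default is a documented
stand-in for manual curation of fragment evidence in real proteomes; on
synthetic data the explicit flag is authoritative. With no evidence of
fragmentation the record fails open to *complete* — a deliberately
conservative choice, since a wrong *complete* can only produce an absent
call that the profile layer treats as 0 rather than ?.

The construct builder works in 1-based inclusive parent coordinates.
`ConstructSpec(start, end)` truncates; substitution windows replace each
position in a window with one residue; `caax_swap` replaces the construct's
final four residues. The swap is defined as a replacement (not an
insertion): the contract the tests rely on is the identity of the terminal
4-mer, and a replacement keeps construct length arithmetic exact. The
packaged CENP-E panel (2111-C, 2,111–2,689, 2,111–2,643, C-10A1…A9, C2698A,
Q2701A, KRAS4b swap) and the 605-residue SPINDLY parent are synthetic
stand-ins: random sequences at the real coordinates, used for coordinate
arithmetic and scanner behaviour, not for sequence analysis.

## Phylogenetic profiles

Profiles are species × trait matrices over {1, 0, ?}. Presence collapses
multiple orthologs by "any"; the dependent CAAX trait is 1 if any complete
ortholog is CAAX-positive, 0 if every complete ortholog is negative, and ?
if the family is present but only fragments (or −4 ambiguity) are
available. A CAAX trait is structurally 0 wherever its host family is
absent, and the container enforces this invariant.

Unknowns are excluded pairwise from statistics, never imputed. Association
is summarized by the phi coefficient of the 2×2 table (undefined margins
reported as `None`, not coerced to 0); no p-value is attached because
species are phylogenetically non-independent, and the package makes no
claim of an independence test. Phylogenetically corrected correlation
models are out of scope.

The packaged ten-lineage reference profile encodes the consensus
qualitative pattern for the corona gene set: ZW10 and CENP-E near-ubiquitous;
ROD/ZWILCH in Obazoa plus Stramenopila/Alveolata; SPINDLY (and its CAAX
box) confined to Obazoa; CENP-E's CAAX box in Opisthokonta/Apusozoa and
Stramenopila/Alveolata with the fragment-poor Breviata rendered unknown.

## Ancestral reconstruction

`sankoff_reconstruct` is the exact minimum-cost dynamic program over states
{0, 1}: per-node cost vectors are combined over children (polytomies are
summed directly, so no arbitrary binarization is introduced), `?` leaves are
zero-cost wildcards, and transition costs are an arbitrary non-negative
(gain, loss) pair with at least one positive. The root prior distinguishes
birth characters from ubiquitous ones: under `forced-0` a present root is
itself a gain, charged on an implicit stem edge above the root; under
`free` the root state is unpenalized. Among co-optimal labelings the
reported one keeps each child in its parent's state when tied and prefers 0
at the root — a DELTRAN-like rule that delays gains toward the tips, which
is the reading under which two disjoint presence clades are two independent
gains rather than an early gain with long loss paths. Because tie-breaking
is a presentation choice, a second dynamic program enumerates the
(gain, loss) pairs achievable by *all* co-optimal labelings and sets an
ambiguity flag whenever the gain count is not unique, so ties are reported
rather than hidden.

`dollo_reconstruct` places the single allowed gain on the edge above the
last common ancestor of the definitely-present leaves and resolves `?`
leaves to minimize losses: within the gain clade, a subtree stays absent
only if it contains a definite absence and no definite presence, giving one
loss per maximal such subtree. Because unknowns could also extend the
origin rootward, the result reports both the latest defensible origin (the
LCA above) and the earliest (the highest ancestor whose subtree contains no
definite absence). Dollo total cost is reported in unit-cost events. A
useful exact property, asserted in the tests: flipping one absent leaf
inside the gain clade to present removes at most one loss (the maximal
absent subtree containing it), though it may add several smaller ones.

Consistency between the two modes holds by construction: Dollo's loss count
equals the Sankoff optimum whenever the gain cost exceeds
n_leaves · cost_loss, which the suite checks on simulated histories.
Maximum-likelihood gain/loss rate estimation and divergence dating are
out of scope.

## Synthetic data

*Trait histories* evolve by a per-edge Bernoulli process: crossing an edge,
an absent trait is gained with probability `gain_rate` and a present trait
lost with probability `loss_rate`. This discrete per-lineage process (rather
than a continuous-time chain) matches the granularity at which gene-content
presence/absence is reasoned about and makes the expected event count
exactly `rate × exposed edges`, which the Monte-Carlo tests verify from the
simulator's own bookkeeping. `dollo_mode` disables gains after the first.
No published rates exist for the corona gene set, so the pipeline defaults
(gain 0.05, loss 0.1 per branch) are illustrative, chosen to give sparse,
reconstructable histories on a ten-leaf tree.

*Proteomes*: each family carries a distinctive nine-residue internal seed
motif — the handle for the tag/motif-based ortholog assigner that stands in
for profile-HMM homology search — plus a terminal 4-mer consistent with the
trait state (family CAAX motif, or a 4-mer with no C at −4). Unknown-CAAX
cells are emitted as C-terminally truncated records flagged `partial=true`;
decoy background proteins are uniform-random with the −4 cysteine excluded
so they cannot create accidental positives. Because assignment is by exact
motif containment, the round trip simulate → emit → scan → profile is an
identity when no fragments are emitted; this is a correctness oracle for
the plumbing, *not* evidence about real homology detection, where ortholog
assignment is the hard part.

*Intensity tables* emulate MaxQuant-style protein-group output on the log2
scale: protein baselines ~ Normal(26, 2), replicate noise SD 0.4, three
replicates per condition, Poisson(5) unique-peptide counts (so a few zeros
exercise the filter), and planted proteins shifted by `effect_log2`
(default 4) in the bait condition. Dropout is missing-not-at-random:
P(missing | x) = 1/(1 + exp(steepness · (x − midpoint))), default midpoint
22 and steepness 1.5, i.e. values ~2 SD below the typical protein are
frequently lost while abundant proteins almost never are. The generator does
not emulate shared peptides, protein-group ambiguity, batch effects, or
correlated contaminant background, so passing recovery tests bound the
pipeline's behaviour under clean MNAR Gaussian conditions only.

## Enrichment analysis

Filtering keeps proteins with ≥ 1 unique peptide (the threshold is
configurable; the rule is implemented literally as stated for the workflow
being reproduced) that are observed in at least 2 replicates of at least
one condition. The variance-stabilizing step is log2 (when raw) followed by
a per-sample-group median/MAD affine alignment — the transformation family
is fixed, its parameters are data-driven and deterministic. Imputation
draws each missing cell from Normal(sample mean − 1.8 · sample SD,
(0.3 · sample SD)²), the conventional left-shifted Gaussian for MNAR
dropout; shift and width are exposed. Per-protein testing is Welch's
two-sample t-test by default (pooled-variance optional); no empirical-Bayes
moderation is applied, a deliberate divergence from limma-style practice to
keep the procedure exactly as specified, and with n = 3 the p-values are
only approximately calibrated (the null suite bounds the pooled KS
statistic at 0.05). Hits require −log10 p > 2 and log2 FC > 2 in the
configured direction (default: enrichment only); raw p-values drive the
flag, with a Benjamini–Hochberg column emitted for reference only. Ranking
sorts hits first, then −log10 p, with p-ties broken by |log2 FC| then
identifier.

## Problem sizes and determinism

The test and acceptance workloads run at desk scale by design: ten-lineage
trees, ≤ 8-leaf random trees against exhaustive enumeration (500 draws),
200-replicate Monte-Carlo loops with 100–300 proteins. Every stochastic
stage takes an explicit seed; the pipeline fans a master seed out per stage
by hashing `"{seed}:{stage}"`, so stage results are reproducible
independently of stage order. Manifests record SHA-256 hashes of all
artifacts and are byte-stable across runs (SVGs are written without date
metadata; the stored config omits run-local paths).
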