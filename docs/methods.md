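# Methods

This note documents the models, conventions and numerical choices behind
`aadckit`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data does and does
not establish about real catalogs.

## Scope and data model

The unit of analysis is a `ProteinRecord`: one annotated decarboxylase
sequence with species/genus/phylum taxonomy, strain label, EC number,
culture-collection provenance (ATCC/NCTC/DSM or other) and a
genome-completeness flag. Nine AADC families are recognized by EC
number; records whose EC maps to no family stay in the catalog but are
excluded from family analyses (and logged). Sequences use the 20
standard residues plus `X`; `X` is treated as unknown and never matches
anything, in identity or in motif work.

## Inclusion filter

A species is "prevalent" when its relative abundance strictly exceeds a
threshold (default 1e-4, i.e. 0.01%) in at least `min_samples` (default
2) samples. Both knobs are configurable; strictness of the inequality
is deliberate and documented because boundary values (exactly 0.01%) are
excluded. The prevalence denominator is always the explicit species
list given to `prevalence()` — the toolkit reports it next to every
percentage rather than leaving it implicit.

## Representative selection

Within one species and family, strains rank: complete genome in a
trusted collection (ATCC/NCTC/DSM) > trusted collection > everything
else. Equal ranks resolve to the lexicographically smallest record id.
This replaces "pick one without preference" with a deterministic rule:
reruns of the same catalog always choose the same representative.

## Alignment and percent identity

Pairwise alignment is global Needleman–Wunsch with affine gaps, run
through Biopython's `PairwiseAligner` (BLOSUM62; a gap run of length L
costs `open + (L-1)·extend`, defaults 10/1). Among co-optimal
alignments the first one the traceback enumerates is returned, which is
deterministic. Tests verify optimality against an independent
brute-force enumeration of all alignments on short sequences.

The internal multiple aligner is center-star: the center sequence is the
one with the smallest summed edit distance to all others (computed
exactly with edlib, which is far cheaper than summing full affine
alignments and selects the same kind of "most central" sequence); every
other sequence is aligned to the center and merged by "once a gap,
always a gap". Center-star is not Clustal Omega — column-level details
will differ — so externally produced alignments (aligned FASTA or
Clustal format) can be substituted anywhere downstream and behave
identically. Identity numbers from the internal aligner should be read
with a few percentage points of slack relative to Clustal-derived ones.

Percent identity follows the common PIM convention: identical residue
columns divided by columns in which **both** rows carry a residue.
Gap-containing columns are excluded from the denominator; `0/0` is
defined as 0. This convention is stated explicitly because published
matrices rarely say which denominator they used; it also means that
aligning a short sequence against a much longer one can only be judged
on their overlap, which inflates identity for length-mismatched pairs
(see Limitations).

Group summaries average the strictly-off-diagonal entries, each
unordered pair once. A single-member group has no summary and is
reported as not applicable, as for the arginine group, whose multiple
unrelated enzyme classes make a single comparable group meaningless.

## Outliers

A member is flagged when its **maximum** identity to any other group
member falls below the threshold (default 30%). Using the maximum means
one close relative suffices to rescue a member — and conversely, two
mutually similar mis-annotations can shield each other. The group's
lowest-identity member is always surfaced, flagged or not, so borderline
cases (40–45% members) remain visible.

## PLP motif analysis

The catalytic lysine column is the alignment column maximizing the
fraction of rows with `K`, with gaps counting against conservation, and
must reach `min_conservation` (default 0.7). Ties on the K fraction are
resolved by tetrad support — the fraction of rows sharing the modal
extracted tetrad at that column — because the catalytic K sits in a
conserved sequence context while an incidentally conserved background K
does not; any remaining tie goes leftmost. The column search runs on the
group's coherent core (flagged outliers excluded) so that a few
mis-annotations cannot push the motif column below the conservation
threshold in small groups; tetrads are then read off every row at that
column, outliers included.

A row's tetrad is the K plus its three immediately N-terminal residues
taken from the **ungapped** sequence, not from alignment columns, so
insertions in other rows cannot corrupt a motif. The K's 1-based
ungapped position is reported but never used for classification.

The consensus pattern renders invariant positions as the residue and
variable positions as a bracket list in descending frequency, with
residues seen in under `minority_fraction` (default 0.10) of tetrads
lowercased — producing patterns like `S-[Fy]-[Sa]-K` or `N-[Ct]-HK`.
The primary motif is the modal tetrad (ties: lexicographically
smallest); every other observed tetrad is a secondary. TrpDC and AAADC
annotations routinely point to the same proteins and are treated as one
motif group, `AAADC/TrpDC`. The arginine family is exempt from
single-consensus derivation: its mixed evolutionary classes admit no one
motif, and the report states "Unable to determine". Flagged outliers
are excluded from consensus derivation, so a family's pattern reflects
its coherent core; when both aromatic annotations are singletons their
members are pooled so the group can still contribute a consensus.

Classification of a tetrad against known consensus sets ranks exact
primary-motif matches above secondary-motif matches above pattern-only
matches. Reassignment proposes a source family for a flagged outlier
only when its tetrad is the **primary** motif of a different family;
since an unrelated sequence usually fails to align its K into the
group's motif column, the outlier's ungapped sequence is scanned for
4-mers ending in K that match a known consensus. Reassignment can only
name families whose consensus was derivable from the data at hand — a
catalog with no aromatic members cannot attribute a `DAHK` outlier.

## Cofactor prediction

Histidine and aspartate-1 decarboxylases are called pyruvoyl-dependent
by family rule. Otherwise, no detected tetrad plus length below
`short_length_cutoff` (default 200 residues, the documented size range
of pyruvoyl-type arginine decarboxylases) yields a pyruvoyl call;
everything else is PLP. A long motif-free sequence therefore defaults
to PLP — absence of a detected motif in a long protein is weaker
evidence than a sub-200-residue frame.

## Profiling

Prevalence counts a species once per family regardless of strains or
paralogs; report percentages are rounded to integers with full precision
kept in machine-readable output. Genus totals sum representative
enzymes; because TrpDC/AAADC twins are one protein with two annotations,
the default counts identical-sequence pairs once (a flag restores
per-annotation counting, and both are written). Length statistics are
exact min/max/range with an exact-value mode by default; a bin width
greater than 1 reports the modal bin's member lengths as an interval
(e.g. `470-484`). Bimodality is assessed by the exact two-cluster 1-D
split minimizing within-cluster variance (exhaustive over split points),
which cleanly separates short (~485 aa) from extended (~715 aa)
lysine-decarboxylase forms.

## Synthetic data: what it emulates, and what it does not

`simulate_family` draws an ancestor, plants the family tetrad at a
position sampled from `motif_region` (default 35–55% of the shortest
sequence), and derives members by per-site substitution at rate
`divergence` (default 0.15, giving ~72% pairwise identity — the regime
of the better-conserved real families), with the motif frozen unless
erosion is enabled. Lengths come from point/normal/mixture models;
mixture components are homologous length variants of one ancestor by
default (lysine-decarboxylase style) or independent lineages when
`independent_components` is set (arginine-decarboxylase style, where the
sub-200-residue pyruvoyl class is unrelated to the long PLP class).

Two deliberate simplifications keep ground truth unambiguous.
Substitutions are uniform over the alternative residues — no rate
matrix — which is sufficient for identity and motif-recovery testing and
analytically transparent. And the background alphabet excludes lysine:
the planted catalytic K is the only K in a simulated sequence, and
motif-free (pyruvoyl-like) families contain none at all. Real proteins
carry ~6% background lysine, some of it incidentally conserved, which is
exactly why the column search needs its tetrad-support tie-break; the
synthetic data exercises that rule only through hand-built alignments in
the unit tests, not through the generator. Passing synthetic tests
therefore demonstrates the pipeline's correctness under clean planted
signal, not its robustness to adversarial background lysines, indels
(the generator produces none beyond length variation), or compositional
bias.

`simulate_catalog` assembles a taxonomy (default: three phyla, genera of
up to ten species), includes each family per species with the default
inclusion probabilities (ArgDC 0.60, A1DC 0.50, GluDC 0.27, A4DC 0.21,
HisDC 0.07, LysDC 0.06, TyrDC 0.05, TrpDC/AAADC 0.03 — the observed
prevalence ordering in gut surveys), emits strain replicates at
`strain_divergence` (default 0.03, keeping within-species identity above
90%), writes abundance tables in which prevalent species clear the
inclusion rule and a rare tail does not, and injects foreign-motif
outliers: with probability `outlier_rate`, a species' enzyme in a
motif-bearing family is replaced by an independent draw from the source
family (default aromatic, tetrad `DAHK`) while keeping the original
annotation. Outliers are not injected into motif-free families (a
"foreign motif" is undetectable there) nor into the source family's own
group. Everything is reproducible byte-for-byte from the catalog seed.

## Problem sizes and defaults in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to
exercise every code path with comfortable statistics: 30 sequences per
family across 20 replicates for motif recovery, 20 replicates of
outlier injection, 500 species for prevalence recovery (binomial
standard errors ~1–2 percentage points), and one 200-species catalog
with two strains per species for the end-to-end measurements. The
alignment-optimality oracle enumerates all alignments exhaustively for
all sequence pairs up to length 2 over a four-letter alphabet and for a
seeded sample of longer pairs up to length 6, where exhaustive pair
enumeration would be astronomically large but per-pair enumeration is
still exact.

## Known limitations

- Center-star alignment degrades when a group mixes very divergent
  members; the percent-identity values involving flagged outliers are
  noisy (their pairwise placement is mediated by a center they match
  poorly). Group means are computed over all members, outliers
  included, and therefore dip below the coherent-core identity.
- Gap-excluded identity overstates similarity for strongly
  length-mismatched pairs; an unrelated long sequence can reach ~30%
  apparent identity against a short family, occasionally straddling the
  outlier threshold.
- The max-identity outlier rule cannot flag two mutually similar
  mis-annotations injected into the same group; the generator therefore
  injects outliers as independent draws.
- Cofactor prediction is rule-based (family identity, motif presence,
  length); it does not model the pyruvoyl self-processing serine or any
  structural evidence.
- No phylogenetic correction: prevalence percentages inherit whatever
  taxon-sampling bias the input catalog has.
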