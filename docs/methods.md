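# Methods

## Ambiguity categories and scoring

A category is a non-empty subset of the 20 standard residues; categories form
a tree whose root is the full alphabet, whose edges never widen the member set,
and whose leaves are singletons. The per-position score of a match is the
inverse of the member-set size, `1/X_i`, bounded between 1/20 = 0.05 (root)
and 1/1 = 1.00 (singleton); a mismatch scores exactly 0. Two consequences the
tests rely on: refining a code to a descendant that still contains the subject
residue can never lower the score, and any non-containing replacement can never
raise it. Residues outside the standard alphabet (`X` in annotated tables)
never match any category: length evidence for such positions is kept (the
length prefilter still counts them) while identity evidence is treated as a
mismatch.

### The default tree

The shipped tree is a stand-in, not a community standard: the root, seven
structural classes (no side chain `G`; small `A C S`; β-branched `I T V`;
medium hydrophobic `L M`; medium hydrophilic `D N`; long flexible `E K Q R`;
ring-containing `F H P W Y`), intermediate splits of the long (`K R` / `E Q`)
and ring (`F W Y` / `H P`) classes, and a singleton leaf per residue —
32 nodes. Real assignment schemes differ between labs and maps, so the tree is
fully user-replaceable via a plain-text file (one node per line: code, parent,
members, label; `#` comments). Nothing in the engine depends on the topology
or on the tree being binary — only member-set sizes enter the score — and the
hydrophobic/hydrophilic split is plain sibling nodes: judging the local
environment is the human assigner's job, not the program's.

## Alignment

Queries are split by IMGT region (FW1, CDR1, FW2, CDR2, FW3, CDR3) and each
region is aligned independently, ungapped and exhaustively. At register
`offset`, query position `i` is compared to subject position `i + offset`; all
offsets in `[-max_shift, +max_shift]` (default 2 residues) are evaluated and
the maximum-score register is kept. Query positions falling outside the
subject at the chosen register are *overhang*: they score 0 and are reported
separately rather than written into the `+`/`-` match string — treating them
as mismatches would conflate length disagreement (already handled by the
prefilter) with identity disagreement. Ties between registers are broken
deterministically: smaller absolute shift, then fewer mismatches, then the
leftmost register.

Whole-sequence modes (protein FASTA, germline alleles) slide the concatenated
query over every start position of the subject, pick the globally best
register, and then report per-region scores by splitting that register at the
query's region boundaries; region shifts are not independent in this mode
because unannotated sequences give no region anchors. Germline hits are ranked
by total score only.

## Filtering

Records flagged unproductive are removed; records with no productivity flag
(plain FASTA has none) are kept with a warning. The length prefilter retains a
record iff `|len(region) - len(query region)| <= tolerance` for every
participating region. Defaults: the three CDRs participate, with tolerance 0
for CDR3 and 1 for CDR1/CDR2 — CDR lengths are the best-determined quantity in
a backbone trace, CDR3 especially is the clone's signature — and framework
regions are opt-in. Records missing a participating region are excluded.
Filtering is order-preserving and idempotent.

## Ranking

Hits are ordered by (1) number of CDR regions whose length equals the query's,
(2) total score, (3) CDR-only score, (4) CDR-located mismatches, (5) total
mismatches, (6) record identifier. The first five criteria follow the order in
which length agreement, score and mismatch location matter scientifically; the
identifier makes the output fully deterministic under input permutation. In
whole-sequence mode, where region lengths are unknown, criterion (1) counts
CDR regions whose best placement has no overhang. Total and CDR-only scores
are raw sums, not normalized by aligned length.

## Light-chain classification

Bulk repertoire sequencing loses heavy/light pairing, so a light-chain query
is searched independently against the κ and λ databases. The classification
compares the maximum and the mean of the total score across each database; the
locus must win on **both** statistics, otherwise the verdict is ambiguous —
split verdicts are reported, never guessed. An empty database after filtering
is also ambiguous (with a warning).

## Synthetic repertoires

The generator emulates what the engine sees downstream of read assembly and
annotation: clonal families (each a germline-like template with members
diverged by independent per-residue point mutations), a fraction of records
flagged unproductive, κ/λ/heavy locus labels, and a planted ground-truth
record (family 0's template, emitted unmutated and always productive).
Defaults: 5 families × 10 members; region lengths FW1 25, CDR1 8, FW2 17,
CDR2 7, FW3 38, CDR3 12 (IMGT-typical, 107 residues total); per-residue
mutation rate 0.05 (a typical amino-acid divergence within a hypermutated
clonal family); unproductive fraction 0.1. Templates are sampled uniformly
over the alphabet; a user template can be supplied to plant a real sequence.

What it deliberately does not model: somatic-hypermutation hotspots, V(D)J
junction structure, phylogenetic lineage within families, nucleotide-level
artefacts, germline gene usage biases, or duplicate-read structure. Passing
recovery tests therefore demonstrates the correctness and discrimination of
the scoring machinery under controlled divergence — not performance on real
repertoires, where family sizes, length distributions and sequence composition
are far less uniform.

Query derivation inverts the assignment process: for each residue a containing
category at the policy depth (singleton leaf by default; a fixed depth or a
random mixed depth are available) is chosen; with probability equal to the
assignment-error rate the position instead receives a same-depth category
*excluding* the residue. Errors are decided by comparing one per-position
uniform draw against the rate, so for a fixed seed the erred-position sets are
nested across increasing rates; recovery-versus-error curves therefore use
common random numbers and are monotone by construction rather than only in
expectation. A single error knob stands in for what is really a mixture of
map-interpretation error, clonal divergence and map heterogeneity; the
simulated mismatch fractions of recovered hits track the knob (binomially), so
rates of 0.04–0.18 reproduce the 4–18% mismatch band observed in practice.

## Numerical and degenerate-input choices

Scores are plain double sums of exact binary fractions (1/1 … 1/20); no
tolerance is needed anywhere in the engine, and tests compare with standard
floating-point tolerance only. Comparisons are case-insensitive. An empty
query region is skipped; a query region missing from a record scores 0 with
full overhang; an empty database (or one emptied by filtering) returns an
empty ranked list with a warning. All randomness lives in the simulator and is
driven by numpy `default_rng` seeds; the engine itself is deterministic.

## Experiment sizes

Validation experiments (recovery, classification, mismatch band) use 20
replicates of 5×10-record repertoires per condition with seeds derived from a
single master seed via `SeedSequence` spawning — large enough for the binomial
checks they make, small enough to re-run in seconds.
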