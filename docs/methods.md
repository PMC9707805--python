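# Methods

`epvmine` reimplements, at desk scale, the computational core of
endogenous viral element (EVE) surveys: translated similarity screening
of host genome assemblies, consolidation of hits into loci, resolution
of loci across species into orthologous sets, minimum-age calibration
of germline incorporation events against a time-calibrated host tree,
and assessment of retained coding capacity.  Because the real inputs of
such surveys are hundreds of vertebrate whole-genome assemblies, the
package pairs the pipeline with a synthetic-data generator that plants
incorporation events with known ground truth; every recovery claim made
by the test suite is a claim about that generator's study conditions.

## The synthetic study system

**Species tree.**  A pure-birth (Yule) process with unit birth rate is
run from two crown lineages until `n_species` lineages exist, then the
time axis is rescaled so that the crown age equals `crown_age` (default
20 species, 100 My).  The tree is ultrametric by construction; leaves
carry synthetic binomial names and internal nodes stable preorder
labels so tree edges can be addressed by their child node.

**Reference library.**  A family-ancestor coding genome (Rep/NS and
VP/Cap CDSs flanked by ITR placeholders) is point-mutated into genus
ancestors (0.35 substitutions/site, stop codons resampled) and each
genus ancestor into reference isolates (0.05 subs/site).  This yields
within-genus peptide identity of roughly 80% versus roughly 25%
between genera — enough genus structure for classification to be
meaningful.  Defaults: 3 genera × 2 isolates, Rep 300 aa, VP 250 aa.

**Planted incorporation events.**  Each event picks a source isolate, a
fragment (whole coding region with probability 0.5, otherwise a single
CDS), and a tree branch, weighted by branch length within an age
window.  The window restricts the insertion branch's child node to ages
≤ 60 My, reflecting the Cenozoic timeframe over which vertebrate
parvoviral incorporations are observed; it also keeps carrier-pair
flank divergence within the range where flank-based orthology is
identifiable (≈ 0.2 substitutions/site between carriers, see below).
The fragment is inserted into the ancestral contig at the child node
and co-evolves with the host genome down every descendant lineage, so
carriers are exactly the child clade and the child-node age is the
event's true minimum age.  Insertion sites are assigned well-separated
slots in ancestral contig coordinates across *all* events — in real
genomes integration sites are effectively unique, and shared flanking
sequence is precisely the orthology signal, so site collisions between
unrelated events would be an artefact of the small simulated contigs
(default 2 × 30 kb per species).

**Neutral decay.**  Along each branch, substitutions arrive as a
Poisson process over sites (uniform with replacement, so observed
divergence follows the Jukes–Cantor expectation) and indels as a
Poisson process with geometric lengths (mean 3 nt), half insertions
and half deletions.  Defaults are 2×10⁻³ substitutions/site/My and
1×10⁻⁴ indel events/site/My for host background and elements alike,
chosen so that ~50 My-old loci remain detectable at roughly 70%
peptide identity.  Nonsense decay is emergent — substitutions create
stop codons — with no separate stop-injection parameter.  Indels are
confined within host/element segment boundaries so that tracked element
coordinates stay exact; there is no lineage-specific element loss
(orthology resolution assumes presence in all descendants).  All
randomness flows from explicit seeds; identical configurations give
byte-identical FASTA output.

What the generator does **not** emulate: host gene content, repeats,
assembly gaps or errors, rate variation across sites and lineages,
selection on retained ORFs, horizontal transfer, and locus loss.
Passing recovery tests therefore demonstrate the internal consistency
of the pipeline under neutral decay at realistic rates — not its
performance on real assemblies, where repeats and assembly artefacts
are the dominant failure modes.

## Translated screen

Contigs are translated in six frames (standard code; codons containing
N render as X, stops as `*`).  The search is seed-and-extend: exact
amino-acid word matches (default word 3) are extended without gaps
under an X-drop of 20; a frame whose best ungapped extension reaches
the trigger score receives a full affine-gap Smith–Waterman
(BLOSUM62, gap of length L costs 11 + L) over probe × frame, iterated
with masking so several non-overlapping alignments per frame can be
reported.  Raw scores are converted to bits with the Karlin–Altschul
transform using the standard ungapped BLOSUM62 constants
(λ = 0.3176, K = 0.134); the default report threshold is 50 bits, and
an E-value is reported informationally.  Bitscore, not E-value, is the
primary filter: it is independent of database size and reproducible at
desk scale.

Two numerical choices matter.  First, the trigger is capped at the raw
score equivalent of the report threshold, so no reportable alignment
can be filtered before the DP.  Second, a word size of 4 proved too
strict in validation — a 20 aa probe region with 8 substitutions can
lack any exact 4-mer while still scoring far above threshold — so the
default word is 3 (≈ 11 expected random word hits per probe–frame,
each costing only a short ungapped extension).  Within triggered
frames the reported score is exactly the full Smith–Waterman optimum;
the heuristic can in principle miss a gapped alignment all of whose
ungapped segments fall below the trigger, the same failure class as
BLAST's.  Hit coordinates are always reported on the forward
nucleotide strand, 0-based half-open; overlapping hits from different
frames/strands are deduplicated keeping the highest bitscore.

Hits are classified by rescoring their aligned peptide against every
library record plus the consensus sequences of already-resolved loci
(ties broken by accession sort): best match below threshold →
non-viral cross-match; best match a locus consensus → ortholog of a
characterised element; otherwise a putatively novel element.

## Locus and ortholog resolution

Per genome, same-contig same-strand hits within 1000 nt merge
transitively into loci (the gap default accommodates Rep–VP spacing
and small host insertions); the locus genus is that of its
highest-bitscore hit.  Loci carry 1000 nt flanks, truncated at contig
edges with a flag.

Orthology is decided on host flanks: two loci of the same genus in
different species match when both flanks align globally (nucleotide
scoring match 2 / mismatch −1 / gap 4 + L) at ≥ 0.75 identity, where
identity counts matches over aligned (non-gap) columns — gap columns
carry placement noise rather than signal at these divergences.  Sets
are single-linkage closures of the match relation (orthology is
transitive), with a paralog guard: candidate pairs merge
best-identity-first and a merge is refused if it would place two loci
of one species in the same set.  At the default decay rates the 0.75
threshold separates cleanly: carrier pairs up to ~120 My apart retain
≈ 0.79 expected flank identity, while unrelated flanks score ≈ 0.5 on
aligned columns.

Each set gets a reference-anchored alignment (members aligned pairwise
to the longest member) and a majority-rule consensus: per column the
majority character wins, ties among bases render as the IUPAC code of
the tied set, and columns with a strict gap majority are omitted.
Identifiers follow the `EPV-<group>.<number>-<host>` convention: the
viral group token (genus name minus the "parvovirus" suffix), a number
unique within the group allocated in catalogue order (optionally from
per-group starting blocks), and the most specific host group shared by
all carriers, or the six-letter species abbreviation (first three
letters of genus and epithet, capitalised) for single-species loci.

The screen and resolution iterate: consensuses join the classification
library, the screen is re-run, and iteration stops when locus spans
and the ortholog partition are unchanged (typically two rounds on
simulated data) or at `max_rounds`.

## Age calibration and congruence

On an ultrametric tree validated to 1e-6 relative tolerance, each
multi-species set is dated by its carrier clade: the crown (MRCA) age
is the minimum incorporation age, and the stem (MRCA-parent) age the
upper bound under presence/absence parsimony, flagged when the MRCA is
the root.  Single-carrier sets are listed without a numeric age.
These are reported by definition (crown = lower, stem = upper) rather
than by any published table's column labels.

As a diagnostic that ortholog sequences branch like their hosts, a
neighbour-joining tree from p-distances (computed on the set's
reference-anchored alignment) is compared to the species tree pruned
to the carriers by unrooted Robinson–Foulds distance; congruent means
RF = 0.  NJ + RF replaces maximum-likelihood reconstruction
deliberately: the diagnostic is a binary flag, and NJ is deterministic
and desk-scale.  Sets with fewer than four members are flagged not
applicable (RF is uninformative there).

## Constrained alignment hierarchy

A constrained MSA fixes its column space to a master reference: each
member is globally aligned to the master and stored as ordered aligned
blocks plus member insertions keyed to master positions;
member-to-member homology exists only through master coordinates.
MSAs link into a tree through shared references (a child's master is a
member of its parent), giving recursive export of whole subtrees into
one coordinate space, position lift-over between any two references
(compositions of partial injections; gap positions map to null),
feature inheritance (endpoints in gaps resolve inward, conservative
spans; wholly unaligned features are dropped with a warning), and
per-member feature coverage (the fraction of a master feature's
positions aligned to member residues).  Member insertions relative to
an export master cannot be represented in a flat alignment without
inflating the master coordinates, so flat exports drop them and record
them in a sidecar.  Nucleotide alignments use match 2 / mismatch −1 /
gap 4 + L; peptide alignments BLOSUM62 with gap 11 + L.

## Coding capacity

Elements are globally aligned to the reference CDS of each gene of
their genus.  Insertions relative to the reference whose length is not
a multiple of three are excised; deletions not a multiple of three are
widened to the nearest reference codon boundaries (the remainder bases
removed); in-frame indels are kept; element overhangs beyond the
reference ends are trimmed so the repaired sequence corresponds to the
reference-spanned region.  Codon-aware repair is implemented as
nucleotide global alignment plus frame bookkeeping — simpler than
protein-guided alignment and adequate at the simulated divergences.
The repaired sequence is scanned in the reference frame for the
longest stop-free peptide stretch; no methionine start is required,
and stretches of ≥ 300 aa (configurable) are flagged as retained.
Only the annotated principal frame per gene is scanned; overlapping
ORFs in alternative frames are out of scope.

## Incidence statistics

The catalogue summarises as unique-locus counts per host class and
viral genus with exact loci-per-genome quotients.  Between-class
comparisons use the pooled two-proportion chi-square test; the Yates
continuity correction (subtracting `0.5·(1/n1 + 1/n2)` from
`|p̂1 − p̂2|`, floored at zero) is on by default, matching the
behaviour of the standard R proportion test, and was verified to
reproduce the published p-values for the mammalian-versus-saurian and
mammalian-versus-actinopterygian comparisons; without correction the
statistic is algebraically the squared pooled z statistic.

## Problem sizes and determinism

Default analysis conditions: 20 species, 100 My crown, 2 × 30 kb
contigs per species, 10 planted events, 12 probes, two screen/resolve
rounds.  Oracle cross-checks run the translated search against an
independent local-alignment oracle on 200 planted instances (≤ 50 aa
probes × 2 kb contigs) and the constrained-MSA aligner against an
independent global DP on 100 pairs (≤ 500 nt).  Congruence is measured
on simulated six-carrier ortholog sets.  All simulations, searches and
exports are deterministic given their seeds.

## Known limitations

- Orthology uses flank sequence comparison only; pre-integration
  (empty-site) alignment and named flanking-gene identification need
  annotated real genomes and are not implemented.
- The screen has no low-complexity masking and no nucleotide-mode
  search; repetitive real genomes would require both.
- Flank-based clustering degrades once carrier-pair divergence pushes
  flank identity below the 0.75 threshold (≳ 130 My of separation at
  the default host rate); deeper events would need a lower threshold
  or empty-site evidence.
- Frameshift repair trusts a single reference CDS per genus/gene; a
  poorly chosen reference biases repaired lengths.
- Expression evidence (RNA-database screening) is out of scope.
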