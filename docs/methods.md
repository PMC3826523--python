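# Methods

## The problem

Early vertebrate evolution included two rounds of whole-genome
duplication (2R) on the stem lineage of jawed vertebrates and a third
round (3R) on the teleost stem. Each round left *paralogons*: sets of
chromosome regions within one genome that descend from a single
ancestral region and therefore carry paralogous members of many gene
families in conserved order. The canonical example treated throughout
this package is the region carrying the visual opsins (LWS, SWS1, SWS2,
RH1, RH2) together with the transducin alpha subunits (GNAT), their
relatives GNAI, the oxytocin/vasopressin receptors (OT/VP-R) and the
L-type calcium channel alpha subunits (CACNA1-L).

Given (i) gene coordinate tables with family and subtype assignments,
(ii) one rooted gene tree per family, and (iii) a rooted species tree
with the WGD events placed on branches, the pipeline answers: which
gene families co-occur in blocks around the anchor genes, which
duplications fall into the 2R/3R time-windows, how do the blocks
assemble into a paralogon, which lineage-specific fissions and
post-WGD translocations rearranged it, and what gene repertoire did
each ancestor carry.

## Pipeline stages and their assumptions

### Chromosome blocks and neighboring-family selection

Blocks are ±W windows (default W = 5 Mb) around each anchor gene,
clipped to the chromosome when its length is known; overlapping
same-chromosome windows are merged by default (an option keeps them
separate for within-chromosome paralogy questions). A family is
*selected* when it has members in at least `min_blocks` distinct blocks
(default 2; several loci in one block count once). Selections from
several anchor sets are pooled as a set union. Families larger than
`max_family_members` (default 200 assigned members) are excluded, on
the grounds that very large families do not yield interpretable
single-family trees. Selection is monotone: enlarging the window can
only add families, raising `min_blocks` can only remove them.

### Duplication dating (LCA reconciliation over WGD placements)

Every gene-tree node is mapped to the most recent species-tree node
whose clade contains all its descendant species. A node is a
duplication when two of its children map to comparable (nested or
equal) species nodes; for polytomies the duplication is located at the
top of the comparable pair rather than at the polytomy's own mapping,
so collapsing weakly supported splits can only move calls *down* the
species tree, never promote a lineage-specific duplication into a WGD
window.

A duplication is dated by its *feasible placement range*: the branch of
its mapped node, extended rootward to just below the parent node's
mapping (including the parent's own branch when the parent is itself a
duplication, since two duplications can share a branch). Branch labels
follow the WGD placements: the branch carrying the 2R events is the
"2R" window (the two doublings are never separated — topology cannot
order two events on one branch), the 3R branch is "3R", branches on
the path between them "between-2R-3R", terminal branches of post-3R
taxa "post-3R-local", everything else "lineage-local" or "pre-window".
The rule for a call is:

* one label across the range → that label;
* range bounded above by a speciation and containing exactly one WGD
  branch → that window (any other placement would demand additional
  independent losses in the lineages whose absence widened the range;
  operationally this is how teleost duplications are conventionally
  dated 3R even when the pre-3R outgroup copy is missing);
* otherwise → `unresolved`. A gene-tree root duplication with no
  outgroup above it is always `unresolved` (its range is unbounded);
  such families are flagged "consistent but undated".

With no gene loss every range is a single branch and the procedure
reduces to plain mapped-branch dating. Duplication–loss cost
optimization is deliberately out of scope; the price is that
duplications whose signature was erased by reciprocal losses (hidden
paralogy) go unflagged, and ambiguous ranges go unresolved rather than
guessed.

An optional *synteny override* (off by default) demotes calls that the
chromosomal locations contradict: if a duplication dated outside every
WGD window has same-species copies on different chromosomes, the
"local" interpretation is untenable and the call becomes `unresolved`.
The override never promotes a call into a window.

Family verdicts poll all supplied trees per family (e.g. NJ and ML
topologies): a tree is window-consistent when it contains at least one
call in the window; `supported-by-all` / `supported-by-one` /
`inconclusive` summarize the poll.

### Paralogon assembly, fission healing, translocation timing

Blocks of the focal genome are joined into a weighted graph: the weight
of (b1, b2) is the number of selected families contributing a locus
pair, one per block, whose gene-tree join node is dated to the window.
Connected components after discarding edges below `min_support`
(default 2 — a single shared family is weak evidence) are the paralogon
groups; the partition refines monotonically as `min_support` rises.

Orthologs are tree-based: two loci from different species are orthologs
exactly when their join node is not a flagged duplication (so a pre-3R
outgroup gene is co-ortholog to both 3R copies).

Fissions are healed against an outgroup: each block is assigned the
outgroup chromosome carrying the strict majority of its genes'
orthologs (at least `min_support` mapped genes); same-species blocks
sharing that chromosome are one ancestral unit split by a
lineage-specific fission. Blocks without a dominant chromosome stay
unmerged and are flagged; absence of a whole region in the outgroup
(e.g. an unassembled segment) therefore never fabricates a fission or a
loss.

Translocations are detected by projecting each derived locus onto the
arrangement of an outgroup that diverged before the most recent WGD,
via its orthologs. On each derived chromosome the *dominant unit* is
the strict majority among projected loci (ties → the chromosome is
skipped with a warning); every maximal run of at least `min_run`
(default 2, single-gene calls behind a flag) consecutive projected loci
from a different unit is a translocation call. When the outgroup
predates the WGD and the derived genome postdates it, the call is timed
`post-<window>`; otherwise timing is `unresolved`. The method assumes
the outgroup arrangement is itself intact for these regions, which is
what the comparison of gar-like and teleost-like genomes shows in the
simulated histories and what motivated the choice of outgroup in the
real analysis.

### Ancestral repertoires (Dollo parsimony)

Cutting each gene tree at its *resolved* dated duplications partitions
the extant loci into subtype lineages, each originating at the species
node of the duplication above it; loci separated from the root only by
unresolved duplications are absorbed into the nearest resolved lineage
and flagged. A lineage is present at its origin and on every path to a
surviving member; losses occupy the minimal branch set covering the
absences, which for a fixed origin is unique — except around
assembly-unreliable species, whose absences are don't-cares: subtrees
absent only there are reported `uncertain`, and when a loss could sit
anywhere on a path toward the remaining reliable absence the equally
parsimonious placements are enumerated (`n_equally_parsimonious`).
Loss placement is *continuation-aware*: a subtree in which the gene
survives as a younger cut lineage (e.g. the retrogene descendants of a
retrotransposed copy) is not a loss of the parent lineage; that
territory is accounted by the younger lineage.

Tree topology cannot distinguish a local duplication immediately
preceding 2R from 2R itself — both reconcile to the gnathostome
ancestor. The *pre*-2R repertoire is therefore inferred from synteny:
lineages of one family that co-occur in a single block of a post-2R
genome must descend from distinct pre-2R genes (co-duplicated copies
land on different paralogous blocks). A family's pre-window count is
the maximum number of its window-dated lineages found together in one
focal-genome block (minimum one when the family has window lineages but
no block representation), plus any lineage predating the window that
survives through it. This is exactly how adjacent gene pairs retained
on one chromosome (opsin SWS/LWS, GNAT/GNAI, the V1/OTR–V2 receptor
pair) reveal the two-gene pre-2R arrangement.

## The simulator

The generator replays an explicit event log (WGD, local duplication,
retrotransposition, loss, translocation, fission) over the species tree
while tracking the full gene genealogy, so every simulated dataset
carries its true gene trees, per-node event labels, and per-locus
ancestral-unit assignments. Chromosomes are ordered gene lists;
coordinates are synthetic (10 kb genes, 2 Mb spacing, 30 kb tandem
gaps) so tandem clusters fall well inside the 1 Mb local-duplicate gap
and distinct genes well outside it, and a ±5 Mb window spans a handful
of neighbors. WGD copies get deterministic chromosome names (parent
name + event label); the ancestral-unit label of every copy is frozen
at the last 2R doubling and inherited through 3R, local duplication and
translocation — which is what "ancestral block of origin" means
downstream.

The scripted scenario encodes the inferred history of the opsin
paralogon: one ancestral chromosome carrying opsin, GNAT, GNAI (tandem
with GNAT), OT/VP-R and CACNA1-L plus two neighbor families, and a
decoy family on an unrelated chromosome; pre-2R tandem duplications
creating the SWS/LWS and V1-OTR/V2 pairs; the 2R quadruplication; stem
losses leaving 5 opsins, 3 GNAT, 3 GNAI, 6 OT/VP-R, 4 CACNA1-L
arranged so that OTR sits with V2B and V1A with V2C; loss of V1B on the
ray-finned stem; the rhodopsin retrotransposition before the
gar–teleost split (intron-less copy far down the same chromosome, as in
the gar genome); 3R with retention of the GNAI1, GNAI2, V1A, CACNA1D,
CACNA1C, CACNA1F and retro-rhodopsin ohnolog pairs only; post-3R tandem
duplications of OTR and V2A on the teleost stem and the RH2
quadruplication in the zebrafish lineage; two post-3R translocations
between paralogous teleost blocks; loss of the second intron-less
rhodopsin in the stickleback lineage; a gar-specific SWS1 tandem pair;
and the fission of the SWS1/V1A chromosome in the human lineage. A
switch (`rhol_origin="local"`) realizes the alternative in which the
second intron-less rhodopsin is a lineage-specific duplicate rather
than a retained 3R copy, an ambiguity that positional data cannot yet
settle.

Stochastic mode draws per-branch events at configured rates: loss and
tandem-duplication probabilities per locus, a translocation probability
per branch (capped, restricted by default to branches at or below the
most recent WGD — the regime in which such rearrangements are observed
— and always moving a two-gene run into a chromosome of a *different*
ancestral unit, since a move between the two 3R copies of one unit is
invisible to outgroup projection and is not the phenomenon modeled).
Losses on a branch are drawn for the loci present at its start and
applied before that branch's WGDs, so a locus lost on the WGD branch
loses both prospective copies. Optional topological noise applies
seeded nearest-neighbor interchanges to the true gene trees. Every
draw comes from the single mandatory seed; identical configurations
are byte-identical.

What the simulator does not model: sequence evolution (trees are given,
not inferred), branch lengths, inversion/breakpoint structure within
blocks, assembly fragmentation, and gene-tree estimation error beyond
NNI noise. Passing tests therefore demonstrate correctness of the
*inference machinery* given trees of the assumed quality, not
robustness to systematic phylogenetic error on real sequences.

## Numerical and procedural choices

* Coordinates are 0-based, half-open, bp; published Mb positions become
  point anchors (`end = start + 1`).
* Local duplicates: same species, chromosome, family and subtype, with
  consecutive gaps (next start minus previous end, floored at 0) of at
  most 1 Mb by default; real tandem pairs sit tens of kb apart and
  dispersed WGD copies tens of Mb, so the threshold is uncritical
  across several orders of magnitude.
* Adjacency pairing (e.g. GNAT–GNAI) is greedy nearest-first on anchor
  distance, ties toward the smaller start; on small instances this
  coincides with minimum-total-distance matching.
* Blocks touching a locus exactly at their half-open end exclude it.
* Subtype strings are upper-cased on ingest; lineage subtype is the
  majority subtype of its members (ties lexicographic).
* All writers emit fixed sort orders; reruns of identical
  configurations are byte-identical.

## Test and acceptance problem sizes

The oracle suites run 110–120 seeded random instances each with gene
trees of up to 8 tips (reconciliation, orthology) and presence patterns
on a 12-tip species tree (Dollo, checked against exhaustive
branch-subset search). Stochastic recovery uses 20 seeded replicates
on the 7-species tree at per-branch loss 0.2 with up to two
translocations (~600–700 surviving WGD nodes per batch); the
end-to-end paralogon property uses 20 replicates at loss 0.05, the
regime in which the focal genome retains at least one anchor per unit.
These sizes keep the whole suite and the acceptance script in the
seconds range while leaving the recovery estimates stable to ~1–2
percentage points across seeds.

## Known limitations

* Hidden paralogy: a WGD duplication both of whose copies lost
  complementary halves of the species tree is undetectable by pure LCA
  reconciliation; such nodes go unflagged (measured ~6% of surviving
  WGD nodes at loss 0.2).
* The pre-window repertoire inference needs at least one block in the
  focal genome preserving the ancestral adjacency; if every such block
  were destroyed the count would fall back to the minimum of one.
* Translocation detection is bounded by outgroup ortholog survival and
  by the strict-majority rule; chromosomes whose projection ties are
  skipped rather than guessed.
* Total extinction of a lineage before leaving any extant descendant is
  unobservable; reconstructed contents equal the simulated truth only
  for lineages with at least one surviving member.
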