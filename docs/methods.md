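# Methods

## The inference problem

A gene family evolves on a rooted species tree by speciation, duplication
and gene loss; each gene copy carries a set of spliceosomal introns that
can be lost (often) and gained (rarely). Observed data are the leaf genes:
their exon–intron structures, a shared protein alignment, a rooted gene
tree, and the species assignment of every gene. The package infers (i)
where duplications and gene losses fall on the species tree, (ii) the
ancestral intron complement at every (species-tree node, gene lineage),
and (iii) the per-branch intron loss/gain events, then prices leaf genes
with a transcription/splicing time model.

## Coordinate and character conventions

* All coordinates are 0-based, half-open, on the coding strand; GFF3 input
  (1-based) and minus-strand records are converted at the parser boundary.
* The insertion point of an intron is the CDS offset of the first base of
  the downstream exon; its phase is that offset mod 3. Phase-0 introns are
  assigned to the alignment column of the residue immediately following
  the insertion point, phase-1/2 introns to the residue whose codon they
  interrupt — this is unambiguous under gaps.
* Two introns are the same homologous site iff they project to the same
  alignment column with the same phase. Same column, different phase is
  always two sites. A configurable column tolerance (default 0) merges
  same-phase sites within `tolerance` columns onto the leftmost column
  (transitive closure), for alignments with boundary jitter; the default
  demands exact column identity.
* Ancestral sites are those observed in at least one gene of a
  user-designated basal reference set, numbered 1..n left-to-right.
  Membership by union (rather than intersection) keeps the numbering
  robust to individual reference genes that have lost a site.
* Matrix states: present / absent / missing, where missing means the
  site's column is gapped or outside the gene's aligned region. Genes with
  no alignable region are dropped rather than scored all-missing, which
  would only add vacuous parsimony degrees of freedom.
* UTR introns are retained in the gene structure but excluded from the
  character matrix; the analysis concerns coding-region introns.
* The terminal-intron rule: when the annotated CDS does not end in a stop
  codon, a `GT` within a 10 bp window (configurable) downstream of the
  last confirmed coding position predicts one further intron and exon.
  A CDS whose last exon already contains the stop codon predicts none.

## Reconciliation

Each gene-tree node `v` maps to `M(v)`, the species-tree LCA of the
species under it. Internal nodes are duplications when their children's
lineages cannot be separated at `M(v)`: each child enters `M(v)` through a
set of `M(v)`'s children (its span), and overlapping spans mean
duplication. With a binary species node this is exactly the classical
`M(v) = M(child)` rule; at polytomies it treats them as soft — unresolved,
never evidence for events. Losses are charged per gene edge: one for every
species node passed strictly between `M(v)` and `M(c)`, plus one at `M(v)`
itself for a duplication whose copy descends below it. Each charged node
places the loss on its off-path child branch; at a polytomy with several
off-path children a single loss is recorded against the polytomy node and
flagged ambiguous (soft polytomies imply one loss, not one per child).
Branches are addressed by their child node id throughout. The test suite
certifies this scoring against exhaustive enumeration over all
ancestor-consistent mappings on small random instances, including
polytomous species trees.

The input gene tree is taken as correct; no rearrangement or re-rooting
search is attempted, and explicitly unrooted newick input is an error
rather than being silently rooted.

## Ancestral intron states

Reconstruction runs on a composite tree: the species tree replicated per
gene lineage (a lineage is a maximal duplication-free piece of the gene
tree), stitched at the duplication nodes. Two modelling choices matter:

* **Duplication copies the gene verbatim.** A daughter lineage's origin
  inherits the parent lineage's intron complement; a loss cannot ride on
  the duplication itself, though a gain may occur between the duplication
  and the next speciation (it is then reported on the daughter lineage at
  the duplication's species node). Without this constraint, a site absent
  from one entire daughter clade would be scored as a single loss "at the
  duplication", collapsing what the species tree resolves as independent
  stem-branch losses — e.g. ancestral site 2 in the packaged dataset,
  which clade I lost separately on the otocephalan and euteleost stems.
* **Missing is non-informative.** Species where the gene was lost, and
  regions outside a gene's aligned row, constrain neither gain placement
  nor loss placement: a subtree with no informative leaf keeps its
  parental state and is never charged an event.

Dollo parsimony then places each site's single gain at the composite LCA
of its possessors and drops subtrees to absent as early as possible;
per-site loss counts are certified minimal by brute force on small random
instances. Sites possessed by no gene are dropped with a warning. The
Fitch alternative minimises total unordered state changes (unit-cost
Sankoff, polytomy-safe); ties resolve toward presence at the root and
toward the parental state below, making the reconstruction deterministic.
Dollo and Fitch agree on homoplasy-free sites, and per site Dollo losses
are never below Fitch changes minus one (the gain).

Event counting follows the branch convention: one "loss event" is one
(species branch × gene lineage) carrying at least one intron loss —
the packaged dataset has six — with per-site loss totals reported
alongside; under the per-site reading the otophysan-stem event alone
comprises three site losses. Cumulative losses for a leaf gene sum the
losses on its composite root-to-leaf path.

## Expression time cost

Parameters (defaults): transcription rate interval 1–1.5 kbp/min, splice
time 3 min per intron, mean intron 0.25 kbp, mean exonic content 1 kbp —
all per the kinetic estimates the analysis builds on. Gene length is
`exonic + n·intron` kbp; transcription time the interval
`[length/1.5, length/1.0]` minutes. Splicing of several introns may
overlap transcription, so the default `serial-min` mode charges a single
3-minute lower bound whenever n ≥ 1; `per-intron` mode charges `3n` for
the fully serial reading. Both are exposed because the kinetics do not
determine which applies. Lengths are reported in kbp to 3 decimals, times
in minutes to 2 decimals.

## Synthetic data

The packaged fixture encodes the 27-species hatching-enzyme study system
exactly as stated structurally: species counts 2/4/8/13 across the four
major groups, ordinal memberships, a species tree whose unconstrained
within-order and basal-euteleost relationships are polytomies, the two
duplications, the clade II gene loss, and the full intron-loss/gain
pathway. Intron phases are placeholders (all 0); no distinct-phase site is
structurally required, and the one novel site is distinguished by column.
Exception genes (EHE7, PeHE1, AcHE2, MfHE2, AcHE4, AcHE5) are carried in
the inventory with an exception flag and no committed structure, since
their configurations are lineage-specific; the `include_exceptions`
switch admits flagged genes that do have structures (e.g. simulated ones).
Toy sequences are same-length proteins with ~1% per-gene substitution and
canonical GT...AG introns of 250 bp over ~1 kbp of exonic sequence, so an
8-intron gene is ~3 kbp — deliberately on the scale the cost model
assumes. The seed randomises sequences only, never the encoded history.

The simulator evolves gene content top-down with designated duplication
and gene-loss branches, independent Bernoulli intron loss per (branch,
present site), per-branch gains at globally unused positions (so every
novel site has exactly one origin, satisfying the Dollo premise by
construction), and substitution without indels — emitted proteins align
exactly, so matrix-construction error is excluded by design. What the
simulator does *not* emulate: alignment uncertainty and indels, gene
conversion, phase-shifting intron sliding, rate heterogeneity across
sites, or gene-tree estimation error. Recovery results on simulated data
therefore measure the reconstruction step alone, not robustness to
upstream error.

## Identifiability of simulated events

Branch-exact recovery of loss events is intrinsically limited, for any
single-gain parsimony method, by two indistinguishabilities: (a)
independent losses of one site on two sister branches produce the same
leaf pattern as a single loss on their parent branch, so parsimony merges
them (probability ≈ p per event at per-branch loss probability p); and
(b) a loss on a branch incident to the root leaves all possessors in the
complementary subtree, so the gain is reconstructed below the loss and
the event is not represented at all. The packaged recovery experiment
(200 replicates, 10-leaf tree, p = 0.1) accordingly recovers ~76% of
simulated losses on the exact branch with ~97% precision, while replay
of every inferred history reproduces the observed leaf matrices exactly
and every history satisfies the single-gain constraint. Interpret
inferred event positions as the most-parsimonious representatives of an
equivalence class, not as certain placements.

## Degenerate inputs and numerical choices

Empty or overlapping exons, out-of-frame CDS lengths and unmapped gene
leaves raise errors naming the offending record. Sites present in zero
genes are dropped with a warning. All tabular outputs have deterministic
row/column order (input gene order; sites by column then phase), and the
pipeline bundle is byte-identical across reruns on identical inputs.
Problem sizes in the packaged experiments — 45-gene fixture, ≤6-leaf
oracle instances, 200-replicate recovery runs — were chosen so the whole
suite completes in seconds while the exhaustive oracles remain feasible.

## Known limitations

* Parsimony only; no likelihood model of intron turnover rates.
* The gene tree is trusted; reconciliation cannot rescue a wrong topology.
* Homology is column+phase identity (plus optional tolerance); there is no
  statistical test of site homology.
* Expression level itself is not modelled; the cost model is arithmetic on
  lengths and kinetic constants, not a kinetic simulation.
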