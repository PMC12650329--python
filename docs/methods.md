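# Methods

This note records the models, conventions and design choices behind
`pufminer`, in enough detail to judge what its tests do and do not
demonstrate.

## Scoring and statistics

Pairwise alignment uses BLOSUM62 with BLAST-style affine gaps (a gap of
length *k* costs open + *k*·extend; defaults 11/1), computed by
`Bio.Align.PairwiseAligner`.  Tiny-instance correctness is checked in the
tests against exhaustive enumeration of all alignment paths, independent of
any dynamic program.  Identity comes in three denominators —
full alignment columns, aligned (both-residue) positions, and the shorter
sequence — because the survey's stages use different conventions:
node collapsing uses the shorter-sequence denominator, redundancy removal
uses aligned positions.

E-values follow the Karlin–Altschul convention with the standard gapped
BLOSUM62 constants λ = 0.267, K = 0.041:
bit = (λS − ln K)/ln 2, E = mn·2^(−bit).  The network edge weight
("alignment score", AS) is max(0, −log₁₀E), floored at 0 so thresholds are
comparable and with E floored at 1e−180 against log overflow.  The hosted
tools this reconstructs do not publish their exact formula; AS here is a
documented convention, and the thresholds 50/80/90 operate on this scale.
For an all-vs-all table the search space mn is fixed per network build as
(mean representative length) × (total representative length): a constant mn
makes AS symmetric under sequence swap and reproducible across thresholds,
which the nesting and symmetry tests rely on.

## Domain model

The stand-in for the curated RC L/M/D1/D2 domain family is a
position-specific scoring matrix over the ≤50 %-gap columns of a seed
alignment, with additive pseudocounts against a uniform background
(f = (c + w·q)/(n + w), score = log₂ f/q, default weight w = 1) and local
affine-gap scanning (gap open 7 bits, extend 1 bit).  The seed alignment
spans all four sub-families — as the real domain family does — which is why
the PsbA/PsbD-like outgroup is *found* by the scan and must be separated
later at the network stage; that ordering is a property of the original
survey this package reproduces.  After each hit the matched region is
masked and the scan repeats, so fusion ORFs yield two non-overlapping hits;
resolution keeps the best two by score.  The default acceptance threshold
of 40 bits sits far below planted-member scores (hundreds of bits, ≥ ~180
even for 30 % fragments) and above the empirical null of shuffled decoys
(≲ 23 bits).  A PSSM rather than a profile HMM is deliberate: it is
deterministic, desk-scale and closed-form checkable; an HMM backend could
replace it behind the same contract.

Homolog membership is the union of the profile route and a pairwise route
(best local AS against any seed query, default threshold 8).  The union is
what rescues full-length homologs too divergent for the domain model — the
generator plants one at extra divergence 0.8 from the PufL root, which
falls below the profile threshold but is comfortably above the pairwise
threshold (AS ≈ 10–15 versus ≤ 4 for every decoy/accessory sequence).

## Synthetic survey model

Sequence evolution is a fixed-length uniform replacement process: along a
branch of length *b* each site mutates with p = 1 − e^(−b), uniformly to
one of the other 19 residues.  Two leaves at branch *b* each therefore have
expected identity (1−p)² + p²/19, which the Monte-Carlo tests check.  No
indels are simulated — fragments supply all length variation — so alignment
semantics stay unambiguous and progressive alignment of intact members is
gapless by construction.

Default study conditions (all in `SimConfig`): root length 300 aa; 4 + 4
clades with 6 members each; divergences within-clade 0.05, between-clade
stem 0.6, family 0.5 (ancestor → PufL/PufM roots), outgroup 1.2
(ancestor → PsbA/PsbD-like root).  These place within-clade identity near
90 % (below the 95 % collapse, AS ≈ 130–180, above every working
threshold), between-clade identity near 30 % (AS ≈ 20–35, below AS 50) and
cross-family/outgroup similarity near noise (AS ≤ ~5) — margins wide enough
that cluster recovery is stable across seeds, which the acceptance script
depends on.  The source publications for such surveys do not report family
divergences; these are the package's own calibration, chosen once.

Clade pair 1 is emitted as single-ORF fusions (member + fixed
low-complexity 10-mer linker `GGSGGSGGSG` + member), giving the domain
splitter a defined gap.  A fragment fraction of 0.1 truncates records to a
contiguous 30–60 % window; truth domains are clipped and dropped below
30 aa, so a fragmented fusion can legitimately retain a single domain.
Decoys are shuffled copies of family sequences (same composition, no
signal).  Clade 3 of both families is "novel": the synthetic reference
database contains ~98 %-identity counterparts of every other family member
(and of the outgroup) but none for clade 3, so uniqueness flags have exact
expected values.  Temperatures are uniform in [42, 90] °C for bins carrying
planted signal and in [0, 42) °C for contaminant bins; missing temperatures
(round(fraction × bins), default 0.2) are assigned to decoy-only filler
bins first so that curation exercises its rules without silently deleting
the planted structure the downstream checks quantify.

Operon architectures are laid out on contigs with 50 bp intergenic gaps,
one genome per (clade, member) pair: fusion clades are always class D;
the remaining genomes receive A/B/C/E by largest-remainder allocation of
the configured mix (guaranteeing coverage of every class with positive
weight), shuffled by the seeded generator.  Class E plants an OmpA-like
segment (a separate 90-aa conserved family) on the PufM C-terminus and the
PufC N-terminus, with the annotation carried in GFF3 attributes.

What the generator does *not* emulate: indels, rate heterogeneity and
empirical substitution preferences, chimeric contigs, annotation errors,
taxonomic breadth, and database-scale reference sets.  Passing tests
therefore demonstrate that the pipeline's logic recovers planted structure
under its stated assumptions — not field performance on real metagenomes.

## Network and tree stages

Node collapsing is greedy and longest-first (ties by id): each sequence
joins the first existing node whose representative reaches 95 % identity
over the shorter sequence, else founds a node — so the representative is
always a longest member.  Whether the original reduction used the
shorter-sequence or alignment-length denominator is not documented
anywhere; the mode is configurable and the default is recorded here.
Components are labeled 1..k by decreasing size; singletons are retained in
exports but excluded from downstream stages (they are typically fragments —
the one pitfall being a genuinely divergent full-length homolog, which is
exactly what the low-threshold rescue scan is for).

The progressive aligner builds an average-linkage guide tree on 3-mer
distances and merges profiles under BLOSUM62 expected scores with the same
affine-gap machinery as the scanners.  Alignment editing is an automated
stand-in for manual curation: rows below 60 % of the median ungapped length
are removed as fragments, then columns above 50 % gaps; both thresholds are
configurable and every removal is logged.  Redundancy removal applies the
aligned-positions rule (identity > 95 % ⇒ discard the row with fewer
residues, ties against the lexicographically later id) scanning in row
order and iterating to a fixed point; because the rule is order-dependent,
the order is part of the contract and the tests replay it independently.

Trees are neighbor joining on p-distances (Poisson correction available)
with deterministic tie-breaking, exact on additive matrices — the
acceptance bar is planted-clade recovery, not topology identity with any
published maximum-likelihood tree, and an external ML backend can be
substituted where that matters.  Rooting picks the edge that best separates
the designated outgroup (warning if it is not monophyletic), splitting the
edge length evenly.

## Pipeline conventions

The discrimination network (AS 90) removes every component containing a
known outgroup reference; the clustered networks (AS 50/80) are built on
the remaining nodes from the same score table, so threshold nesting holds
by construction.  Tree input is the AS 80 non-singleton representatives
plus the outgroup references (re-added for rooting).  Uniqueness queries
are the hot-spring ingroup tree representatives, scored against the
reference set with local-alignment identity over the shorter sequence and
a strict < 0.95 cutoff.  The manifest echoes every threshold and count per
stage and is byte-reproducible for a fixed configuration; run-to-run
determinism is asserted in the tests.

Pipeline configuration is a typed dataclass (`PipelineConfig`) echoed into
the manifest rather than a separate YAML file; the CLI exposes the same
knobs as options.  One SSN → tree pass is performed; re-entry (re-cluster
after tree-based edits) is possible by feeding a pipeline's outputs back
through the stage functions, which are all public.

## Operon design

Codon optimization offers two policies: `most_frequent` (per-residue
argmax, deterministic, maximizes summed codon frequency by per-residue
independence) and `weighted_random` (seeded draws proportional to usage).
Both guarantee translate(optimize(p)) = p.  The bundled host table is a
*constructed* GC-rich usage (softmax on codon GC within each synonymous
family) mimicking the GC3 bias of an alphaproteobacterial expression host;
it is labeled synthetic and any measured table can be supplied as TSV.
The 6-His tag is inserted immediately after the initiator methionine and
encoded with the same usage table.  Masses are average residue masses plus
one water (Biopython's table), reported in kDa to one decimal — the
convention used for gel annotations; monoisotopic masses are out of scope.

## Numerical and degenerate-input choices

Alignment traceback prefers match over vertical over horizontal moves, so
reported coordinates are deterministic.  Local alignments with no
positive-scoring pair return an explicit empty result rather than an error.
NJ branch lengths are clamped at zero; a distance between rows with no
overlapping aligned columns is an error naming the pair.  Profile building
requires ≥3 seed rows and ≥10 match columns.  Curation classifies every
input bin (kept or excluded-with-reason); the pipeline exits cleanly with a
partial manifest when curation keeps nothing or fewer than two nodes
remain.

## Problem sizes

The default survey (35 bins, ~176 proteins of ~300 aa, ~55 network
sequences) is sized so the full pipeline completes in well under a minute
on one CPU and the whole test suite in a few minutes, while keeping every
planted margin wide; all sizes scale through `SimConfig`.

## Known limitations

Uniqueness is all-vs-all exact local alignment — fine at desk scale,
quadratic beyond it.  The PSSM lacks position-specific gap penalties.  The
progressive aligner has no iterative refinement.  Architecture
classification trusts the gene labels it is given (from annotation or
ground truth); it does not itself call orthologs.  Fragmented genes can
break operon adjacency and demote a genome to `fragment_or_unknown`, which
is why architecture accuracy is stated over non-fragmented genomes.
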