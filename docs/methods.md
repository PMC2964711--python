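# Methods

## Coordinates, reference and exclusions

All positions are 1-based coordinates on a 16,569-nt mitogenome laid out
like the revised Cambridge Reference Sequence: control region 16024–16569 +
1–576, coding region 577–16023, canonical gene map (13 protein-coding
genes, 2 rRNAs, 22 tRNAs; ND6 and eight tRNAs on the light strand).
HVS-I analysis window 16024–16383 and HVS-II 57–372 (the standard
convention); motif *parsing* tolerates the full control region because
published tables occasionally cite sites such as 16463.

Site 16519 is never scored.  The hypervariable poly-C tracts
(16184–16193 and 303–315) exclude **length variation only**: the variant
caller drops insertions/deletions inside them and the simulator never
plants any there, but substitutions at tract positions are kept — 16189,
inside the tract, is itself a subclade diagnostic, so excluding tract
substitutions would be self-defeating.  Indels elsewhere are normalised by
right-shifting to the 3′ end of homopolymer runs, the usual mtDNA
nomenclature convention, making placement deterministic.

The packaged reference is **synthetic**: a deterministic pseudorandom
sequence at mtDNA-like base composition with the poly-C tracts and a small
set of anchored bases at positions where the packaged survey's
transversion tokens constrain the reference state (e.g. 16147=C so that
both `147G` and `147A` are transversions).  Consequences: coordinate
conventions, windows, gene intervals and every algorithm are exactly as
for the real rCRS, but *which* coding sites are synonymous is a property
of the synthetic sequence.  Classification of real coding variants
requires dropping in the real rCRS (`load_reference(path)`); nothing else
changes.

## Subclade classification

Clades are defined by the diagnostics arising on their branch (motif
notation per segment, with `@` marking an expected back mutation and
`anti_hvs1` sites whose presence excludes a clade).  The classifier scores
each haplotype against the *cumulative* profile of every clade — a child's
diagnostic at a position supersedes its ancestor's, which is how the
16147 G→A change and expected reversions behave on the real tree — and
assigns the minimal weighted cost:

| evidence against a clade                   | weight |
|--------------------------------------------|--------|
| diagnostic site entirely absent (missing)  | 4      |
| diagnostic site called with another base   | 3      |
| private call the path does not explain     | 2      |
| expected back mutation violated            | 1      |
| expected back mutation satisfied           | −1     |

Coding diagnostics are skipped for control-region-only records; HVS-II
diagnostics only count when HVS-II was typed.  Ties between nested clades
resolve to the deeper clade (a record matching N1a1a exactly is reported
as N1a1a1, whose extra diagnostics are invisible in HVS data — matching
how published tables label such records); ties between incomparable clades
resolve to the common ancestor with status `ambiguous`.  Strict mode
instead requires every visible diagnostic present and picks the deepest
such clade.

The weight ordering encodes: a missing diagnostic is stronger evidence
against a clade than an unexplained private mutation; conflicts at
recurrent sites are penalised mildly; and an absent ancestral mutation
where the clade predicts a reversion is positive evidence (this last term
is what separates the 16086-less N1a1a2 types, which lack 16172, from
N1a1a1).  With these weights the classifier reproduces the recorded label
of **every** row of the packaged survey (weighted concordance 1.000).
The weights are exposed (`MatchWeights`) and the clade tree is an editable
YAML config; the N1a1a2/N1a1a3 coding diagnostics are unknown from
published sources and those clades therefore rest on control-region motifs
(16086 + HVS-II 152-199-204-207 + the 16172 reversion; 16154).

## Reduced median network and tree extraction

Haplotypes are recoded as binary vectors over observed (position, derived
state) characters, 0 = reference state; a triallelic position yields two
characters sharing the position tag; characters carried by every record
are moved to the stem ("basal") rather than kept as constant columns.
The observed vectors are closed under triple-wise majority (median); for
binary data the closed set contains the latent ancestors of the
most-parsimonious trees.  Implementation detail: vectors are bit-packed
and each closure pass pairs the whole pool against the newly added
frontier only (med(a,b,c) = (a∧b)∨(c∧(a∨b))), which keeps the closure
tractable on survey-sized inputs (the packaged 115-row table closes to
~700 vectors in seconds).

The network graph links vectors whose coordinate interval contains no
third pool vector; multi-mutation links are subdivided with latent
intermediate nodes (sites applied in ascending order from the
lexicographically smaller endpoint) so every edge carries exactly one
character.  Incompatible character pairs whose multiplicity-weighted
support ratio exceeds the reduction parameter *r* (default 2, the
conventional default) are reduced: a latent degree-2 corner of the
conflict cycle is removed, weakest neighbourhood first, only when an
equivalent two-edge path remains — a conservative reduction that provably
never changes the minimum tree length.  Inferred nodes of degree ≤ 1 are
pruned.

Tree extraction finds the minimum-weight Steiner tree of the network over
the observed haplotypes plus the outgroup attachment (exact Dreyfus–Wagner
up to 14 terminals; the networkx approximation beyond, with a logged
warning), roots it at the node nearest the outgroup state (all-reference
by default), and collapses unobserved degree-2 pass-through nodes into
multi-mutation edges.  If several nodes tie for the outgroup attachment
the extraction refuses with the candidate list; an override
(`root=<taxon>`) or forced homoplasy resolutions (`<site label>=force`,
implemented by ε-weighting the forced edge and adding its endpoints as
terminals) resolve it.  All iteration orders are fixed (sites ascending,
taxa lexicographic), so outputs are bit-reproducible.

## ρ dating

ρ is the multiplicity-weighted mean count of class-filtered mutations on
the root→haplotype path; identical sampled haplotypes count once per
individual, so *n* counts mtDNAs.  σ² = Σ_edges (n_below/n)² · m_edge
(Saillard et al.).  Ages are ρ·rate and σ·rate; reports round to whole
years, internal values stay unrounded.  Mutation classes: *all
coding-region base substitutions* (indels never count) and *synonymous
transitions* — a transition in a protein-coding gene leaving the amino
acid unchanged in **every** overlapping reading frame (the conservative
choice for the ATP8/ATP6 and ND4L/ND4 overlaps); codons incomplete at a
feature boundary are ignored for that frame.  Positions inside the coding
window but in no annotated feature classify as `other` and are logged.

The calibration table ships six rates back-computed from a published
subclade age table whose printed ages and standard errors are all
consistent with per-clade (ρ, σ) pairs: 5,140 and 4,610 years per coding
substitution; 6,764, 7,650, 7,884 and 7,990 years per synonymous
transition.  They are package defaults to be confirmed against the
original calibration literature; the table is a TSV the user can replace.

## Synthetic data generator

The generator emulates the data-generating model the ρ clock assumes: a
clock-like genealogy (star, random coalescent "yule", or fixed Newick)
whose branches accrue independent Poisson mutation counts per class, with
positions drawn uniformly from the exact legal pool of each class —
synonymous-transition sites enumerated codon-by-codon from the gene map,
control sites from the hypervariable windows minus exclusions — and never
reused along a root→tip path (back mutations only on request, as the
classifier's hard case).  Because "all coding substitutions" subsumes
synonymous transitions, non-synonymous changes are planted at intensity
1/rate_coding − 1/rate_syn, so both class totals are Poisson with the
stated means; a config whose coding rate implies fewer coding changes than
synonymous transitions alone is rejected.

Defaults mirror the study scale: 19 mtDNAs, TMRCA 10,000 years (inside
the published subclade range), rates 5,140 / 6,764 y per mutation, and a
control-region rate of 20,180 y per transition (the classic HVS-I
transition clock).  The packaged 19-tip demonstration genealogy fixes the
study's subtree sizes (10/3/4/2 + outliers, TMRCA 18,000 y) and uses seed
13 — the first seed under which every internal branch carries at least one
mutation, the structural condition for topology recovery to be well-posed.
Motif-table emission plants each clade's control-region diagnostic path
plus Poisson(0.5 by default) private mutations drawn *outside* the tree's
diagnostic sites, so planted labels are recoverable by construction.

What the generator does **not** emulate: rate heterogeneity across sites,
hypervariable hotspots, heteroplasmy, ancient-DNA damage, and sequencing
error.  Passing tests therefore demonstrate correctness of the machinery
under the clock model's own assumptions, not robustness to real-data
artefacts.

## Numerical and testing choices

* Exhaustive parsimony oracle (tests): Dreyfus–Wagner dynamic program over
  the full site hypercube, independent of the package's graph code; used
  on instances up to 10 taxa × 10 sites.
* ρ/σ oracle: explicit path enumeration from scratch.
* Coverage calibration: ρ ± 2σ covers the true per-lineage expectation in
  ≥ 93% of 1,000 star simulations at study scale (observed ≈ 95%); the
  same property holds end-to-end through genome emission, variant calling,
  network building and tree extraction (400 replicates at 10 tips).
* Monte-Carlo χ² check: the asymptotic upper-tail p agrees with a
  10,000-draw permutation null within 0.01 on tables with expected counts
  ≥ 5 (2×2 tables are too discrete for that bound and are not used).
* The heterogeneity grouping that yields d.f. 81 on the N1a1a1a table
  pools all Kazakh samples (Kazakhstan, Kazakhs, Kazakh-South Siberia)
  into one origin column; it ships as an explicit two-column merge map so
  users can substitute their own partition, and the test reports d.f.
  alongside χ².

## Limitations

* The shipped reference is synthetic; real-sequence synonymy
  classification requires the real rCRS (drop-in replacement).
* The reduction step implements a conservative, provably
  length-preserving subset of the classical frequency-criterion
  reduction; heavily reticulate data are returned with their cycles
  rather than aggressively resolved.
* Steiner extraction is exact only up to 14 terminals; larger conflicted
  networks fall back to an approximation (logged).
* The classifier's weights are calibrated to reproduce the published
  survey's labelling conventions; very different nomenclature traditions
  may need re-tuning via `MatchWeights`.
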