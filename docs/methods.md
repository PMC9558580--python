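# Methods

## The demarcation framework

A genus is operationalized as a clade of a rooted core-genome phylogeny
whose members all share pairwise core-proteome average amino-acid identity
(cpAAI) at or above a threshold τ, while every comparison between a member
and a non-member falls below τ. The default τ = 86.0 % sits inside the
low-density interval that separates within-genus from between-genus
comparisons in the *Rhizobiaceae*; because the threshold is approximate, a
±1.0-point warn band flags borderline reports ("supplementary evidence
recommended") rather than silently deciding them. The threshold is
inclusive: a value exactly at τ counts as within-genus.

`propose_genera` recurses from the root and accepts the shallowest clade
whose report is consistent; inconsistent clades recurse into their
children. Two asymmetries are deliberate:

* **Supra-threshold clades are never auto-split.** When between-clade
  values exceed τ, splitting requires biological judgement, so it must be
  requested as a `force_split` override carrying a justification, which is
  recorded in the proposal. Conversely `force_merge` accepts a clade
  despite sub-threshold internal values (e.g. to preserve a historical
  genus).
* **Leaves that never joined a consistent clade become singleton genera.**
  A singleton separated from everything by < τ is a legitimate
  isolated lineage; one that shares ≥ τ with outside taxa is flagged for
  expert review, since no tree-consistent assignment satisfies the
  threshold for it.

`max_between` is computed against *all* non-members, not only the sister
clade — the stricter reading, which makes "consistent" proposals robust to
distant stragglers.

A consequence of the no-auto-split policy worth knowing: the number of
proposed genera is not globally monotone in τ (raising τ can turn a
supra-threshold mosaic of singletons into one consistent clade). On
tree-compatible nested similarity — which well-behaved cpAAI matrices
approximate — monotonicity holds, and the property suite tests it there.

## cpAAI

cpAAI(i, j) = 100 · (1 − D/L) over the concatenated marker alignment,
where L counts columns in which both rows hold an unambiguous residue and
D those that differ. Sites with `-` (missing marker or alignment gap),
`X` (ambiguous translation) or `*` (stop) are excluded **per pair**
(pairwise deletion), so two genomes missing disjoint marker subsets remain
comparable over their common columns. Complete deletion (drop a column if
any taxon has a gap) was rejected because a single sparse genome would
shrink L for every pair. Pairs with fewer than `min_compared_sites`
(default 100) compared sites are retained but flagged unreliable; a pair
with no common site is NaN. Matrix outputs round to 1 decimal in reports
and 4 decimals in TSV serialization.

Note that `ape::dist.aa(pairwise.deletion=TRUE)` — a common way to count
protein substitutions in R — deletes only unknown-residue sites and counts
gap-vs-residue as a difference; on gap-free alignments the two conventions
coincide, and the test suite cross-checks against it exactly there.

## Marker search

The extraction pipeline is self-contained rather than shelling out to an
external translated-search tool. Each marker's query is the majority-rule
consensus of its reference alignment (gap-majority columns dropped; ties
broken lexicographically for determinism); an optional `all_rows` mode
searches every reference row and keeps the best hit. The query is aligned
locally (Smith–Waterman, BLOSUM62, gap open 11 / extend 1, first gap
position costing the open penalty) against all six reading frames of every
contig, translated with genetic code table 11; stop codons translate to
`*` (scoring −4 against every residue) and any codon containing a
non-ACGT base to `X`. A hit spanning an internal stop is kept but flagged
as a possible frameshift or pseudogene.

Acceptance thresholds default to identity ≥ 30 % and coverage ≥ 70 % of
the consensus — the same spirit as the whole-proteome AAI ortholog
criteria, since no tighter standard exists for this step; both are
configurable. Equal best scores are broken by contig id, then
forward-strand start, then `+` strand, making results independent of
iteration order. Coordinates are 0-based half-open on the forward strand;
translating the recorded interval (reverse-complemented for `-` hits)
reproduces the extracted protein exactly, a property-tested invariant.

Placement back into the reference ("keep-length") aligns the extracted
protein globally to the consensus with free terminal gaps and writes each
matched residue into the reference column hosting that consensus position;
insertions relative to the consensus are discarded. This keeps the
supermatrix column count fixed across genomes — the stability cpAAI needs
— at the cost of ignoring residues with no reference column, a deliberate
trade-off.

## wpAAI and POCP

Both consume all-vs-all protein hit tables in the standard 12-column
tabular format, produced by any external search tool or by the built-in
exhaustive Smith–Waterman generator (practical for small or synthetic
proteomes only). The built-in generator computes no e-value statistics and
emits NaN; thresholds can then run in `ignore_evalue` mode (identity +
coverage only), which is off by default. An ortholog pair for wpAAI is a
reciprocal best hit (by bit score, ties by e-value then subject id) with
both directions passing e-value < 1e−3, identity > 30 % and alignment
length > 70 % of the query protein; wpAAI is the unweighted mean of the
pair identities (the two directional identities averaged). POCP counts
each query protein once however many qualifying hits it has, with
"length of the protein" read as the query protein length.

## GANTC density

The CcrM methyltransferase motif GANTC is counted on the forward strand
only: the motif is self-complementary, so one strand covers both.
Overlapping occurrences count independently (regex lookahead). The middle
position accepts `N` — an unknown base is still potentially a site — while
the four outer positions require exact A/C/G/T. Density is
1000 · count / total assembly length (sites/kb). In real *Rhizobiaceae*
data this density separates genera with means near 1.1 vs 1.7 sites/kb;
the package computes the statistic but leaves its interpretation to the
demarcation evidence table.

## Gap scanning

Histograms use bins of width 0.5 % (configurable) with edges anchored at
multiples of the width — edge alignment is otherwise arbitrary, and
anchoring at zero makes results reproducible across value ranges. A gap is
a maximal run of interior bins with count ≤ `max_count` (default 0, a
strictly empty gap); raising `max_count` tolerates stray comparisons
inside, which is how a "five of 4371 comparisons" near-gap is detected.

## The simulator

The generator emulates a multi-genome study at desk scale: a Yule
(pure-birth, rate 1) tree rescaled to a chosen mean root-to-tip depth;
single-copy marker proteins (default 170 markers of 100–500 aa) evolved
down the tree; assemblies built by back-translating each protein with
uniformly drawn synonymous codons (table 11), adding an ATG start and a
stop codon, and planting the cassette at non-overlapping uniform positions
and strands in i.i.d. background contigs of configurable GC (default 0.6,
matching the GC-rich rhizobial range).

Substitutions follow a 20-state equal-rates (Poisson) model: along a
branch of length *t* (expected substitutions/site) each site is hit with
probability 1 − exp(−(20/19)·t) and redrawn uniformly over all 20
residues. This is the exact marginal of the equal-rates Markov chain, so
branch effects compose along paths and pairwise identity has the closed
form P(d) = 1/20 + (19/20)·exp(−(20/19)·d) — 1 at d = 0, 1/20 as d → ∞.
The equal-rates model was chosen over an empirical substitution matrix
precisely because this closed form lets parameter-recovery tests compare
measured cpAAI against truth analytically; realism is secondary to
testability. (A per-branch rule of "substitute to a uniformly random
*different* residue" looks equivalent but is not Markov-composable and
disagrees with the closed form for multi-branch paths; the redraw-over-20
formulation is used throughout.)

Defaults: no indels, so extraction and placement are exactly invertible
and a reference "alignment" is just stacked equal-length rows. An optional
indel mode (one geometric-length insertion or deletion per marker per
taxon, mean 2 residues) exists for robustness testing only and
deliberately breaks the exact identity bookkeeping. Planted-partition
scenarios join per-genus Yule clades (depth = `within_depth`) on root stems
of `between_extra`/2, giving direct control of within- vs between-genus
identity through P(d).

What the simulator does **not** emulate: gene calling noise, paralogy and
gene loss, horizontal transfer and recombination, codon-usage and
strand-composition bias, repeats, and real indel processes. Passing the
recovery tests therefore demonstrates the correctness of the measurement
chain (search, placement, concatenation, cpAAI, demarcation) under the
stated model, not robustness to every artefact of real assemblies.

## Problem sizes and numerics

The recovery suite uses 8 taxa × 30 markers (120–220 aa) in ~16–20 kb
2-contig assemblies, with planted 3/3/2 genera at within-depth 0.025 and
between-extra 0.20 substitutions/site — identities ≈ 95–100 % within and
≈ 78–82 % between, a ≥ 4-point separation across τ. At these sizes the
full pipeline recomputes in about two minutes on one CPU; measured cpAAI
matrices land well under 1.5 points RMS of the closed-form expectation.
Statistical checks (closed-form identity recovery at
d ∈ {0.02, 0.05, 0.1, 0.2, 0.4} over 20 000 sites) use 3-standard-error
bounds. All randomness flows from explicit integer seeds; every generator
is bit-reproducible for a fixed seed.

## Known limitations

* Single best hit per marker: frameshifted genes split across local hits,
  and spliced or fragmented markers, are not reassembled.
* The built-in aligner provides no e-value statistics; external search
  tables are required when e-value thresholds must be honoured exactly.
* The tree is consumed as rooted; no automatic rooting or support
  recomputation is attempted.
* Family-level demarcation (the low-70s cpAAI break) is reported by the
  gap scan but no family partition logic is built.
* cpAAI on genomes with < 50 % of markers found triggers a warning; such
  rows are unlikely to be comparable across pairs.
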