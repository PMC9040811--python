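# Methods

This note documents the models, rules, and numerical choices behind qsmine,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Evidence model

The pipeline consumes precomputed annotation evidence rather than running
annotation services: per-protein domain hits (InterPro/Pfam namespaces, with
E-values) and per-protein KO assignments, alongside a protein FASTA and GFF3
coordinates. Two evidence tracks are used deliberately:

* **LuxI/LuxR homologs** are authenticated from *domain architecture*. A Pfam
  HMM gate is applied first — PF00765 (autoinducer synthase) for LuxI,
  PF03472 (autoinducer-binding domain) for LuxR, at E < 1e-5, strict
  inequality — then required InterPro signature domains are checked. LuxI
  requires IPR016181 (acyl-CoA N-acyltransferase) and IPR001690 (autoinducer
  synthase); IPR018311 (autoinducer synthesis conserved site) is treated as
  an expected-but-not-mandatory site, because functional synthases lacking it
  are documented (the RaiI-type case) — its absence downgrades a call to
  `accepted_with_flags{missing_conserved_site}` rather than rejecting it.
  LuxR requires all four of IPR005143, IPR036388, IPR016032, IPR000792.
  No alignment-coverage requirement is imposed on the gate hit; only the
  E-value is gated.
* **All other components** (QseE/F, RpfF/C/G/B, Clp, AhlD, LsrB, QseB, CviR)
  are inventoried from KO evidence via a packaged KO→role catalog. K19666
  (SolR-type LuxR) is in the catalog although it is not one of the 77
  reference KOs; the catalog notes this.

Domain-hit rows above a caller-supplied E-value threshold are *flagged*, never
silently dropped — filtering is the classifier's decision, and the full
evidence chain is retained on every call.

## Adjacency (pair vs solo)

"Adjacent" is operationalized as: same replicon, intergenic gap ≤ 2,000 bp,
and ≤ 2 intervening genes; both thresholds are configurable. Matching is
greedy nearest-neighbor with ties broken by smaller gap, then lexicographic
feature id, so output is deterministic and each feature joins at most one
pair. Unmatched accepted homologs become `luxI_solo`/`luxR_solo`.

## System summary

* **AI-3**: QseEF pairs are counted as min(#QseE, #QseF) with leftovers
  reported as orphans. Adjacency is *not* required for this count — the
  two-component sets are tallied by multiplicity.
* **DSF**: completeness is a tier plus an explicit missing list rather than a
  boolean, because a genome lacking only the downstream regulator Clp still
  constitutes a working sensing circuit: `full` = {RpfF, RpfC, RpfG, RpfB,
  Clp}; `missing_clp` = all but Clp; `core` = the RpfF/RpfC/RpfG circuit
  present (RpfB absent); `partial` = any other non-empty subset.
* **QQ (AhlD)**: each copy is counted, and its validity is downgraded to
  `questionable` when the conservation report flags a broken signature motif
  or a truncation.
* **AI-2**: LsrB alone (no Lsr transporter evidence is modelled) sets a
  "doubtful" flag rather than a positive system call.

## Conservation checks

Pairwise alignment is optimal global affine-gap (Gotoh), with a gap of length
k costing `gap_open + k*gap_extend`; defaults gap_open = 6, gap_extend = 1
(the bit-penalty convention of the original alignments, used here with a
BLOSUM62 substitution matrix). Traceback is deterministic: on ties,
match/mismatch beats a gap in the reference row, which beats a gap in the
candidate row. The ambiguous residue X scores 0 against everything and never
satisfies a key-residue or motif position — ambiguity cannot create a
conservation claim.

Key-residue profiles are packaged as YAML: LuxI (10 positions), LuxR (9),
RpfF (4), AhlD (6 zinc-coordination positions). **The packaged reference
sequences are synthetic stand-ins**, generated so that every key position and
motif anchor is satisfied; curated family references are not redistributed.
The profile format accepts any replacement reference, and positions are
validated against it at load time. The RpfB profile ships with an empty key
position list (its active-site threonine/glutamate coordinates are not
established for the synthetic reference), so the RpfB residue check is a
documented no-op until a user supplies a profile.

The AhlD zinc-metallohydrolase signature is a spaced motif: block HXHXDH,
then a lone H, then a distal D. The published anchor coordinates (102, 179,
201 on the family reference) imply 71 and 21 intervening residues, which is
inconsistent with the printed spacer counts (63 and 24); the default follows
the anchors with a ±10-residue window per spacer, and literal spacer counts
are available via configuration (`spacers: [[63, 63], [24, 24]]`). Scanning
is exhaustive (no heuristics): all complete chains are enumerated and
non-overlapping hits selected left to right. A sequence that ends inside a
spacer window or before the next block can fit yields `truncated`, which is
distinct from `motif_absent` — a truncated lactonase is reported as possibly
incomplete evidence, not as a confirmed signature loss.

## Phylogenetics

* **MSA**: progressive alignment along a UPGMA guide tree built from 3-mer
  set distances; profiles are merged by optimal profile–profile affine-gap
  alignment where a column pair scores the frequency-weighted mean
  substitution score (gap symbols contribute zero). Deterministic for a fixed
  input order. This is an implemented aligner, not a wrapper; numerical
  identity with external MSA tools is not a goal — correctness is established
  against homology-map truth from the simulator.
* **Distances**: pairwise deletion (columns gapped in either member of the
  pair are excluded for that pair only), p = differing/shared sites, Poisson
  multiple-hit correction d = −ln(1 − p). A pair with no shared ungapped
  columns, or with p = 1 (correction diverges), is *undefined*: recorded in
  failure records, never imputed. The caller may drop offending sequences
  (greedy: repeatedly remove the sequence in the most undefined pairs, ties
  lexicographic) or abort.
* **NJ**: canonical Saitou–Nei Q-criterion agglomeration. The Q minimum is
  selected over the upper triangle only (the two triangles can differ by one
  ulp from summation order), with ties broken by the lexicographically
  smallest sorted pair of cluster labels (a cluster is labelled by its
  smallest leaf). Negative branch lengths are clamped to zero with the
  deficit moved to the sibling branch, preserving the pair's summed length;
  in the terminal three-cluster closed form negatives are clamped to zero.
* **Bootstrap**: replicate r draws columns with replacement using an
  independent substream (`SeedSequence(seed, spawn_key=(r,))`), so runs are
  reproducible and replicates order-independent. A replicate **fails** when
  any pairwise distance is undefined in the resample; failed replicates are
  counted and excluded from the support denominator. This operational failure
  rule is this package's own definition of replicate failure — chosen to make
  the "n replicates failed" bookkeeping explicit and testable — and supports
  are percentages of *successful* replicates containing each internal
  bipartition of the reference tree.
* Trees are built only for families with ≥ 4 accepted members: NJ needs 3,
  and 4 is the smallest family with an internal edge to attach a support to.

## Gene neighborhoods

The context window is [start − 5,000, end + 5,000] measured from the focal
gene's boundaries (not its midpoint), clipped to the replicon and wrapping
only on circular replicons. Features partially overlapping the window are
included with their overlap length. Keyword flags are case-insensitive
substring matches on product text (defaults: transposase, mobile element,
integrase, recombinase, transposon), with upstream/downstream defined
relative to the focal gene's strand. Product strings are treated as free
text; no ontology is assumed.

## Synthetic data

`simulate_family` evolves a root protein down a tree: per branch of length b,
each site receives a Poisson(b) number of events, each event replacing the
residue uniformly among the other 19. The expected proportion of differing
sites between sequences at path length t is therefore
p(t) = (19/20)(1 − e^(−20t/19)), which the tests verify by Monte Carlo.
Optional single-residue indels (rate per site per unit branch length, 50/50
insertion/deletion) are tracked in a global homology-column registry, giving
a true alignment for MSA benchmarking.

`plant_genome`/`make_cohort` build annotated genomes by sequential layout:
cassettes (AI-1 pair with a configurable intra-pair gap, LuxI/LuxR solos,
QseEF sets, DSF subsets, AhlD variants, LsrB, QseB, CviR) separated by enough
filler genes and spacing that nothing pairs across cassettes by accident.
Overlapping gene plans cannot arise by construction. Cassette proteins derive
from the packaged synthetic references (optionally diverged by the
substitution process); the AhlD variants are: `valid` (reference),
`motif_broken` (distal D anchor substituted, yielding `motif_absent`), and
`truncated` (cut inside the first spacer window, yielding `truncated`).
Filler products come from a neutral vocabulary with no mobile-element
keywords, so keyword flags in tests come only from planted neighbors; the
expected neighborhood flags are derived from the final layout geometry.
Everything planted is recorded in a truth ledger (JSON), and cohort output is
byte-identical under a fixed spec and seed.

What the generator does **not** emulate: real genome composition (GC content,
codon structure — nucleotide sequences are not generated at all), annotation
noise (wrong KO assignments, spurious domain hits), operonic gene order
beyond the planted cassettes, and realistic protein families (the references
are synthetic). Passing the end-to-end recovery test therefore demonstrates
that the calling logic is faithful to its rules under clean evidence, not
that the rules are robust to noisy real-world annotation.

## Problem sizes

The default test and acceptance workloads use: families of 6 leaves × 500
sites over 20 seeds for distance recovery (mean absolute error ≤ 0.05);
bootstrap supports at 100 replicates; alignment-oracle pairs of length ≤ 8
over a reduced alphabet (exhaustive enumeration stays exact and cheap); 50
random additive matrices of 4–8 taxa against exhaustive least-squares
topology search; 200 random 2-kb sequences for motif-scan agreement; and a
12-genome, 4-genus planted cohort for end-to-end recovery. These sizes give
stable statistics while keeping the whole suite fast on one CPU.

## Limitations

* The conservation verdicts are only as meaningful as the reference profiles;
  with the synthetic stand-ins they verify machinery, not biology.
* The Pfam gate uses E-values as given in the input table; no coverage or
  bit-score criterion is applied.
* NJ with Poisson-corrected distances assumes uniform rates across sites and
  lineages; no rate heterogeneity or model selection is offered.
* AI-2 detection is limited to LsrB presence; the full Lsr transport operon
  is not modelled.
* Circular-replicon wrap-around is supported for neighborhood windows but
  planted test genomes are linear by default.
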