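# qsmine

Genome mining of quorum-sensing (QS) and quorum-quenching (QQ) systems in
bacterial genomes, built for comparative surveys such as cohorts of
acidophiles (*Acidithiobacillus*, *Leptospirillum*, *Sulfobacillus*,
*Acidiphilium*) from acid mine drainage environments.

Given per-genome bundles — a protein FASTA, GFF3 gene coordinates, an
InterProScan-style domain-hit table, and a KEGG Orthology (KO) assignment
table — the pipeline answers: which QS circuits does each genome carry, are
the key catalytic/binding residues intact, how are the homologs related, and
what sits next to them on the chromosome?

## What it computes

* **KO inventory** — presence/absence of the 77 QS-pathway (ko02024) KOs per
  genome, and genus-level Venn sharing (which KOs all genera share, which are
  genus-exclusive).
* **LuxI/LuxR authentication** — domain-architecture rules: a Pfam HMM gate
  (PF00765 / PF03472 at E < 1e-5) plus required InterPro signature domains
  (LuxI: IPR016181 + IPR001690, with IPR018311 optional but flagged when
  absent; LuxR: IPR005143 + IPR036388 + IPR016032 + IPR000792, all required).
* **Pair/solo calls** — greedy nearest-neighbor adjacency on each replicon
  (defaults: intergenic gap ≤ 2 kb and ≤ 2 intervening genes); unmatched
  homologs are reported as solos/orphans.
* **System summary** — per genome: AI-1 (pair/solo), AI-3 QseEF multiplicity
  (pairs = min(#QseE, #QseF), leftovers are orphans), DSF completeness tier
  over {RpfF, RpfC, RpfG, RpfB, Clp}, AhlD count with validity, and an
  LsrB-only AI-2 flag.
* **Conservation checks** — optimal global affine-gap alignment
  (Needleman–Wunsch/Gotoh) of candidates against family references; key
  residues (e.g. LuxI R23/F27/W33/E42/D44/D47/R68 + F82/E100/R103, LuxR
  W62/Y66/D75/P76/W90/G113 + E180/L184/G190, RpfF G86/G138/E141/E161); and the
  zinc-metallohydrolase spaced motif of AhlD, HXHXDH (102) … H (179) … D (201),
  plus the TPGHTPGH block motif. Truncation is distinguished from absence.
* **Phylogenies** — progressive MSA (k-mer UPGMA guide tree, profile–profile
  affine alignment), pairwise-deletion p-distances with Poisson correction
  d = −ln(1 − p), canonical neighbor joining, and column-resampling bootstrap
  in which a replicate *fails* (and is excluded from the support denominator)
  when any pairwise distance is undefined in the resample.
* **Gene neighborhoods** — the 5-kbp context around each accepted LuxI/R
  homolog, with mobile-element keyword flags (transposase, integrase, ...)
  labelled upstream/downstream relative to the focal gene's strand.
* **Synthetic cohorts** — `qsmine.synthetic_data` generates annotated genomes
  with planted cassettes and a machine-readable truth ledger, so every stage
  is testable without downloads.

## Worked example

Simulate a 12-genome cohort with planted QS/QQ cassettes and run the full
pipeline:

```bash
qsmine simulate --out demo/cohort --seed 1
qsmine all --manifest demo/cohort/manifest.tsv --out demo/out --seed 1
```

`demo/out/report/cohort_systems.tsv` then contains one row per genome:

```
genome_id  ai1        ai1_pairs  ai1_solos  ai3_qseEF_pairs  ai3_orphans  dsf_tier     qq_ahlD  qq_ahlD_questionable  ai2_lsrB_only  extras
AFE01      pair       1          0          2                0            full         0        0                     False
ATH02      pair       1          0          2                1            missing_clp  0        0                     False
ACA03      none       0          0          0                1            core         0        0                     False
LFO05      solo_only  0          1          0                0            full         0        0                     False          CviR
STH08      none       0          0          0                0            none         1        1                     False
ACP09      solo_only  0          1          0                0            none         1        1                     False          RaiI
...
```

Reading it: `AFE01` carries an adjacent LuxI/LuxR pair, two complete QseEF
two-component sets, and a full DSF system. `ATH02` has an extra QseF orphan
and a DSF set lacking only the Clp regulator. `LFO05` carries a lone
CviR-type LuxR (a solo receptor, no cognate synthase nearby). `STH08`'s AhlD
lactonase is counted but marked questionable — its HXHXDH…H…D zinc-binding
signature is broken — and `ACP09`'s AhlD is truncated before the signature
completes, likewise questionable; `ACP09` also carries a RaiI-type LuxI solo
that lacks the autoinducer-synthesis conserved site (accepted with a flag,
not rejected). Trees for every family with ≥ 4 members are written under
`demo/out/trees/`, e.g.

```
(ATH02|ATH02_P0002:0.000000,LFO05|LFO05_P0001:0.000000,(AFE01|AFE01_P0003:0.000000,AFE12|AFE12_P0002:0.000000)100:0.000000);
```

(integer internal-node labels are bootstrap support percentages; at zero
planted divergence branch lengths are zero), and
`demo/out/report/ko_sharing.json` holds the genus-level Venn regions of the
KO inventory.

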