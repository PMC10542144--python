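# Methods

## The problem

CheA, the central histidine kinase of chemosensory pathways, is a
multi-domain protein whose classical arrangement — Hpt, P2/CheY-binding,
H-kinase_dim, HATPase_c, CheW — turns out to describe fewer than half of
its homologs. Surveying CheA diversity at genome scale requires (i)
detecting domains whose profiles have very different sensitivities
(the kinase and CheW domains are found reliably; Hpt, P2 and the
dimerization domain are often missed by stringent searches and need a
sensitive second pass), (ii) repairing systematic artefacts
(split-domain insertions that double-count CheW; genes truncated at
contig ends; bipartite operons encoding Hpt separately), and (iii)
aggregating architecture statistics per cohort and per phylogenomic
class (F1–F17, Tfp, ACF). `cheascope` implements that workflow and a
synthetic-data generator that emulates the published cohort-level
frequencies, so the whole pipeline is exercised end to end without any
external downloads.

## Domain models and the scoring stand-in

Real surveys score sequences against curated profile HMMs (stringent
tier) and profile–profile comparisons (sensitive tier). Those models and
tools are external resources; here each family is represented by a
`DomainModel`: a fixed synthetic consensus string (lengths 60–115),
length bounds, and for Hpt a conserved histidine at consensus position
48 (1-based), mirroring the His-48 reference numbering. Detection is by
**windowed ungapped identity** to the consensus:

* standard tier: identity ≥ 0.60 over the whole sequence — the
  profile-HMM stand-in;
* sensitive tier: identity ≥ 0.40, applied only to unannotated regions
  of ≥ 100 residues (the published average-domain-size cutoff) — the
  stand-in for profile–profile matches at >90% probability.

Both thresholds live in `ScanConfig` and must satisfy
0 < sensitive < standard ≤ 1. Because linkers, split insertions and
dimerization extensions are drawn from a 5-letter low-complexity
alphabet (G,S,A,P,T), background windows sit near 5% identity and the
two thresholds separate three regimes cleanly: intact (~1.0), degraded
(~0.5), background (~0.05). Real hit tables (native TSV or HMMER
`--domtblout` via `Bio.SearchIO`, envelope coordinates, `acc` column as
the 0–1 score) can be ingested instead, so the stand-in scorer is never
a commitment for production data.

**Fragments.** Each family is scanned with its full consensus window and
with its two consensus halves. Overlapping same-family candidates are
ranked by *matching-residue count* (identity × window length), ties to
smaller start then longer window. An intact domain therefore resolves to
one full-window hit even if a substitution dents its identity, while a
split domain — full-window identity ~0.5, half-window identity ~1.0 —
resolves to two fragment hits at the stringent tier, reproducing the
two-hits-for-one-CheW artefact of profile searches. The dimerization
domain is scanned through its two ~27-residue helix sub-motifs; a
helix-1 match pairs with the nearest downstream helix-2 match within 170
residues (the maximal extended-dimerization span) and unpaired sub-motif
matches are discarded. Hits shorter than 0.70 × the family's minimum
length are flagged `partial` (strict inequality at the boundary).

**Uncovered regions.** Terminal gaps and inter-hit gaps are treated
uniformly by the 100-residue rule (the source procedure is silent on
termini; this is the package's choice).

## The synthetic generator

The generator defines the study conditions. Architectures are drawn from
class-conditional templates whose default weights encode the published
cohort frequencies exactly (the template-mixture marginals are: classical
46%, P2 present 48%, Hpt-less 1.7% — split 0.9% truncation / 0.8%
bipartite — two-CheW 8% with 99% of class F5 duplicated, multi-Hpt 18%
composed of ACF 12% + Tfp 4.74% + F4 1.26% so that ACF+Tfp hold 93% of
multi-Hpt records, CheY-like 34%, Tfp conditional
P(CheY-like | multi-Hpt) = 94%). Multi-Hpt copy numbers follow a
distribution over 2–8 with >50% at ≥5 copies; one Tfp record per cohort
is forced to fourteen Hpt copies, the published maximum. Hpt-less
templates carry an `hpt_mode` tag (`truncated` / `bipartite`) consumed by
the genome generator. The published constraints on the multi-Hpt/CheY-like
co-occurrence (Tfp conditional 94%, ACF+Tfp share 93%, overall >90%)
bound the overall conditional to at most 93%; the defaults set the ACF
conditional to 1.0 and the ACF share high enough that the overall value
lands near 91.5%, satisfying all three published statements
simultaneously.

Sequence-level channels, each applied per domain instance and recorded
in the ground truth:

| parameter | default | effect |
|---|---|---|
| `degrade_prob` | 0.05 | identity pinned to ~0.5: invisible to the stringent tier, rescued by the sensitive tier |
| `split_prob` | 0.05 | 50-residue low-complexity insertion mid-CheW |
| `his_loss_prob` | 0.10 | conserved His replaced in an Hpt copy |
| `dim_extended_prob` / cap | 0.20 / 170 | inter-helix extension; realized span in (70, 170] |
| `linker_len_range` | (20, 40) | low-complexity linkers between domains and at termini |

Degradation substitutes every second residue (random parity and
replacement letters, the His site exempt), which pins the identity of
*every* scanning segment — full window, halves, helices — to ~0.5,
strictly inside (0.40, 0.60). A sequential substitute-until-below-0.6
scheme would let 50-residue half-windows fluctuate across 0.60 about 8%
of the time and silently leak degraded domains into the stringent tier;
the deterministic placement delivers the intended guarantee exactly.
The linker minimum of 20 makes the unannotated region around any
degraded domain at least 60 + 2×20 = 100 residues, so at default
settings every degraded domain is rescuable and no published marginal is
eroded by the rescue cutoff.

Genome neighborhoods are gene tables only (no nucleotide sequence): one
contig per genome, genes laid sequentially with operon ids. A
configurable fraction of genomes (`sink_prob`) is of the
phosphate-sink-eligible kind — a single cheA drawn from classes whose
templates all carry CheY-like — with phosphatase genes present at
60/871 (the published complement of the 811/871 = 93.1% lacking rate);
other genomes carry 1–3 cheA genes from the full mixture and
phosphatases at 0.85. Bipartite-mode cheA genes receive an
`hpt_standalone` partner in the same operon; truncation-mode genes are
placed with their end inside the 100-nt contig-end margin (the margin is
a configuration choice; no distance cutoff is published).

All randomness flows from one integer seed through numpy's PCG64;
identical (config, n, seed) produce byte-identical FASTA/TSV outputs.

## Architecture building

Overlap resolution is greedy by decreasing score (ties: smaller start,
then lexicographic family); on ≤8-hit instances it provably equals the
lexicographic-maximal maximal disjoint subset, which the tests verify by
exhaustive enumeration. Split merging joins consecutive same-family
hits when the gap is ≤ `max_merge_gap` (default 60, covering the
documented 50-residue insertion with margin) **and** the merged span is
≤ family max_len + gap — the length guard, not the gap, is what protects
genuine tandem duplications (two full CheW copies span ≥ 220 residues
against a 180 budget, while split fragments span ~150). Merging never
crosses an intervening hit of another family, preserving true
CheW–CheY-like–CheW arrangements, and is idempotent.

A record is called CheA iff it carries ≥1 HATPase_c and ≥1 CheW — the
two universally detectable domains that uniquely distinguish CheA
homologs; the dimerization domain is expected but not required for the
call because its detection is sensitivity-limited. The dimerization
domain is "extended" when its span exceeds 70 residues (the classical
~60–70 range). CheY-like placement is order-based: before the first
core-like domain → N-terminal; after the last CheW → C-terminal;
otherwise internal (no quantitative rule is published; this is a stated
decision).

## Statistics and genome calls

Percentages are exact fractions internally, rounded to one decimal only
in emitted tables. Co-occurrence conditionals raise an explicit error on
an empty denominator rather than returning 0. Class profiles report the
modal architecture string per class with lexicographic tie-breaks. The
core-domain rule: a family is core iff it is present in every record
whose absence is not explained by `truncated_candidate` or
`bipartite_partner_found`; a family absent everywhere is never core. Hpt
thus enters the core set only via genome-context rescue, reproducing the
published argument, while P2 (48% presence) and CheY-like (34%) never
can.

The phosphate-sink test takes genomes with exactly one cheA whose record
has `cheY_like_present`, and reports the percentage lacking all of
cheZ/cheC/cheX. Bipartite detection is restricted to same-operon
evidence (the published evidence is operonic).

## Problem sizes and numerical choices

Cohort-level checks use n = 20,000 proteins (the scale at which every
configured marginal is recovered within 4 binomial standard errors,
±1.5 percentage points at worst); the sink cohort uses 871 eligible
genomes, matching the published denominator. The full survey-scale
analysis (generation + two-tier scan + building + statistics) runs in
about 40 s on one CPU; the scanner is vectorized over sequence windows
with numpy. Conserved-His calls use Biopython's `PairwiseAligner`
(global; match +1, mismatch −1, gap open −2, gap extend −1) with a
±1-column tolerance at the site, which makes calls invariant to
terminal padding of the hit.

## What the synthetic cohorts do and do not show

The generator reproduces the *reported frequencies and artefact
mechanisms*, not biology: sequences are synthetic consensus instances
with low-complexity linkers, families are mutually dissimilar by
construction, there is no phylogenetic correlation between records, no
length variation within families beyond the modeled extension/insertion
channels, and degradation is uniform rather than position-specific.
Passing tests therefore demonstrate that the pipeline's logic — tiered
rescue, fragment merging, flag computation, explained-absence
accounting, co-occurrence arithmetic — is correct under controlled
conditions; they do not validate profile-search sensitivity on natural
sequences. For real data the scanner should be replaced by ingested
HMMER/profile–profile hit tables, which the same downstream machinery
consumes unchanged.

## Known limitations

* The identity-based scorer has no gap model; domains fragmented by
  insertions other than the modeled mid-domain split may merge
  imperfectly.
* Class labels are input metadata (as in the source survey, where a
  dedicated classifier assigned them); the package does not predict
  classes from sequence.
* Operon assignment is accepted as input; no operon prediction from
  intergenic distances.
* The genome generator emits gene tables, not nucleotide sequences.
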