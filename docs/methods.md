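# Methods

This note records the scientific model implemented by `lactamine`, the
assumptions behind it, the tunable parameters and their defaults, what
the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Cluster detection

Macrolactam BGCs are found by chaining homology hits rather than by
profile-HMM annotation. The inputs are (a) annotated gene features
(GenBank CDS records, normalised internally to 0-based half-open
coordinates) and (b) a 12-column tabular homology-hit table produced by
any aligner; the homology search itself is deliberately an input, not a
component — re-running it adds nothing to the method and would drag an
external tool into the pipeline.

Five query panels, one per starter-unit type, each combine four core
incorporation-machinery queries (VinN-, VinL-, VinM-, VinK-like), the
type-specific starter-biosynthesis queries, and one PKS query
(IdnP1-like). Parameters, with defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `max_hit_gap` (g) | 80 000 bp | maximal gap between facing boundaries of consecutive hit-bearing genes in one chain; generous because long PKS genes interrupt hit runs |
| min unique queries (u) | N − 2 (N − 4 for β-Ala) | minimum distinct queries per chain; β-Ala clusters legitimately lack the glutamate-mutase pair |
| `max_intermediate_distance` (md) | 70 000 bp | window extension around the outermost hits to capture intermediate genes |
| `pks_identity_floor` | 0.50 | identity below which a PKS-query hit does not count as assembly-line evidence (PKS homology is unreliable across module counts) |
| `evalue_ceiling` | none | optional e-value filter; off by default since hit tables are assumed pre-thresholded by the aligner |

Gaps are measured between facing gene boundaries, not midpoints, and
clusters never span contigs. Strand is carried but ignored by the
chaining logic — real macrolactam clusters mix gene orientations.

Curation is the deterministic replacement of what is usually a manual
step, and every decision is recorded as a flag on the cluster object:

1. overlapping windows of the same type collapse to the call with the
   most distinct queries (`within_type_duplicate`);
2. clusters with no PKS evidence in the window are removed (`no_pks`).
   PKS evidence is either a PKS-query hit at ≥ the identity floor or a
   gene whose product text matches a configurable lexicon
   (`polyketide synthase`, `PKS`, `beta-ketoacyl synthase`). We remove
   *all* PKS-less calls, not only those on contig edges: the assembly
   line is essential for the compound class, and without this screen a
   window containing only the four shared incorporation genes would
   satisfy u for the smaller panels and masquerade as a β-Phe or β-Ala
   cluster. Contig-edge windows carry an additional `contig_edge` flag;
3. windows claimed by several panels are resolved by type-specific
   evidence: most type-specific hits wins, ties break on their summed
   scores, and the 3-Amp/β-Ala pair — which shares all its type
   queries — is decided by biosynthetic logic (mutase present → 3-Amp,
   decarboxylase alone → β-Ala). A residual tie is reported as
   `ambiguous`, never silently dropped.

## Module grammar and functionality

PKS genes are supplied in assembly-line order (default: order of
appearance in the cluster); domains either come from an exchange table
or from the built-in motif scanner. The scanner is regex-based
(active-site neighbourhoods: TACSS for KS, GHSxG for AT, HxxxGxxxxP for
DH, GxGxxG for KR, GxDSL for ACP, …) and is intended for fixture-grade
annotation; profile-HMM detection is explicitly out of scope, and real
genomes should bring external annotations.

Modules split at each ACP; a leading AT/ACP-only unit is the loading
module. An extension module is **functional** iff KS, AT and ACP are all
present and it is not a stalled dehydration position — i.e. not (KR
absent while a DH with an incomplete catalytic triad is present). The
DH triad requires the His of HxxxGxxxxP plus a downstream Asp of
DxxxQ/H. The β-carbon state follows the reductive loop: no KR → ketone;
KR only → hydroxyl; KR + active DH → enoyl (double-bond geometry is
deliberately left unassigned — sequence data alone does not support
E/Z calls); KR + DH + ER → methylene.

KR stereotypes use the published fingerprint scheme: the 50-aa window
downstream of the NADPH-binding GxGxxG motif is searched for the LDD
motif (B-type → *R*-hydroxyl) or the conserved Trp (A-type →
*S*-hydroxyl). A sequence with neither, both, or no Rossmann motif is
`unassigned` and its hydroxyl stereochemistry left open — the classifier
never guesses. A1/A2/B1/B2 subtypes are collapsed to A/B; nothing in
the pipeline depends on the finer split.

## Ring size and formula model

With *m* functional extension modules, ring atoms = 2m + 4 for every
β-amino-acid starter (ring N + 3 starter carbons + 2 per module). The
rule is anchored by three worked architectures: 8 extensions → the
20-membered macrotermycin scaffold, 9 → the 22-membered ciromicin
scaffold, 11 → 26-membered bombyxamycin-like macrolactams. It is a
stated model, carried in the output metadata, not a fitted parameter.

Formulas use additive ketide bookkeeping: the free β-amino acid starter
plus, per functional module, C₂H₂O (ketone) / C₂H₄O (hydroxyl) / C₂H₂
(enoyl) / C₂H₄ (methylene), + CH₂ per methylmalonyl AT, − H₂O for lactam
closure. Carbon numbering runs from the lactam carbonyl (C-1); module
*i* of *m* controls C-(2(m−i)+3).

The worked templates in `architectures.py` (mte / pac / bom) encode the
per-module β-state pattern — one ketide ketone (module 1 slot), one
(*S*)-hydroxyl at module 6 (the position that carries the A-type KR and,
in the isolated compounds, the C-7/C-9 (*S*)-OH and the xylosamine
sugar), enoyl positions elsewhere, one methylmalonyl branch. This
pattern is a reconstruction: it reproduces the measured congener masses
(aglycone + C₅H₉NO₃ → [M+H]⁺ 499.2808 for the 22-ring; + O → 515.2757;
the 20-ring analogues at 473.2652/489.26) and the C₂H₂ relationship
between the two families, but the exact distribution of states along
the chain is constrained only by those totals, not independently
verified per position. The two defective-module patterns are likewise
explicit choices: module 9 missing its KS and module 10 lacking KR with
a dead DH (mte); module 10 alone defective (pac).

Tailoring placement is reported as *proposed*: the glycosylation site
is the (*S*)-hydroxyl position when one exists, otherwise `unplaced`;
oxidation sites are always `unplaced`. These follow homology reasoning,
not computation, and are labelled accordingly. A stretch of ≥ 3
conjugated enoyl positions raises a boolean
`spontaneous_cyclization_prone` flag (polyene macrolactams of this
class undergo light/heat/acid-induced 2+4 cycloaddition); no
cycloaddition product structure is generated.

SMILES output is constructed atom-by-atom around the macrocycle.
Hydroxyl stereocentres are written with @/@@ only where a KR class fixed
S/R, and the @ direction is a fixed convention of the writer, not a
validated CIP assignment; the tests hold the emitted SMILES to ring-size
and molecular-formula agreement (checked against rdkit's independent
ring perception and formula calculator), not to stereochemical depiction.

## Mass arithmetic

Monoisotopic masses come from an embedded, versioned table of
most-abundant-isotope masses (C 12, H 1.00782503207, N 14.0030740048,
O 15.9949146196, S 31.971971, P 30.97376163 Da); nothing is read from
the environment. The adduct convention adds a neutral H atom and
ignores the electron mass — this reproduces the standard printed calcd
value 473.2652 for protonated C₂₆H₃₆N₂O₆ exactly, and places the
computed [M+H]⁺ of the xylosaminylated-oxidised 22-ring core within
2 ppm of the observed 515.2766 feature. Δm/z annotation defaults to a
0.01 Da tolerance, deliberately tighter than the 0.02 Da networking
tolerance to keep CH₂-scale ambiguities out of edge labels. The
transformation table (O, C₂H₂, CH₂, H₂O, H₂, xylosaminyl C₅H₉NO₃)
self-checks at load: every stored Δ-mass must equal the mass of its
Δ-formula.

Genome-to-metabolome linking enumerates the aglycone plus multisets of
at most `max_mods` transformations, glycosylations bounded by the
cluster's GT gene count and oxidations by its CYP count, and reports
nodes within a 10 ppm default tolerance.

## Networking

The modified cosine transforms intensities by square root, normalises
to unit L2 norm, collects candidate peak pairs within the fragment
tolerance either directly or after shifting by the precursor-mass
difference (single shift; no multi-shift), and accepts pairs greedily by
descending intensity product with each peak used once. Greedy matching
is the standard networking practice; on spectra of ≤ 5 peaks the tests
assert it equals the exhaustive optimal assignment, and an independent
implementation (matchms) is used as a cross-check on larger spectra.
Defaults: 0.02 Da tolerances, ≥ 4 matched ions and cosine ≥ 0.75 per
edge (the threshold in use is always logged; no top-K neighbour
pruning by default), components below size 2 reported as singletons,
library hits at score > 0.7 with ≥ 6 matched peaks.

## Synthetic data

The generators produce every input with known ground truth under a
fixed seed (same spec + seed → byte-identical files):

* **Genomes** — one contig with ~20 background genes around a planted
  cluster: the four core incorporation genes, the type-specific genes,
  six PKS genes whose translations are rendered from the architecture
  templates, GT/CYP genes and an optional γ-butyrolactone regulatory
  gene (flagged, never modelled). Decoy variants plant only the core
  set or only the type set. Planted proteins are motif-bearing random
  sequences: catalytic fingerprints at controlled positions, linkers
  drawn from an alphabet (no C/D/G/H/P/S/W) that cannot spell any
  scanner motif, so domain calls on fixtures are exact by construction.
* **Hit tables** — one row per planted homolog with identity uniform in
  a configurable range (default 60–90%, comfortably above the 50%
  floor), plus optional low-identity spurious rows as negative
  controls. Identities are simulated directly, so mining tests measure
  the windowing logic, not alignment quality.
* **Spectra** — congener series sharing a fragment ladder (12 fragments
  by default, uniform over [120 Da, precursor − 60 Da]); peaks above a
  random split point shift with the congener's mass offset, mimicking a
  modification on one side of the molecule. Noise peaks are uniform in
  m/z over [50, precursor] with log-normal intensities (σ = 1).

What the generators do **not** emulate: codon usage and GC content
(placeholder nucleotide sequence), real homolog sequence divergence,
fragmentation chemistry, isotope patterns, multiply charged species and
retention behaviour. Passing the planted-recovery and network-recall
tests therefore demonstrates the correctness of the windowing, grammar
and scoring logic under the stated noise model — not detection
performance on real genomes or real LC-MS/MS runs.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated
data: contigs of ≤ ~40 genes, 50 seeded genomes for the
recovery/rejection benchmark, 20 seeded congener triples for network
recall, spectra of ≤ ~40 peaks, and exhaustive oracles (window
enumeration, optimal peak assignment) restricted to sizes where
enumeration is exact and fast. These sizes exercise every code path of
the method; the algorithms are linear-to-quadratic in genes and peaks,
so nothing changes structurally at genome scale.

Degenerate inputs are defined rather than left to chance: empty
spectra score (0, 0); a zero Δm/z annotates as nothing; curation never
raises; `classify_kr` falls back to `unassigned`; a cluster whose
modules are all non-functional refuses to predict a core; 3-Afa
starters require an explicit alkyl-chain length, which is not
predictable from the BGC.

## Known limitations

* trans-AT and NRPS-hybrid assembly lines are out of scope; the module
  grammar assumes cis-AT colinearity.
* Double-bond geometry, 3D conformation and NMR-level stereochemistry
  are not predicted.
* The motif scanner is not an HMM; on real proteins external domain
  annotation should be supplied through the exchange table.
* The per-module β-state patterns of the worked templates are
  mass-constrained reconstructions (see above), so position-level
  states for real clusters should be taken as proposals.
* Taxonomic abundance tabulation requires a caller-supplied
  contig-to-taxon map; no taxonomy is inferred.
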