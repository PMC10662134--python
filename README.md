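# lactamine

Targeted discovery of **β-amino-acid macrolactam** natural products from
genomes and metabolomes: detect and type macrolactam biosynthetic gene
clusters (BGCs) from annotated genome records and homology hits, predict
the encoded macrolactam core structure from the PKS module architecture,
and connect those predictions to MS/MS data by monoisotopic-mass
arithmetic, Δm/z transformation annotation and modified-cosine molecular
networking.

It is written for natural-product genome miners and metabolomics people
who work on polyketide macrolactams (vicenistatin, ciromicins,
macrotermycins, fluvirucins, hitachimycin, heronamides, …) and want the
genome-to-metabolome chain of reasoning as reproducible code instead of
a manual protocol.

## The model

**Cluster detection.** Macrolactam BGCs share a starter-unit
incorporation machinery: a VinN-type adenylation enzyme, a standalone
VinL-type ACP, a VinM-type aminoacylating adenylation enzyme and a
VinK-type standalone acyltransferase, plus starter-specific biosynthesis
enzymes that discriminate the five starter types — 3-Amp (glutamate
mutase VinH/VinI + decarboxylase VinO), 3-Aba (IdnL4/IdnL3), 3-Afa
(CmiS1/CmiS2), β-Phe (HitA) and β-Ala (VinO without the mutase). Genes
bearing hits to one panel are chained while consecutive hit genes are
≤ *g* = 80 000 bp apart; a chain is a candidate cluster when it covers at
least *N* − 2 distinct queries (*N* − 4 for β-Ala), with intermediate
genes within 70 000 bp folded into the window. Deterministic curation
collapses duplicate windows, requires a PKS assembly line in proximity
and resolves windows claimed by several panels (mutase present → 3-Amp;
decarboxylase without mutase → β-Ala).

**Structure prediction.** Type-I PKS colinearity: one module per ACP,
an extension module is functional iff KS, AT and ACP are present and it
is not a stalled dehydration position (no KR with a DH whose His/Asp
catalytic triad is incomplete). With *m* functional extension modules
and any β-amino-acid starter the macrolactam ring closes over

```
ring atoms = 2·m + 4        (N + 3 starter carbons + 2 carbons per module)
```

so 8 → 20-membered (macrotermycin-type), 9 → 22-membered
(ciromicin-type), 11 → 26-membered (bombyxamycin-like). Each module's
reductive loop sets its β-carbon state — ketone (no KR), hydroxyl (KR;
*S* for an A-type KR by the Trp fingerprint, *R* for B-type by the LDD
fingerprint), enoyl (KR + active DH) or methylene (KR + DH + ER) — and
methylmalonyl-specific ATs (YASH motif) add methyl branches. Carbons
are numbered from the lactam carbonyl; module *i* controls
C-(2(m−i)+3), which places the A-type KR of module 6 at C-7 of a
20-ring and C-9 of a 22-ring, where the (*S*)-hydroxyl and the
xylosamine sugar of the isolated compounds sit.

**Metabolome linking.** Aglycone formulas come from additive ketide
bookkeeping; [M+H]⁺ values from an embedded monoisotopic mass table.
Candidate tailoring (glycosylation bounded by GT gene counts, oxidation
by CYP counts) is enumerated and matched to MS feature masses by ppm;
precursor Δm/z values between networked spectra are annotated as
chemical transformations (+O oxidation, +C₂H₂ ketide double-bond
difference, +C₅H₉NO₃ xylosaminylation, …). Networking uses the modified
cosine (sqrt intensities, L2 normalisation, direct or precursor-shifted
peak matching, greedy one-to-one assignment).

## Worked example

Predict the core encoded by the ciromicin-type (*pac*) assembly line and
link it to the two observed metabolite features:

```python
from lactamine.architectures import template_modules
from lactamine import StarterUnit, predict_core, emit_smiles, link_genome_to_nodes

modules = template_modules("pac")          # 10 extension modules on 6 genes
core = predict_core(modules, StarterUnit("3-Amp"),
                    {"glycosylation": 2, "oxidation": 1})
print(core.ring_size, core.aglycone_formula.hill(), core.positions["C-9"])
print(emit_smiles(core))
for m in link_genome_to_nodes(core, [(499.281, "node_499"), (515.276, "node_515")]):
    print(m["node_id"], m["formula"], list(m["modifications"]),
          round(m["predicted_mz"], 4), f"{m['ppm_error']:+.1f} ppm")
```

prints

```
22 C23H29NO3 hydroxyl_S
O=C1C=CC=CC=CC[C@H](O)C=CC=CC=CC(C)=CCC(=O)C(C)CN1
node_499 C28H38N2O6 ['xylosaminyl'] 499.2808 +0.4 ppm
node_515 C28H38N2O7 ['xylosaminyl', 'O'] 515.2757 +0.5 ppm
```

Module 10 of the *pac* line lacks its KR and carries a degenerate DH
triad, so only nine extensions count and a 22-membered ring is
predicted; its aglycone C₂₃H₂₉NO₃ plus one xylosaminyl residue matches
the *m/z* 499.281 feature (the deglyco-oxidised precursor), and one
further oxidation matches the *m/z* 515.276 feature (ciromicin A) —
both within 1 ppm. The polyene stretch also raises the
`spontaneous_cyclization_prone` flag (light/heat/acid-induced 2+4
cycloaddition).

The same stages are available from a shell:

```bash
lactamine simulate genome --architecture mte --seed 42 --out sim/
lactamine mine --genome sim/genome.gbk --hits sim/hits.tsv --out clusters.tsv
lactamine modules --genome sim/genome.gbk --out modules.tsv
lactamine predict --modules modules.tsv --genome sim/genome.gbk \
    --starter amp --gt 3 --cyp 2 --smiles --out core.json
lactamine run --architecture pac --seed 7 --out run_out/   # end to end
```

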