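"""Synthetic genomes, hit tables and MS/MS spectra with known truth.

Everything the pipeline consumes can be fabricated here under a fixed
seed: actinobacterial-style contigs with planted macrolactam BGCs (or
decoys), matching homology-hit tables with controlled identities, and
congener MS/MS spectra built from shared fragment ladders plus noise.

Planted protein sequences are motif-bearing random sequences, not real
homologs: catalytic-site fingerprints are inserted at controlled
positions and all filler residues are drawn from an alphabet that cannot
spell any scanner motif, so domain calls on fixtures are exact. Hit
identities are simulated directly in the hit table, decoupling mining
tests from alignment quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architectures import ARCHITECTURES, domain_sequence, template_domain_specs
from .io_formats import GeneFeature, HitRecord, SpectrumRecord, write_genbank, write_hit_table
from .mass_annotation import (
    DEFAULT_TRANSFORMATIONS,
    MolecularFormula,
    adduct_mz,
    annotate_delta,
)

__all__ = [
    "PlantSpec",
    "GenomeTruth",
    "gen_genome",
    "gen_hit_table",
    "gen_spectra",
    "render_protein",
]

#: Filler alphabet for linkers/background proteins: no C/D/G/H/P/S/W, so
#: no scanner motif or KR/DH fingerprint can arise by chance.
_SAFE_ALPHABET = np.array(list("AEFIKLMNQRTVY"))

_BACKGROUND_PRODUCTS = [
    "hypothetical protein",
    "ABC transporter permease",
    "MFS transporter",
    "TetR family transcriptional regulator",
    "two-component sensor kinase",
    "aldo/keto reductase",
    "ribosomal protein",
    "DNA polymerase III subunit",
    "aminotransferase",
    "acyl-CoA dehydrogenase",
]

#: Planted homolog genes per starter type: (query name, product text).
_CORE_GENES = [
    ("VinN", "starter unit adenylation enzyme"),
    ("VinL", "standalone acyl carrier protein"),
    ("VinM", "aminoacylating adenylation enzyme"),
    ("VinK", "standalone acyltransferase"),
]
_TYPE_GENES = {
    "3-Amp": [
        ("VinH", "glutamate mutase subunit E"),
        ("VinI", "glutamate mutase subunit S"),
        ("VinO", "glutamate decarboxylase"),
    ],
    "3-Aba": [
        ("IdnL4", "glutamate-2,3-aminomutase"),
        ("IdnL3", "amino acid decarboxylase"),
    ],
    "3-Afa": [
        ("CmiS1", "thioesterase"),
        ("CmiS2", "FAD-dependent oxidase"),
    ],
    "beta-Phe": [("HitA", "phenylalanine-2,3-aminomutase")],
    "beta-Ala": [("VinO", "glutamate decarboxylase")],
}


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic contig.

    ``architecture`` is a key of :data:`ARCHITECTURES` (or None for a
    decoy); ``decoy`` is ``"core_only"`` / ``"type_only"`` / None.
    """

    seed: int
    architecture: str | None = "mte"
    starter_type: str = "3-Amp"
    decoy: str | None = None
    n_background: int = 20
    contig_id: str = "synthetic_contig_1"
    identity_range: tuple[float, float] = (60.0, 90.0)
    with_gamma_bl: bool = False


@dataclass
class GenomeTruth:
    """Ground truth emitted beside every generated genome."""

    contig_id: str
    starter_type: str | None
    architecture: str | None
    cluster_loci: list[str] = field(default_factory=list)
    query_to_locus: dict[str, str] = field(default_factory=dict)
    pks_loci: list[str] = field(default_factory=list)
    n_modules: int = 0
    n_functional_modules: int = 0
    window_start: int = 0
    window_end: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_SAFE_ALPHABET, size=length))


def render_protein(
    module_specs: list[list[tuple[str, dict]]], rng: np.random.Generator
) -> str:
    """Concatenate domain fingerprint sequences with inert linkers."""
    parts = [_random_protein(rng, int(rng.integers(10, 25)))]
    for spec in module_specs:
        for kind, props in spec:
            parts.append(domain_sequence(kind, props))
            parts.append(_random_protein(rng, int(rng.integers(12, 25))))
    return "".join(parts)


def _split_modules_over_genes(
    specs: list[list[tuple[str, dict]]], n_genes: int
) -> list[list[list[tuple[str, dict]]]]:
    base = len(specs) // n_genes
    split = [len(specs) - base * (n_genes - 1)] + [base] * (n_genes - 1)
    out, idx = [], 0
    for take in split:
        out.append(specs[idx: idx + take])
        idx += take
    return out


def gen_genome(
    spec: PlantSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, list[GeneFeature]], GenomeTruth]:
    """Generate one contig with a planted cluster (or decoy) plus truth.

    Same spec + seed gives byte-identical output. When ``out_dir`` is
    given, writes ``genome.gbk`` and ``truth.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[GeneFeature] = []
    truth = GenomeTruth(
        contig_id=spec.contig_id,
        starter_type=None if spec.decoy else spec.starter_type,
        architecture=None if spec.decoy else spec.architecture,
    )

    pos = 200
    counter = 0

    def add_gene(product: str, translation: str, tag_prefix: str = "BG") -> GeneFeature:
        nonlocal pos, counter
        counter += 1
        length = 3 * len(translation) + 3
        strand = "+" if rng.random() < 0.7 else "-"
        g = GeneFeature(
            contig_id=spec.contig_id,
            locus_tag=f"{tag_prefix}_{counter:04d}",
            start=pos,
            end=pos + length,
            strand=strand,
            product=product,
            translation=translation,
        )
        genes.append(g)
        pos += length + int(rng.integers(50, 400))
        return g

    n_before = spec.n_background // 2
    for _ in range(n_before):
        add_gene(
            str(rng.choice(_BACKGROUND_PRODUCTS)),
            _random_protein(rng, int(rng.integers(150, 450))),
        )

    cluster_loci: list[str] = []
    if spec.decoy != "none_at_all":
        plant_core = spec.decoy in (None, "core_only")
        plant_type = spec.decoy in (None, "type_only")
        plant_pks = spec.decoy is None

        if plant_core:
            for query, product in _CORE_GENES:
                g = add_gene(product, _random_protein(rng, int(rng.integers(200, 400))), "MLC")
                truth.query_to_locus[query] = g.locus_tag
                cluster_loci.append(g.locus_tag)
        if plant_type:
            for query, product in _TYPE_GENES[spec.starter_type]:
                g = add_gene(product, _random_protein(rng, int(rng.integers(200, 400))), "MLC")
                truth.query_to_locus[query] = g.locus_tag
                cluster_loci.append(g.locus_tag)
        if plant_pks:
            arch_name = spec.architecture or "mte"
            arch = ARCHITECTURES[arch_name]
            specs = template_domain_specs(arch_name)
            truth.n_modules = sum(1 for s in specs if {k for k, _ in s} != {"AT", "ACP"})
            per_gene = _split_modules_over_genes(specs, arch["n_pks_genes"])
            for gi, gene_specs in enumerate(per_gene, start=1):
                protein = render_protein(gene_specs, rng)
                g = add_gene("modular type I polyketide synthase", protein, "PKS")
                truth.pks_loci.append(g.locus_tag)
                cluster_loci.append(g.locus_tag)
                if gi == 1:
                    truth.query_to_locus["IdnP1"] = g.locus_tag
            for _ in range(arch["tailoring"].get("glycosylation", 0)):
                g = add_gene("glycosyltransferase", _random_protein(rng, 300), "MLC")
                cluster_loci.append(g.locus_tag)
            for _ in range(arch["tailoring"].get("oxidation", 0)):
                g = add_gene("cytochrome P450 monooxygenase", _random_protein(rng, 320), "MLC")
                cluster_loci.append(g.locus_tag)
            if spec.with_gamma_bl:
                g = add_gene("gamma-butyrolactone synthase AfsA-like", _random_protein(rng, 250), "MLC")
                cluster_loci.append(g.locus_tag)
            # planted functional module count from the template's defects
            n_func = 0
            for s in specs:
                kinds = [k for k, _ in s]
                if set(kinds) == {"AT", "ACP"}:
                    continue
                dh_active = any(k == "DH" and p.get("active", True) for k, p in s)
                has_dh = any(k == "DH" for k, _ in s)
                has_kr = any(k == "KR" for k, _ in s)
                ok = {"KS", "AT", "ACP"} <= set(kinds) and not (
                    not has_kr and has_dh and not dh_active
                )
                n_func += int(ok)
            truth.n_functional_modules = n_func

    for _ in range(spec.n_background - n_before):
        add_gene(
            str(rng.choice(_BACKGROUND_PRODUCTS)),
            _random_protein(rng, int(rng.integers(150, 450))),
        )

    truth.cluster_loci = cluster_loci
    if cluster_loci:
        by_tag = {g.locus_tag: g for g in genes}
        truth.window_start = min(by_tag[t].start for t in cluster_loci)
        truth.window_end = max(by_tag[t].end for t in cluster_loci)

    genome = {spec.contig_id: genes}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genbank(genome, out_dir / "genome.gbk")
        (out_dir / "truth.json").write_text(truth.to_json() + "\n")
    return genome, truth


def gen_hit_table(
    truth: GenomeTruth,
    identity_range: tuple[float, float] = (60.0, 90.0),
    seed: int = 0,
    n_spurious: int = 0,
    spurious_loci: list[str] | None = None,
    out_path: str | Path | None = None,
) -> list[HitRecord]:
    """Fabricate the homology-hit table for a generated genome.

    One hit per planted homolog with identity uniform in
    ``identity_range``; optional spurious low-identity hits against the
    supplied loci serve as negative controls.
    """
    rng = np.random.default_rng(seed)
    hits: list[HitRecord] = []
    for query, locus in sorted(truth.query_to_locus.items()):
        ident = float(rng.uniform(*identity_range))
        aln = int(rng.integers(250, 450))
        hits.append(
            HitRecord(
                query_id=query,
                subject_locus=locus,
                percent_identity=round(ident, 1),
                alignment_length=aln,
                bitlike_score=round(ident * aln / 100.0, 1),
                evalue=1e-50,
                below_identity_floor=ident < 50.0,
            )
        )
    for i in range(n_spurious):
        if not spurious_loci:
            break
        locus = spurious_loci[i % len(spurious_loci)]
        ident = float(rng.uniform(20.0, 34.0))
        hits.append(
            HitRecord(
                query_id="IdnP1",
                subject_locus=locus,
                percent_identity=round(ident, 1),
                alignment_length=120,
                bitlike_score=round(ident, 1),
                evalue=0.5,
                below_identity_floor=True,
            )
        )
    if out_path is not None:
        write_hit_table(hits, out_path)
    return hits


def gen_spectra(
    structures: list[tuple[str, MolecularFormula]],
    n_noise: int = 6,
    sigma_mz: float = 0.0,
    noise_intensity_sigma: float = 1.0,
    n_fragments: int = 12,
    seed: int = 0,
) -> tuple[list[SpectrumRecord], list[dict]]:
    """Congener MS/MS spectra from a shared fragment ladder + noise.

    Congeners share a fragment ladder below a random split point; ladder
    peaks above the split are shifted by the congener's mass offset from
    the first (base) structure, mimicking a modification on one side of
    the molecule. Noise peaks are uniform in m/z over [50, precursor]
    with log-normal intensities. Returns the spectra and the truth list
    of intended network edges with their Δm/z annotations.
    """
    if not structures:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(seed)
    precursors = [(name, adduct_mz(f, "[M+H]+")) for name, f in structures]
    base_mz = precursors[0][1]
    ladder = np.sort(rng.uniform(120.0, base_mz - 60.0, size=n_fragments))
    intensities = rng.uniform(20.0, 100.0, size=n_fragments)
    split = float(rng.uniform(np.quantile(ladder, 0.3), np.quantile(ladder, 0.7)))

    spectra: list[SpectrumRecord] = []
    for name, mz in precursors:
        delta = mz - base_mz
        peaks = []
        for frag, inten in zip(ladder, intensities):
            frag_mz = frag + (delta if frag > split else 0.0)
            if sigma_mz > 0:
                frag_mz += float(rng.normal(0.0, sigma_mz))
            peaks.append((float(frag_mz), float(inten)))
        for _ in range(n_noise):
            peaks.append(
                (
                    float(rng.uniform(50.0, mz)),
                    float(rng.lognormal(0.0, noise_intensity_sigma)),
                )
            )
        spectra.append(
            SpectrumRecord(spectrum_id=name, precursor_mz=float(mz), charge=1, peaks=peaks)
        )

    edges = []
    for i, (name_a, mz_a) in enumerate(precursors):
        for name_b, mz_b in precursors[i + 1:]:
            edges.append(
                {
                    "a": name_a,
                    "b": name_b,
                    "delta_mz": abs(mz_a - mz_b),
                    "annotations": annotate_delta(mz_a, mz_b, DEFAULT_TRANSFORMATIONS, tol=0.01),
                }
            )
    return spectra, edges
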