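"""Worked assembly-line templates for the known macrolactam clusters.

Each template is a symbolic description of the module/domain layout of a
characterised cluster family:

* ``mte`` — macrotermycin-type: six PKS genes, ten extension modules, of
  which modules 9 (missing its KS) and 10 (no KR, degenerate DH triad)
  are non-functional → eight functional extensions, 20-membered ring.
* ``pac`` — ciromicin-type (pac/asa/cir): same layout but module 9 is
  intact; only module 10 is non-functional → nine functional extensions,
  22-membered ring.
* ``bom`` — bombyxamycin-like (A. xylanica): eleven functional extension
  modules, 26-membered ring.

The per-module β-state pattern (a ketide ketone from the KR-less first
module, an (S)-hydroxyl from the A-type KR of module 6, enoyl positions
elsewhere, one methylmalonyl branch) reproduces the measured congener
masses of the macrotermycin/ciromicin families, including their C2H2
relationship; see docs/methods.md for the reconstruction rationale.
"""

from __future__ import annotations

from .io_formats import GeneFeature
from .pks_architecture import DomainAnnotation, PKSModule, parse_modules

__all__ = [
    "ARCHITECTURES",
    "template_modules",
    "template_domain_specs",
    "module_spec",
    "modules_from_specs",
]

# symbolic domain spec: (kind, properties)
_LOADING = [("AT", {}), ("ACP", {})]


def module_spec(
    kr: str | None,
    dh: str | None = None,
    er: bool = False,
    at: str = "malonyl",
    omit: tuple[str, ...] = (),
) -> list[tuple[str, dict]]:
    """Build one extension module's symbolic domain list.

    ``kr`` is the KR class (``"A"``/``"B"``/``"u"`` for unassigned) or
    None for no KR; ``dh`` is ``"active"``/``"degenerate"`` or None;
    ``omit`` drops core domains to plant defects.
    """
    spec: list[tuple[str, dict]] = []
    if "KS" not in omit:
        spec.append(("KS", {}))
    if "AT" not in omit:
        spec.append(("AT", {"substrate": at}))
    if dh is not None:
        spec.append(("DH", {"active": dh == "active"}))
    if er:
        spec.append(("ER", {}))
    if kr is not None:
        spec.append(("KR", {"class": kr}))
    if "ACP" not in omit:
        spec.append(("ACP", {}))
    return spec


def _common_head() -> list[list[tuple[str, dict]]]:
    """Modules 1–8 shared by the mte and pac templates."""
    return [
        module_spec(kr=None),                                   # M1: ketone position
        module_spec(kr="u", dh="active", at="methylmalonyl"),   # M2: enoyl + Me branch
        module_spec(kr="u", dh="active"),                       # M3: enoyl
        module_spec(kr="B", dh="active"),                       # M4: enoyl
        module_spec(kr="u", dh="active"),                       # M5: enoyl
        module_spec(kr="A"),                                    # M6: (S)-hydroxyl
        module_spec(kr="B", dh="active"),                       # M7: enoyl
        module_spec(kr="B", dh="active"),                       # M8: enoyl
    ]


def _mte_template() -> list[list[tuple[str, dict]]]:
    return (
        [_LOADING]
        + _common_head()
        + [
            module_spec(kr="B", dh="active", omit=("KS",)),     # M9: KS missing
            module_spec(kr=None, dh="degenerate"),              # M10: no KR, dead DH
        ]
    )


def _pac_template() -> list[list[tuple[str, dict]]]:
    return (
        [_LOADING]
        + _common_head()
        + [
            module_spec(kr="B", dh="active"),                   # M9: functional enoyl
            module_spec(kr=None, dh="degenerate"),              # M10: no KR, dead DH
        ]
    )


def _bom_template() -> list[list[tuple[str, dict]]]:
    head = _common_head()
    return [_LOADING] + head + [
        module_spec(kr="B", dh="active"),                       # M9
        module_spec(kr="B", dh="active"),                       # M10
        module_spec(kr="B", dh="active", er=True),              # M11: fully reduced
    ]


ARCHITECTURES: dict[str, dict] = {
    "mte": {
        "template": _mte_template,
        "starter_type": "3-Amp",
        "n_pks_genes": 6,
        "tailoring": {"glycosylation": 3, "oxidation": 2},
    },
    "pac": {
        "template": _pac_template,
        "starter_type": "3-Amp",
        "n_pks_genes": 6,
        "tailoring": {"glycosylation": 2, "oxidation": 1},
    },
    "bom": {
        "template": _bom_template,
        "starter_type": "3-Amp",
        "n_pks_genes": 6,
        "tailoring": {"glycosylation": 0, "oxidation": 0},
    },
}

# Fixture fingerprint sequences; each trips exactly the motifs of its
# own domain kind and nothing else.
_DH_ACTIVE_SEQ = "AFLMHLLTGSVDRPAAMKLRENMAFKDAAFQMLRAE"
# His motif intact so the scanner still sees a DH, but the downstream Asp
# of the catalytic triad is lost:
_DH_DEAD_SEQ = "AFLMHLLTGSVDRPAAMKLRENMAFKEAAFQMLRAE"
_KR_ROSSMANN = "AMKVALVTGGTGGLG"
_KR_SEQS = {
    "A": _KR_ROSSMANN + "AEVARNLAQEGARNLVLTSRRGEAHQAWEELRALGAEVTVRAVNVTNRAAVEALV",
    "B": _KR_ROSSMANN + "AEVARNLAQEGARNLVLTSRRGEAHQALDDLRALGAEVTVRAVNVTNRAAVEALV",
    "u": _KR_ROSSMANN + "AEVARNLAQEGARNLVLTSRRGEAHQAVEELRALGAEVTVRAVNVTNRAAVEALV",
}
_KIND_SEQ = {
    "KS": "EAMNMNTACSSALVAVELAVKELRE",
    "ACP": "FNELGVDSLMAVELRNELEAEF",
    "ER": "ALVAGGVGMAAVMLAEKLNAKVFATA",
    "TE": "RLFAFGYSAGAMLAYELAKRLEE",
    "MT": "VLEIGCGTGATLMRVAEAFE",
}
_AT_SEQ = {
    "malonyl": "KVFMFTGQGAQMAGHSMGEHAFHLYETERAVFE",
    "methylmalonyl": "KVFMFTGQGAQMAGHSQGEYASHVETERAVFE",
}


def domain_sequence(kind: str, props: dict) -> str:
    """A synthetic amino-acid sequence carrying the motif(s) for one domain."""
    if kind == "DH":
        return _DH_ACTIVE_SEQ if props.get("active", True) else _DH_DEAD_SEQ
    if kind == "KR":
        return _KR_SEQS[props.get("class", "u")]
    if kind == "AT":
        base = _AT_SEQ.get(props.get("substrate", "malonyl"), _AT_SEQ["malonyl"])
        return base
    return _KIND_SEQ[kind]


def template_domain_specs(name: str) -> list[list[tuple[str, dict]]]:
    """The symbolic module list (loading first) for a named architecture."""
    if name not in ARCHITECTURES:
        raise KeyError(f"unknown architecture {name!r}; choose from {sorted(ARCHITECTURES)}")
    return ARCHITECTURES[name]["template"]()


def _annotations_for(spec: list[tuple[str, dict]], offset: int = 0) -> list[DomainAnnotation]:
    domains = []
    pos = offset
    for kind, props in spec:
        seq = domain_sequence(kind, props)
        dom = DomainAnnotation(
            kind=kind, aa_start=pos, aa_end=pos + len(seq), sequence=seq
        )
        if kind == "DH":
            dom.motif_flags["DH_triad_complete"] = bool(props.get("active", True))
        elif kind == "KR":
            cls = props.get("class", "u")
            dom.motif_flags["KR_fingerprint"] = {
                "A": "W_present", "B": "LDD_present"
            }.get(cls, "none")
        elif kind == "AT":
            dom.at_substrate = props.get("substrate", "malonyl")
        domains.append(dom)
        pos += len(seq) + 15
    return domains


def modules_from_specs(
    specs: list[list[tuple[str, dict]]],
    locus: str = "PKS1",
    contig_id: str = "synthetic",
) -> list[PKSModule]:
    """Build parsed modules from symbolic domain specs on a single gene."""
    domains: list[DomainAnnotation] = []
    offset = 0
    for spec in specs:
        mod_domains = _annotations_for(spec, offset)
        domains.extend(mod_domains)
        offset = (mod_domains[-1].aa_end + 40) if mod_domains else offset
    length = max((d.aa_end for d in domains), default=100) * 3 + 3
    gene = GeneFeature(
        contig_id=contig_id, locus_tag=locus, start=100, end=100 + length,
        strand="+", product="modular type I polyketide synthase",
    )
    return parse_modules([(gene, domains)])


def template_modules(name: str) -> list[PKSModule]:
    """Parsed, functionality-assessed modules for a named architecture.

    Modules are distributed over the template's PKS genes in assembly-line
    order (the mte/pac layout: 2+2+2+1+1+2 modules per gene, loading on
    the first gene).
    """
    arch = ARCHITECTURES[name]
    specs = template_domain_specs(name)
    n_genes = arch["n_pks_genes"]
    per_gene: list[list[list[tuple[str, dict]]]] = [[] for _ in range(n_genes)]
    # loading module rides on gene 1; remaining modules round-robin in blocks
    split = [len(specs) - (len(specs) // n_genes) * (n_genes - 1)] + [
        len(specs) // n_genes
    ] * (n_genes - 1)
    idx = 0
    for gi, take in enumerate(split):
        for _ in range(take):
            per_gene[gi].append(specs[idx])
            idx += 1

    genes: list[tuple[GeneFeature, list[DomainAnnotation]]] = []
    start = 100
    for gi, gene_specs in enumerate(per_gene, start=1):
        domains: list[DomainAnnotation] = []
        offset = 0
        for spec in gene_specs:
            mod_domains = _annotations_for(spec, offset)
            domains.extend(mod_domains)
            offset = (mod_domains[-1].aa_end + 40) if mod_domains else offset
        length = max((d.aa_end for d in domains), default=100) * 3 + 3
        gene = GeneFeature(
            contig_id=f"{name}_contig",
            locus_tag=f"{name}P{gi}",
            start=start,
            end=start + length,
            strand="+",
            product="modular type I polyketide synthase",
        )
        genes.append((gene, domains))
        start += length + 200
    return parse_modules(genes)
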