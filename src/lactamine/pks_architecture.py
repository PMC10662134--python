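"""Type-I PKS module parsing, functionality calls and KR stereotyping.

A modular PKS gene is an ordered run of catalytic domains; one module per
acyl-carrier protein (ACP). Extension modules minimally need KS, AT and
ACP; reductive loop domains (KR, DH, ER) set the oxidation state of the
β-carbon handled by that module. Ketoreductases are classified into the
A/B stereospecificity classes by the published sequence fingerprints: the
LDD motif in the catalytic region marks a B-type KR (→ R-configured
β-hydroxyl), a conserved tryptophan without LDD marks an A-type KR (→ S);
anything else stays unassigned rather than guessed. Dehydratase activity
requires a complete catalytic His/Asp triad (His of the HxxxGxxxxP motif
plus the downstream Asp of DxxxQ/H).

Domain annotation may be supplied externally (exchange TSV) or produced
by the built-in motif scanner, which is regex-based and intended for
fixture-grade annotation, not for HMM-quality discovery.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import GeneFeature

__all__ = [
    "DomainAnnotation",
    "PKSModule",
    "DOMAIN_KINDS",
    "scan_domains",
    "parse_modules",
    "check_dh_triad",
    "classify_kr",
    "classify_at_substrate",
    "assess_functionality",
    "beta_state",
    "read_domain_table",
    "write_domain_table",
]

DOMAIN_KINDS = ("KS", "AT", "DH", "ER", "KR", "ACP", "TE", "MT")

# Motif regexes used by the fixture-grade scanner. Each targets the
# canonical active-site neighbourhood of its domain.
_DOMAIN_MOTIFS: dict[str, str] = {
    "KS": r"TACSS",          # KS active-site Cys neighbourhood
    "AT": r"GHS[QLMA]G",     # AT GHSxG serine motif
    "DH": r"H.{3}G.{4}P",    # DH catalytic His motif
    "ER": r"GGVG[ML]A",      # ER NADPH site
    "KR": r"G.[GS]..G",      # Rossmann GxGxxG
    "ACP": r"G[LIV]DS[LI]",  # phosphopantetheine Ser motif
    "TE": r"GYS.G",          # TE lipase-like Ser motif
    "MT": r"GCG[TI]G",       # SAM-binding site
}

_DH_HIS_MOTIF = re.compile(r"H.{3}G.{4}P")
_DH_ASP_MOTIF = re.compile(r"D.{3}[QH]")
_KR_NADPH_MOTIF = re.compile(r"G.[GS]..G")
#: Width of the catalytic-region window searched downstream of the
#: NADPH-binding motif for the stereospecificity fingerprints.
KR_FINGERPRINT_WINDOW = 50

_AT_METHYLMALONYL = re.compile(r"YASH")
_AT_MALONYL = re.compile(r"HAFH")

BETA_STATES = ("ketone", "hydroxyl_S", "hydroxyl_R", "hydroxyl", "enoyl", "methylene", "none")


@dataclass
class DomainAnnotation:
    kind: str
    aa_start: int
    aa_end: int
    sequence: str = ""
    motif_flags: dict = field(default_factory=dict)
    at_substrate: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not self.aa_start < self.aa_end:
            raise ValueError(f"{self.kind}: need aa_start < aa_end")


@dataclass
class PKSModule:
    """One PKS module: an ordered domain list ending at its ACP."""

    index: int
    gene_locus: str
    domains: list[DomainAnnotation]
    is_loading: bool = False
    functional: bool | None = None
    kr_class: str = "absent"
    beta: str = "none"

    @property
    def domain_kinds(self) -> list[str]:
        return [d.kind for d in self.domains]

    def has(self, kind: str) -> bool:
        return kind in self.domain_kinds

    def domain(self, kind: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None


def check_dh_triad(dh_sequence: str) -> bool:
    """True iff the DH catalytic triad is complete.

    Requires the His of the HxxxGxxxxP motif and, downstream of it, the
    Asp of the DxxxQ/H motif. Sequences shorter than the motif span are
    incomplete by definition.
    """
    if not dh_sequence:
        return False
    his = _DH_HIS_MOTIF.search(dh_sequence)
    if his is None:
        return False
    return _DH_ASP_MOTIF.search(dh_sequence, his.end()) is not None


def classify_kr(kr_sequence: str) -> str:
    """KR stereospecificity class from sequence fingerprints.

    Searches the 50-aa window downstream of the NADPH-binding GxGxxG
    motif: LDD present → ``"B"``; the conserved Trp present without LDD →
    ``"A"``; neither, both, or no Rossmann motif → ``"unassigned"``.
    """
    if not kr_sequence:
        return "unassigned"
    m = _KR_NADPH_MOTIF.search(kr_sequence)
    if m is None:
        return "unassigned"
    window = kr_sequence[m.end(): m.end() + KR_FINGERPRINT_WINDOW]
    has_ldd = "LDD" in window
    has_trp = "W" in window
    if has_ldd and has_trp:
        warnings.warn("KR carries both the LDD and Trp fingerprints; left unassigned")
        return "unassigned"
    if has_ldd:
        return "B"
    if has_trp:
        return "A"
    return "unassigned"


def classify_at_substrate(at_sequence: str) -> str:
    """Malonyl vs methylmalonyl specificity from the YASH/HAFH motif table."""
    if _AT_METHYLMALONYL.search(at_sequence):
        return "methylmalonyl"
    if _AT_MALONYL.search(at_sequence):
        return "malonyl"
    return "unknown"


def scan_domains(protein: str) -> list[DomainAnnotation]:
    """Locate PKS domains in a protein by active-site motif matching.

    Motif hits are collected across all domain kinds, sorted by position
    and deduplicated (first match wins on overlap). Each annotation's
    span runs from its motif to the next motif (or sequence end), so
    downstream motif checks see the right subsequence.
    """
    found: list[tuple[int, str]] = []
    for kind, pattern in _DOMAIN_MOTIFS.items():
        for m in re.finditer(pattern, protein):
            found.append((m.start(), kind))
    found.sort()
    # drop overlapping calls at (almost) the same site
    pruned: list[tuple[int, str]] = []
    for pos, kind in found:
        if pruned and pos - pruned[-1][0] < 6:
            continue
        pruned.append((pos, kind))

    domains: list[DomainAnnotation] = []
    for i, (pos, kind) in enumerate(pruned):
        start = max(0, pos - 10)
        end = pruned[i + 1][0] - 10 if i + 1 < len(pruned) else len(protein)
        end = max(end, start + 1)
        seq = protein[start:end]
        dom = DomainAnnotation(kind=kind, aa_start=start, aa_end=end, sequence=seq)
        if kind == "DH":
            dom.motif_flags["DH_triad_complete"] = check_dh_triad(seq)
        elif kind == "KR":
            cls = classify_kr(seq)
            dom.motif_flags["KR_fingerprint"] = {
                "A": "W_present", "B": "LDD_present"
            }.get(cls, "none")
        elif kind == "AT":
            dom.at_substrate = classify_at_substrate(seq)
        domains.append(dom)
    return domains


def parse_modules(
    pks_genes: list[tuple[GeneFeature, list[DomainAnnotation]]],
) -> list[PKSModule]:
    """Split ordered PKS genes into modules at each ACP.

    ``pks_genes`` must already be in assembly-line order (which can differ
    from genomic coordinate order). A leading AT/ACP-only unit is the
    loading module; module indices are consecutive across genes, loading
    excluded. Trailing ACP-less domains attach to the previous module with
    a warning; genes with no recognisable domains are skipped.
    """
    modules: list[PKSModule] = []
    next_index = 1
    for gene, domains in pks_genes:
        if not domains:
            warnings.warn(f"{gene.locus_tag}: no recognisable PKS domains; gene skipped")
            continue
        current: list[DomainAnnotation] = []
        for dom in sorted(domains, key=lambda d: d.aa_start):
            current.append(dom)
            if dom.kind == "ACP":
                kinds = {d.kind for d in current}
                is_loading = (
                    not modules
                    and next_index == 1
                    and "KS" not in kinds
                    and kinds <= {"AT", "ACP"}
                )
                mod = PKSModule(
                    index=0 if is_loading else next_index,
                    gene_locus=gene.locus_tag,
                    domains=list(current),
                    is_loading=is_loading,
                )
                if not is_loading:
                    next_index += 1
                modules.append(mod)
                current = []
        if current:
            if modules:
                warnings.warn(
                    f"{gene.locus_tag}: trailing ACP-less domains attached to module "
                    f"{modules[-1].index}"
                )
                modules[-1].domains.extend(current)
            else:
                warnings.warn(f"{gene.locus_tag}: domains without any ACP; dropped")

    for mod in modules:
        kr = mod.domain("KR")
        if kr is None:
            mod.kr_class = "absent"
        else:
            fp = kr.motif_flags.get("KR_fingerprint")
            if fp is None and kr.sequence:
                mod.kr_class = classify_kr(kr.sequence)
            else:
                mod.kr_class = {"LDD_present": "B", "W_present": "A"}.get(fp, "unassigned")
        mod.functional = assess_functionality(mod)
        if mod.functional and not mod.is_loading:
            mod.beta = beta_state(mod)
    return modules


def assess_functionality(module: PKSModule) -> bool:
    """Can this module perform (and finish) an extension?

    Non-functional iff a core domain (KS/AT/ACP) is missing, or the
    module lacks a KR while carrying a DH with an incomplete catalytic
    triad (a stalled dehydration position). Loading modules are exempt.
    """
    if module.is_loading:
        return True
    kinds = set(module.domain_kinds)
    if not {"KS", "AT", "ACP"} <= kinds:
        return False
    if "KR" not in kinds and "DH" in kinds:
        dh = module.domain("DH")
        complete = dh.motif_flags.get("DH_triad_complete")
        if complete is None:
            complete = check_dh_triad(dh.sequence)
        if not complete:
            return False
    return True


def beta_state(module: PKSModule) -> str:
    """β-carbon oxidation state implied by the module's reductive loop.

    No KR → ketone; KR alone → hydroxyl (S for an A-type KR, R for
    B-type, unknown stereo when unassigned); KR plus an active DH →
    enoyl (double bond, geometry deliberately unassigned); KR + DH + ER →
    fully reduced methylene.
    """
    if module.functional is False:
        raise ValueError(f"module {module.index} is non-functional; no beta state")
    kinds = set(module.domain_kinds)
    if "KR" not in kinds:
        return "ketone"
    dh = module.domain("DH")
    dh_active = False
    if dh is not None:
        flag = dh.motif_flags.get("DH_triad_complete")
        dh_active = check_dh_triad(dh.sequence) if flag is None else bool(flag)
    if dh_active and "ER" in kinds:
        return "methylene"
    if dh_active:
        return "enoyl"
    kr_class = module.kr_class
    if kr_class in ("absent", "unassigned") and module.domain("KR") is not None:
        kr_class = classify_kr(module.domain("KR").sequence)
    return {"A": "hydroxyl_S", "B": "hydroxyl_R"}.get(kr_class, "hydroxyl")


# ---------------------------------------------------------------------------
# domain-annotation exchange table (TSV: locus, kind, aa_start, aa_end,
# sequence, flags, at_substrate)

def write_domain_table(
    annotated: list[tuple[str, list[DomainAnnotation]]], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("locus\tkind\taa_start\taa_end\tsequence\tflags\tat_substrate\n")
        for locus, domains in annotated:
            for d in sorted(domains, key=lambda d: d.aa_start):
                flags = ";".join(f"{k}={v}" for k, v in sorted(d.motif_flags.items()))
                fh.write(
                    f"{locus}\t{d.kind}\t{d.aa_start}\t{d.aa_end}\t{d.sequence}\t"
                    f"{flags}\t{d.at_substrate}\n"
                )


def read_domain_table(path: str | Path) -> list[tuple[str, list[DomainAnnotation]]]:
    out: dict[str, list[DomainAnnotation]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus\t"):
            raise ValueError(f"{path}: not a domain-annotation table")
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 7:
                raise ValueError(f"{path}: row {lineno} has {len(cols)} columns, expected 7")
            locus, kind, s, e, seq, flags, at_sub = cols
            motif_flags: dict = {}
            for item in filter(None, flags.split(";")):
                k, _, v = item.partition("=")
                motif_flags[k] = {"True": True, "False": False}.get(v, v)
            dom = DomainAnnotation(
                kind=kind, aa_start=int(s), aa_end=int(e), sequence=seq,
                motif_flags=motif_flags, at_substrate=at_sub,
            )
            if locus not in out:
                out[locus] = []
                order.append(locus)
            out[locus].append(dom)
    return [(locus, out[locus]) for locus in order]
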