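"""Colinearity-based prediction of the macrolactam core structure.

The model: a β-amino-acid starter contributes three ring carbons plus the
ring nitrogen; every *functional* extension module adds a ketide (C2)
unit, so a line with m functional extension modules closes a ring of
2m + 4 atoms (8 → the 20-membered macrotermycin-type scaffold, 9 → the
22-membered ciromicin-type scaffold, 11 → 26-membered bombyxamycin-like
macrolactams). Carbons are numbered from the lactam carbonyl (C-1); the
β-carbon set by module i sits at C-(2(m−i)+3), so an A-type KR in module
6 lands an (S)-hydroxyl at C-7 of a 20-ring and C-9 of a 22-ring —
exactly the published stereochemistry correlation for these scaffolds.

Molecular formulas follow additive ketide bookkeeping: starter amino
acid + per-module unit (C2H2O ketone / C2H4O hydroxyl / C2H2 enoyl /
C2H4 methylene, + CH2 per methylmalonyl branch) − H2O for lactam
closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mass_annotation import MolecularFormula
from .pks_architecture import PKSModule

__all__ = [
    "StarterUnit",
    "CoreStructure",
    "predict_ring_size",
    "predict_core",
    "aglycone_formula",
    "emit_smiles",
]

#: Free β-amino-acid formulas and side-chain descriptions per starter type.
_STARTER_DATA = {
    "3-Amp": ("C4H9NO2", "methyl at C2"),
    "3-Aba": ("C4H9NO2", "methyl at C3"),
    "3-Afa": ("C3H7NO2", "alkyl chain at C3"),
    "beta-Phe": ("C9H11NO2", "phenyl at C3"),
    "beta-Ala": ("C3H7NO2", "none"),
}

_UNIT_FORMULA = {
    "ketone": "C2H2O",
    "hydroxyl": "C2H4O",
    "hydroxyl_S": "C2H4O",
    "hydroxyl_R": "C2H4O",
    "enoyl": "C2H2",
    "methylene": "C2H4",
}


@dataclass(frozen=True)
class StarterUnit:
    """A β-amino-acid starter. All types contribute 3 ring carbons + N."""

    type: str
    alkyl_length: int | None = None
    ring_carbons: int = 3

    def __post_init__(self) -> None:
        if self.type not in _STARTER_DATA:
            raise ValueError(
                f"unknown starter type {self.type!r}; choose from {sorted(_STARTER_DATA)}"
            )
        if self.type == "3-Afa" and (self.alkyl_length is None or self.alkyl_length < 1):
            raise ValueError(
                "3-Afa starters need an explicit alkyl chain length "
                "(not predictable from the BGC)"
            )

    @property
    def side_chain(self) -> str:
        return _STARTER_DATA[self.type][1]

    @property
    def formula(self) -> MolecularFormula:
        base = MolecularFormula.parse(_STARTER_DATA[self.type][0])
        if self.type == "3-Afa":
            n = self.alkyl_length
            return base + MolecularFormula.parse(f"C{n}H{2 * n}")
        return base


@dataclass
class CoreStructure:
    """A predicted macrolactam core."""

    ring_size: int
    starter: StarterUnit
    positions: dict[str, str]
    methyl_branches: list[str]
    tailoring: dict[str, int]
    aglycone_formula: MolecularFormula
    proposed_sites: dict[str, str] = field(default_factory=dict)
    spontaneous_cyclization_prone: bool = False
    n_functional_modules: int = 0


def predict_ring_size(functional_extension_modules: int, starter: StarterUnit) -> int:
    """Macrolactam ring size (atoms) from the number of functional extensions.

    ring = 2m + 4 for every β-amino-acid starter: the starter gives three
    carbons plus the nitrogen, each functional module two more carbons.
    """
    m = functional_extension_modules
    if m < 1:
        raise ValueError("no functional extension modules: no macrocycle forms")
    return 2 * m + 4


def predict_core(
    modules: list[PKSModule],
    starter: StarterUnit,
    tailoring_genes: dict[str, int] | None = None,
) -> CoreStructure:
    """Walk the assembly line and predict the macrolactam core.

    Only functional extension modules contribute ketide units. Position
    states come from each module's β-state; methyl branches from
    methylmalonyl-specific ATs. The spontaneous 2+4-cycloaddition flag is
    raised when three or more consecutive modules leave conjugated enoyl
    positions (polyene stretches behave this way under light, heat or
    acid).
    """
    tailoring = dict(tailoring_genes or {})
    extensions = [mod for mod in modules if not mod.is_loading]
    functional = [mod for mod in extensions if mod.functional]
    if not functional:
        raise ValueError("all extension modules are non-functional; no core predicted")

    m = len(functional)
    ring_size = predict_ring_size(m, starter)

    positions: dict[str, str] = {"C-1": "carbonyl"}
    methyl_branches: list[str] = []
    formula = starter.formula
    enoyl_run = best_run = 0

    for rank, mod in enumerate(functional, start=1):
        # rank in biosynthetic order; module `rank` sets the state of
        # beta carbon C-(2(m-rank)+3) and owns alpha carbon C-(2(m-rank)+2)
        beta_pos = 2 * (m - rank) + 3
        alpha_pos = beta_pos - 1
        state = mod.beta if mod.beta != "none" else "ketone"
        positions[f"C-{beta_pos}"] = state
        at = mod.domain("AT")
        if at is not None and at.at_substrate == "methylmalonyl":
            methyl_branches.append(f"C-{alpha_pos}")
        formula = formula + MolecularFormula.parse(_UNIT_FORMULA[state])
        if at is not None and at.at_substrate == "methylmalonyl":
            formula = formula + MolecularFormula.parse("CH2")
        if state == "enoyl":
            enoyl_run += 1
            best_run = max(best_run, enoyl_run)
        else:
            enoyl_run = 0

    formula = formula - MolecularFormula.parse("H2O")  # lactam closure

    proposed: dict[str, str] = {}
    if tailoring.get("glycosylation", 0) > 0:
        s_hydroxyls = [p for p, s in positions.items() if s == "hydroxyl_S"]
        proposed["glycosylation"] = s_hydroxyls[0] if s_hydroxyls else "unplaced"
    if tailoring.get("oxidation", 0) > 0:
        proposed["oxidation"] = "unplaced"

    return CoreStructure(
        ring_size=ring_size,
        starter=starter,
        positions=positions,
        methyl_branches=methyl_branches,
        tailoring=tailoring,
        aglycone_formula=formula,
        proposed_sites=proposed,
        spontaneous_cyclization_prone=best_run >= 3,
        n_functional_modules=m,
    )


def aglycone_formula(core: CoreStructure) -> MolecularFormula:
    """Molecular formula of the aglycone (pre-tailoring) core."""
    if not core.positions or not core.aglycone_formula.counts:
        raise ValueError("empty core has no formula")
    return core.aglycone_formula


def _starter_side_tokens(starter: StarterUnit) -> tuple[str, str]:
    """SMILES branch tokens for starter carbons C2 and C3."""
    c2 = "(C)" if starter.type == "3-Amp" else ""
    if starter.type == "3-Aba":
        c3 = "(C)"
    elif starter.type == "beta-Phe":
        c3 = "(c2ccccc2)"
    elif starter.type == "3-Afa":
        c3 = "(" + "C" * starter.alkyl_length + ")"
    else:
        c3 = ""
    return c2, c3


def emit_smiles(core: CoreStructure) -> str:
    """Render the core as SMILES.

    The macrocycle is written atom-by-atom from the lactam carbonyl to
    the nitrogen. Hydroxyl stereocentres are written with @/@@ only when
    a KR class fixed S/R; the direction is a fixed convention of this
    writer, not a CIP assignment. The largest ring of the output equals
    ``core.ring_size`` and its formula equals the aglycone formula.
    """
    m = core.n_functional_modules
    n_ring_carbons = 2 * m + 3
    branch_positions = set(core.methyl_branches)
    c2_tok, c3_tok = _starter_side_tokens(core.starter)

    parts = ["O=C1"]
    for j in range(2, n_ring_carbons + 1):
        label = f"C-{j}"
        state = core.positions.get(label)
        # an enoyl beta carbon is double-bonded to the preceding alpha carbon
        bond = "=" if (state == "enoyl") else ""
        if j == n_ring_carbons:  # starter C3, bears N
            parts.append(bond + "C" + c3_tok)
        elif j == n_ring_carbons - 1:  # starter C2
            parts.append(bond + "C" + c2_tok)
        elif state in (None, "methylene", "enoyl"):
            branch = "(C)" if label in branch_positions else ""
            parts.append(bond + "C" + branch)
        elif state == "ketone":
            parts.append("C(=O)")
        elif state == "hydroxyl_S":
            parts.append("[C@H](O)")
        elif state == "hydroxyl_R":
            parts.append("[C@@H](O)")
        elif state == "hydroxyl":
            parts.append("C(O)")
        else:  # pragma: no cover - exhaustive above
            parts.append("C")
    parts.append("N1")
    return "".join(parts)
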