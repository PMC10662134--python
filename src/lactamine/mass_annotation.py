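"""Monoisotopic mass arithmetic, Δm/z annotation and node linking.

The mass table is a pinned, embedded copy of the IUPAC/CODATA
most-abundant-isotope masses — never read from the environment — so that
every printed mass in the pipeline is reproducible bit-for-bit. The
adduct convention adds the mass of a neutral hydrogen atom and ignores
the electron mass; this is the convention under which the calculated
[M+H]+ of C26H36N2O6 comes out as 473.2652, matching the standard
printed value for the macrotermycin scaffold.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "MolecularFormula",
    "MONOISOTOPIC_MASS",
    "PROTON_ADDUCT_MASS",
    "Transformation",
    "TransformationTable",
    "DEFAULT_TRANSFORMATIONS",
    "monoisotopic_mass",
    "adduct_mz",
    "annotate_delta",
    "link_genome_to_nodes",
]

#: Monoisotopic (most-abundant-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: [M+H]+ under the neutral-H convention (electron mass ignored).
PROTON_ADDUCT_MASS = MONOISOTOPIC_MASS["H"]

_ADDUCTS = {"[M+H]+": 1.00782503207, "[M+Na]+": 22.98976928}


@dataclass(frozen=True)
class MolecularFormula:
    """Element→count map over C, H, N, O, S, P with an optional charge."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0) -> "MolecularFormula":
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(counts=items, charge=charge)

    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse a Hill-style formula string like ``C26H37N2O6``."""
        import re

        counts: Counter[str] = Counter()
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_dict(dict(counts), charge=charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.as_dict())
        c.update(other.as_dict())
        return MolecularFormula.from_dict(dict(c), charge=self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.as_dict())
        c.subtract(other.as_dict())
        if any(v < 0 for v in c.values()):
            raise ValueError(f"subtraction gives negative counts: {dict(c)}")
        return MolecularFormula.from_dict(dict(c), charge=self.charge - other.charge)

    def hill(self) -> str:
        d = self.as_dict()
        order = [el for el in ("C", "H") if el in d] + sorted(set(d) - {"C", "H"})
        return "".join(el + (str(d[el]) if d[el] != 1 else "") for el in order)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of most-abundant-isotope masses, Da (charge ignored here)."""
    if not formula.counts:
        raise ValueError("empty formula has no mass")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)


def adduct_mz(neutral: MolecularFormula, adduct: str = "[M+H]+") -> float:
    """m/z of a singly charged adduct of a neutral molecule."""
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; choose from {sorted(_ADDUCTS)}")
    return monoisotopic_mass(neutral) + _ADDUCTS[adduct]


@dataclass(frozen=True)
class Transformation:
    name: str
    delta_formula: MolecularFormula

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.delta_formula)


@dataclass
class TransformationTable:
    """Named chemical transformations used for Δm/z dereplication."""

    entries: list[Transformation] = field(default_factory=list)

    def __post_init__(self) -> None:
        # self-check: stored masses must be the masses of the formulas
        for t in self.entries:
            recomputed = monoisotopic_mass(t.delta_formula)
            assert abs(t.delta_mass - recomputed) < 1e-9

    def get(self, name: str) -> Transformation:
        for t in self.entries:
            if t.name == name:
                return t
        raise KeyError(name)


def _t(name: str, formula: str) -> Transformation:
    return Transformation(name, MolecularFormula.parse(formula))


#: Oxidation, double-bond-bearing ketide difference, methylation,
#: water, saturation, and the xylosaminyl glycosyl residue.
DEFAULT_TRANSFORMATIONS = TransformationTable(
    entries=[
        _t("O", "O"),
        _t("C2H2", "C2H2"),
        _t("CH2", "CH2"),
        _t("H2O", "H2O"),
        _t("H2", "H2"),
        _t("xylosaminyl", "C5H9NO3"),
    ]
)


def annotate_delta(
    mz_a: float,
    mz_b: float,
    table: TransformationTable = DEFAULT_TRANSFORMATIONS,
    tol: float = 0.01,
) -> list[str]:
    """Transformation names whose mass matches |mz_a − mz_b| within tol.

    Sorted by absolute mass error; empty when nothing matches (including
    a zero difference). Symmetric in its arguments.
    """
    if mz_a <= 0 or mz_b <= 0:
        raise ValueError("m/z values must be positive")
    delta = abs(mz_a - mz_b)
    scored = [
        (abs(delta - t.delta_mass), t.name)
        for t in table.entries
        if abs(delta - t.delta_mass) <= tol
    ]
    return [name for _, name in sorted(scored)]


def link_genome_to_nodes(
    core,
    nodes: list[tuple[float, str]],
    max_mods: int = 3,
    ppm: float = 10.0,
    table: TransformationTable = DEFAULT_TRANSFORMATIONS,
) -> list[dict]:
    """Match a predicted core structure against MS feature nodes.

    Enumerates the aglycone formula plus multisets of at most ``max_mods``
    tailoring transformations — glycosylations bounded by the cluster's
    GT count, oxidations by its CYP count — computes each [M+H]+ and
    reports nodes within the ppm tolerance, best match first.
    """
    aglycone = core.aglycone_formula
    gt_limit = min(max_mods, core.tailoring.get("glycosylation", 0))
    ox_limit = min(max_mods, core.tailoring.get("oxidation", 0))

    candidates: list[tuple[MolecularFormula, tuple[str, ...]]] = []
    for n_gly, n_ox in itertools.product(range(gt_limit + 1), range(ox_limit + 1)):
        if n_gly + n_ox > max_mods:
            continue
        f = aglycone
        for _ in range(n_gly):
            f = f + table.get("xylosaminyl").delta_formula
        for _ in range(n_ox):
            f = f + table.get("O").delta_formula
        mods = ("xylosaminyl",) * n_gly + ("O",) * n_ox
        candidates.append((f, mods))

    matches: list[dict] = []
    for mz, node_id in nodes:
        for f, mods in candidates:
            predicted = adduct_mz(f, "[M+H]+")
            err_ppm = (mz - predicted) / predicted * 1e6
            if abs(err_ppm) <= ppm:
                matches.append(
                    {
                        "node_id": node_id,
                        "node_mz": mz,
                        "modifications": mods,
                        "formula": f.hill(),
                        "predicted_mz": predicted,
                        "ppm_error": err_ppm,
                    }
                )
    matches.sort(key=lambda m: abs(m["ppm_error"]))
    return matches
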