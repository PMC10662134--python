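"""Candidate macrolactam BGC calling from gene features and homology hits.

The detector reproduces a cblaster-style windowing scheme: genes bearing
hits to a starter-unit query panel are chained while consecutive
hit-bearing genes are no more than ``max_hit_gap`` apart (gap measured
between facing gene boundaries), chains with enough distinct queries are
kept, and the gene window is widened to take in intermediate genes within
``max_intermediate_distance`` of the outermost hits. A deterministic
curation pass replaces the original manual steps: within-type duplicate
merging, contig-edge/no-PKS rejection, and cross-type resolution by
type-specific hit evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .io_formats import GeneFeature, HitRecord

__all__ = [
    "QueryPanel",
    "MiningParams",
    "CandidateCluster",
    "PANELS",
    "DEFAULT_PKS_LEXICON",
    "call_clusters",
    "curate",
    "resolve_type",
    "tabulate_abundance",
]

#: Core incorporation-machinery queries shared by every macrolactam BGC:
#: starter-loading adenylation enzyme (VinN-like), standalone ACP
#: (VinL-like), amino-protecting aminoacylation enzyme (VinM-like) and
#: standalone dipeptidyl-transferring AT (VinK-like).
CORE_QUERIES = ("VinN", "VinL", "VinM", "VinK")

#: Product-text lexicon used as a fallback PKS-proximity signal.
DEFAULT_PKS_LEXICON = ("polyketide synthase", "PKS", "beta-ketoacyl synthase")


@dataclass(frozen=True)
class QueryPanel:
    """One starter-unit-specific query panel.

    ``type_queries`` are the β-amino-acid biosynthesis enzymes that
    discriminate starter types; ``u_offset`` is how many missing queries
    the minimum-unique-hit rule tolerates (u = N − u_offset).
    """

    starter_type: str
    type_queries: tuple[str, ...]
    core_queries: tuple[str, ...] = CORE_QUERIES
    pks_query: str = "IdnP1"
    u_offset: int = 2

    @property
    def all_queries(self) -> tuple[str, ...]:
        return self.core_queries + self.type_queries + (self.pks_query,)

    @property
    def n_queries(self) -> int:
        return len(self.all_queries)

    @property
    def min_unique(self) -> int:
        u = self.n_queries - self.u_offset
        if u < 1:
            raise ValueError(
                f"panel {self.starter_type}: u = N - u_offset = {u} must be >= 1"
            )
        return u


#: The five starter-unit panels. 3-Amp and β-Ala share biosynthesis
#: queries (glutamate mutase VinH/VinI, decarboxylase VinO); β-Ala BGCs
#: lack the mutase, hence the relaxed u_offset of 4.
PANELS: dict[str, QueryPanel] = {
    "3-Amp": QueryPanel("3-Amp", ("VinH", "VinI", "VinO")),
    "3-Aba": QueryPanel("3-Aba", ("IdnL4", "IdnL3")),
    "3-Afa": QueryPanel("3-Afa", ("CmiS1", "CmiS2")),
    "beta-Phe": QueryPanel("beta-Phe", ("HitA",)),
    "beta-Ala": QueryPanel("beta-Ala", ("VinH", "VinI", "VinO"), u_offset=4),
}


@dataclass(frozen=True)
class MiningParams:
    max_hit_gap: int = 80_000
    max_intermediate_distance: int = 70_000
    pks_identity_floor: float = 0.50
    evalue_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.max_hit_gap <= 0 or self.max_intermediate_distance <= 0:
            raise ValueError("distance parameters must be positive")
        if not 0.0 <= self.pks_identity_floor <= 1.0:
            raise ValueError("identity floor is a fraction in [0, 1]")


@dataclass
class CandidateCluster:
    contig_id: str
    gene_window: list[str]
    hit_set: dict[str, HitRecord]
    starter_type: str
    window_start: int
    window_end: int
    has_pks_in_proximity: bool = False
    curation_flags: set[str] = field(default_factory=set)

    @property
    def unique_query_count(self) -> int:
        return len(self.hit_set)


def _best_hits_per_query(
    hits: list[HitRecord], panel: QueryPanel, params: MiningParams
) -> dict[str, list[HitRecord]]:
    """Panel hits grouped by subject locus, e-value-filtered if configured."""
    by_locus: dict[str, list[HitRecord]] = {}
    queries = set(panel.all_queries)
    for h in sorted(hits, key=lambda h: (h.subject_locus, h.query_id, -h.bitlike_score)):
        if h.query_id not in queries:
            continue
        if params.evalue_ceiling is not None and h.evalue > params.evalue_ceiling:
            continue
        by_locus.setdefault(h.subject_locus, []).append(h)
    return by_locus


def call_clusters(
    genes: dict[str, list[GeneFeature]],
    hits: list[HitRecord],
    panel: QueryPanel,
    params: MiningParams = MiningParams(),
    pks_lexicon: tuple[str, ...] = DEFAULT_PKS_LEXICON,
) -> list[CandidateCluster]:
    """Call candidate clusters for one query panel.

    Returns maximal chains of hit-bearing genes whose consecutive gaps are
    <= ``max_hit_gap`` and which cover at least N − u_offset distinct
    queries, with windows widened by intermediate genes and a PKS-proximity
    flag. Clusters never span contigs.
    """
    panel.min_unique  # validates u >= 1 up front
    known_loci = {g.locus_tag for gs in genes.values() for g in gs}
    for h in hits:
        if h.subject_locus not in known_loci:
            raise ValueError(f"hit subject {h.subject_locus} not found in gene table")

    hits_by_locus = _best_hits_per_query(hits, panel, params)
    clusters: list[CandidateCluster] = []

    for contig_id, contig_genes in genes.items():
        ordered = sorted(contig_genes, key=lambda g: g.start)
        hit_genes = [g for g in ordered if g.locus_tag in hits_by_locus]
        if not hit_genes:
            continue
        # maximal chains under the gap rule
        chains: list[list[GeneFeature]] = [[hit_genes[0]]]
        for g in hit_genes[1:]:
            gap = g.start - chains[-1][-1].end
            if gap <= params.max_hit_gap:
                chains[-1].append(g)
            else:
                chains.append([g])

        for chain in chains:
            hit_set: dict[str, HitRecord] = {}
            for g in chain:
                for h in hits_by_locus[g.locus_tag]:
                    prev = hit_set.get(h.query_id)
                    if prev is None or h.bitlike_score > prev.bitlike_score:
                        hit_set[h.query_id] = h
            if len(hit_set) < panel.min_unique:
                continue
            lo, hi = chain[0].start, chain[-1].end
            window = [
                g
                for g in ordered
                if g.start >= lo - params.max_intermediate_distance
                and g.end <= hi + params.max_intermediate_distance
            ]
            window_loci = {g.locus_tag for g in window}
            has_pks = any(
                h.query_id == panel.pks_query
                and h.subject_locus in window_loci
                and h.percent_identity >= params.pks_identity_floor * 100.0
                for hs in hits_by_locus.values()
                for h in hs
            ) or any(
                any(tok.lower() in g.product.lower() for tok in pks_lexicon)
                for g in window
            )
            clusters.append(
                CandidateCluster(
                    contig_id=contig_id,
                    gene_window=[g.locus_tag for g in window],
                    hit_set=hit_set,
                    starter_type=panel.starter_type,
                    window_start=window[0].start,
                    window_end=window[-1].end,
                    has_pks_in_proximity=has_pks,
                )
            )
    return clusters


def resolve_type(
    cluster: CandidateCluster, per_panel_hits: dict[str, dict[str, HitRecord]]
) -> str:
    """Resolve the starter type of a window called by several panels.

    The panel with the most type-specific (non-core, non-PKS) hits wins;
    ties break on summed scores of those hits; a residual tie is returned
    as ``"ambiguous"``. The 3-Amp / β-Ala pair is special-cased on
    biosynthetic logic: glutamate mutase (VinH/VinI) present → 3-Amp,
    decarboxylase without mutase → β-Ala.
    """
    evidence: dict[str, tuple[int, float]] = {}
    for type_name, hit_set in per_panel_hits.items():
        panel = PANELS[type_name]
        specific = [h for q, h in hit_set.items() if q in panel.type_queries]
        evidence[type_name] = (len(specific), sum(h.bitlike_score for h in specific))

    best = max(evidence.values())
    winners = [t for t, e in evidence.items() if e == best]
    if len(winners) == 1:
        return winners[0]
    if set(winners) == {"3-Amp", "beta-Ala"}:
        # the shared-query pair: mutase presence is the discriminant
        merged = {q for hs in per_panel_hits.values() for q in hs}
        if {"VinH", "VinI"} & merged:
            return "3-Amp"
        if "VinO" in merged:
            return "beta-Ala"
    return "ambiguous"


def _windows_overlap(a: CandidateCluster, b: CandidateCluster) -> bool:
    return a.contig_id == b.contig_id and bool(set(a.gene_window) & set(b.gene_window))


def curate(
    clusters: list[CandidateCluster],
    contig_lengths: dict[str, int] | None = None,
) -> list[CandidateCluster]:
    """Deterministic curation of raw cluster calls.

    Within-type duplicates (overlapping windows on one contig) collapse
    to the call with the highest unique-query count; windows with no PKS
    gene in proximity are removed — a macrolactam BGC without a
    detectable assembly line is not a credible call — with contig-edge
    windows carrying an extra flag; windows shared between panels are
    resolved with :func:`resolve_type`. Removed clusters keep their
    flags, so a caller holding the inputs can audit every decision.
    Curation never raises.
    """
    # 1. within-type duplicate collapse
    by_type: dict[str, list[CandidateCluster]] = {}
    for c in clusters:
        by_type.setdefault(c.starter_type, []).append(c)

    survivors: list[CandidateCluster] = []
    for type_name, group in by_type.items():
        merged_groups: list[list[CandidateCluster]] = []
        for c in sorted(group, key=lambda c: (c.contig_id, c.window_start)):
            placed = False
            for mg in merged_groups:
                if any(_windows_overlap(c, other) for other in mg):
                    mg.append(c)
                    placed = True
                    break
            if not placed:
                merged_groups.append([c])
        for mg in merged_groups:
            best = max(mg, key=lambda c: c.unique_query_count)
            if len(mg) > 1:
                best = replace(
                    best, curation_flags=best.curation_flags | {"within_type_duplicate"}
                )
            survivors.append(best)

    # 2. PKS-proximity screen: a macrolactam call needs an assembly line.
    # Windows on a contig boundary additionally carry the edge flag.
    kept: list[CandidateCluster] = []
    for c in survivors:
        length = (contig_lengths or {}).get(c.contig_id)
        at_edge = c.window_start <= 0 or (length is not None and c.window_end >= length)
        if at_edge:
            c.curation_flags.add("contig_edge")
        if not c.has_pks_in_proximity:
            c.curation_flags.add("no_pks")
            continue
        kept.append(c)

    # 3. cross-type resolution
    resolved: list[CandidateCluster] = []
    consumed: set[int] = set()
    for i, c in enumerate(kept):
        if i in consumed:
            continue
        overlapping = [
            (j, other)
            for j, other in enumerate(kept)
            if j > i and _windows_overlap(c, other) and other.starter_type != c.starter_type
        ]
        if not overlapping:
            resolved.append(c)
            continue
        group = [c] + [o for _, o in overlapping]
        consumed.update(j for j, _ in overlapping)
        per_panel = {g.starter_type: g.hit_set for g in group}
        winner_type = resolve_type(c, per_panel)
        best = max(group, key=lambda g: g.unique_query_count)
        resolved.append(
            replace(
                best,
                starter_type=winner_type,
                curation_flags=best.curation_flags | {"cross_type_duplicate"},
            )
        )
    return resolved


def tabulate_abundance(
    clusters: list[CandidateCluster], taxon_map: dict[str, str]
) -> pd.DataFrame:
    """Absolute and relative cluster abundance per taxon and starter type.

    ``taxon_map`` maps contig ids to family/genus labels; unmapped contigs
    count under ``"unassigned"``. Fractions sum to 1 over the whole table
    (empty for zero clusters).
    """
    rows = [
        {
            "taxon": taxon_map.get(c.contig_id, "unassigned"),
            "starter_type": c.starter_type,
        }
        for c in clusters
    ]
    if not rows:
        return pd.DataFrame(columns=["taxon", "starter_type", "count", "fraction"])
    counts = Counter((r["taxon"], r["starter_type"]) for r in rows)
    total = sum(counts.values())
    table = pd.DataFrame(
        [
            {"taxon": t, "starter_type": s, "count": n, "fraction": n / total}
            for (t, s), n in sorted(counts.items())
        ]
    )
    return table
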