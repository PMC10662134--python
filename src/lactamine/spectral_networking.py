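"""Modified-cosine similarity and molecular-network construction.

The similarity is the networking score used for MS/MS dereplication:
peak intensities are square-root transformed and L2-normalised, and two
peaks may be matched either directly (within the fragment tolerance) or
after shifting one spectrum by the precursor-mass difference, so that
congeners whose fragments move with a modification still align. Matching
is greedy by descending intensity product with each peak used at most
once — standard networking practice; on small spectra it coincides with
the optimal one-to-one assignment.

Default parameters follow common networking settings for this compound
class: 0.02 Da precursor/fragment tolerances, at least four matched
ions, cosine 0.75, minimum cluster size 2; library hits need a score
above 0.7 and at least six matched peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import SpectrumRecord
from .mass_annotation import DEFAULT_TRANSFORMATIONS, TransformationTable, annotate_delta

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "modified_cosine",
    "build_network",
    "library_match",
    "write_edge_table",
]


@dataclass(frozen=True)
class NetworkParams:
    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    min_matched_ions: int = 4
    cosine_min: float = 0.75
    min_cluster_size: int = 2
    library_min_score: float = 0.7
    library_min_peaks: int = 6

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 <= self.cosine_min <= 1.0 and 0.0 <= self.library_min_score <= 1.0):
            raise ValueError("cosine thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class NetworkEdge:
    spectrum_a: str
    spectrum_b: str
    score: float
    matched: int
    delta_mz: float
    annotations: tuple[str, ...] = ()


def _normalised(spectrum: SpectrumRecord) -> tuple[np.ndarray, np.ndarray]:
    mz = np.array([p[0] for p in spectrum.peaks], dtype=float)
    inten = np.sqrt(np.array([p[1] for p in spectrum.peaks], dtype=float))
    norm = np.linalg.norm(inten)
    if norm > 0:
        inten = inten / norm
    return mz, inten


def modified_cosine(
    a: SpectrumRecord, b: SpectrumRecord, fragment_tol: float = 0.02
) -> tuple[float, int]:
    """Modified-cosine score and matched-peak count for two spectra.

    Candidate pairs are peaks within ``fragment_tol`` directly or after
    shifting spectrum b by (precursor_b − precursor_a); pairs are
    accepted greedily by descending intensity product, each peak used
    once. Empty spectra score (0.0, 0).
    """
    if not a.peaks or not b.peaks:
        return 0.0, 0
    mz_a, int_a = _normalised(a)
    mz_b, int_b = _normalised(b)
    shift = b.precursor_mz - a.precursor_mz

    candidates: list[tuple[float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for offset in (0.0, shift) if abs(shift) > 1e-12 else (0.0,):
        # peaks match when mz_a ≈ mz_b − offset
        j = 0
        for i in range(len(mz_a)):
            target = mz_a[i]
            lo = np.searchsorted(mz_b, target + offset - fragment_tol, side="left")
            hi = np.searchsorted(mz_b, target + offset + fragment_tol, side="right")
            for j in range(lo, hi):
                if (i, j) not in seen:
                    seen.add((i, j))
                    candidates.append((float(int_a[i] * int_b[j]), i, j))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for product, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += product
        matched += 1
    return min(score, 1.0), matched


def build_network(
    spectra: list[SpectrumRecord],
    params: NetworkParams = NetworkParams(),
    table: TransformationTable = DEFAULT_TRANSFORMATIONS,
    delta_tol: float = 0.01,
) -> tuple[list[NetworkEdge], list[list[str]], nx.Graph]:
    """All-vs-all molecular network.

    Edges are kept when the modified cosine reaches ``cosine_min`` with
    at least ``min_matched_ions`` matched peaks; each edge's precursor
    Δm/z is annotated against the transformation table. Components
    smaller than ``min_cluster_size`` are reported as singletons. The
    edge set is invariant to input spectrum order.
    """
    graph = nx.Graph()
    ordered = sorted(spectra, key=lambda s: s.spectrum_id)
    for s in ordered:
        graph.add_node(s.spectrum_id, precursor_mz=s.precursor_mz)
    edges: list[NetworkEdge] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            score, matched = modified_cosine(a, b, params.fragment_tol)
            if score >= params.cosine_min and matched >= params.min_matched_ions:
                delta = abs(a.precursor_mz - b.precursor_mz)
                ann = (
                    tuple(annotate_delta(a.precursor_mz, b.precursor_mz, table, delta_tol))
                    if delta > delta_tol
                    else ()
                )
                edge = NetworkEdge(
                    spectrum_a=a.spectrum_id,
                    spectrum_b=b.spectrum_id,
                    score=round(score, 6),
                    matched=matched,
                    delta_mz=delta,
                    annotations=ann,
                )
                edges.append(edge)
                graph.add_edge(
                    a.spectrum_id,
                    b.spectrum_id,
                    score=edge.score,
                    matched=matched,
                    delta_mz=delta,
                    annotation=";".join(ann),
                )
    components = [
        sorted(c)
        for c in nx.connected_components(graph)
        if len(c) >= params.min_cluster_size
    ]
    components.sort()
    return edges, components, graph


def library_match(
    query: SpectrumRecord,
    library: list[SpectrumRecord],
    params: NetworkParams = NetworkParams(),
) -> list[tuple[str, float, int]]:
    """Library identification: score above threshold and enough peaks.

    Returns (library id, score, matched) tuples, best first.
    """
    if not library:
        return []
    out = []
    for ref in library:
        score, matched = modified_cosine(query, ref, params.fragment_tol)
        if score > params.library_min_score and matched >= params.library_min_peaks:
            out.append((ref.spectrum_id, score, matched))
    out.sort(key=lambda t: -t[1])
    return out


def write_edge_table(edges: list[NetworkEdge], path) -> None:
    """Edge table TSV: id_a, id_b, cosine, matched, delta, annotation."""
    with open(path, "w", newline="\n") as fh:
        fh.write("id_a\tid_b\tcosine\tmatched\tdelta_mz\tannotation\n")
        for e in sorted(edges, key=lambda e: (e.spectrum_a, e.spectrum_b)):
            fh.write(
                f"{e.spectrum_a}\t{e.spectrum_b}\t{e.score:.4f}\t{e.matched}\t"
                f"{e.delta_mz:.4f}\t{';'.join(e.annotations)}\n"
            )
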