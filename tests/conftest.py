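"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from lactamine.io_formats import GeneFeature, HitRecord


def make_gene(
    locus: str,
    start: int,
    end: int,
    contig: str = "ctg1",
    product: str = "hypothetical protein",
    strand: str = "+",
) -> GeneFeature:
    return GeneFeature(
        contig_id=contig, locus_tag=locus, start=start, end=end,
        strand=strand, product=product,
        translation="M" + "A" * max(1, (end - start) // 3 - 2),
    )


def make_hit(query: str, locus: str, pident: float = 70.0, score: float = 200.0) -> HitRecord:
    return HitRecord(
        query_id=query, subject_locus=locus, percent_identity=pident,
        alignment_length=300, bitlike_score=score, evalue=1e-50,
        below_identity_floor=pident < 50.0,
    )


def brute_force_windows(genes, hits_by_locus, g, min_unique):
    """Exhaustive window oracle for cluster calling on one contig.

    Enumerates every contiguous run of hit-bearing genes, keeps runs
    whose consecutive gaps are all <= g and which cover >= min_unique
    distinct queries, and returns the maximal ones (not contained in a
    larger valid run) as tuples of locus tags.
    """
    ordered = sorted(genes, key=lambda x: x.start)
    hit_genes = [x for x in ordered if x.locus_tag in hits_by_locus]
    valid = []
    n = len(hit_genes)
    for i in range(n):
        for j in range(i, n):
            run = hit_genes[i: j + 1]
            gaps_ok = all(
                run[k + 1].start - run[k].end <= g for k in range(len(run) - 1)
            )
            if not gaps_ok:
                continue
            queries = {
                h.query_id for x in run for h in hits_by_locus[x.locus_tag]
            }
            if len(queries) >= min_unique:
                valid.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in valid)
    ]
    return {
        tuple(x.locus_tag for x in hit_genes[i: j + 1]) for (i, j) in maximal
    }


def optimal_assignment_score(a, b, fragment_tol=0.02):
    """Exhaustive optimal one-to-one peak matching (small spectra only).

    Independent oracle for the modified cosine: same sqrt/L2 transform
    and shift rule, but the matching maximises the summed products over
    all one-to-one assignments instead of matching greedily.
    """
    import numpy as np

    if not a.peaks or not b.peaks:
        return 0.0, 0

    def norm(s):
        mz = np.array([p[0] for p in s.peaks])
        it = np.sqrt(np.array([p[1] for p in s.peaks]))
        n = np.linalg.norm(it)
        return mz, it / n if n > 0 else it

    mz_a, ia = norm(a)
    mz_b, ib = norm(b)
    shift = b.precursor_mz - a.precursor_mz
    pairs = []
    for i in range(len(mz_a)):
        for j in range(len(mz_b)):
            if (
                abs(mz_a[i] - mz_b[j]) <= fragment_tol
                or abs(mz_a[i] + shift - mz_b[j]) <= fragment_tol
            ):
                pairs.append((i, j))

    best = (0.0, 0)
    n = len(pairs)
    for r in range(1, n + 1):
        for combo in itertools.combinations(pairs, r):
            ai = [p[0] for p in combo]
            bj = [p[1] for p in combo]
            if len(set(ai)) != r or len(set(bj)) != r:
                continue
            s = sum(ia[i] * ib[j] for i, j in combo)
            if s > best[0]:
                best = (s, r)
    return min(best[0], 1.0), best[1]


@pytest.fixture()
def mte_genome(tmp_path):
    """A seeded mte-template genome on disk plus its truth record."""
    from lactamine.synthetic_data import PlantSpec, gen_genome

    spec = PlantSpec(seed=11, architecture="mte")
    genome, truth = gen_genome(spec, tmp_path)
    return genome, truth, tmp_path
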