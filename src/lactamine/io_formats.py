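"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are normalised at the boundary to 0-based,
half-open intervals; GenBank's 1-based inclusive convention exists only
inside :func:`read_genbank` / :func:`write_genbank`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

__all__ = [
    "GeneFeature",
    "HitRecord",
    "SpectrumRecord",
    "read_genbank",
    "write_genbank",
    "read_hit_table",
    "write_hit_table",
    "read_mgf",
    "write_mgf",
]

HIT_TABLE_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated CDS.

    ``start``/``end`` are 0-based half-open base-pair coordinates on the
    contig; ``strand`` is ``'+'`` or ``'-'``; ``translation`` is the
    protein sequence (20-letter alphabet plus X).
    """

    contig_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search (outfmt-6 dialect)."""

    query_id: str
    subject_locus: str
    percent_identity: float
    alignment_length: int
    bitlike_score: float
    evalue: float
    below_identity_floor: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"({self.query_id} vs {self.subject_locus})"
            )
        if self.bitlike_score < 0 or self.evalue < 0:
            raise ValueError("score and e-value must be non-negative")


@dataclass
class SpectrumRecord:
    """A single MS/MS spectrum: precursor m/z, charge, and a peak list.

    Peaks are kept sorted ascending by m/z.
    """

    spectrum_id: str
    precursor_mz: float
    charge: int = 1
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.spectrum_id}: precursor m/z must be positive")
        if self.charge <= 0:
            raise ValueError(f"{self.spectrum_id}: charge must be a positive integer")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"{self.spectrum_id}: negative peak intensity")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _feature_to_gene(contig_id: str, feat: SeqFeature, seq: Seq | None) -> GeneFeature | None:
    quals = feat.qualifiers
    locus = quals.get("locus_tag", [None])[0]
    if locus is None:
        warnings.warn(f"{contig_id}: CDS without /locus_tag skipped")
        return None
    translation = quals.get("translation", [None])[0]
    if translation is None:
        try:
            if seq is None:
                raise ValueError("no sequence")
            translation = str(feat.extract(seq).translate(to_stop=False)).rstrip("*")
            warnings.warn(f"{locus}: missing /translation, synthesised from sequence")
        except Exception:
            warnings.warn(f"{locus}: missing /translation and no usable sequence; feature rejected")
            return None
    strand = "-" if feat.location.strand == -1 else "+"
    # Biopython already exposes locations 0-based half-open.
    return GeneFeature(
        contig_id=contig_id,
        locus_tag=locus,
        start=int(feat.location.start),
        end=int(feat.location.end),
        strand=strand,
        product=quals.get("product", [""])[0],
        translation=translation,
    )


def read_genbank(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read CDS features from a GenBank flat file, grouped by contig.

    Coordinates are converted to 0-based half-open and features sorted by
    start. Returns an empty dict for an empty file.
    """
    path = Path(path)
    genomes: dict[str, list[GeneFeature]] = {}
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    for rec in records:
        genes: list[GeneFeature] = []
        seq: Seq | None
        try:
            seq = rec.seq if (len(rec.seq) and bytes(rec.seq)) else None
        except Exception:  # LOCUS declares a length but ORIGIN is absent
            seq = None
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene = _feature_to_gene(rec.id, feat, seq)
            if gene is not None:
                genes.append(gene)
        seen: set[str] = set()
        for g in genes:
            if g.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {g.locus_tag} on contig {rec.id}")
            seen.add(g.locus_tag)
        genomes[rec.id] = sorted(genes, key=lambda g: g.start)
    return genomes


def write_genbank(
    genomes: dict[str, list[GeneFeature]],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write gene features back out as a GenBank flat file.

    When no nucleotide sequence is supplied an N-run placeholder of the
    declared contig length is used so the file stays parseable.
    """
    records = []
    for contig_id, genes in genomes.items():
        length = (contig_lengths or {}).get(
            contig_id, max((g.end for g in genes), default=0) + 100
        )
        seq = Seq((sequences or {}).get(contig_id, "N" * length))
        rec = SeqRecord(seq, id=contig_id, name=contig_id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        for g in sorted(genes, key=lambda g: g.start):
            loc = FeatureLocation(g.start, g.end, strand=-1 if g.strand == "-" else 1)
            feat = SeqFeature(loc, type="CDS")
            feat.qualifiers["locus_tag"] = [g.locus_tag]
            feat.qualifiers["product"] = [g.product]
            feat.qualifiers["translation"] = [g.translation]
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def read_hit_table(path: str | Path, identity_floor: float = 0.50) -> list[HitRecord]:
    """Read a 12-column tab-separated homology hit table.

    Rows below ``identity_floor`` (a fraction) are retained but flagged
    ``below_identity_floor`` — filtering is the mining module's decision,
    not the reader's.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: row {lineno} has {len(cols)} columns, expected 12"
                )
            try:
                pident = float(cols[2])
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_locus=cols[1],
                        percent_identity=pident,
                        alignment_length=int(cols[3]),
                        bitlike_score=float(cols[11]),
                        evalue=float(cols[10]),
                        below_identity_floor=pident < identity_floor * 100.0,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (deterministic order)."""
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            aln = h.alignment_length
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_locus,
                        f"{h.percent_identity:.2f}",
                        str(aln),
                        "0",
                        "0",
                        "1",
                        str(aln),
                        "1",
                        str(aln),
                        f"{h.evalue:.3g}",
                        f"{h.bitlike_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file into spectrum records.

    Blocks without a PEPMASS line are skipped with a warning. CHARGE
    strings like ``1+`` are normalised to a positive integer (default 1).
    """
    spectra: list[SpectrumRecord] = []
    with _mgf.read(str(path), convert_arrays=1, use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                warnings.warn(f"{path}: spectrum block {i} without PEPMASS skipped")
                continue
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 1
            sid = str(params.get("title", f"spectrum_{i}"))
            peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                SpectrumRecord(
                    spectrum_id=sid,
                    precursor_mz=float(pepmass[0]),
                    charge=abs(charge) or 1,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[SpectrumRecord], path: str | Path, header: str = "") -> None:
    """Write spectra as MGF; round-trips with :func:`read_mgf` to 6 decimals."""
    with open(path, "w", newline="\n") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")
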