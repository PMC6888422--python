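"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions are centralized here: GFF3 is 1-based inclusive on
disk, BED output is 0-based half-open, and all conversions happen at this
boundary. Packaged fixtures (the 64-gene family table and the SA/MeJA
regulation lists) are loaded from ``sawrky/data``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates basic syntax."""


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its own integrity checks."""


@dataclass(frozen=True)
class SeqRecord:
    """A sequence record: ``id`` is the first whitespace-delimited header
    token, ``sequence`` is uppercase with no internal whitespace."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"SeqRecord {self.id!r}: whitespace in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding start and exon layout.

    ``cds_start`` is the 1-based position of the first base of the start
    codon: on the plus strand the minimum CDS coordinate, on the minus
    strand the maximum. ``exons`` are 1-based inclusive, sorted,
    non-overlapping intervals.
    """

    gene_id: str
    contig: str
    strand: str
    cds_start: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            if end < start:
                raise ValueError(f"{self.gene_id}: exon end < start")
            prev_end = end


@dataclass(frozen=True)
class FamilyFixtureRow:
    """One row of the packaged 64-gene family table."""

    gene: str
    orf_aa: int
    motif_string: str
    zinc_labels: tuple[str, ...]
    subcellular: str
    group: str

    @property
    def n_domains(self) -> int:
        return len(self.motif_string.split("/"))

    @property
    def major_group(self) -> str:
        """I, II or III (subgroup letters stripped)."""
        return "II" if self.group in {"IIa", "IIb", "IIc", "IId", "IIe"} else self.group


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Wrapped sequence lines are concatenated; record order is preserved.
    Text before the first header is a format error.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description if rec.description != rec.id else ""
        records.append(
            SeqRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    One :class:`GeneModel` per ``gene`` feature. When a gene has several
    mRNAs, the first (by start coordinate, then ID) supplies the exon
    structure. ``cds_start`` follows the strand convention documented on
    :class:`GeneModel`. With ``contig_lengths`` given, exons outside the
    declared contig are a validation error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA"), key=lambda f: (f.start, f.id)
        )
        parent = mrnas[0] if mrnas else gene
        exons = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start, gene.end)]
        cds = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="CDS")
        )
        if not cds:
            cds = exons
        cds_start = cds[0][0] if gene.strand == "+" else cds[-1][1]
        if contig_lengths is not None:
            clen = contig_lengths.get(gene.seqid)
            if clen is not None and any(e > clen or s < 1 for s, e in exons):
                raise ValueError(
                    f"{gene.id}: exon outside contig {gene.seqid} (len {clen})"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds_start=cds_start,
                exons=tuple(exons),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Packaged fixtures

_DATA = resources.files("sawrky") / "data"

_ZINC_LABEL_RE = re.compile(r"^C-X(\d+)-C-X(\d+)-HX([A-Z])$")


def normalize_zinc_label(label: str) -> str:
    """Strip typographic styling from a zinc-finger label.

    Accepts mixed styles such as ``C-X_5_-C-X_23_-HXH`` or ``C-X6-CX23-HXH``
    and returns the plain form ``C-X5-C-X23-HXH``.
    """
    s = label.replace("_", "").replace(" ", "")
    m = re.match(r"^C-?X(\d+)-?C-?X(\d+)-?HX([A-Z])$", s)
    if not m:
        raise ValueError(f"unparseable zinc-finger label: {label!r}")
    a, b, z = m.groups()
    return f"C-X{a}-C-X{b}-HX{z}"


def load_family_fixture() -> list[FamilyFixtureRow]:
    """Load the packaged 64-gene family table (gene, ORF length, conserved
    motif string, zinc-finger labels, subcellular prediction, group)."""
    df = pd.read_csv(_DATA / "sawrky_table1.tsv", sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        labels = tuple(
            normalize_zinc_label(x) for x in rec.zinc_labels.split("/")
        )
        rows.append(
            FamilyFixtureRow(
                gene=rec.gene,
                orf_aa=int(rec.orf_aa),
                motif_string=rec.motif_string,
                zinc_labels=labels,
                subcellular=rec.subcellular,
                group=rec.group,
            )
        )
    names = [r.gene for r in rows]
    expected = {f"SaWRKY{i}" for i in range(1, 65)}
    if len(rows) != 64 or set(names) != expected or len(set(names)) != 64:
        raise FixtureError("family fixture must hold SaWRKY1..SaWRKY64 exactly")
    for r in rows:
        if r.orf_aa < 1:
            raise FixtureError(f"{r.gene}: non-positive ORF length")
        if r.group not in {"I", "IIa", "IIb", "IIc", "IId", "IIe", "III"}:
            raise FixtureError(f"{r.gene}: unknown group {r.group!r}")
        for lab in r.zinc_labels:
            if not _ZINC_LABEL_RE.match(lab):
                raise FixtureError(f"{r.gene}: bad zinc label {lab!r}")
    return rows


def load_regulation_fixture() -> dict[str, dict[str, frozenset[str]]]:
    """Load the hormone-response gene lists.

    Returns ``{hormone: {"up": genes, "down": genes}}`` for the SA and MeJA
    treatments (13 up / 12 down under SA; 18 up / 6 down under MeJA).
    """
    df = pd.read_csv(_DATA / "regulation_sa_meja.tsv", sep="\t", dtype=str)
    out: dict[str, dict[str, frozenset[str]]] = {}
    for hormone, sub in df.groupby("hormone"):
        out[hormone] = {
            direction: frozenset(g["gene"])
            for direction, g in sub.groupby("direction")
        }
    for hormone, dirs in out.items():
        if dirs.get("up", frozenset()) & dirs.get("down", frozenset()):
            raise FixtureError(f"{hormone}: up/down lists overlap")
    expected = {"SA": (13, 12), "MeJA": (18, 6)}
    for hormone, (n_up, n_down) in expected.items():
        if len(out[hormone]["up"]) != n_up or len(out[hormone]["down"]) != n_down:
            raise FixtureError(f"{hormone}: unexpected list sizes")
    return out


# ---------------------------------------------------------------------------
# Writers


def write_bed(hits: Sequence, path: str | Path) -> None:
    """Write motif hits as BED6 (0-based half-open, strand in column 6).

    ``hits`` carry 1-based inclusive genomic coordinates (``start``, ``end``)
    plus ``contig``, ``gene_id``, ``strand``.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.gene_id}\t0\t{h.strand}\n"
            )


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (``classify.Tree``) as Newick with branch lengths and
    integer support labels where present."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_table(rows, path: str | Path) -> None:
    """Write a DataFrame or list of dicts as a TSV with a header row.

    Floats are printed with 6 significant digits for diff-able output.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())
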