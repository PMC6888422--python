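"""Promoter extraction, W-box scanning, target calling, and enrichment.

The W-box is the cis-element bound by WRKY transcription factors; the scan
consensus is (C/T)TGAC(C/T). Promoters are anchored at the translation
start (first base of the ATG codon) and extend a configurable distance
upstream (default 2 kb). Genes whose promoter carries at least
``min_boxes_for_target`` W-boxes (default 5) are called potential WRKY
targets, and the target set is tested for pathway enrichment with the
hypergeometric upper tail plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, SeqRecord, revcomp


@dataclass(frozen=True)
class PromoterScanConfig:
    promoter_len: int = 2000
    consensus: str = "YTGACY"  # IUPAC for (C/T)TGAC(C/T)
    min_boxes_for_target: int = 5
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        if not re.fullmatch(r"[ACGTRYSWKMBDHVN]+", self.consensus):
            raise ValueError("consensus must be IUPAC DNA")


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def _iupac_regex(consensus: str) -> str:
    return "".join(
        b if len(_IUPAC[b]) == 1 else f"[{_IUPAC[b]}]" for b in consensus
    )


def _revcomp_consensus(consensus: str) -> str:
    return "".join(_IUPAC_COMP[b] for b in reversed(consensus))


@dataclass(frozen=True)
class MotifHit:
    """A consensus match; genomic coordinates are 1-based inclusive."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    matched: str


@dataclass(frozen=True)
class PromoterRegion:
    """A gene's extracted promoter, oriented 5'→3' relative to the gene.

    ``genomic_start``/``genomic_end`` (1-based inclusive) locate the
    region on the contig; ``truncated`` flags promoters shorter than the
    configured length because of a contig edge.
    """

    gene_id: str
    contig: str
    strand: str
    sequence: str
    genomic_start: int
    genomic_end: int
    truncated: bool


def extract_promoter(
    gene: GeneModel,
    genome: Mapping[str, SeqRecord],
    cfg: PromoterScanConfig = PromoterScanConfig(),
) -> PromoterRegion:
    """Extract the promoter upstream of the translation start.

    Plus strand: bases [cds_start - L, cds_start - 1]; minus strand: bases
    [cds_start + 1, cds_start + L] reverse-complemented. Truncated at the
    contig edge; an empty promoter (start codon at the edge) draws a
    warning and yields an empty sequence.
    """
    if gene.contig not in genome:
        raise KeyError(f"{gene.gene_id}: contig {gene.contig!r} not in genome")
    contig_seq = genome[gene.contig].sequence
    L = cfg.promoter_len
    if gene.strand == "+":
        start = max(1, gene.cds_start - L)
        end = gene.cds_start - 1
        seq = contig_seq[start - 1 : end] if end >= start else ""
    else:
        start = gene.cds_start + 1
        end = min(len(contig_seq), gene.cds_start + L)
        seq = revcomp(contig_seq[start - 1 : end]) if end >= start else ""
    if not seq:
        warnings.warn(f"{gene.gene_id}: start codon at contig edge; empty promoter")
    return PromoterRegion(
        gene_id=gene.gene_id,
        contig=gene.contig,
        strand=gene.strand,
        sequence=seq,
        genomic_start=start,
        genomic_end=end,
        truncated=len(seq) < L,
    )


def scan_wbox(
    seq: str, cfg: PromoterScanConfig = PromoterScanConfig()
) -> list[tuple[int, str, str]]:
    """Scan a promoter for the W-box consensus.

    Returns ``(offset, strand, matched_6mer)`` tuples sorted by offset then
    strand. Forward hits match the consensus directly; with
    ``scan_both_strands`` the reverse-complement consensus is also scanned,
    reporting minus-strand hits at the same forward offsets. Overlapping
    matches are all counted. ``N`` (or any non-ACGT letter) never matches.
    """
    if re.search(r"[^ACGTN]", seq):
        warnings.warn("non-ACGTN characters in promoter sequence")
    hits = []
    fwd = re.compile(f"(?=({_iupac_regex(cfg.consensus)}))")
    for m in fwd.finditer(seq):
        hits.append((m.start(), "+", m.group(1)))
    if cfg.scan_both_strands:
        rev = re.compile(f"(?=({_iupac_regex(_revcomp_consensus(cfg.consensus))}))")
        for m in rev.finditer(seq):
            hits.append((m.start(), "-", m.group(1)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def promoter_hits(
    promoter: PromoterRegion, cfg: PromoterScanConfig = PromoterScanConfig()
) -> list[MotifHit]:
    """Scan one promoter and map hit offsets back to genomic coordinates."""
    out = []
    k = len(cfg.consensus)
    for offset, strand, matched in scan_wbox(promoter.sequence, cfg):
        if promoter.strand == "+":
            g_start = promoter.genomic_start + offset
            g_strand = strand
        else:
            g_start = promoter.genomic_end - offset - (k - 1)
            g_strand = "+" if strand == "-" else "-"
        out.append(
            MotifHit(
                gene_id=promoter.gene_id,
                contig=promoter.contig,
                start=g_start,
                end=g_start + k - 1,
                strand=g_strand,
                matched=matched,
            )
        )
    return out


def count_and_filter(
    per_gene_hits: Mapping[str, Sequence],
    cfg: PromoterScanConfig = PromoterScanConfig(),
) -> tuple[pd.DataFrame, frozenset[str], dict[str, int]]:
    """Per-gene W-box counts, the target gene set, and the count histogram.

    The histogram bins are 0, 1, 2, 3, 4 and ">=5"; targets are genes with
    at least ``min_boxes_for_target`` boxes (boundary inclusive).
    """
    counts = {g: len(h) for g, h in per_gene_hits.items()}
    table = pd.DataFrame(
        sorted(counts.items()), columns=["gene", "n_wbox"]
    )
    thr = cfg.min_boxes_for_target
    targets = frozenset(g for g, c in counts.items() if c >= thr)
    hist = {str(i): 0 for i in range(5)}
    hist[">=5"] = 0
    for c in counts.values():
        hist[str(c) if c < 5 else ">=5"] += 1
    return table, targets, hist


def gene_structure(gene: GeneModel) -> tuple[int, int]:
    """(n_exons, n_introns) for a gene model; introns = exons - 1."""
    n_exons = len(gene.exons)
    if n_exons < 1:
        raise ValueError(f"{gene.gene_id}: gene without exons")
    return n_exons, n_exons - 1


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


def enrich(
    targets: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    pathway_map: Mapping[str, Sequence[tuple[str, str]]],
    top: int | None = 20,
) -> list[EnrichmentRow]:
    """Pathway over-representation of the target set.

    ``pathway_map`` maps gene → [(pathway_id, pathway_name), ...] over the
    background universe. Per pathway, p = P(X >= k) under the
    hypergeometric null with population N = |background|, K background
    genes in the pathway and n = |targets| draws; q is the
    Benjamini-Hochberg adjusted p across all tested pathways. Rows are
    sorted by p (ties by pathway id); ``top`` limits the report.
    """
    targets = set(targets)
    background = set(background)
    if not targets:
        raise ValueError("empty target set")
    if not targets <= background:
        raise ValueError("targets must be a subset of the background")
    N = len(background)
    n = len(targets)
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for gene, pathways in pathway_map.items():
        if gene not in background:
            continue
        for pid, pname in pathways:
            members.setdefault(pid, set()).add(gene)
            names[pid] = pname
    rows = []
    for pid in sorted(members):
        K = len(members[pid])
        k = len(members[pid] & targets)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, K, k, min(p, 1.0)))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    out = [
        EnrichmentRow(
            pathway_id=pid,
            pathway_name=names[pid],
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            q=float(q),
        )
        for (pid, K, k, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p, r.pathway_id))
    return out if top is None else out[:top]


def read_pathway_map(path) -> dict[str, list[tuple[str, str]]]:
    """Read a gene→pathway TSV (gene_id, pathway_id, pathway_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[tuple[str, str]]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(rec.gene_id, []).append((rec.pathway_id, rec.pathway_name))
    return out
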