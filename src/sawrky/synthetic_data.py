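"""Generators producing inputs with known planted truth for every pipeline
stage: proteins with planted WRKY domains, genomes with planted W-box
counts, triplicate Cq tables with planted fold changes, and Poisson count
matrices.

All generators are deterministic under a fixed seed. Random streams are
consumed in documented order (flanks left to right for proteins; contigs
in plan order, then per-gene offsets, for genomes; genes × hormones ×
timepoints × replicates for Cq tables). Synthetic backgrounds are
rejection-sampled so they contain no accidental motif instances, which
makes planted counts exact truths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .family_id import AA20, DomainGrammar, parse_pattern_label
from .io_formats import FamilyFixtureRow, GeneModel, SeqRecord, revcomp

# flank/spacer alphabet excludes W, C and H so that neither heptapeptides
# nor zinc-finger arrangements can arise by accident
SAFE_AA = "".join(c for c in AA20 if c not in "WCH")

WBOX_WORDS = ("CTGACC", "CTGACT", "TTGACC", "TTGACT")


# ---------------------------------------------------------------------------
# Proteins


@dataclass(frozen=True)
class DomainPlan:
    """One planted WRKY domain: heptapeptide variant plus finger geometry.
    ``finger=None`` plants a heptapeptide with no valid finger."""

    heptapeptide: str = "WRKYGQK"
    finger: Optional[tuple[int, int, str]] = (5, 23, "H")  # (a, b, z)


@dataclass(frozen=True)
class ProteinPlan:
    id: str
    domains: tuple[DomainPlan, ...]
    length: Optional[int] = None
    finger_gap: int = 3

    def min_length(self) -> int:
        need = 0
        for dom in self.domains:
            need += 7
            if dom.finger is not None:
                a, b, _ = dom.finger
                need += self.finger_gap + a + b + 5
        return need


def _rand_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SAFE_AA), size=n)) if n > 0 else ""


def gen_wrky_protein(plan: ProteinPlan, seed: int = 0) -> SeqRecord:
    """Realize a protein plan as a sequence.

    Domains are inserted left to right with exact planted spacings; flanks
    and spacers come from an alphabet free of W, C and H, so the planted
    domains are the only grammar matches. Raises when the plan does not
    fit in the requested length.
    """
    rng = np.random.default_rng(seed)
    need = plan.min_length()
    length = plan.length if plan.length is not None else need + 20 * (len(plan.domains) + 1)
    slack = length - need
    if slack < 0:
        raise ValueError(
            f"{plan.id}: length {length} too short for planted domains ({need})"
        )
    n_slots = len(plan.domains) + 1
    per = slack // n_slots
    flank_sizes = [per] * n_slots
    flank_sizes[-1] += slack - per * n_slots
    parts = []
    for dom_idx, dom in enumerate(plan.domains):
        parts.append(_rand_flank(rng, flank_sizes[dom_idx]))
        parts.append(dom.heptapeptide)
        if dom.finger is not None:
            a, b, z = dom.finger
            parts.append(_rand_flank(rng, plan.finger_gap))
            parts.append("C" + _rand_flank(rng, a) + "C" + _rand_flank(rng, b))
            parts.append("H" + _rand_flank(rng, 1) + z)
    parts.append(_rand_flank(rng, flank_sizes[-1]))
    seq = "".join(parts)
    assert len(seq) == length
    return SeqRecord(id=plan.id, sequence=seq)


def plan_from_fixture_row(
    row: FamilyFixtureRow, fingerless: bool = False
) -> ProteinPlan:
    """Build a protein plan from a family-table row.

    One finger is planted per heptapeptide, consuming the row's labels in
    order (rows listing more labels than domains contribute only the first
    ``n_domains``). With ``fingerless`` the heptapeptides are planted
    without any valid finger arrangement.
    """
    heptas = row.motif_string.split("/")
    labels = row.zinc_labels[: len(heptas)]
    domains = []
    for i, hepta in enumerate(heptas):
        if fingerless or i >= len(labels):
            finger = None
        else:
            finger = parse_pattern_label(labels[i])
        domains.append(DomainPlan(heptapeptide=hepta, finger=finger))
    return ProteinPlan(id=row.gene, domains=tuple(domains), length=row.orf_aa)


def gen_family_fasta(
    rows: Sequence[FamilyFixtureRow],
    seed: int = 0,
    fingerless: Sequence[str] = (),
) -> list[SeqRecord]:
    """Realize every family-table row as one synthetic protein of exactly
    the row's ORF length embedding its planted domain pattern(s).

    ``fingerless`` names genes whose heptapeptides are planted without a
    detectable finger (negative controls for proteins whose conserved
    zinc-finger motif was not recovered by motif discovery).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(rows))
    records = []
    for row, child in zip(rows, child_seeds):
        plan = plan_from_fixture_row(row, fingerless=row.gene in set(fingerless))
        records.append(gen_wrky_protein(plan, seed=child.entropy % (2**31)))
    return records


# ---------------------------------------------------------------------------
# Genomes


@dataclass(frozen=True)
class GenePlan:
    gene_id: str
    contig: str
    strand: str
    cds_start: int
    exons: tuple[tuple[int, int], ...]
    n_wbox: int


@dataclass(frozen=True)
class GenomePlan:
    contig_lengths: Mapping[str, int]
    genes: tuple[GenePlan, ...]
    promoter_len: int = 2000


@dataclass
class GenomeSim:
    """A realized synthetic genome: sequence records, gene models, GFF3
    text and the planted-truth table."""

    contigs: list[SeqRecord]
    genes: list[GeneModel]
    gff3: str
    truth: pd.DataFrame


def simple_genome_plan(
    wbox_counts: Mapping[str, int],
    promoter_len: int = 2000,
    alternate_strands: bool = True,
) -> GenomePlan:
    """One gene per contig, promoters fully contained in the contig.

    Plus-strand genes sit at cds_start = promoter_len + 500 with a
    three-exon layout; minus-strand genes mirror it.
    """
    genes = []
    lengths = {}
    clen = promoter_len + 4000
    for i, (gene_id, count) in enumerate(sorted(wbox_counts.items())):
        contig = f"ctg{i + 1}"
        lengths[contig] = clen
        minus = alternate_strands and i % 2 == 1
        if not minus:
            cs = promoter_len + 500
            exons = ((cs, cs + 800), (cs + 1000, cs + 1700), (cs + 2000, cs + 2400))
            strand = "+"
        else:
            cs = clen - promoter_len - 500
            exons = ((cs - 2400, cs - 2000), (cs - 1700, cs - 1000), (cs - 800, cs))
            strand = "-"
        genes.append(
            GenePlan(
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                cds_start=cs,
                exons=exons,
                n_wbox=count,
            )
        )
    return GenomePlan(contig_lengths=lengths, genes=tuple(genes), promoter_len=promoter_len)


def _motif_free_dna(rng: np.random.Generator, n: int) -> str:
    """Random DNA with no W-box instance on either strand.

    Bases are drawn one at a time; a draw completing a forbidden 6-mer is
    redrawn (at most one of the two patterns can constrain a given window,
    so at least two of the four bases always remain legal).
    """
    from .regulome import PromoterScanConfig, scan_wbox
    import warnings

    out: list[str] = []
    bases = "ACGT"
    for _ in range(n):
        while True:
            out.append(bases[rng.integers(0, 4)])
            if len(out) < 6:
                break
            window = "".join(out[-6:])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if not scan_wbox(window):
                    break
            out.pop()
    return "".join(out)


def gen_genome(plan: GenomePlan, seed: int = 0) -> GenomeSim:
    """Realize a genome plan: motif-free background with exactly the
    planned number of W-box instances planted at non-overlapping random
    promoter offsets.

    Raises when a promoter cannot hold its planted boxes.
    """
    from .regulome import scan_wbox
    import warnings

    rng = np.random.default_rng(seed)
    L = plan.promoter_len
    contig_seqs = {
        name: list(_motif_free_dna(rng, length))
        for name, length in plan.contig_lengths.items()
    }
    truth_rows = []
    gene_models = []
    k = 6
    for gp in plan.genes:
        if gp.n_wbox * k > L:
            raise ValueError(f"{gp.gene_id}: promoter too crowded")
        for _attempt in range(100):
            promoter = list(_motif_free_dna(rng, L))
            offsets: list[int] = []
            while len(offsets) < gp.n_wbox:
                cand = int(rng.integers(0, L - k + 1))
                if all(abs(cand - o) >= k for o in offsets):
                    offsets.append(cand)
            for off in offsets:
                word = WBOX_WORDS[rng.integers(0, len(WBOX_WORDS))]
                if rng.integers(0, 2):
                    word = revcomp(word)
                promoter[off : off + k] = word
            text = "".join(promoter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                found = len(scan_wbox(text))
            if found == gp.n_wbox:
                break
        else:
            raise RuntimeError(f"{gp.gene_id}: could not plant exact W-box count")
        seq = contig_seqs[gp.contig]
        if gp.strand == "+":
            start = gp.cds_start - L  # 1-based; promoter = [start, cds_start-1]
            seq[start - 1 : gp.cds_start - 1] = text
        else:
            start = gp.cds_start + 1
            seq[start - 1 : start - 1 + L] = revcomp(text)
        gene_models.append(
            GeneModel(
                gene_id=gp.gene_id,
                contig=gp.contig,
                strand=gp.strand,
                cds_start=gp.cds_start,
                exons=gp.exons,
            )
        )
        truth_rows.append(
            {"gene": gp.gene_id, "strand": gp.strand, "n_wbox": gp.n_wbox}
        )
    contigs = [
        SeqRecord(id=name, sequence="".join(s)) for name, s in contig_seqs.items()
    ]
    gff_lines = ["##gff-version 3"]
    for gm in gene_models:
        lo = min(s for s, _ in gm.exons)
        hi = max(e for _, e in gm.exons)
        base = f"{gm.contig}\tsawrky_sim\t"
        tail = f"\t.\t{gm.strand}\t."
        gff_lines.append(
            f"{base}gene\t{lo}\t{hi}{tail}\tID={gm.gene_id}"
        )
        mrna = f"{gm.gene_id}.t1"
        gff_lines.append(
            f"{base}mRNA\t{lo}\t{hi}{tail}\tID={mrna};Parent={gm.gene_id}"
        )
        for idx, (s, e) in enumerate(gm.exons, 1):
            gff_lines.append(
                f"{base}exon\t{s}\t{e}{tail}\tID={mrna}.exon{idx};Parent={mrna}"
            )
            gff_lines.append(
                f"{base}CDS\t{s}\t{e}\t.\t{gm.strand}\t0\tID={mrna}.cds{idx};Parent={mrna}"
            )
    return GenomeSim(
        contigs=contigs,
        genes=gene_models,
        gff3="\n".join(gff_lines) + "\n",
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrPlan:
    """Planted fold changes per gene × hormone × timepoint.

    ``folds[gene][hormone]`` maps timepoint (h) → linear fold relative to
    the 0 h calibrator. Noise SDs are in Cq cycles.
    """

    folds: Mapping[str, Mapping[str, Mapping[int, float]]]
    ref_sd: float = 0.05
    noise_sd: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.ref_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for gene, per_h in self.folds.items():
            for hormone, per_t in per_h.items():
                if any(f <= 0 for f in per_t.values()):
                    raise ValueError(f"{gene}/{hormone}: folds must be positive")


def regulation_qpcr_plan(
    regulation: Mapping[str, Mapping[str, frozenset[str]]],
    universe: Sequence[str],
    up_fold: float = 3.0,
    down_fold: float = 0.3,
    timepoints: Sequence[int] = (3, 6),
    ref_sd: float = 0.05,
    noise_sd: float = 0.1,
) -> QpcrPlan:
    """Build a Cq plan whose planted directions follow a regulation
    fixture: up genes get ``up_fold`` at every treated timepoint, down
    genes ``down_fold``, all others 1.0."""
    folds: dict[str, dict[str, dict[int, float]]] = {}
    for gene in universe:
        folds[gene] = {}
        for hormone, dirs in regulation.items():
            if gene in dirs.get("up", frozenset()):
                f = up_fold
            elif gene in dirs.get("down", frozenset()):
                f = down_fold
            else:
                f = 1.0
            folds[gene][hormone] = {t: f for t in timepoints}
    return QpcrPlan(folds=folds, ref_sd=ref_sd, noise_sd=noise_sd)


def gen_qpcr(plan: QpcrPlan, seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format triplicate Cq table from a plan.

    Per replicate, reference Cq values are baselines (20 and 21 cycles)
    plus Normal(0, ref_sd); the target Cq at timepoint t is the gene's
    baseline minus log2(fold_t) plus Normal(0, noise_sd). Deterministic
    given the seed; rows are emitted gene × hormone × timepoint ×
    replicate in sorted order.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(plan.folds):
        base = float(rng.uniform(24.0, 30.0))
        for hormone in sorted(plan.folds[gene]):
            per_t = dict(plan.folds[gene][hormone])
            per_t.setdefault(0, 1.0)
            for t in sorted(per_t):
                fold = per_t[t]
                for rep in range(1, plan.n_replicates + 1):
                    ref1 = 20.0 + float(rng.normal(0.0, plan.ref_sd)) if plan.ref_sd else 20.0
                    ref2 = 21.0 + float(rng.normal(0.0, plan.ref_sd)) if plan.ref_sd else 21.0
                    noise = float(rng.normal(0.0, plan.noise_sd)) if plan.noise_sd else 0.0
                    cq_t = base - math.log2(fold) + noise
                    rows.append(
                        {
                            "gene": gene,
                            "hormone": hormone,
                            "timepoint": t,
                            "replicate": rep,
                            "cq_target": cq_t,
                            "cq_ref1": ref1,
                            "cq_ref2": ref2,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count matrices


def gen_count_matrix(
    true_expression: pd.DataFrame,
    lengths_bp: Mapping[str, int],
    library_sizes: Mapping[str, int],
    seed: int = 0,
):
    """Poisson read counts from true expression levels.

    counts ~ Poisson(expr × length_kb × library_millions), so RPKM on the
    output is an unbiased estimator of the input expression.
    """
    from .expression import CountMatrix

    genes = tuple(true_expression.index)
    samples = tuple(true_expression.columns)
    lengths = np.array([lengths_bp[g] for g in genes], dtype=float)
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    lam = (
        true_expression.to_numpy(float)
        * (lengths[:, None] / 1e3)
        * (libs[None, :] / 1e6)
    )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return CountMatrix(
        genes=genes,
        samples=samples,
        counts=counts,
        lengths_bp=lengths,
        mapped_totals=libs,
    )


# ---------------------------------------------------------------------------
# Subgroup placement benchmark


@dataclass
class SubgroupBenchmark:
    """Synthetic reference/query domain sets with planted subgroup truth.

    The reference sequences stand in for the labeled Arabidopsis WRKY
    domains used to anchor subgroup clades; they are synthetic (prototype
    per subgroup plus random substitutions), not real At sequences.
    """

    sequences: dict[str, str]
    reference_labels: dict[str, str]
    query_truth: dict[str, str]


def gen_subgroup_benchmark(
    subgroups: Sequence[str] = ("IIa", "IIb", "IIc", "IId", "IIe"),
    n_refs: int = 3,
    n_queries: int = 2,
    domain_len: int = 60,
    mut_subgroup: int = 18,
    mut_ref: int = 4,
    mut_query: int = 6,
    seed: int = 0,
) -> SubgroupBenchmark:
    """Plant subgroup structure as a two-level star phylogeny: subgroup
    prototypes diverge from a common ancestral domain by ``mut_subgroup``
    substitutions; references and queries diverge from their prototype by
    ``mut_ref`` / ``mut_query`` substitutions."""
    rng = np.random.default_rng(seed)
    aa = list(AA20)

    def mutate(seq: str, n_mut: int) -> str:
        s = list(seq)
        pos = rng.choice(len(s), size=n_mut, replace=False)
        for p in pos:
            choices = [c for c in aa if c != s[p]]
            s[p] = choices[rng.integers(0, len(choices))]
        return "".join(s)

    sequences: dict[str, str] = {}
    ref_labels: dict[str, str] = {}
    query_truth: dict[str, str] = {}
    ancestor = "".join(rng.choice(aa, size=domain_len))
    for sg in subgroups:
        proto = mutate(ancestor, mut_subgroup)
        for r in range(n_refs):
            rid = f"REF_{sg}_{r + 1}"
            sequences[rid] = mutate(proto, mut_ref)
            ref_labels[rid] = sg
        for q in range(n_queries):
            qid = f"Q_{sg}_{q + 1}"
            sequences[qid] = mutate(proto, mut_query)
            query_truth[qid] = sg
    return SubgroupBenchmark(
        sequences=sequences,
        reference_labels=ref_labels,
        query_truth=query_truth,
    )
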