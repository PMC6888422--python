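"""WRKY domain detection, zinc-finger typing, and family-table construction.

A WRKY domain is recognized by its N-terminal heptapeptide (WRKYGQK or a
variant differing at the sixth position) followed, within a bounded window,
by a zinc-finger-like arrangement C-Xa-C-Xb-H-X-Z whose spacings a and b
fall in narrow ranges. The fourth coordinating residue Z distinguishes the
C-C-H-H type (groups I/II) from the C-C-H-C type diagnostic of group III,
with rarer variants (Z = T, L, V, Y, S) also occurring.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_LABEL_RE = re.compile(r"^C-X(\d+)-C-X(\d+)-HX([A-Z])$")


@dataclass(frozen=True)
class DomainGrammar:
    """The motif grammar: heptapeptide consensus set plus zinc-finger
    spacing constraints.

    ``finger_search_window`` is the number of residues downstream of the
    heptapeptide end within which the first cysteine of the finger must
    start. Spacing ``a`` counts residues between the two cysteines,
    ``b`` between the second cysteine and the histidine.
    """

    heptapeptides: tuple[str, ...] = ("WRKYGQK", "WRKYGKK", "WRKYGHK")
    finger_search_window: int = 100
    a_range: tuple[int, int] = (3, 7)
    b_range: tuple[int, int] = (22, 23)

    def __post_init__(self) -> None:
        if self.a_range[0] > self.a_range[1] or self.b_range[0] > self.b_range[1]:
            raise ValueError("spacing ranges must be non-empty")
        if self.finger_search_window < self.b_range[1] + self.a_range[1] + 4:
            raise ValueError("search window too small for the spacing ranges")


@dataclass(frozen=True)
class ZincFingerPattern:
    """Positions (0-based) of the four coordinating residues C, C, H, Z
    with Z at ``h1_pos + 2``."""

    c1_pos: int
    c2_pos: int
    h1_pos: int
    z_pos: int
    z_residue: str

    @property
    def a(self) -> int:
        return self.c2_pos - self.c1_pos - 1

    @property
    def b(self) -> int:
        return self.h1_pos - self.c2_pos - 1


@dataclass(frozen=True)
class DomainHit:
    hepta_start: int
    hepta_seq: str
    finger: Optional[ZincFingerPattern] = None


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    length_aa: int
    hits: tuple[DomainHit, ...]
    zinc_type: str

    @property
    def n_domains(self) -> int:
        return len(self.hits)

    @property
    def fingers(self) -> tuple[ZincFingerPattern, ...]:
        return tuple(h.finger for h in self.hits if h.finger is not None)


@dataclass
class FamilyMember:
    annotation: DomainAnnotation
    sequence: str


@dataclass
class FamilyTable:
    """Non-redundant family: representative members after greedy clustering."""

    members: list[FamilyMember]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.annotation.protein_id for m in self.members]


def scan_heptapeptide(seq: str, grammar: DomainGrammar = DomainGrammar()) -> list[DomainHit]:
    """Report every 7-mer window of ``seq`` matching a grammar consensus,
    left to right; overlapping matches are all reported.

    Non-standard characters draw a warning; windows containing them never
    match.
    """
    bad = set(seq) - set(AA20)
    if bad:
        warnings.warn(
            f"non-standard residues {sorted(bad)} in sequence; positions skipped"
        )
    consensi = set(grammar.heptapeptides)
    hits = []
    for i in range(len(seq) - 6):
        window = seq[i : i + 7]
        if window in consensi:
            hits.append(DomainHit(hepta_start=i, hepta_seq=window))
    return hits


def extract_zinc_finger(
    seq: str, hit: DomainHit, grammar: DomainGrammar = DomainGrammar()
) -> Optional[ZincFingerPattern]:
    """Find the first zinc-finger arrangement downstream of a heptapeptide.

    The window for the first cysteine spans ``finger_search_window``
    residues after the heptapeptide end. Candidates are ordered by smallest
    c1 position, then smallest spacing a, then smallest b; the first
    arrangement with C at both cysteine slots, H at the histidine slot and
    at least two further residues wins. Absence is returned as ``None``.
    """
    start = hit.hepta_start + 7
    stop = min(len(seq), start + grammar.finger_search_window)
    a_lo, a_hi = grammar.a_range
    b_lo, b_hi = grammar.b_range
    for c1 in range(start, stop):
        if seq[c1] != "C":
            continue
        for a in range(a_lo, a_hi + 1):
            c2 = c1 + a + 1
            if c2 >= len(seq) or seq[c2] != "C":
                continue
            for b in range(b_lo, b_hi + 1):
                h1 = c2 + b + 1
                z = h1 + 2
                if z >= len(seq) or seq[h1] != "H":
                    continue
                return ZincFingerPattern(
                    c1_pos=c1, c2_pos=c2, h1_pos=h1, z_pos=z, z_residue=seq[z]
                )
    return None


def format_pattern(p: ZincFingerPattern) -> str:
    """Render a finger as its label, e.g. ``C-X5-C-X23-HXH``."""
    return f"C-X{p.a}-C-X{p.b}-HX{p.z_residue}"


def parse_pattern_label(label: str) -> tuple[int, int, str]:
    """Parse a label ``C-X{a}-C-X{b}-HX{Z}`` into ``(a, b, z)``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"bad zinc-finger label: {label!r}")
    return int(m.group(1)), int(m.group(2)), m.group(3)


def classify_zinc_type(patterns: Sequence[ZincFingerPattern]) -> str:
    """Collapse a protein's finger patterns to a single type label.

    No finger detected → ``undetected``. Otherwise the C-terminal (last)
    domain's fourth residue decides: H → ``C-C-H-H``, C → ``C-C-H-C``,
    any other residue Z → the variant label ``C-C-H-Z``.
    """
    if not patterns:
        return "undetected"
    z = patterns[-1].z_residue
    return f"C-C-H-{z}"


def annotate_protein(rec, grammar: DomainGrammar = DomainGrammar()) -> DomainAnnotation:
    """Scan a protein record for heptapeptides, extract each domain's
    finger, and assign the zinc type."""
    seq = rec.sequence
    hits = [
        DomainHit(h.hepta_start, h.hepta_seq, extract_zinc_finger(seq, h, grammar))
        for h in scan_heptapeptide(seq, grammar)
    ]
    fingers = [h.finger for h in hits if h.finger is not None]
    return DomainAnnotation(
        protein_id=rec.id,
        length_aa=len(seq),
        hits=tuple(hits),
        zinc_type=classify_zinc_type(fingers),
    )


def dedupe_members(
    annotated: Sequence[tuple[DomainAnnotation, str]],
    identity_threshold: float = 0.95,
    align=None,
) -> FamilyTable:
    """Greedy redundancy removal, CD-HIT style.

    Candidates are sorted by length descending (ties by id); each joins the
    first retained representative whose global-alignment identity is at or
    above the threshold, else becomes a new representative. ``align`` may
    inject an identity function ``(a, b) -> float``; the default uses
    :func:`sawrky.classify.global_align`.
    """
    if align is None:
        from .classify import global_align

        def align(a, b):  # noqa: F811 - default identity function
            return global_align(a, b)[1]

    order = sorted(
        annotated, key=lambda t: (-len(t[1]), t[0].protein_id)
    )
    reps: list[FamilyMember] = []
    for ann, seq in order:
        if ann.n_domains == 0:
            continue  # not a family member without a heptapeptide
        placed = False
        for rep in reps:
            if align(rep.sequence, seq) >= identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(FamilyMember(annotation=ann, sequence=seq))
    return FamilyTable(members=reps)


def read_hmmer_domtbl(path, evalue_max: float = 1e-5) -> set[str]:
    """Read target names from an HMMER3 ``--domtblout`` table, keeping rows
    with full-sequence E-value at or below ``evalue_max``.

    Plumbing for pre-filtering candidate proteins by an externally run
    profile search; no HMM scoring happens here.
    """
    keep: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            try:
                evalue = float(parts[6])
            except (IndexError, ValueError):
                raise ValueError(f"malformed domtblout line: {line!r}")
            if evalue <= evalue_max:
                keep.add(parts[0])
    return keep
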