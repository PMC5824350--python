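"""Sequence I/O and alphabet utilities for mature-miRNA panels.

Mature miRNAs are stored canonically as RNA (A/C/G/U); primer work happens
on the DNA view (A/C/G/T).  Family structure is derived from pairwise
global-alignment identity: miRNA family members are near-identical, often
differing by a single nucleotide, and the design engine switches strategy
once similarity crosses a threshold (90% by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

_RNA_BASES = frozenset("ACGU")
_DNA_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC nucleotide codes and their expansions (DNA alphabet).
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

MIN_MIRNA_LEN = 16
MAX_MIRNA_LEN = 30


class SequenceError(ValueError):
    """Raised for malformed sequences or panels."""


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: identifier plus canonical RNA sequence.

    Mature miRNAs are 18-25 nt; a small margin (16-30) is tolerated so that
    slightly trimmed or extended annotations still load, anything outside
    is rejected.
    """

    id: str
    sequence: str  # RNA alphabet, uppercase

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not (MIN_MIRNA_LEN <= len(seq) <= MAX_MIRNA_LEN):
            raise SequenceError(
                f"{self.id}: length {len(seq)} nt outside [{MIN_MIRNA_LEN}, "
                f"{MAX_MIRNA_LEN}] (mature miRNAs are 18-25 nt)"
            )
        bad = set(seq) - _RNA_BASES
        if bad:
            raise SequenceError(f"{self.id}: ambiguous/invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dna(self) -> str:
        """DNA view of the mature sequence (U -> T)."""
        return self.sequence.replace("U", "T")


@dataclass
class SequencePanel:
    """A collection of miRNAs with a family assignment (id -> family label)."""

    members: list[MiRNA] = field(default_factory=list)
    family_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate ids in panel: {dup}")
        for m in self.members:
            self.family_assignment.setdefault(m.id, m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def get(self, mirna_id: str) -> MiRNA:
        for m in self.members:
            if m.id == mirna_id:
                return m
        raise KeyError(mirna_id)

    def family_of(self, mirna_id: str) -> list[MiRNA]:
        label = self.family_assignment[mirna_id]
        return [m for m in self.members if self.family_assignment[m.id] == label]


def parse_fasta(path) -> SequencePanel:
    """Read a FASTA file of mature miRNAs into a panel.

    U and T are both accepted; sequences are stored canonically as RNA.
    Duplicate record ids are an error.  An empty file yields an empty panel
    (with a warning), not an error.
    """
    members: list[MiRNA] = []
    seen: set[str] = set()
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in seen:
                raise SequenceError(f"duplicate FASTA id: {record.id}")
            seen.add(record.id)
            members.append(MiRNA(record.id, str(record.seq)))
    except ValueError as exc:  # Biopython parse failure
        raise SequenceError(f"malformed FASTA in {path}: {exc}") from exc
    if not members:
        with open(path) as fh:
            if fh.read().strip():
                raise SequenceError(f"malformed FASTA in {path}: no records found")
        logger.warning("empty FASTA file: %s", path)
    return SequencePanel(members=members)


def write_fasta(panel: SequencePanel, path, alphabet: str = "rna") -> None:
    with open(path, "w") as fh:
        for m in panel:
            seq = m.sequence if alphabet == "rna" else m.dna
            fh.write(f">{m.id}\n{seq}\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an unambiguous DNA string."""
    seq = seq.upper()
    bad = set(seq) - _DNA_BASES
    if bad:
        raise SequenceError(f"cannot reverse-complement ambiguous bases {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(pattern: str) -> list[str]:
    """All concrete DNA expansions of an IUPAC pattern, lexicographically.

    The number of expansions is the product of the per-position degeneracies
    (e.g. the 5'-tail pattern CGWTSSRCRC has five 2-fold positions -> 32).
    """
    pattern = pattern.upper()
    choices = []
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise SequenceError(f"invalid IUPAC code {ch!r} in {pattern!r}")
        choices.append(sorted(IUPAC_CODES[ch]))
    return ["".join(p) for p in itertools.product(*choices)]


def _global_alignment(a: str, b: str):
    """One optimal global alignment maximizing matches.

    Match +1, mismatch 0; gaps carry a tiny penalty so that among
    match-equivalent alignments the gapless/shortest one is chosen
    deterministically.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1e-3
    aligner.extend_gap_score = -1e-3
    return aligner.align(a, b)[0]


def _aligned_columns(a: str, b: str):
    """Yield (col_a, col_b, pos_a) per alignment column; '-' marks a gap.

    pos_a is the 0-based coordinate on `a` (for a-gap columns, the index of
    the next `a` base, i.e. the insertion point).
    """
    aln = _global_alignment(a, b)
    sa, sb = str(aln[0]), str(aln[1])
    ia = 0
    for ca, cb in zip(sa, sb):
        yield ca, cb, ia
        if ca != "-":
            ia += 1


def pairwise_similarity(a: MiRNA | str, b: MiRNA | str) -> float:
    """Percent identity of the optimal global alignment.

    Matches divided by alignment length, in [0, 100].  Two members of a
    single-nucleotide family (22-23 nt) land at >= 90%, the regime in which
    the specific-FR design system takes over.
    """
    sa = a.sequence if isinstance(a, MiRNA) else a
    sb = b.sequence if isinstance(b, MiRNA) else b
    if not sa or not sb:
        raise SequenceError("cannot compare empty sequences")
    if sa == sb:
        return 100.0
    cols = list(_aligned_columns(sa, sb))
    matches = sum(1 for ca, cb, _ in cols if ca == cb and ca != "-")
    return 100.0 * matches / len(cols)


def diff_positions(a: MiRNA | str, b: MiRNA | str) -> list[int]:
    """0-based positions (on `a`) where the global alignment differs.

    Gap columns count as differences.  Equal-length inputs compare
    column-by-column without gaps.
    """
    sa = a.sequence if isinstance(a, MiRNA) else a
    sb = b.sequence if isinstance(b, MiRNA) else b
    if len(sa) == len(sb):
        return [i for i, (x, y) in enumerate(zip(sa, sb)) if x != y]
    out: list[int] = []
    for ca, cb, pos in _aligned_columns(sa, sb):
        if ca != cb:
            out.append(min(pos, len(sa) - 1))
    return sorted(set(out))


def group_families(panel: SequencePanel, threshold: float = 90.0) -> SequencePanel:
    """Single-linkage family grouping at a similarity threshold.

    Returns a new panel whose family labels are the lexicographically
    smallest member id of each group, so the partition is invariant under
    input permutation.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    members = panel.members
    parent = {m.id: m.id for m in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # keep the lexicographically smaller id as the root/label
            lo, hi = sorted((rx, ry))
            parent[hi] = lo

    for m1, m2 in itertools.combinations(members, 2):
        if pairwise_similarity(m1, m2) >= threshold:
            union(m1.id, m2.id)

    assignment = {m.id: find(m.id) for m in members}
    return SequencePanel(members=list(members), family_assignment=assignment)


def max_similarity(target: MiRNA, panel: SequencePanel) -> float:
    """Highest pairwise similarity of `target` to any other panel member."""
    best = 0.0
    for m in panel:
        if m.id == target.id:
            continue
        best = max(best, pairwise_similarity(target, m))
    return best


def panel_report(panel: SequencePanel) -> str:
    """Tab-separated panel summary: id, length, family, max similarity."""
    lines = ["id\tlength\tfamily\tmax_similarity"]
    for m in panel:
        lines.append(
            f"{m.id}\t{len(m)}\t{panel.family_assignment[m.id]}\t"
            f"{max_similarity(m, panel):.2f}"
        )
    return "\n".join(lines) + "\n"
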