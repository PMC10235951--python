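"""Genetic-code-aware sequence primitives.

The euplotid nuclear code (NCBI translation table 10) keeps UAA/UAG as the
only stop codons and reassigns UGA to cysteine.  Because stop codons inside
*Euplotes* coding sequences direct +1/+2 ribosomal frameshifting rather than
termination, the natural unit of coding sequence here is the *maximal
stop-free codon run* in a fixed frame, not an ATG-anchored ORF: frameshift
joins occur exactly at the stop codons that bound these runs, and the
definition is robust to 5'-truncated transcripts.

Coordinates are 0-based, half-open, always on the oriented (sense-strand)
transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "GeneticCode",
    "EUPLOTID",
    "STANDARD",
    "Transcript",
    "OrfSegment",
    "translate",
    "find_orfs",
    "revcomp",
    "orient_transcript",
    "read_fasta",
    "write_fasta",
    "read_orthogroups",
    "write_orthogroups",
    "read_tree",
]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table; stops are '*'."""

    name: str
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(name=table.names[0], codon_to_aa=mapping)

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; codons containing N yield 'X'."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]


EUPLOTID = GeneticCode.from_ncbi(10)  # UGA = Cys; TAA/TAG remain stops
STANDARD = GeneticCode.from_ncbi(1)


@dataclass
class Transcript:
    """One oriented nucleotide sequence from a transcriptome assembly."""

    id: str
    species: str
    seq: str
    orientation: str = "undetermined"  # sense | antisense | undetermined
    orientation_method: str = "none"  # polyA | polyT | alignment | none
    was_reverse_complemented: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id}: empty sequence")
        _check_alphabet(self.seq)

    @property
    def at_fraction(self) -> float:
        informative = len(self.seq) - self.seq.count("N")
        if informative == 0:
            return 0.0
        return (self.seq.count("A") + self.seq.count("T")) / informative

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class OrfSegment:
    """Maximal stop-free in-frame codon run, half-open nt coordinates."""

    start: int
    end: int
    frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if (self.end - self.start) % 3:
            raise ValueError("segment length must be a codon multiple")
        if self.start % 3 != self.frame:
            raise ValueError("frame must equal start mod 3")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    def protein(self, seq: str, code: GeneticCode = EUPLOTID) -> str:
        return translate(seq[self.start : self.end], code, 0)


def translate(seq: str, code: GeneticCode = EUPLOTID, frame: int = 0) -> str:
    """Translate from ``frame``; '*' marks stops, N-containing codons give 'X'.

    The incomplete trailing codon is dropped.
    """
    _check_alphabet(seq)
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(seq) < frame + 3:
        raise ValueError("sequence too short for requested frame")
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(code.aa(seq[i : i + 3]))
    return "".join(out)


def find_orfs(seq: str, code: GeneticCode = EUPLOTID) -> list[OrfSegment]:
    """All maximal stop-free codon runs in the three forward frames.

    N-containing codons terminate runs (they cannot be scored as coding).
    Sorted by length descending, then by (start, frame) for determinism.
    """
    _check_alphabet(seq)
    segments: list[OrfSegment] = []
    for frame in range(3):
        run_start: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if code.is_stop(codon) or "N" in codon:
                if run_start is not None:
                    segments.append(OrfSegment(run_start, i, frame))
                    run_start = None
            elif run_start is None:
                run_start = i
            i += 3
        if run_start is not None:
            segments.append(OrfSegment(run_start, i, frame))
    segments.sort(key=lambda s: (-(s.end - s.start), s.start, s.frame))
    return segments


def revcomp(seq: str) -> str:
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _trailing_run(seq: str, base: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def _leading_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def _indel_count_vs_ortholog(seq: str, ortholog_cds: str) -> tuple[int, float]:
    """(gap count, -score) of the longest ORF aligned locally to an ortholog
    CDS; the negated score breaks indel-count ties toward the orientation
    that actually aligns."""
    from Bio import Align

    orfs = find_orfs(seq)
    if not orfs:
        return (10**9, 0.0)
    longest = seq[orfs[0].start : orfs[0].end]
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    try:
        aln = aligner.align(longest, ortholog_cds)[0]
    except (IndexError, ValueError):
        return (10**9, 0.0)
    a, b = str(aln[0]), str(aln[1])
    return (a.count("-") + b.count("-"), -float(aln.score))


def orient_transcript(
    t: Transcript,
    ortholog_cds: str | None = None,
    min_run: int = 10,
) -> Transcript:
    """Resolve sense-strand orientation of a raw transcript.

    A terminal polyA run (>= ``min_run`` consecutive A at the 3' end) marks the
    sense strand; a leading polyT run marks the antisense strand, in which case
    the stored sequence is reverse complemented.  Both signals together are
    contradictory and leave the transcript undetermined.  Without either tail
    (truncated transcripts), the orientation minimising indels in the longest
    ORF aligned to a provided ortholog CDS is chosen.  Idempotent on already
    oriented transcripts.
    """
    if t.orientation != "undetermined" and t.orientation_method != "none":
        return t
    has_polya = _trailing_run(t.seq, "A") >= min_run
    has_polyt = _leading_run(t.seq, "T") >= min_run
    if has_polya and has_polyt:
        warnings.warn(
            f"transcript {t.id}: both polyA tail and leading polyT run; "
            "orientation left undetermined"
        )
        return replace(t, orientation="undetermined", orientation_method="none")
    if has_polya:
        return replace(t, orientation="sense", orientation_method="polyA")
    if has_polyt:
        return replace(
            t,
            seq=revcomp(t.seq),
            orientation="antisense",
            orientation_method="polyT",
            was_reverse_complemented=True,
        )
    if ortholog_cds is not None:
        fwd = _indel_count_vs_ortholog(t.seq, ortholog_cds)
        rev = _indel_count_vs_ortholog(revcomp(t.seq), ortholog_cds)
        if rev < fwd:
            return replace(
                t,
                seq=revcomp(t.seq),
                orientation="antisense",
                orientation_method="alignment",
                was_reverse_complemented=True,
            )
        if fwd <= rev and fwd < 10**9:
            return replace(t, orientation="sense", orientation_method="alignment")
    return replace(t, orientation="undetermined", orientation_method="none")


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; ids preserved verbatim."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_orthogroups(path: str | Path) -> pd.DataFrame:
    """Orthogroup membership table: orthogroup_id, species, transcript_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"orthogroup_id", "species", "transcript_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orthogroup table missing columns: {sorted(missing)}")
    return df


def write_orthogroups(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tree(path_or_string: str | Path) -> dendropy.Tree:
    """Rooted newick tree with branch lengths (synonymous subs/site)."""
    source = str(path_or_string)
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class TreeNode:
    index: int
    name: str
    parent: int  # -1 for root
    length: float
    is_leaf: bool


class TreeTable:
    """Flat preorder view of a rooted tree, with stable node names.

    Leaves keep their taxon labels (spaces replaced by underscores);
    internal nodes are named N1, N2, ... in preorder, so the same newick
    string always yields the same branch identifiers.
    """

    def __init__(self, tree: dendropy.Tree):
        self.nodes: list[TreeNode] = []
        index_of: dict[int, int] = {}
        n_internal = 0
        for node in tree.preorder_node_iter():
            parent = index_of[id(node.parent_node)] if node.parent_node else -1
            if node.is_leaf():
                name = node.taxon.label.replace(" ", "_")
            else:
                n_internal += 1
                name = f"N{n_internal}"
            idx = len(self.nodes)
            index_of[id(node)] = idx
            self.nodes.append(
                TreeNode(
                    index=idx,
                    name=name,
                    parent=parent,
                    length=float(node.edge.length or 0.0),
                    is_leaf=node.is_leaf(),
                )
            )
        self.index_by_name = {n.name: n.index for n in self.nodes}

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent >= 0)

    def branches(self):
        """Every non-root node, i.e. the branch from its parent."""
        return (n for n in self.nodes if n.parent >= 0)

    def children(self, index: int) -> list[int]:
        return [n.index for n in self.nodes if n.parent == index]
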