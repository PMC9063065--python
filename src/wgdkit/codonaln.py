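"""Codon-aware pairwise alignment.

Aligns two coding sequences by globally aligning their translations
(BLOSUM62, affine gaps) and back-translating the gapped proteins, so that
gaps always fall on codon boundaries and the reading frame is preserved.
Inputs must be clean ORFs; frameshift- or stop-tolerant alignment is out
of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from . import seqio
from .seqio import CodingSequence


@dataclass(frozen=True)
class CodonAlignment:
    """Two equal-length gapped in-frame codon strings.

    Gaps occur in runs whose length is divisible by 3; stripping gaps
    recovers the source coding sequences.
    """

    id_1: str
    id_2: str
    codon_str_1: str
    codon_str_2: str

    def __post_init__(self) -> None:
        s1, s2 = self.codon_str_1, self.codon_str_2
        if len(s1) != len(s2):
            raise ValueError(f"{self.id_1}/{self.id_2}: aligned strings differ in length")
        if len(s1) % 3 != 0:
            raise ValueError(f"{self.id_1}/{self.id_2}: aligned length not divisible by 3")
        for s, sid in ((s1, self.id_1), (s2, self.id_2)):
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(f"{sid}: gap breaks codon frame at column {i + 1}")

    @property
    def n_codon_columns(self) -> int:
        """Number of codon columns where both sequences are ungapped."""
        n = 0
        for i in range(0, len(self.codon_str_1), 3):
            if self.codon_str_1[i] != "-" and self.codon_str_2[i] != "-":
                n += 1
        return n

    def ungapped_codon_pairs(self) -> list[tuple[str, str]]:
        """Codon pairs at columns where neither sequence is gapped."""
        pairs = []
        for i in range(0, len(self.codon_str_1), 3):
            c1 = self.codon_str_1[i : i + 3]
            c2 = self.codon_str_2[i : i + 3]
            if "-" not in c1 and "-" not in c2:
                pairs.append((c1, c2))
        return pairs


def align_codons(cds1: CodingSequence, cds2: CodingSequence) -> CodonAlignment:
    """Codon-aware global alignment of two coding sequences.

    Equivalent to back-translating the global BLOSUM62 protein alignment
    of the two translations; deterministic for given inputs.
    """
    from .homology import align_pair  # local import: homology also imports seqio

    p1 = seqio.translate(cds1)
    p2 = seqio.translate(cds2)
    _, (g1, g2) = align_pair(p1, p2, mode="global")
    return seqio.backtranslate_alignment(g1, g2, cds1, cds2)


def write_alignments(alignments: Iterable[CodonAlignment], path: str | Path) -> None:
    """Write codon alignments as concatenated 2-record FASTA blocks."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f">{aln.id_1}\n{aln.codon_str_1}\n>{aln.id_2}\n{aln.codon_str_2}\n")


def read_alignments(path: str | Path) -> list[CodonAlignment]:
    """Read codon alignments written by :func:`write_alignments`."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: expected blocks of two FASTA records")
    out = []
    for i in range(0, len(lines), 4):
        h1, s1, h2, s2 = lines[i : i + 4]
        if not (h1.startswith(">") and h2.startswith(">")):
            raise ValueError(f"{path}: malformed block at line {i + 1}")
        out.append(CodonAlignment(h1[1:].split()[0], h2[1:].split()[0], s1.upper(), s2.upper()))
    return out
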