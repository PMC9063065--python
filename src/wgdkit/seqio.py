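"""Coding-sequence and protein I/O.

Reads and writes FASTA, validates coding sequences against the standard
genetic code, translates, and back-translates gapped protein alignments
into codon alignments.  Every other module builds on the two record types
defined here.

Only the standard nuclear genetic code is supported: the comparative
analyses this package implements operate on predicted nuclear gene models.
Ambiguity codes (``N``, ``X``) are rejected on load rather than silently
masked, because synonymous/non-synonymous site counting is undefined on
ambiguous codons; ``drop_invalid=True`` skips offending records with a
warning instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_BASES = "TCAG"
#: Standard genetic code, NCBI translation table 1 ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
        16 * i + 4 * j + k
    ]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c, a in GENETIC_CODE.items() if a != "*"))

_NT_ALPHABET = frozenset("ACGT")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SeqIOError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame protein-coding nucleotide sequence.

    Invariants: length divisible by 3 and >= 3, uppercase ``ACGT`` only,
    no internal stop codon.  A terminal stop codon is trimmed on
    construction via :func:`read_fasta` / :meth:`from_nt`.
    """

    id: str
    nt: str

    def __post_init__(self) -> None:
        _validate_cds(self.id, self.nt)

    @classmethod
    def from_nt(cls, id: str, nt: str) -> "CodingSequence":
        """Build from raw nucleotides, uppercasing and trimming a terminal stop."""
        nt = nt.upper()
        if len(nt) % 3 == 0 and len(nt) >= 3 and nt[-3:] in STOP_CODONS:
            nt = nt[:-3]
        return cls(id, nt)

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence over the 20 standard residues (no gaps)."""

    id: str
    aa: str

    def __post_init__(self) -> None:
        if not self.aa:
            raise SeqIOError(f"protein record {self.id!r} is empty")
        bad = next((i for i, c in enumerate(self.aa) if c not in _AA_ALPHABET), None)
        if bad is not None:
            raise SeqIOError(
                f"protein record {self.id!r}: illegal character {self.aa[bad]!r} "
                f"at position {bad + 1}"
            )


def _validate_cds(id: str, nt: str) -> None:
    if not nt:
        raise SeqIOError(f"coding sequence {id!r} is empty")
    bad = next((i for i, c in enumerate(nt) if c not in _NT_ALPHABET), None)
    if bad is not None:
        raise SeqIOError(
            f"coding sequence {id!r}: illegal character {nt[bad]!r} at position {bad + 1}"
        )
    if len(nt) % 3 != 0:
        raise SeqIOError(f"coding sequence {id!r}: length {len(nt)} not divisible by 3")
    if len(nt) < 3:
        raise SeqIOError(f"coding sequence {id!r}: shorter than one codon")
    for ci in range(len(nt) // 3):
        if GENETIC_CODE[nt[3 * ci : 3 * ci + 3]] == "*":
            raise SeqIOError(f"coding sequence {id!r}: internal stop codon at codon {ci + 1}")


def read_fasta(
    path: str | Path, alphabet: str, drop_invalid: bool = False
) -> list[CodingSequence] | list[ProteinRecord]:
    """Read a FASTA file into validated records.

    Parameters
    ----------
    path:
        FASTA file with one or more records.
    alphabet:
        ``"nt"`` for coding sequences (terminal stop trimmed) or ``"aa"``
        for proteins.
    drop_invalid:
        Skip records failing validation (with a logged warning) instead of
        raising.

    Raises
    ------
    SeqIOError
        On duplicate ids, illegal characters, frame violations or internal
        stops (unless ``drop_invalid``).
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        try:
            if alphabet == "nt":
                records.append(CodingSequence.from_nt(rec.id, raw))
            else:
                records.append(ProteinRecord(rec.id, raw))
        except SeqIOError as exc:
            if drop_invalid:
                log.warning("dropping record %s: %s", rec.id, exc)
                warnings.warn(f"dropping record {rec.id}: {exc}", stacklevel=2)
            else:
                raise
    if n_parsed == 0:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[CodingSequence | ProteinRecord], path: str | Path, width: int = 80
) -> None:
    """Write records as multi-line FASTA (``width`` columns per line)."""
    seqs = []
    for r in records:
        s = r.nt if isinstance(r, CodingSequence) else r.aa
        seqs.append(SeqRecord(Seq(s), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def translate(cds: CodingSequence) -> ProteinRecord:
    """Translate a valid coding sequence under the standard genetic code."""
    aa = []
    for ci in range(cds.n_codons):
        res = GENETIC_CODE[cds.nt[3 * ci : 3 * ci + 3]]
        if res == "*":  # unreachable for a validated CodingSequence
            raise SeqIOError(f"{cds.id!r}: internal stop codon at codon {ci + 1}")
        aa.append(res)
    return ProteinRecord(cds.id, "".join(aa))


def backtranslate_alignment(
    aln_aa_1: str,
    aln_aa_2: str,
    cds1: CodingSequence,
    cds2: CodingSequence,
):
    """Expand a gapped protein alignment back to its source codons.

    Each residue is replaced by its source codon and each ``-`` by ``---``,
    yielding two equal-length gapped codon strings.  The ungapped protein
    strings must equal the translations of the supplied coding sequences.

    Returns
    -------
    CodonAlignment
    """
    from .codonaln import CodonAlignment

    if len(aln_aa_1) != len(aln_aa_2):
        raise SeqIOError("gapped protein strings differ in length")
    out = []
    for gapped, cds in ((aln_aa_1, cds1), (aln_aa_2, cds2)):
        prot = translate(cds).aa
        pos = 0
        chunks = []
        for col, res in enumerate(gapped):
            if res == "-":
                chunks.append("---")
                continue
            if pos >= len(prot) or prot[pos] != res:
                raise SeqIOError(
                    f"{cds.id!r}: residue {res!r} at alignment column {col + 1} "
                    f"does not match translated CDS"
                )
            chunks.append(cds.nt[3 * pos : 3 * pos + 3])
            pos += 1
        if pos != len(prot):
            raise SeqIOError(f"{cds.id!r}: alignment uses {pos} residues, CDS has {len(prot)}")
        out.append("".join(chunks))
    return CodonAlignment(cds1.id, cds2.id, out[0], out[1])


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Read a two-column TSV manifest mapping species label -> FASTA path."""
    mapping: dict[str, Path] = {}
    base = Path(path).parent
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SeqIOError(f"manifest {path}, line {ln}: expected 2 tab-separated columns")
        label, p = parts[0].strip(), Path(parts[1].strip())
        if label in mapping:
            raise SeqIOError(f"manifest {path}: duplicate label {label!r}")
        mapping[label] = p if p.is_absolute() else base / p
    return mapping
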