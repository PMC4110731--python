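"""Sequence data model: mature miRNAs and per-gene region sequences.

All sequences are handled as RNA, 5'->3', over the alphabet {A,C,G,U} for
miRNAs and {A,C,G,U,N} for gene regions (N marks masked genomic bases and
never participates in a base pair).  DNA input is accepted and transcribed
on the fly (T->U); promoter sequences are treated as the transcribed-sense
strand so that scanning logic is uniform across regions.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "RegionKind",
    "MiRNA",
    "GeneRegions",
    "SequenceError",
    "FastaError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "select_longest_isoform",
    "load_mirnas",
    "load_gene_regions",
]

_MIRNA_ALPHABET = frozenset("ACGU")
_GENE_ALPHABET = frozenset("ACGUN")


class SequenceError(ValueError):
    """A sequence violates the alphabet or length contract."""


class FastaError(ValueError):
    """A FASTA file is malformed; the message carries the offending line."""


class RegionKind(enum.Enum):
    """The four gene regions scanned for target sites."""

    PROMOTER = "promoter"
    UTR5 = "5utr"
    CDS = "cds"
    UTR3 = "3utr"

    def __str__(self) -> str:  # stable serialization name
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "RegionKind":
        try:
            return _REGION_NAMES[name.strip().lower()]
        except KeyError:
            raise SequenceError(
                f"unknown region {name!r}; expected one of "
                f"{sorted(_REGION_NAMES)}"
            ) from None


_REGION_NAMES = {r.value: r for r in RegionKind}
_REGION_NAMES.update({"utr5": RegionKind.UTR5, "utr3": RegionKind.UTR3})

#: Regions in their genomic 5'->3' order; used for deterministic output.
REGION_ORDER = (RegionKind.PROMOTER, RegionKind.UTR5, RegionKind.CDS, RegionKind.UTR3)


def normalize_sequence(raw: str, *, allow_n: bool = True) -> str:
    """Uppercase a nucleotide string and transcribe T->U.

    Parameters
    ----------
    raw:
        Input nucleotide string (RNA or DNA, any case).
    allow_n:
        Whether the ambiguity character N is permitted (gene regions yes,
        miRNAs no).

    Raises
    ------
    SequenceError
        If the input is empty or contains a character outside the alphabet;
        the message names the 1-based offending position.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper().replace("T", "U")
    alphabet = _GENE_ALPHABET if allow_n else _MIRNA_ALPHABET
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise SequenceError(
                f"illegal character {ch!r} at position {pos} "
                f"(allowed: {''.join(sorted(alphabet))})"
            )
    return seq


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3'.  Positions 1-8 of ``sequence`` form the
    extended seed whose pairing to the target defines a seed-match site."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence, allow_n=False)
        if len(seq) < 8:
            raise SequenceError(
                f"miRNA {self.id!r}: length {len(seq)} < 8; the full seed "
                "(positions 1-8) must exist"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Nucleotides 1-8 (5' end)."""
        return self.sequence[:8]


@dataclass
class GeneRegions:
    """Per-gene region sequences; any subset of the four regions may be
    present."""

    gene_id: str
    region_seqs: dict[RegionKind, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_seqs = {
            region: normalize_sequence(seq, allow_n=True)
            for region, seq in self.region_seqs.items()
        }

    def __getitem__(self, region: RegionKind) -> str:
        return self.region_seqs[region]

    def __contains__(self, region: RegionKind) -> bool:
        return region in self.region_seqs


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------
# A deliberately strict reader: the standard parsers silently accept empty
# records and junk before the first header, while the loading contract here
# is to fail with the offending line number.


def read_fasta(path: str | Path | io.TextIOBase) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (id, sequence).

    Multi-line records are concatenated and sequences are normalized
    (uppercase, T->U).  The record id is the full header line after ``>``
    (leading/trailing whitespace stripped).

    Raises
    ------
    FastaError
        On a missing header, an empty record, or an empty file; the message
        names the line number.
    SequenceError
        On an illegal sequence character.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        lines = Path(path).read_text().splitlines()
        name = str(path)

    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FastaError(
                f"{name}: empty record {header!r} at line {header_line}"
            )
        records.append((header, normalize_sequence("".join(chunks))))

    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            header_line = lineno
            chunks = []
            if not header:
                raise FastaError(f"{name}: empty header at line {lineno}")
        else:
            if header is None:
                raise FastaError(
                    f"{name}: sequence before first header at line {lineno}"
                )
            chunks.append(line)
    flush()
    if not records:
        raise FastaError(f"{name}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def select_longest_isoform(records: Iterable[tuple[str, str]]) -> dict[str, str]:
    """Collapse isoforms: keep, per gene, the single longest sequence.

    Ties are broken by the lexicographically smallest sequence so the
    result is independent of input order.
    """
    best: dict[str, str] = {}
    for gene_id, seq in records:
        cur = best.get(gene_id)
        if cur is None or len(seq) > len(cur) or (len(seq) == len(cur) and seq < cur):
            best[gene_id] = seq
    return best


def _split_header(header: str) -> tuple[str, str | None]:
    """First whitespace token is the gene id; an optional ``|region``
    suffix on that token selects the region for combined files."""
    token = header.split()[0]
    if "|" in token:
        gene_id, _, region = token.rpartition("|")
        return gene_id, region
    return token, None


def load_mirnas(path: str | Path) -> list[MiRNA]:
    """Load mature miRNAs from FASTA (first header token is the id)."""
    out = []
    for header, seq in read_fasta(path):
        out.append(MiRNA(id=header.split()[0], sequence=seq))
    return out


def load_gene_regions(
    region_paths: Mapping[RegionKind, str | Path] | None = None,
    combined_path: str | Path | None = None,
) -> dict[str, GeneRegions]:
    """Load per-gene region sequences.

    Either ``region_paths`` maps each region to its own FASTA file, or
    ``combined_path`` names one FASTA whose header tokens carry a
    ``gene|region`` suffix.  Isoforms (repeated gene ids within a region)
    are resolved per region by :func:`select_longest_isoform`.
    """
    per_region: dict[RegionKind, list[tuple[str, str]]] = {}
    if region_paths:
        for region, path in region_paths.items():
            per_region.setdefault(region, [])
            for header, seq in read_fasta(path):
                gene_id, suffix = _split_header(header)
                per_region[region].append((gene_id, seq))
    if combined_path is not None:
        for header, seq in read_fasta(combined_path):
            gene_id, suffix = _split_header(header)
            if suffix is None:
                raise FastaError(
                    f"combined FASTA record {header!r} lacks the "
                    "'gene|region' suffix"
                )
            per_region.setdefault(RegionKind.from_name(suffix), []).append(
                (gene_id, seq)
            )

    genes: dict[str, GeneRegions] = {}
    for region in REGION_ORDER:
        if region not in per_region:
            continue
        for gene_id, seq in select_longest_isoform(per_region[region]).items():
            genes.setdefault(gene_id, GeneRegions(gene_id)).region_seqs[region] = seq
    return genes
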