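"""Amplicon handling: FASTA I/O, in-silico PCR, and pairwise difference counts.

The assay targets a short hyper-variable region of the mitochondrial 12S rRNA
gene, amplified with a universal elasmobranch primer pair.  Given a template
(e.g. a mitogenome), :func:`in_silico_pcr` locates both primer footprints and
returns the product, primers included.  :func:`pairwise_differences` counts
substitutions between two amplicons — the quantity that ultimately determines
how far apart two species' melt signatures can be.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import Align, SeqIO
from Bio.Seq import Seq

__all__ = [
    "AmpliconRecord",
    "PrimerPair",
    "DEFAULT_PRIMERS",
    "IUPAC_EXPANSION",
    "read_fasta",
    "write_fasta",
    "in_silico_pcr",
    "pairwise_differences",
    "NoAmplificationError",
    "AmbiguousProductError",
    "FastaFormatError",
]

#: IUPAC nucleotide ambiguity codes mapped to the bases they may represent.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Universal elasmobranch 12S primers (as synthesized, 5'->3').
FORWARD_PRIMER = "ACGTCAGGTCGAGGTGTAG"
REVERSE_PRIMER = "ATGTTACGACTTGCCTCCTCTT"


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class NoAmplificationError(ValueError):
    """Raised when a primer finds no binding site on the template."""

    def __init__(self, primer_name: str, template_id: str):
        self.primer_name = primer_name
        super().__init__(
            f"no binding site for {primer_name} primer on template {template_id!r}"
        )


class AmbiguousProductError(ValueError):
    """Raised when more than one candidate product exists."""

    def __init__(self, coordinates: list[tuple[int, int]]):
        self.coordinates = coordinates
        super().__init__(f"multiple candidate products at coordinates {coordinates}")


@dataclasses.dataclass(frozen=True)
class AmpliconRecord:
    """A labelled DNA sequence, either a PCR template or an amplified product."""

    id: str
    sequence: str
    species_label: str = ""
    role: str = "amplicon"  # "template" | "amplicon"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(IUPAC_EXPANSION)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.role not in ("template", "amplicon"):
            raise ValueError(f"role must be 'template' or 'amplicon', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        """GC fraction with ambiguity codes counted by fractional expansion."""
        total = 0.0
        for ch in self.sequence:
            exp = IUPAC_EXPANSION[ch]
            total += len(exp & {"G", "C"}) / len(exp)
        return total / len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3' as synthesized.

    The reverse primer anneals to the plus strand via its reverse complement,
    so product search looks for ``revcomp(reverse)`` downstream of the forward
    site.  ``max_mismatch`` is the per-primer mismatch budget (IUPAC-aware).
    """

    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        for seq in (self.forward, self.reverse):
            bad = set(seq) - set(IUPAC_EXPANSION)
            if bad:
                raise ValueError(f"primer contains non-IUPAC characters {sorted(bad)}")


#: The assay's default primer pair with zero mismatch tolerance.
DEFAULT_PRIMERS = PrimerPair()


def read_fasta(path: str | Path, role: str = "amplicon") -> list[AmpliconRecord]:
    """Read a FASTA file into :class:`AmpliconRecord` objects, order preserved.

    Sequences are uppercased.  The species label is taken from the description
    after the first whitespace when present, otherwise left empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[AmpliconRecord] = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FastaFormatError(f"{path}: empty file")
        if not first.startswith(">"):
            raise FastaFormatError(f"{path}: line 1 is not a FASTA header")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        parts = rec.description.split(None, 1)
        label = parts[1].strip() if len(parts) > 1 else ""
        try:
            records.append(AmpliconRecord(id=rec.id, sequence=seq,
                                          species_label=label, role=role))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: entry {rec.id!r}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[AmpliconRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA, sequence wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.species_label else f"{rec.id} {rec.species_label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _codes_match(primer_code: str, template_code: str) -> bool:
    return bool(IUPAC_EXPANSION[primer_code] & IUPAC_EXPANSION[template_code])


def _find_sites(template: str, probe: str, max_mismatch: int) -> list[int]:
    """All start positions where ``probe`` matches with <= max_mismatch mismatches."""
    hits = []
    n, m = len(template), len(probe)
    for start in range(n - m + 1):
        mism = 0
        for j in range(m):
            if not _codes_match(probe[j], template[start + j]):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def in_silico_pcr(template: AmpliconRecord,
                  primers: PrimerPair = DEFAULT_PRIMERS) -> AmpliconRecord:
    """Extract the PCR product from a template, primer footprints included.

    The product runs from the first forward-primer match through the end of the
    reverse-complemented reverse-primer site.  Matching is IUPAC-aware with at
    most ``primers.max_mismatch`` mismatches per primer.

    Raises :class:`NoAmplificationError` naming the failing primer, or
    :class:`AmbiguousProductError` when several products are possible.
    """
    if template.role != "template":
        raise ValueError(f"in_silico_pcr expects role='template', got {template.role!r}")
    seq = template.sequence
    fwd_sites = _find_sites(seq, primers.forward, primers.max_mismatch)
    if not fwd_sites:
        raise NoAmplificationError("forward", template.id)
    rev_probe = reverse_complement(primers.reverse)
    rev_sites = _find_sites(seq, rev_probe, primers.max_mismatch)
    if not rev_sites:
        raise NoAmplificationError("reverse", template.id)

    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_probe)
            if end > f + len(primers.forward):
                products.append((f, end))
    if not products:
        raise NoAmplificationError("reverse", template.id)
    # Distinct product sequences from the first forward site count as ambiguity.
    first_f = min(f for f, _ in products)
    candidates = sorted({(f, e) for f, e in products if f == first_f})
    if len(candidates) > 1:
        raise AmbiguousProductError(candidates)
    f, end = candidates[0]
    return AmpliconRecord(
        id=f"{template.id}|amplicon",
        sequence=seq[f:end],
        species_label=template.species_label,
        role="amplicon",
    )


def pairwise_differences(a: AmpliconRecord, b: AmpliconRecord) -> int:
    """Count substitution differences between two amplicons.

    Equal-length inputs are compared position-by-position (Hamming count of
    unequal codes).  Unequal lengths fall back to a global alignment
    (match +1, mismatch -1, gap -2); only substitution columns are counted,
    gap columns are not.
    """
    sa, sb = a.sequence, b.sequence
    if len(sa) == len(sb):
        return sum(1 for x, y in zip(sa, sb) if x != y)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(sa, sb)[0]
    subs = 0
    for col_a, col_b in zip(*alignment.indices):
        if col_a >= 0 and col_b >= 0 and sa[col_a] != sb[col_b]:
            subs += 1
    return subs
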