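"""Sequence ingestion and precursor annotation for an actinoporin-like family.

Actinoporin genes are expressed as prepropeptide transcripts: a secretory
signal peptide (19 residues in the Heteractis family consensus), a short
acidic propeptide ending in a dibasic Lys-Arg cleavage site, and the mature
~175-residue toxin.  Mature isoforms are typed by their first residue
(Ala -> "A" isoforms, Ser -> "S" isoforms).

This module reads FASTA / GenBank records, locates open reading frames with
their Kozak-context flags, segments translated precursors at the Lys-Arg
site, types and deduplicates mature isoforms, and writes the isoform report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AnnotationError,
    DatasetUnavailableError,
    DuplicateIdError,
    IllegalCharacterError,
    ParseError,
)

__all__ = [
    "NucleotideRecord",
    "ProteinRecord",
    "OpenReadingFrame",
    "PrecursorAnnotation",
    "MatureIsoform",
    "read_fasta",
    "read_genbank",
    "find_orfs",
    "translate_orf",
    "annotate_precursor",
    "classify_isoform",
    "deduplicate",
    "isoform_report",
    "load_deposited_dataset",
]

_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA record; alphabet restricted to A, C, G, T, N."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG..stop ORF in 1-based coordinates on the forward strand.

    ``end`` is the last coding base; the stop codon is excluded, so
    ``coding_length`` is three times the protein length plus three is the
    span to the stop.  The Kozak flags report whether the nucleotides at
    start-3 and start+4 (1-based, i.e. the base before the context and the
    base after ATG) are adenines, the two context positions most conserved
    in metazoan messages.
    """

    start: int
    end: int
    coding_length: int
    kozak_minus3_a: bool
    kozak_plus4_a: bool

    def __post_init__(self) -> None:
        if self.coding_length != self.end - self.start + 1:
            raise ValueError("coding_length must equal end - start + 1")
        if self.coding_length % 3 != 0:
            raise ValueError("coding_length must be a multiple of 3")


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Segmentation of a precursor into signal / propeptide / mature."""

    protein: str
    signal_end: int
    pro_end: int
    mature: str
    cleavage_motif: str

    @property
    def signal(self) -> str:
        return self.protein[: self.signal_end]

    @property
    def propeptide(self) -> str:
        return self.protein[self.signal_end : self.pro_end]


@dataclass
class MatureIsoform:
    id: str
    sequence: str
    n_type: str
    multiplicity: int = 1
    source_ids: list[str] = field(default_factory=list)


def _check_alphabet(seq: str, allowed: set[str], record_id: str) -> None:
    bad = set(seq) - allowed
    if bad:
        pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
        raise IllegalCharacterError(
            f"record {record_id!r}: illegal character {seq[pos-1]!r} at position {pos}"
        )


def read_fasta(path: str | os.PathLike, alphabet: str = "dna"):
    """Read a multi-record FASTA into Nucleotide/Protein records.

    Sequences are whitespace-stripped and uppercased; duplicate ids and
    characters outside the chosen alphabet raise typed errors naming the
    record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    allowed = _DNA_ALPHABET if alphabet == "dna" else _PROTEIN_ALPHABET
    cls = NucleotideRecord if alphabet == "dna" else ProteinRecord
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        _check_alphabet(seq, allowed, rec.id)
        out.append(cls(id=rec.id, sequence=seq, description=rec.description))
    return out


def read_genbank(path: str | os.PathLike) -> tuple[NucleotideRecord, list[dict]]:
    """Read a GenBank flat file; return the ORIGIN sequence and CDS features.

    Features are returned as dicts with 1-based inclusive ``start``/``end``
    keys, mirroring the flat-file coordinates.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ParseError(f"{path}: no GenBank record found (missing ORIGIN?)")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}")
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: record {rec.id!r} has no ORIGIN sequence")
    features = [
        {
            "type": f.type,
            "start": int(f.location.start) + 1,
            "end": int(f.location.end),
        }
        for f in rec.features
        if f.type == "CDS"
    ]
    return NucleotideRecord(id=rec.id, sequence=seq, description=rec.description), features


def find_orfs(record: NucleotideRecord, min_protein_len: int = 1) -> list[OpenReadingFrame]:
    """Forward-strand ATG..stop ORFs, longest first.

    Every ORF starts at ATG and ends immediately before an in-frame stop;
    nested ATGs within a longer ORF are reported as their own (shorter)
    ORFs.  Returned coordinates are 1-based; ``coding_length`` excludes the
    stop codon.
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    seq = record.sequence
    n = len(seq)
    orfs: list[OpenReadingFrame] = []
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        # find first in-frame stop strictly after the ATG
        stop = None
        for j in range(i + 3, n - 2, 3):
            if seq[j : j + 3] in _STOPS:
                stop = j
                break
        if stop is None:
            continue
        coding = stop - i
        if coding // 3 < min_protein_len:
            continue
        orfs.append(
            OpenReadingFrame(
                start=i + 1,
                end=stop,
                coding_length=coding,
                kozak_minus3_a=(i - 3 >= 0 and seq[i - 3] == "A"),
                kozak_plus4_a=(i + 3 < n and seq[i + 3] == "A"),
            )
        )
    orfs.sort(key=lambda o: (-o.coding_length, o.start))
    return orfs


def translate_orf(record: NucleotideRecord, orf: OpenReadingFrame) -> str:
    """Translate an ORF; ambiguity code N yields 'X' in the protein."""
    cds = record.sequence[orf.start - 1 : orf.end]
    return str(Seq(cds).translate())


def annotate_precursor(
    protein: str, signal_len: int = 19, search_window: int = 45
) -> PrecursorAnnotation:
    """Segment a precursor at the first Lys-Arg dibasic site after the signal.

    The signal-peptide length is a family constant (19 residues for the
    Heteractis consensus), not predicted.  The propeptide ends at the Arg of
    the first "KR" dimer strictly after ``signal_len`` and within
    ``search_window`` residues of the precursor start; the mature chain is
    everything after it.
    """
    if len(protein) <= signal_len + 2:
        raise AnnotationError(
            f"precursor too short ({len(protein)} aa) for a {signal_len}-aa signal"
        )
    window = protein[: min(search_window, len(protein))]
    # pro_end is the 1-based index of the R; K sits at pro_end-1 > signal_len
    pos = None
    for i in range(signal_len, len(window) - 1):  # i = 0-based index of K
        if window[i] == "K" and window[i + 1] == "R":
            pos = i + 2
            break
    if pos is None:
        raise AnnotationError(
            f"no Lys-Arg cleavage site after residue {signal_len} within the "
            f"first {search_window} residues (scanned {window!r})"
        )
    return PrecursorAnnotation(
        protein=protein,
        signal_end=signal_len,
        pro_end=pos,
        mature=protein[pos:],
        cleavage_motif=protein[pos - 2 : pos],
    )


def classify_isoform(mature: str) -> str:
    """Type a mature chain by its first residue: 'A', 'S', or 'other'."""
    if not mature:
        raise ValueError("mature sequence is empty")
    first = mature[0]
    return first if first in ("A", "S") else "other"


def deduplicate(records) -> list[MatureIsoform]:
    """Collapse identical protein strings into isoforms with multiplicities.

    Input is an iterable of (id, sequence) pairs or ProteinRecord objects.
    Grouping is exact-string; output order is first occurrence, so the result
    is deterministic and permutation of later duplicates cannot reorder it.
    """
    seen: dict[str, MatureIsoform] = {}
    for rec in records:
        rid, seq = (rec.id, rec.sequence) if hasattr(rec, "sequence") else rec
        if seq in seen:
            iso = seen[seq]
            iso.multiplicity += 1
            iso.source_ids.append(rid)
        else:
            seen[seq] = MatureIsoform(
                id=rid,
                sequence=seq,
                n_type=classify_isoform(seq),
                multiplicity=1,
                source_ids=[rid],
            )
    return list(seen.values())


def isoform_report(isoforms: list[MatureIsoform]) -> pd.DataFrame:
    """Tabular isoform report (id, type, length, multiplicity, sources)."""
    return pd.DataFrame(
        {
            "id": [i.id for i in isoforms],
            "n_type": [i.n_type for i in isoforms],
            "length": [len(i.sequence) for i in isoforms],
            "multiplicity": [i.multiplicity for i in isoforms],
            "source_ids": [",".join(i.source_ids) for i in isoforms],
        }
    )


def load_deposited_dataset(directory: str | os.PathLike = "data/deposited"):
    """Load a local copy of the cloned actinoporin precursor dataset.

    The cloned Heteractis crispa precursor cDNAs are public GenBank records
    (accessions MG887781-MG887823).  This package ships no copy of them; to
    run the deposited-data analyses, download the records and place them as
    ``<directory>/hcrispa_precursors.fasta`` (nucleotide FASTA, one record
    per accession, plus any previously published isoforms to include).
    Raises :class:`DatasetUnavailableError` when the file is absent.
    """
    path = Path(directory) / "hcrispa_precursors.fasta"
    if not path.exists():
        raise DatasetUnavailableError(
            f"deposited-family dataset not found at {path}; download GenBank "
            "accessions MG887781-MG887823 as nucleotide FASTA and place the "
            "file there to enable deposited-data analyses"
        )
    return read_fasta(path, alphabet="dna")
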