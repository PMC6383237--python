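"""Reading and writing the formats the pipeline touches.

Alignments come in as aligned (gapped) FASTA with one designated *reference*
record — the intact ortholog every lesion is measured against.  Allele labels
follow the ``*<digit>`` convention used in comparative gene-loss studies:
``>O_hoffmanni*2`` is allele 2 of species ``O_hoffmanni``; a header without the
suffix denotes the single observed allele.

Gene models (exon intervals plus intron sequences, for splice analysis) are a
small documented YAML file, see :func:`read_gene_model`.

Disruption reports are written as a tab-separated event table plus a
per-species summary, with a JSON mirror alongside for programmatic use; the
TSV round-trips losslessly through :func:`read_report`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genedecay.errors import (
    AlignmentShapeError,
    AlphabetError,
    EventConsistencyError,
    MissingReferenceError,
    MissingSequenceError,
    ModelConsistencyError,
)

#: accepted residue alphabet: bases, N, IUPAC ambiguity codes, and the gap
ALPHABET = frozenset("ACGTNRYSWKMBDHV-")
#: unambiguous bases
BASES = frozenset("ACGT")
#: standard-code stop codons
STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})

_ALLELE_RE = re.compile(r"^(?P<species>.+)\*(?P<allele>\d+)$")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: an allele of one species."""

    id: str
    species: str
    allele_label: str
    residues: str

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")


def _parse_header(seq_id: str) -> tuple[str, str]:
    """Split ``species*allele`` headers; no suffix means a single allele."""
    m = _ALLELE_RE.match(seq_id)
    if m:
        return m.group("species"), m.group("allele")
    return seq_id, ""


def make_record(seq_id: str, residues: str) -> SequenceRecord:
    """Build a :class:`SequenceRecord`, normalizing case and parsing the allele suffix."""
    species, allele = _parse_header(seq_id)
    return SequenceRecord(id=seq_id, species=species, allele_label=allele,
                          residues=residues.upper())


@dataclass
class CodingAlignment:
    """A gapped multiple alignment of orthologous coding sequences.

    ``reference_id`` names the intact anchor whose reading frame defines every
    downstream coordinate; ``coding_start`` is the 1-based *ungapped* reference
    position of the first CDS base (1 when the alignment is the bare CDS).
    """

    records: list[SequenceRecord]
    reference_id: str
    coding_start: int = 1

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment contains no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}={len(r.residues)}" for r in self.records)
            raise AlignmentShapeError(f"records differ in aligned length: {detail}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentShapeError(f"duplicate record ids: {', '.join(dupes)}")
        if self.reference_id not in set(ids):
            raise MissingReferenceError(
                f"reference id {self.reference_id!r} not found among "
                f"{len(ids)} records")
        self._by_id = {r.id: r for r in self.records}

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].residues)

    def reference(self) -> SequenceRecord:
        return self._by_id[self.reference_id]

    def get(self, seq_id: str) -> SequenceRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise MissingSequenceError(
                f"sequence id {seq_id!r} not found in alignment") from None

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def validate_reference_orf(self, stop_set: frozenset[str] = STANDARD_STOPS) -> None:
        """Check the reference reads as an open frame ending in a stop codon.

        Applied to the gap-stripped reference from ``coding_start`` onward;
        raises :class:`AlphabetError` on failure.
        """
        cds = self.reference().residues.replace("-", "")[self.coding_start - 1:]
        if len(cds) < 6 or len(cds) % 3:
            raise AlphabetError(
                f"reference {self.reference_id!r}: ungapped CDS length {len(cds)} "
                "is not a positive multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in stop_set:
            raise AlphabetError(
                f"reference {self.reference_id!r}: CDS does not end in a stop "
                f"codon (found {codons[-1]})")
        internal = [i + 1 for i, c in enumerate(codons[:-1]) if c in stop_set]
        if internal:
            raise AlphabetError(
                f"reference {self.reference_id!r}: internal stop codon at "
                f"codon {internal[0]}")


def _check_alphabet(seq_id: str, residues: str) -> None:
    for col, ch in enumerate(residues, start=1):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {seq_id!r} column {col}: illegal character {ch!r}")


def read_alignment(path: str | Path, reference_id: str, *,
                   coding_start: int = 1, validate_orf: bool = True) -> CodingAlignment:
    """Read an aligned FASTA file into a :class:`CodingAlignment`.

    Residues are upper-cased; allele labels are parsed from a trailing
    ``*<digit>`` header token.  Unequal record lengths raise
    :class:`AlignmentShapeError`; an absent reference raises
    :class:`MissingReferenceError`; characters outside the IUPAC nucleotide
    alphabet raise :class:`AlphabetError` naming the record and column.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        _check_alphabet(rec.id, residues)
        records.append(make_record(rec.id, residues))
    aln = CodingAlignment(records=records, reference_id=reference_id,
                          coding_start=coding_start)
    if validate_orf:
        aln.validate_reference_orf()
    return aln


def write_alignment(aln: CodingAlignment, path: str | Path) -> None:
    """Write an alignment back to gapped FASTA (60-column wrapped, stable order)."""
    out = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """Exon/intron layout of one gene, for splice-acceptor analysis.

    ``exons`` are 1-based closed intervals in gene coordinates, strictly
    increasing and non-overlapping; ``introns`` holds the intron nucleotide
    sequences in order (one fewer than exons); ``coding_start_offset`` is the
    0-based offset of the CDS start within the first exon.
    """

    gene_id: str
    exons: list[tuple[int, int]]
    introns: list[str]
    coding_start_offset: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelConsistencyError(f"gene {self.gene_id!r}: no exons")
        for start, end in self.exons:
            if start > end or start < 1:
                raise ModelConsistencyError(
                    f"gene {self.gene_id!r}: bad exon interval ({start}, {end})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ModelConsistencyError(
                    f"gene {self.gene_id!r}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or are out of order")
        if len(self.introns) != len(self.exons) - 1:
            raise ModelConsistencyError(
                f"gene {self.gene_id!r}: {len(self.exons)} exons require "
                f"{len(self.exons) - 1} introns, got {len(self.introns)}")
        if self.coding_start_offset < 0:
            raise ModelConsistencyError(
                f"gene {self.gene_id!r}: negative coding_start_offset")
        self.introns = [s.upper() for s in self.introns]
        for k, intron in enumerate(self.introns, start=1):
            bad = set(intron) - ALPHABET
            if bad:
                raise ModelConsistencyError(
                    f"gene {self.gene_id!r}: intron {k} contains illegal "
                    f"characters {sorted(bad)}")


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a gene model from a small YAML file.

    Expected keys::

        gene_id: CCL16_like
        coding_start_offset: 0      # optional, default 0
        exons:
          - [1, 120]
          - [221, 380]
          - [501, 640]
        introns:                    # sequences, in order; len == len(exons) - 1
          - ACGT...AG
          - ACGT...AG
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelConsistencyError(f"{path}: gene model file is not a mapping")
    try:
        exons = [tuple(int(x) for x in pair) for pair in raw["exons"]]
        introns = [str(s) for s in raw.get("introns", [])]
        gene_id = str(raw.get("gene_id", Path(path).stem))
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelConsistencyError(f"{path}: malformed gene model ({exc})") from exc
    return GeneModel(gene_id=gene_id, exons=exons, introns=introns,
                     coding_start_offset=int(raw.get("coding_start_offset", 0)))


# ---------------------------------------------------------------------------
# reports

_EVENT_COLUMNS = ["seq_id", "species", "allele", "kind", "ref_position",
                  "length", "detail"]


def write_report(events: Sequence, statuses: Sequence, path: str | Path) -> None:
    """Write the disruption report.

    ``path`` receives the event table (TSV, one row per event); a per-species
    summary goes to ``<path stem>.summary.tsv`` and a JSON mirror of events
    plus per-allele verdicts to ``<path stem>.json``.  Events must reference
    sequence ids present in ``statuses``.
    """
    from genedecay.disruption_scan import summarize_species  # cycle guard

    by_id = {s.seq_id: s for s in statuses}
    rows = []
    for ev in events:
        if ev.seq_id not in by_id:
            raise EventConsistencyError(
                f"event references {ev.seq_id!r}, which has no status entry")
        st = by_id[ev.seq_id]
        rows.append({"seq_id": ev.seq_id, "species": st.species,
                     "allele": st.allele_label, "kind": ev.kind,
                     "ref_position": ev.ref_position, "length": ev.length,
                     "detail": ev.detail})
    table = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)

    stem = path.with_suffix("")
    if statuses:
        summarize_species(list(statuses)).to_csv(
            Path(f"{stem}.summary.tsv"), sep="\t", index=False)
    mirror = {
        "events": rows,
        "statuses": [{"seq_id": s.seq_id, "species": s.species,
                      "allele": s.allele_label, "verdict": s.verdict,
                      "n_events": len(s.events)} for s in statuses],
    }
    with open(f"{stem}.json", "w") as fh:
        json.dump(mirror, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> list:
    """Read an event table written by :func:`write_report` back into events."""
    from genedecay.disruption_scan import DisruptionEvent

    table = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"detail": str, "allele": str, "seq_id": str,
                               "species": str, "kind": str})
    events = []
    for row in table.itertuples(index=False):
        events.append(DisruptionEvent(seq_id=row.seq_id, kind=row.kind,
                                      ref_position=int(row.ref_position),
                                      length=int(row.length),
                                      detail=str(row.detail)))
    return events
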