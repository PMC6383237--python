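"""Reference-anchored coordinate maps for gapped coding alignments.

Comparative gene-loss studies report lesion positions against the one intact
ortholog in the alignment, not against each decayed sequence.  Two numbering
conventions are in use and both are supported:

``alignment_columns``
    every alignment column counts, including columns where the reference is
    gapped (i.e. indels are included in the numbering).  This is the usual
    convention of published alignment figures and the default here.

``ungapped_reference``
    only reference non-gap sites are numbered; columns where the reference is
    gapped map to a gap marker (0).  Convenient for interoperating with
    annotation coordinates of the reference sequence.

The reading frame is defined solely by the reference record's coding start;
query sequences never redefine the frame — codon *i* of any sequence means
"the residues aligned under reference codon *i*".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from genedecay.errors import CoordinateRangeError
from genedecay.seq_io import CodingAlignment

#: marker for "reference is gapped at this column" in ungapped_reference mode
GAP_MARK = 0

MODES = ("alignment_columns", "ungapped_reference")


@dataclass
class CoordinateMap:
    """Bidirectional map between alignment columns and reference positions.

    ``column_to_refpos[c-1]`` gives the reference position of 1-based column
    ``c`` (``GAP_MARK`` where the reference is gapped, in ungapped mode);
    ``refpos_to_column[p-1]`` is its inverse over non-gap columns.
    """

    reference_id: str
    mode: str
    column_to_refpos: np.ndarray
    refpos_to_column: np.ndarray
    coding_start: int
    _residue_columns: np.ndarray = field(repr=False, default=None)
    alignment_length: int = 0

    def refpos_of_column(self, column: int) -> int:
        self._check_column(column)
        return int(self.column_to_refpos[column - 1])

    def column_of_refpos(self, refpos: int) -> int:
        if not 1 <= refpos <= len(self.refpos_to_column):
            raise CoordinateRangeError(
                f"reference position {refpos} outside 1..{len(self.refpos_to_column)}")
        return int(self.refpos_to_column[refpos - 1])

    def position_at_or_after_column(self, column: int) -> int:
        """First reference position at or after a column.

        For columns inside a reference gap run this is the next numbered
        position downstream (or ``n_ref + 1`` past the final residue), used to
        anchor insertion events.
        """
        self._check_column(column)
        tail = self.column_to_refpos[column - 1:]
        nz = tail[tail != GAP_MARK]
        if nz.size:
            return int(nz[0])
        return len(self.refpos_to_column) + 1

    # -- codon grid ---------------------------------------------------------

    @property
    def coding_start_column(self) -> int:
        """Alignment column of the first CDS base of the reference."""
        return int(self._residue_columns[self.coding_start - 1])

    def n_coding_codons(self) -> int:
        """Number of whole codons available from the coding start, in this mode."""
        if self.mode == "alignment_columns":
            return (self.alignment_length - self.coding_start_column + 1) // 3
        n_res = len(self._residue_columns)
        return (n_res - (self.coding_start - 1)) // 3

    def codon_columns(self, codon_index: int) -> tuple[int, int, int]:
        """The three 1-based alignment columns under reference codon ``codon_index``."""
        n = self.n_coding_codons()
        if not 1 <= codon_index <= n:
            raise CoordinateRangeError(
                f"codon index {codon_index} outside 1..{n}")
        if self.mode == "alignment_columns":
            c0 = self.coding_start_column + 3 * (codon_index - 1)
            return (c0, c0 + 1, c0 + 2)
        p0 = (self.coding_start - 1) + 3 * (codon_index - 1)
        cols = self._residue_columns[p0:p0 + 3]
        return (int(cols[0]), int(cols[1]), int(cols[2]))

    def _check_column(self, column: int) -> None:
        if not 1 <= column <= self.alignment_length:
            raise CoordinateRangeError(
                f"column {column} outside 1..{self.alignment_length}")


@dataclass(frozen=True)
class Codon:
    """Three residues of one sequence under one reference codon."""

    codon_index: int
    nucleotides: str
    complete: bool


def build_coordinate_map(aln: CodingAlignment,
                         mode: str = "alignment_columns") -> CoordinateMap:
    """Build the coordinate map of an alignment's reference in the given mode."""
    if mode not in MODES:
        raise ValueError(f"numbering mode must be one of {MODES}, got {mode!r}")
    ref = aln.reference()
    length = aln.alignment_length
    is_res = np.frombuffer(ref.residues.encode("ascii"), dtype=np.uint8) != ord("-")
    residue_columns = np.nonzero(is_res)[0] + 1
    if aln.coding_start < 1 or aln.coding_start > residue_columns.size:
        raise CoordinateRangeError(
            f"coding_start {aln.coding_start} outside the reference's "
            f"{residue_columns.size} residues")
    if mode == "alignment_columns":
        col_to_ref = np.arange(1, length + 1)
        ref_to_col = np.arange(1, length + 1)
    else:
        col_to_ref = np.where(is_res, np.cumsum(is_res), GAP_MARK)
        ref_to_col = residue_columns
    return CoordinateMap(reference_id=aln.reference_id, mode=mode,
                         column_to_refpos=col_to_ref, refpos_to_column=ref_to_col,
                         coding_start=aln.coding_start,
                         _residue_columns=residue_columns,
                         alignment_length=length)


def codon_at(cmap: CoordinateMap, aln: CodingAlignment, seq_id: str,
             codon_index: int) -> Codon:
    """Extract the residues of ``seq_id`` aligned under reference codon ``codon_index``."""
    cols = cmap.codon_columns(codon_index)
    residues = aln.get(seq_id).residues
    nts = "".join(residues[c - 1] for c in cols)
    return Codon(codon_index=codon_index, nucleotides=nts,
                 complete="-" not in nts)


def coding_residues(cmap: CoordinateMap, aln: CodingAlignment, seq_id: str) -> str:
    """Concatenation of a sequence's residues over all reference codons, in order."""
    return "".join(codon_at(cmap, aln, seq_id, i).nucleotides
                   for i in range(1, cmap.n_coding_codons() + 1))
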