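"""Alternative splice-acceptor detection and intron-retention prediction.

When a new acceptor dinucleotide arises inside an intron a short distance
upstream of the annotated 3' splice site, splicing at the new site retains the
intervening intron segment in the mature transcript.  If the retained length
is a multiple of three the reading frame survives and the protein simply gains
``length / 3`` residues — the benign outcome observed for pika-like lineages
(a 21-nt retention inserting seven amino acids at the start of exon 2); any
other length shifts the frame.

The scanner is purely motif-based: it enumerates every occurrence of the
acceptor dinucleotide (canonical intron-terminal ``AG`` by default; the motif
and the side it is read on are configurable) within a window upstream of the
annotated acceptor.  No splice-strength scoring is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from genedecay.errors import CoordinateRangeError, NotAnAlternativeError
from genedecay.seq_io import GeneModel

SIDES = ("intron_terminal", "exon_initial")


@dataclass(frozen=True)
class SpliceSite:
    """A candidate acceptor site within an intron.

    ``position_in_intron`` is the 1-based position of the last intron
    nucleotide the acceptor would use; ``offset_nt`` its distance upstream of
    the annotated acceptor (0 for the annotated site itself);
    ``retained_sequence`` the intron suffix that would be retained in the
    transcript when this site is used (empty for offset 0).
    """

    intron_index: int
    position_in_intron: int
    dinucleotide: str
    offset_nt: int
    retained_sequence: str = ""

    def __post_init__(self) -> None:
        if self.offset_nt < 0:
            raise ValueError("offset_nt must be non-negative")
        if len(self.retained_sequence) != self.offset_nt:
            raise ValueError("retained_sequence length must equal offset_nt")


@dataclass(frozen=True)
class RetentionPrediction:
    """Consequence of splicing at an upstream acceptor: an intron-retention insertion."""

    inserted_nt: int
    in_frame: bool
    inserted_aa: int
    inserted_peptide: str

    def __post_init__(self) -> None:
        if self.in_frame != (self.inserted_nt % 3 == 0):
            raise ValueError("in_frame inconsistent with inserted_nt")
        expected_aa = self.inserted_nt // 3 if self.in_frame else 0
        if self.inserted_aa != expected_aa:
            raise ValueError("inserted_aa inconsistent with inserted_nt")


def find_acceptor_candidates(model: GeneModel, intron_index: int,
                             search_window: int, *, motif: str = "AG",
                             side: str = "intron_terminal") -> list[SpliceSite]:
    """Enumerate acceptor candidates in the window upstream of the annotated 3' end.

    The annotated acceptor (offset 0) is always first in the returned list;
    alternative sites are every position whose use would end the intron within
    ``search_window`` nucleotides upstream, sorted by increasing offset.  With
    ``side="intron_terminal"`` the motif must be the last two intron
    nucleotides the site would use (canonical ``AG``); with
    ``side="exon_initial"`` it must be the first two nucleotides of the
    retained segment, expressing the exon-flank reading of acceptor context.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if len(motif) != 2:
        raise ValueError(f"acceptor motif must be 2 nt, got {motif!r}")
    motif = motif.upper()
    if not 1 <= intron_index <= len(model.introns):
        raise CoordinateRangeError(
            f"gene {model.gene_id!r} has {len(model.introns)} introns; "
            f"intron {intron_index} requested")
    intron = model.introns[intron_index - 1]
    if search_window > len(intron):
        raise CoordinateRangeError(
            f"search window {search_window} exceeds intron {intron_index} "
            f"length {len(intron)}")
    sites = [SpliceSite(intron_index=intron_index,
                        position_in_intron=len(intron),
                        dinucleotide=intron[-2:], offset_nt=0)]
    for offset in range(1, search_window + 1):
        pos = len(intron) - offset  # last intron nt used by this candidate
        if side == "intron_terminal":
            if pos < 2:
                continue
            dinucleotide = intron[pos - 2:pos]
        else:
            if pos < 0 or pos + 2 > len(intron):
                continue
            dinucleotide = intron[pos:pos + 2]
        if dinucleotide == motif:
            sites.append(SpliceSite(intron_index=intron_index,
                                    position_in_intron=pos,
                                    dinucleotide=dinucleotide,
                                    offset_nt=offset,
                                    retained_sequence=intron[pos:]))
    return sites


def predict_retention(site: SpliceSite) -> RetentionPrediction:
    """Predict the intron-retention insertion from using an upstream acceptor.

    The retained segment is translated in the downstream-exon frame (the
    insertion sits at the exon start, so an in-frame retention reads straight
    through); out-of-frame retentions report no peptide.
    """
    if site.offset_nt == 0:
        raise NotAnAlternativeError(
            "offset 0 is the annotated acceptor; nothing is retained")
    in_frame = site.offset_nt % 3 == 0
    peptide = ""
    if in_frame:
        peptide = str(Seq(site.retained_sequence).translate())
    return RetentionPrediction(inserted_nt=site.offset_nt, in_frame=in_frame,
                               inserted_aa=site.offset_nt // 3 if in_frame else 0,
                               inserted_peptide=peptide)


def compare_acceptor_positions(pos_species_a: int, pos_species_b: int) -> int:
    """Absolute offset between two species' acceptor positions in a shared frame."""
    return abs(pos_species_a - pos_species_b)
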