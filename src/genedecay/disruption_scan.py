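"""Detection and classification of coding-sequence lesions.

Given a gapped alignment anchored on an intact reference, this module finds
per-allele lesions — premature stop codons, frame-disrupting and in-frame
indels, loss of the start codon, and damage to required sequence motifs such
as the CC-chemokine cysteine pair — and aggregates them into per-allele and
per-species functional verdicts.

Verdict semantics
-----------------
``pseudogene``
    at least one truncating lesion: a premature stop (including a stop created
    at a motif codon), a frameshift indel, or loss of the start codon.
``impaired_motif``
    no truncating lesion, but a required motif residue is substituted — the
    protein is intact in length yet likely compromised.
``functional``
    no truncating or motif lesions; in-frame indels alone do not demote an
    allele (they are reported but preserve the reading frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from genedecay.errors import CoordinateRangeError, EventConsistencyError
from genedecay.ref_coords import CoordinateMap, codon_at
from genedecay.seq_io import BASES, STANDARD_STOPS, CodingAlignment

logger = logging.getLogger(__name__)

#: event kinds that truncate the product and force a pseudogene verdict
DISRUPTING_KINDS = frozenset(
    {"premature_stop", "frameshift_indel", "start_loss", "motif_stop_loss"})

EVENT_KINDS = DISRUPTING_KINDS | {"inframe_indel", "motif_substitution"}

VERDICTS = ("functional", "pseudogene", "impaired_motif")


@dataclass(frozen=True)
class DisruptionEvent:
    """One detected lesion, positioned in reference-anchored coordinates.

    ``ref_position`` is a codon index for stop/motif/start events and the
    first affected reference position for indels; ``length`` is the indel span
    in nucleotides (0 for non-indel events).
    """

    seq_id: str
    kind: str
    ref_position: int
    length: int = 0
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "frameshift_indel" and self.length % 3 == 0:
            raise ValueError(
                f"frameshift_indel length {self.length} is a multiple of 3")
        if self.kind == "inframe_indel" and (self.length <= 0 or self.length % 3):
            raise ValueError(
                f"inframe_indel length {self.length} is not a positive multiple of 3")


@dataclass(frozen=True)
class MotifSpec:
    """Required residues at fixed reference codons (e.g. the CC motif C@53,C@54)."""

    name: str
    codon_indices: tuple[int, ...]
    required_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codon_indices) != len(self.required_residues):
            raise ValueError("codon_indices and required_residues differ in length")

    @classmethod
    def parse(cls, text: str, name: str = "motif") -> "MotifSpec":
        """Parse the ``RESIDUE@CODON`` comma-list syntax, e.g. ``"C@53,C@54"``."""
        indices, residues = [], []
        for token in text.split(","):
            token = token.strip()
            try:
                residue, pos = token.split("@")
                indices.append(int(pos))
                residues.append(residue.strip().upper())
            except ValueError as exc:
                raise ValueError(f"bad motif token {token!r}; "
                                 "expected RESIDUE@CODON") from exc
        return cls(name=name, codon_indices=tuple(indices),
                   required_residues=tuple(residues))


@dataclass
class GeneStatus:
    """Per-allele functional verdict with its supporting events."""

    seq_id: str
    species: str
    allele_label: str
    verdict: str
    events: list[DisruptionEvent] = field(default_factory=list)
    frame_offset: int = 0
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual scanners


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def reference_terminal_stop_index(aln: CodingAlignment, cmap: CoordinateMap,
                                  stop_set: Iterable[str] = STANDARD_STOPS
                                  ) -> int | None:
    """Codon index of the reference's terminal stop, or None if it has none."""
    stop_set = frozenset(s.upper() for s in stop_set)
    for i in range(cmap.n_coding_codons(), 0, -1):
        codon = codon_at(cmap, aln, aln.reference_id, i)
        if codon.complete and codon.nucleotides in stop_set:
            return i
    return None


def detect_premature_stops(aln: CodingAlignment, cmap: CoordinateMap,
                           seq_id: str,
                           stop_set: Iterable[str] = STANDARD_STOPS
                           ) -> list[DisruptionEvent]:
    """Find in-frame stop codons strictly before the reference's terminal stop.

    Codons containing gaps or ambiguity codes are skipped (logged) rather than
    guessed; the terminal stop position itself never yields an event.
    """
    stop_set = frozenset(s.upper() for s in stop_set)
    if not stop_set:
        raise ValueError("stop_set must be non-empty")
    terminal = reference_terminal_stop_index(aln, cmap, stop_set)
    limit = terminal if terminal is not None else cmap.n_coding_codons() + 1
    events = []
    for i in range(1, limit):
        codon = codon_at(cmap, aln, seq_id, i)
        if not codon.complete:
            logger.debug("%s codon %d skipped (gap-containing: %s)",
                         seq_id, i, codon.nucleotides)
            continue
        if not set(codon.nucleotides) <= BASES:
            logger.debug("%s codon %d skipped (ambiguous: %s)",
                         seq_id, i, codon.nucleotides)
            continue
        if codon.nucleotides in stop_set:
            ref_codon = codon_at(cmap, aln, aln.reference_id, i).nucleotides
            events.append(DisruptionEvent(
                seq_id=seq_id, kind="premature_stop", ref_position=i,
                detail=f"{ref_codon}>{codon.nucleotides}"))
    return events


def detect_start_loss(aln: CodingAlignment, cmap: CoordinateMap,
                      seq_id: str) -> list[DisruptionEvent]:
    """Report loss of the initiator ATG (mutated or gapped) at reference codon 1.

    Only checked when the reference itself starts with ATG.
    """
    ref_start = codon_at(cmap, aln, aln.reference_id, 1)
    if ref_start.nucleotides != "ATG":
        return []
    codon = codon_at(cmap, aln, seq_id, 1)
    if codon.nucleotides == "ATG":
        return []
    return [DisruptionEvent(seq_id=seq_id, kind="start_loss", ref_position=1,
                            detail=f"ATG>{codon.nucleotides}")]


def detect_indels(aln: CodingAlignment, cmap: CoordinateMap,
                  seq_id: str) -> list[DisruptionEvent]:
    """Find maximal indel runs of a query against the reference.

    A *deletion* is a maximal run of columns where the query is gapped and the
    reference has a residue; an *insertion* is the converse.  Columns gapped in
    both sequences belong to neither and terminate runs.  Runs whose length is
    not a multiple of 3 are ``frameshift_indel``, the rest ``inframe_indel``;
    ``ref_position`` is the first reference position of (deletions) or after
    (insertions) the run, in the map's numbering mode.
    """
    query = aln.get(seq_id).residues
    ref = aln.reference().residues
    events = []
    run_kind = None  # "del" | "ins"
    run_start = 0
    run_len = 0

    def close(end_col: int) -> None:
        nonlocal run_kind, run_len
        if run_kind is None:
            return
        kind = "frameshift_indel" if run_len % 3 else "inframe_indel"
        if cmap.mode == "alignment_columns":
            pos = run_start
        elif run_kind == "del":
            pos = cmap.refpos_of_column(run_start)
        else:
            pos = cmap.position_at_or_after_column(run_start)
        tag = "del" if run_kind == "del" else "ins"
        events.append(DisruptionEvent(seq_id=seq_id, kind=kind,
                                      ref_position=pos, length=run_len,
                                      detail=f"{tag}{run_len}"))
        run_kind, run_len = None, 0

    for col in range(1, aln.alignment_length + 1):
        q, r = query[col - 1], ref[col - 1]
        if q == "-" and r != "-":
            state = "del"
        elif q != "-" and r == "-":
            state = "ins"
        else:
            state = None
        if state != run_kind:
            close(col)
            if state is not None:
                run_kind, run_start, run_len = state, col, 0
        if state is not None:
            run_len += 1
    close(aln.alignment_length + 1)
    return events


def frame_offset(aln: CodingAlignment, seq_id: str) -> int:
    """Net reading-frame offset of a query: ungapped(query) - ungapped(reference).

    Reported alongside per-event calls so that mutually compensating
    frameshifts (a +1 and a -1 indel) remain visible as such.
    """
    return aln.get(seq_id).ungapped_length - aln.reference().ungapped_length


def check_motif(aln: CodingAlignment, cmap: CoordinateMap, seq_id: str,
                spec: MotifSpec) -> list[DisruptionEvent]:
    """Check required motif residues; stop codons there are ``motif_stop_loss``.

    Gap-containing codons yield ``motif_substitution`` with detail ``"gap"``.
    """
    n = cmap.n_coding_codons()
    for idx in spec.codon_indices:
        if not 1 <= idx <= n:
            raise CoordinateRangeError(
                f"motif codon {idx} outside coding range 1..{n}")
    events = []
    for idx, required in zip(spec.codon_indices, spec.required_residues):
        codon = codon_at(cmap, aln, seq_id, idx)
        if not codon.complete:
            events.append(DisruptionEvent(
                seq_id=seq_id, kind="motif_substitution", ref_position=idx,
                detail="gap"))
            continue
        observed = _translate(codon.nucleotides)
        if observed == required:
            continue
        if observed == "*":
            events.append(DisruptionEvent(
                seq_id=seq_id, kind="motif_stop_loss", ref_position=idx,
                detail=f"{required}{idx}*({codon.nucleotides})"))
        else:
            events.append(DisruptionEvent(
                seq_id=seq_id, kind="motif_substitution", ref_position=idx,
                detail=f"{required}{idx}{observed}"))
    return events


def check_terminal_stop(aln: CodingAlignment, cmap: CoordinateMap, seq_id: str,
                        stop_set: Iterable[str] = STANDARD_STOPS) -> str | None:
    """Note (not an event) when a query lacks a stop where the reference ends."""
    stop_set = frozenset(s.upper() for s in stop_set)
    terminal = reference_terminal_stop_index(aln, cmap, stop_set)
    if terminal is None:
        return f"reference {aln.reference_id!r} has no terminal stop codon"
    codon = codon_at(cmap, aln, seq_id, terminal)
    if codon.complete and codon.nucleotides in stop_set:
        return None
    return (f"{seq_id}: missing terminal stop at codon {terminal} "
            f"(observed {codon.nucleotides})")


# ---------------------------------------------------------------------------
# aggregation


def scan_sequence(aln: CodingAlignment, cmap: CoordinateMap, seq_id: str, *,
                  motif: MotifSpec | None = None,
                  stop_set: Iterable[str] = STANDARD_STOPS
                  ) -> tuple[list[DisruptionEvent], list[str]]:
    """Run all scanners on one sequence and merge overlapping calls.

    A premature stop located at a declared motif codon is reported once, as
    ``motif_stop_loss`` (which still counts as a premature stop for the
    verdict), so a single lesion yields a single event.
    """
    events = list(detect_start_loss(aln, cmap, seq_id))
    stops = detect_premature_stops(aln, cmap, seq_id, stop_set)
    motif_events: list[DisruptionEvent] = []
    if motif is not None:
        motif_events = check_motif(aln, cmap, seq_id, motif)
        stop_loss_at = {e.ref_position for e in motif_events
                        if e.kind == "motif_stop_loss"}
        stops = [e for e in stops if e.ref_position not in stop_loss_at]
    events.extend(stops)
    events.extend(detect_indels(aln, cmap, seq_id))
    events.extend(motif_events)
    notes = []
    note = check_terminal_stop(aln, cmap, seq_id, stop_set)
    if note:
        notes.append(note)
    return events, notes


def classify_allele(events: Sequence[DisruptionEvent], *, seq_id: str | None = None,
                    species: str = "", allele_label: str = "",
                    frame_offset: int = 0,
                    notes: Sequence[str] = ()) -> GeneStatus:
    """Derive an allele's verdict from its event list.

    All events must belong to one sequence; ``motif_stop_loss`` counts as a
    premature stop, in-frame indels alone leave the allele functional.
    """
    ids = {e.seq_id for e in events}
    if len(ids) > 1:
        raise EventConsistencyError(
            f"events span multiple sequences: {sorted(ids)}")
    if seq_id is None:
        if not ids:
            raise EventConsistencyError("empty event list requires explicit seq_id")
        seq_id = next(iter(ids))
    elif ids and ids != {seq_id}:
        raise EventConsistencyError(
            f"events belong to {sorted(ids)}, not {seq_id!r}")
    kinds = {e.kind for e in events}
    if kinds & DISRUPTING_KINDS:
        verdict = "pseudogene"
    elif "motif_substitution" in kinds:
        verdict = "impaired_motif"
    else:
        verdict = "functional"
    return GeneStatus(seq_id=seq_id, species=species, allele_label=allele_label,
                      verdict=verdict, events=list(events),
                      frame_offset=frame_offset, notes=list(notes))


def scan_alignment(aln: CodingAlignment, cmap: CoordinateMap, *,
                   motif: MotifSpec | None = None,
                   stop_set: Iterable[str] = STANDARD_STOPS,
                   include_reference: bool = False) -> list[GeneStatus]:
    """Scan every record (minus the reference, by default) and classify it."""
    statuses = []
    for rec in aln.records:
        if rec.id == aln.reference_id and not include_reference:
            continue
        events, notes = scan_sequence(aln, cmap, rec.id, motif=motif,
                                      stop_set=stop_set)
        statuses.append(classify_allele(
            events, seq_id=rec.id, species=rec.species,
            allele_label=rec.allele_label,
            frame_offset=frame_offset(aln, rec.id), notes=notes))
    return statuses


def summarize_species(statuses: Sequence[GeneStatus]) -> pd.DataFrame:
    """Aggregate per-allele verdicts to a per-species table.

    A species is ``functional`` if at least one allele is functional (a
    heterozygote with one intact allele still makes the protein),
    ``pseudogene`` if every allele is, and ``impaired`` otherwise.
    """
    rows = []
    by_species: dict[str, list[GeneStatus]] = {}
    for st in statuses:
        by_species.setdefault(st.species, []).append(st)
    for species in sorted(by_species):
        alleles = by_species[species]
        verdicts = [a.verdict for a in alleles]
        if "functional" in verdicts:
            species_verdict = "functional"
        elif all(v == "pseudogene" for v in verdicts):
            species_verdict = "pseudogene"
        else:
            species_verdict = "impaired"
        rows.append({
            "species": species,
            "n_alleles": len(alleles),
            "allele_verdicts": ",".join(verdicts),
            "n_events": sum(len(a.events) for a in alleles),
            "species_verdict": species_verdict,
        })
    return pd.DataFrame(rows, columns=["species", "n_alleles", "allele_verdicts",
                                       "n_events", "species_verdict"])
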