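"""Lesion detection, classification, and the brute-force scan oracle."""

import itertools

import numpy as np
import pytest

from genedecay.disruption_scan import (
    DisruptionEvent,
    MotifSpec,
    check_motif,
    check_terminal_stop,
    classify_allele,
    detect_indels,
    detect_premature_stops,
    detect_start_loss,
    frame_offset,
    scan_alignment,
    scan_sequence,
    summarize_species,
)
from genedecay.errors import EventConsistencyError
from genedecay.ref_coords import build_coordinate_map
from genedecay.seq_io import STANDARD_STOPS

from conftest import (
    alignment_from,
    make_cds,
    random_gapped_alignment,
    set_codon,
    translate,
)

MOTIF = MotifSpec(name="CC", codon_indices=(53, 54), required_residues=("C", "C"))


# ---------------------------------------------------------------------------
# independent oracles


def oracle_codon_cols(ref_aligned, mode, codon_index):
    residue_cols = [i + 1 for i, c in enumerate(ref_aligned) if c != "-"]
    if mode == "alignment_columns":
        c0 = residue_cols[0] + 3 * (codon_index - 1)
        return [c0, c0 + 1, c0 + 2]
    return residue_cols[3 * (codon_index - 1):3 * codon_index]


def oracle_n_codons(ref_aligned, mode):
    residue_cols = [i + 1 for i, c in enumerate(ref_aligned) if c != "-"]
    if mode == "alignment_columns":
        return (len(ref_aligned) - residue_cols[0] + 1) // 3
    return len(residue_cols) // 3


def oracle_stops(aln, mode, seq_id, stop_set=STANDARD_STOPS):
    """Per-codon brute force: translate every complete codon, compare to stops."""
    ref = aln.reference().residues
    query = aln.get(seq_id).residues
    n = oracle_n_codons(ref, mode)

    def codon_of(seq, i):
        return "".join(seq[c - 1] for c in oracle_codon_cols(ref, mode, i))

    terminal = None
    for i in range(n, 0, -1):
        c = codon_of(ref, i)
        if "-" not in c and c in stop_set:
            terminal = i
            break
    out = []
    for i in range(1, (terminal if terminal else n + 1)):
        c = codon_of(query, i)
        if "-" in c or set(c) - set("ACGT"):
            continue
        if c in stop_set:
            out.append((i, f"{codon_of(ref, i)}>{c}"))
    return out


def oracle_indels(aln, mode, seq_id):
    """Per-column brute force over (ref, query) state runs."""
    ref = aln.reference().residues
    query = aln.get(seq_id).residues

    def state(col):
        r, q = ref[col - 1], query[col - 1]
        if q == "-" and r != "-":
            return "del"
        if q != "-" and r == "-":
            return "ins"
        return None

    def refpos_at_or_after(col):
        count = 0
        for i, c in enumerate(ref, start=1):
            if c != "-":
                count += 1
                if i >= col:
                    return count
        return ref.replace("-", "").__len__() + 1

    out = []
    cols = range(1, len(ref) + 1)
    for st, group in itertools.groupby(cols, key=state):
        group = list(group)
        if st is None:
            continue
        length = len(group)
        kind = "frameshift_indel" if length % 3 else "inframe_indel"
        if mode == "alignment_columns":
            pos = group[0]
        elif st == "del":
            pos = sum(1 for c in ref[:group[0]] if c != "-")
        else:
            pos = refpos_at_or_after(group[0])
        out.append((kind, pos, length, f"{st}{length}"))
    return out


# ---------------------------------------------------------------------------
# premature stops


class TestPrematureStops:
    def setup_method(self):
        self.ref = make_cds(60, cys_motif_at=(53, 54))

    def _scan(self, query):
        aln = alignment_from({"ref": self.ref, "q": query}, "ref")
        cmap = build_coordinate_map(aln)
        return aln, detect_premature_stops(aln, cmap, "q")

    def test_tgc_to_tga_stop_gain_at_codon_53(self):
        _, events = self._scan(set_codon(self.ref, 53, "TGA"))
        assert [(e.kind, e.ref_position, e.detail) for e in events] == \
            [("premature_stop", 53, "TGC>TGA")]

    def test_gag_to_tag_stop_gain(self):
        ref = set_codon(self.ref, 20, "GAG")
        aln = alignment_from({"ref": ref, "q": set_codon(ref, 20, "TAG")}, "ref")
        cmap = build_coordinate_map(aln)
        events = detect_premature_stops(aln, cmap, "q")
        assert [(e.ref_position, e.detail) for e in events] == [(20, "GAG>TAG")]

    def test_query_identical_to_reference_yields_nothing(self):
        _, events = self._scan(self.ref)
        assert events == []

    def test_terminal_stop_never_reported(self):
        # query keeps only the terminal stop; nothing upstream is a stop
        _, events = self._scan(self.ref)
        assert all(e.ref_position != 60 for e in events)

    def test_gapped_and_ambiguous_codons_skipped(self):
        q = set_codon(self.ref, 10, "T-A")
        q = set_codon(q, 12, "TRA")
        _, events = self._scan(q)
        assert events == []

    def test_custom_stop_set(self):
        aln = alignment_from(
            {"ref": self.ref, "q": set_codon(self.ref, 7, "TGA")}, "ref")
        cmap = build_coordinate_map(aln)
        # vertebrate-mitochondrial-style set without TGA: no event
        assert detect_premature_stops(aln, cmap, "q", {"TAA", "TAG"}) == []


# ---------------------------------------------------------------------------
# indels


class TestIndels:
    @pytest.mark.parametrize("length,kind", [
        (16, "frameshift_indel"), (19, "frameshift_indel"),
        (20, "frameshift_indel"), (3, "inframe_indel"),
        (21, "inframe_indel"), (24, "inframe_indel"),
    ])
    def test_deletion_length_classification(self, length, kind):
        ref = make_cds(30)
        query = ref[:30] + "-" * length + ref[30 + length:]
        aln = alignment_from({"ref": ref, "q": query}, "ref")
        cmap = build_coordinate_map(aln)
        events = detect_indels(aln, cmap, "q")
        assert [(e.kind, e.ref_position, e.length, e.detail) for e in events] == \
            [(kind, 31, length, f"del{length}")]

    @pytest.mark.parametrize("length,kind", [
        (16, "frameshift_indel"), (24, "inframe_indel")])
    def test_insertion_length_classification(self, length, kind):
        ref = make_cds(30)
        ins = "A" * length
        aln = alignment_from({"ref": ref[:30] + "-" * length + ref[30:],
                              "q": ref[:30] + ins + ref[30:]}, "ref")
        cmap = build_coordinate_map(aln)
        events = detect_indels(aln, cmap, "q")
        assert [(e.kind, e.length, e.detail) for e in events] == \
            [(kind, length, f"ins{length}")]

    def test_insertion_position_modes(self):
        ref = make_cds(30)
        aligned_ref = ref[:30] + "---" + ref[30:]
        aln = alignment_from({"ref": aligned_ref,
                              "q": ref[:30] + "AAA" + ref[30:]}, "ref")
        ungapped = build_coordinate_map(aln, mode="ungapped_reference")
        cols = build_coordinate_map(aln, mode="alignment_columns")
        assert detect_indels(aln, ungapped, "q")[0].ref_position == 31
        assert detect_indels(aln, cols, "q")[0].ref_position == 31

    def test_adjacent_runs_stay_separate_events(self):
        """A deletion touching an uncarried insertion block yields two events."""
        ref = make_cds(30)
        aligned_ref = ref[:30] + "---" + ref[30:]
        query = ref[:26] + "----" + "---" + ref[30:]  # del run then both-gap
        aln = alignment_from({"ref": aligned_ref, "q": query}, "ref")
        cmap = build_coordinate_map(aln, mode="ungapped_reference")
        events = detect_indels(aln, cmap, "q")
        assert [(e.kind, e.ref_position, e.length) for e in events] == \
            [("frameshift_indel", 27, 4)]

    def test_event_lengths_sum_to_net_frame_offset(self):
        """Signed indel lengths always reconcile with the ungapped-length gap."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            aln = random_gapped_alignment(rng, n_codons=12)
            cmap = build_coordinate_map(aln)
            for seq_id in aln.ids():
                if seq_id == "ref":
                    continue
                net = 0
                for e in detect_indels(aln, cmap, seq_id):
                    net += e.length if e.detail.startswith("ins") else -e.length
                assert net == frame_offset(aln, seq_id)


# ---------------------------------------------------------------------------
# motif, start, terminal stop


class TestMotifAndEnds:
    def setup_method(self):
        self.ref = make_cds(60, cys_motif_at=(53, 54))

    def _aln(self, query):
        aln = alignment_from({"ref": self.ref, "q": query}, "ref")
        return aln, build_coordinate_map(aln)

    def test_stop_at_motif_codon_is_motif_stop_loss(self):
        aln, cmap = self._aln(set_codon(self.ref, 53, "TGA"))
        events = check_motif(aln, cmap, "q", MOTIF)
        assert [(e.kind, e.ref_position) for e in events] == \
            [("motif_stop_loss", 53)]

    def test_lysine_at_motif_codon_is_substitution_with_detail(self):
        aln, cmap = self._aln(set_codon(self.ref, 53, "AAA"))
        events = check_motif(aln, cmap, "q", MOTIF)
        assert [(e.kind, e.detail) for e in events] == \
            [("motif_substitution", "C53K")]

    def test_intact_motif_yields_no_events(self):
        aln, cmap = self._aln(self.ref)
        assert check_motif(aln, cmap, "q", MOTIF) == []

    def test_gapped_motif_codon_reports_gap_detail(self):
        aln, cmap = self._aln(set_codon(self.ref, 54, "T--"))
        events = check_motif(aln, cmap, "q", MOTIF)
        assert [(e.ref_position, e.detail) for e in events] == [(54, "gap")]

    def test_motif_spec_parse(self):
        spec = MotifSpec.parse("C@53,C@54")
        assert spec.codon_indices == (53, 54)
        assert spec.required_residues == ("C", "C")

    def test_start_loss_detected(self):
        aln, cmap = self._aln("CTG" + self.ref[3:])
        events = detect_start_loss(aln, cmap, "q")
        assert [(e.kind, e.ref_position, e.detail) for e in events] == \
            [("start_loss", 1, "ATG>CTG")]
        aln, cmap = self._aln(self.ref)
        assert detect_start_loss(aln, cmap, "q") == []

    def test_missing_terminal_stop_noted_not_evented(self):
        query = set_codon(self.ref, 60, "TAC")
        aln, cmap = self._aln(query)
        note = check_terminal_stop(aln, cmap, "q")
        assert note and "missing terminal stop" in note and "codon 60" in note
        assert check_terminal_stop(aln, cmap, "ref") is None

    def test_scan_merges_stop_at_motif_codon_into_one_event(self):
        aln, cmap = self._aln(set_codon(self.ref, 53, "TGA"))
        events, _ = scan_sequence(aln, cmap, "q", motif=MOTIF)
        assert [e.kind for e in events] == ["motif_stop_loss"]


# ---------------------------------------------------------------------------
# classification


class TestClassification:
    E = staticmethod(lambda kind, pos=1, length=0: DisruptionEvent(
        seq_id="a", kind=kind, ref_position=pos, length=length))

    @pytest.mark.parametrize("events,verdict", [
        ([("premature_stop", 53, 0)], "pseudogene"),
        ([("motif_stop_loss", 53, 0)], "pseudogene"),
        ([("frameshift_indel", 10, 16)], "pseudogene"),
        ([("start_loss", 1, 0)], "pseudogene"),
        ([("motif_substitution", 53, 0)], "impaired_motif"),
        ([("motif_substitution", 53, 0), ("inframe_indel", 90, 24)],
         "impaired_motif"),
        ([("inframe_indel", 90, 24)], "functional"),
        ([], "functional"),
    ])
    def test_verdict_follows_event_kinds(self, events, verdict):
        evs = [self.E(k, p, l) for k, p, l in events]
        assert classify_allele(evs, seq_id="a").verdict == verdict

    def test_mixed_sequence_ids_rejected(self):
        evs = [DisruptionEvent(seq_id="a", kind="premature_stop", ref_position=1),
               DisruptionEvent(seq_id="b", kind="premature_stop", ref_position=2)]
        with pytest.raises(EventConsistencyError):
            classify_allele(evs)

    def test_species_summary_heterozygote_is_functional(self):
        statuses = [
            classify_allele([], seq_id="p*1", species="pika", allele_label="1"),
            classify_allele([self.E("premature_stop", 53)], seq_id="a",
                            species="pika", allele_label="2"),
        ]
        statuses[1].species = "pika"
        table = summarize_species(statuses)
        assert table.loc[0, "species_verdict"] == "functional"
        assert table.loc[0, "n_alleles"] == 2

    def test_species_summary_all_pseudogene_and_impaired(self):
        def mk(sid, sp, kind, pos, length=0):
            ev = DisruptionEvent(seq_id=sid, kind=kind, ref_position=pos,
                                 length=length)
            return classify_allele([ev], seq_id=sid, species=sp)

        statuses = [
            mk("a", "rabbit", "premature_stop", 53),
            mk("b", "rabbit", "frameshift_indel", 5, 16),
            mk("c", "cottontail", "motif_substitution", 53),
        ]
        table = summarize_species(statuses).set_index("species")
        assert table.loc["rabbit", "species_verdict"] == "pseudogene"
        assert table.loc["cottontail", "species_verdict"] == "impaired"

    def test_eleven_disrupted_species_all_pseudogene(self):
        statuses = [classify_allele(
            [DisruptionEvent(seq_id=f"s{i}", kind="premature_stop",
                             ref_position=53)],
            seq_id=f"s{i}", species=f"sp{i}") for i in range(11)]
        table = summarize_species(statuses)
        assert (table["species_verdict"] == "pseudogene").all()
        assert len(table) == 11


# ---------------------------------------------------------------------------
# end-to-end on the hand-planted mini study


class TestGliresLikeAlignment:
    def test_scan_reproduces_planted_lesion_pattern(self, glires_like_alignment):
        aln = glires_like_alignment
        cmap = build_coordinate_map(aln)
        statuses = {s.seq_id: s for s in scan_alignment(aln, cmap, motif=MOTIF)}
        assert statuses["rabbit_like*1"].verdict == "pseudogene"
        assert statuses["cottontail_like"].verdict == "impaired_motif"
        assert statuses["hare_like"].verdict == "pseudogene"
        assert statuses["pika_like*1"].verdict == "functional"
        assert statuses["pika_like*2"].verdict == "pseudogene"
        table = summarize_species(list(statuses.values())).set_index("species")
        assert table.loc["pika_like", "species_verdict"] == "functional"

    @pytest.mark.parametrize("mode", ["alignment_columns", "ungapped_reference"])
    def test_scan_matches_brute_force_oracle(self, mode):
        """Stops and indels equal the per-codon/per-column brute-force scan."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            aln = random_gapped_alignment(rng, n_codons=10)
            cmap = build_coordinate_map(aln, mode=mode)
            for seq_id in aln.ids():
                if seq_id == "ref":
                    continue
                got = [(e.ref_position, e.detail)
                       for e in detect_premature_stops(aln, cmap, seq_id)]
                assert got == oracle_stops(aln, mode, seq_id)
                got = [(e.kind, e.ref_position, e.length, e.detail)
                       for e in detect_indels(aln, cmap, seq_id)]
                assert got == oracle_indels(aln, mode, seq_id)
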