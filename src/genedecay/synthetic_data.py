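"""Coding-sequence evolution simulator with planted pseudogenization events.

Sequences evolve root-to-leaves along a rooted, branch-length-bearing
phylogeny under a nucleotide substitution model (JC69 or K80).  Lesions —
stop gains, deletions, insertions, motif substitutions — are *planted* on
named branches, applied deterministically at the branch midpoint and inherited
by every descendant; branches downstream of a gene-loss lesion evolve at an
accelerated rate (``rate_multiplier_after_loss``), emulating the relaxation of
selective constraint on a pseudogene.  Substitution noise never creates
indels, so the emitted alignment is exactly gapped and no realignment step is
needed; the sequence truth (which leaf inherited which lesion, and the verdict
that follows) is emitted alongside the alignment for parameter-recovery
testing.

Lineages that have *not* lost the gene can optionally evolve under a minimal
purifying constraint (``functional_constraint``): substitutions that would
create an in-frame stop codon are rejected, and the start codon, the terminal
stop, and any declared constrained codons (e.g. the CC-chemokine cysteine
pair) are held fixed.  A loss lesion lifts the constraint, so pseudogenized
branches drift freely — the asymmetry the relative-rate test is meant to
detect.  With the constraint off, the process is the bare nucleotide model.

Determinism: one seeded random stream, consumed in pre-order over branches
(left to right as written in the newick string), so identical (config, seed)
pairs produce byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq

from genedecay.disruption_scan import DisruptionEvent, MotifSpec, scan_alignment
from genedecay.errors import SimConfigError
from genedecay.ref_coords import build_coordinate_map
from genedecay.relative_rate import classify_sites, tajima_rrt
from genedecay.seq_io import STANDARD_STOPS, CodingAlignment, make_record

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_STOP_ORDER = ("TAA", "TAG", "TGA")  # tie-break order for planted stop gains

MODELS = ("JC69", "K80")

#: all sense codons, grouped by encoded residue (standard code)
_CODONS_BY_RESIDUE: dict[str, list[str]] = {}
for _codon in ("".join(c) for c in itertools.product(_BASES, repeat=3)):
    _aa = str(Seq(_codon).translate())
    if _aa != "*":
        _CODONS_BY_RESIDUE.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_RESIDUE.values():
    _v.sort()


# ---------------------------------------------------------------------------
# planted events


@dataclass(frozen=True)
class PlantedEvent:
    """One lesion (or rate shift) planted on a named branch.

    ``position`` is a 1-based root-sequence coordinate; insertions go *after*
    ``position`` (0 inserts before the first base).  ``codon_index`` addresses
    stop gains and motif substitutions.
    """

    kind: str  # stop_gain | deletion | insertion | motif_sub | rate_shift
    branch: str
    codon_index: int = 0
    position: int = 0
    length: int = 0
    target_residue: str = ""
    multiplier: float = 1.0

    @property
    def is_loss(self) -> bool:
        """Does this lesion trigger post-loss rate acceleration?"""
        if self.kind == "stop_gain":
            return True
        if self.kind in ("deletion", "insertion"):
            return self.length % 3 != 0
        return False


def stop_gain(branch: str, codon_index: int) -> PlantedEvent:
    """Mutate a codon to the nearest stop (minimal base changes, tie TAA<TAG<TGA)."""
    return PlantedEvent(kind="stop_gain", branch=branch, codon_index=codon_index)


def deletion(branch: str, position: int, length: int) -> PlantedEvent:
    return PlantedEvent(kind="deletion", branch=branch, position=position,
                        length=length)


def insertion(branch: str, position: int, length: int) -> PlantedEvent:
    return PlantedEvent(kind="insertion", branch=branch, position=position,
                        length=length)


def motif_sub(branch: str, codon_index: int, target_residue: str) -> PlantedEvent:
    return PlantedEvent(kind="motif_sub", branch=branch, codon_index=codon_index,
                        target_residue=target_residue.upper())


def rate_shift(branch: str, multiplier: float) -> PlantedEvent:
    """Multiply the substitution rate from this branch's midpoint onward (no lesion)."""
    return PlantedEvent(kind="rate_shift", branch=branch, multiplier=multiplier)


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class SimConfig:
    """Everything a simulation needs; identical (config, seed) replays exactly."""

    tree: str                      # newick, rooted, branch lengths in subs/site
    root_sequence: str             # CDS: length % 3 == 0, starts ATG, ends stop
    substitution_model: str = "JC69"
    kappa: float = 2.0             # K80 transition/transversion rate ratio
    planted_events: list[PlantedEvent] = field(default_factory=list)
    rate_multiplier_after_loss: float = 1.0
    heterozygous: list[tuple[str, PlantedEvent]] = field(default_factory=list)
    reference_id: str = "ancestor"
    include_reference: bool = True
    branch_scale: float = 1.0      # global multiplier on branch lengths
    functional_constraint: bool = True  # purifying constraint until loss
    constrained_codons: tuple[int, ...] = ()  # held fixed while functional
    seed: int | None = None


@dataclass
class SimTruth:
    """The planted-event ledger a simulation emits.

    ``leaf_events`` holds the *effective* (observable) lesions per emitted
    record: later codon events on a root-to-leaf path overwrite earlier ones
    at the same codon, and codon lesions fully erased by a later deletion are
    dropped.  ``inherited_events`` keeps the raw inherited list;
    ``branch_substitutions`` the realized per-branch substitution counts.
    """

    leaf_events: dict[str, list[PlantedEvent]]
    inherited_events: dict[str, list[PlantedEvent]]
    expected_verdict: dict[str, str]
    branch_substitutions: dict[str, int]

    def to_dict(self) -> dict:
        def evs(events: list[PlantedEvent]) -> list[dict]:
            return [{"kind": e.kind, "branch": e.branch,
                     "codon_index": e.codon_index, "position": e.position,
                     "length": e.length, "target_residue": e.target_residue}
                    for e in events]
        return {
            "leaf_events": {k: evs(v) for k, v in self.leaf_events.items()},
            "expected_verdict": dict(self.expected_verdict),
            "branch_substitutions": dict(self.branch_substitutions),
        }


# ---------------------------------------------------------------------------
# substitution machinery


def _transition_matrix(model: str, t: float, kappa: float = 2.0) -> np.ndarray:
    """Per-site base transition probabilities P(t), order A C G T.

    Branch lengths are expected substitutions per site; K80 rates are
    normalized so alpha + 2*beta = 1 (alpha/beta = kappa).
    """
    if model not in MODELS:
        raise SimConfigError(f"substitution model must be one of {MODELS}")
    if t < 0:
        raise SimConfigError(f"negative branch length {t}")
    if model == "JC69":
        same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        diff = (1.0 - same) / 3.0
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    # transitions: A<->G (purines), C<->T (pyrimidines)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts
    return P


def _sample_states(P: np.ndarray, current: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw new states per site from the rows of P indexed by current states."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(current.size)
    return (u[:, None] >= cum[current]).sum(axis=1).astype(np.int8)


def jc69_expected_divergence(t: float) -> float:
    """Closed-form probability that a site differs across a JC69 branch of length t."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


# ---------------------------------------------------------------------------
# lineage state


#: stop codons as base-index triplets (A=0, C=1, G=2, T=3)
_STOP_CODES = np.array([[3, 0, 0], [3, 0, 2], [3, 2, 0]], dtype=np.int8)


@dataclass
class _Lineage:
    seq: np.ndarray                       # int8 over root coords; -1 = deleted
    frozen: np.ndarray                    # bool; planted lesion sites
    insertions: dict[int, np.ndarray]     # planted-event index -> residues
    events: list[PlantedEvent]
    rate_factor: float = 1.0
    lost: bool = False                    # inherited a loss lesion

    def copy(self) -> "_Lineage":
        return _Lineage(seq=self.seq.copy(), frozen=self.frozen.copy(),
                        insertions={k: v.copy() for k, v in self.insertions.items()},
                        events=list(self.events), rate_factor=self.rate_factor,
                        lost=self.lost)

    def evolve(self, t: float, model: str, kappa: float,
               rng: np.random.Generator,
               protected: np.ndarray | None = None) -> int:
        """Apply substitution noise over an effective branch length t; return #changes.

        ``protected`` (a bool site mask) is honoured, and stop-creating codon
        changes are rejected, only while the lineage is still functional.
        """
        if t <= 0:
            return 0
        constrained = protected is not None and not self.lost
        P = _transition_matrix(model, t, kappa)
        changed = 0
        mask = (self.seq >= 0) & ~self.frozen
        if constrained:
            mask &= ~protected
        idx = np.nonzero(mask)[0]
        if idx.size:
            before = self.seq.copy()
            cur = self.seq[idx].astype(np.intp)
            self.seq[idx] = _sample_states(P, cur, rng)
            if constrained:
                self._reject_new_stops(before)
            changed += int(np.count_nonzero(self.seq[idx] != before[idx]))
        for key in sorted(self.insertions):
            arr = self.insertions[key]
            new = _sample_states(P, arr.astype(np.intp), rng)
            changed += int(np.count_nonzero(new != arr))
            self.insertions[key] = new
        return changed

    def _reject_new_stops(self, before: np.ndarray) -> None:
        """Revert codons that substitution noise turned into in-frame stops.

        Only reachable on functional lineages, whose sequence is complete
        (no deletions), so the root reading frame applies throughout.
        """
        codons = self.seq.reshape(-1, 3)
        is_stop = (codons[:, None, :] == _STOP_CODES[None, :, :]).all(axis=2).any(axis=1)
        is_stop[-1] = False  # terminal stop is legitimate (and protected anyway)
        for ci in np.nonzero(is_stop)[0]:
            sites = slice(3 * ci, 3 * ci + 3)
            self.seq[sites] = before[sites]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise SimConfigError(f"root sequence contains non-ACGT base {exc}") from exc


def _decode(arr: Iterable[int]) -> str:
    return "".join(_BASES[i] for i in arr)


def _nearest_codon(current: str, candidates: Sequence[str]) -> str:
    """Candidate with fewest base changes from ``current``; ties keep list order."""
    best, best_d = None, 4
    for cand in candidates:
        d = sum(a != b for a, b in zip(current, cand))
        if d < best_d:
            best, best_d = cand, d
    return best


def _validate_root(seq: str) -> None:
    if len(seq) < 9 or len(seq) % 3:
        raise SimConfigError(
            f"root sequence length {len(seq)} is not a usable multiple of 3")
    if seq[:3] != "ATG":
        raise SimConfigError("root sequence must start with ATG")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STANDARD_STOPS:
        raise SimConfigError("root sequence must end in a stop codon")
    internal = [i + 1 for i, c in enumerate(codons[:-1]) if c in STANDARD_STOPS]
    if internal:
        raise SimConfigError(f"root sequence has internal stop at codon {internal[0]}")


def _apply_event(lin: _Lineage, ev: PlantedEvent, ev_index: int,
                 config: SimConfig, rng: np.random.Generator) -> None:
    n = len(config.root_sequence)
    if ev.kind in ("stop_gain", "motif_sub"):
        if not 1 <= ev.codon_index <= n // 3:
            raise SimConfigError(
                f"planted {ev.kind} codon {ev.codon_index} outside 1..{n // 3}")
        sites = np.arange(3 * (ev.codon_index - 1), 3 * ev.codon_index)
        if np.any(lin.seq[sites] < 0):
            raise SimConfigError(
                f"planted {ev.kind} at codon {ev.codon_index} targets deleted sites")
        current = _decode(lin.seq[sites])
        if ev.kind == "stop_gain":
            target = _nearest_codon(current, _STOP_ORDER)
        else:
            candidates = _CODONS_BY_RESIDUE.get(ev.target_residue)
            if not candidates:
                raise SimConfigError(
                    f"no sense codon encodes residue {ev.target_residue!r}")
            target = _nearest_codon(current, candidates)
        lin.seq[sites] = _encode(target)
        lin.frozen[sites] = True
    elif ev.kind == "deletion":
        if not (1 <= ev.position and ev.position + ev.length - 1 <= n
                and ev.length > 0):
            raise SimConfigError(
                f"planted deletion ({ev.position}, len {ev.length}) outside "
                f"root sequence of {n} nt")
        lin.seq[ev.position - 1:ev.position - 1 + ev.length] = -1
    elif ev.kind == "insertion":
        if not (0 <= ev.position <= n and ev.length > 0):
            raise SimConfigError(
                f"planted insertion ({ev.position}, len {ev.length}) outside "
                f"root sequence of {n} nt")
        lin.insertions[ev_index] = rng.integers(0, 4, ev.length).astype(np.int8)
    elif ev.kind == "rate_shift":
        lin.rate_factor = ev.multiplier
    else:
        raise SimConfigError(f"unknown planted event kind {ev.kind!r}")
    if ev.is_loss:
        lin.lost = True
        lin.rate_factor = max(lin.rate_factor, config.rate_multiplier_after_loss)
    lin.events.append(ev)


def _effective_events(events: Sequence[PlantedEvent]) -> list[PlantedEvent]:
    """Resolve overwrites: later codon events win; deletions erase covered codons."""
    indels = [e for e in events if e.kind in ("deletion", "insertion")]
    codon_claims: dict[int, PlantedEvent] = {}
    for e in events:
        if e.kind in ("stop_gain", "motif_sub"):
            codon_claims[e.codon_index] = e
    kept_codon_events = []
    for ci, e in sorted(codon_claims.items()):
        span = range(3 * (ci - 1) + 1, 3 * ci + 1)
        covered = all(any(d.kind == "deletion"
                          and d.position <= p <= d.position + d.length - 1
                          for d in indels) for p in span)
        if not covered:
            kept_codon_events.append(e)
    return indels + kept_codon_events


def _expected_verdict(effective: Sequence[PlantedEvent]) -> str:
    if any(e.kind == "stop_gain" or
           (e.kind in ("deletion", "insertion") and e.length % 3)
           for e in effective):
        return "pseudogene"
    if any(e.kind == "motif_sub" for e in effective):
        return "impaired_motif"
    return "functional"


# ---------------------------------------------------------------------------
# the simulator


def _branch_ids(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    ids: dict[str, dendropy.Node] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        else:
            label = f"node{i}"
        if label in ids:
            raise SimConfigError(f"duplicate branch/leaf label {label!r} in tree")
        ids[label] = node
        node._genedecay_id = label  # type: ignore[attr-defined]
    return ids


def simulate(config: SimConfig, seed: int | None = None
             ) -> tuple[CodingAlignment, SimTruth]:
    """Run one simulation; returns the exactly-gapped alignment and its truth.

    ``seed`` overrides ``config.seed``; one of the two must be set.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise SimConfigError("a seed is required (config.seed or the seed argument)")
    _validate_root(config.root_sequence)
    if config.substitution_model not in MODELS:
        raise SimConfigError(
            f"substitution model must be one of {MODELS}, "
            f"got {config.substitution_model!r}")
    tree = dendropy.Tree.get(data=config.tree, schema="newick",
                             preserve_underscores=True)
    ids = _branch_ids(tree)
    events_by_branch: dict[str, list[tuple[int, PlantedEvent]]] = {}
    for i, ev in enumerate(config.planted_events):
        if ev.branch not in ids:
            raise SimConfigError(
                f"planted event targets unknown branch {ev.branch!r}; "
                f"known: {sorted(ids)}")
        events_by_branch.setdefault(ev.branch, []).append((i, ev))

    rng = np.random.default_rng(seed)
    model, kappa = config.substitution_model, config.kappa
    n_sites = len(config.root_sequence)
    protected = None
    if config.functional_constraint:
        protected = np.zeros(n_sites, dtype=bool)
        protected[:3] = True            # start codon
        protected[-3:] = True           # terminal stop
        for ci in config.constrained_codons:
            if not 1 <= ci <= n_sites // 3:
                raise SimConfigError(
                    f"constrained codon {ci} outside 1..{n_sites // 3}")
            protected[3 * (ci - 1):3 * ci] = True
    root_lin = _Lineage(seq=_encode(config.root_sequence),
                        frozen=np.zeros(n_sites, dtype=bool),
                        insertions={}, events=[])
    states: dict[dendropy.Node, _Lineage] = {}
    branch_subs: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        label = node._genedecay_id  # type: ignore[attr-defined]
        if node.parent_node is None:
            lin = root_lin
            for i, ev in events_by_branch.get(label, []):
                _apply_event(lin, ev, i, config, rng)
            states[node] = lin
            continue
        lin = states[node.parent_node].copy()
        b = (node.edge.length or 0.0) * config.branch_scale
        here = events_by_branch.get(label, [])
        if here:
            changed = lin.evolve(0.5 * b * lin.rate_factor, model, kappa, rng,
                                 protected)
            for i, ev in here:
                _apply_event(lin, ev, i, config, rng)
            changed += lin.evolve(0.5 * b * lin.rate_factor, model, kappa, rng,
                                  protected)
        else:
            changed = lin.evolve(b * lin.rate_factor, model, kappa, rng,
                                 protected)
        branch_subs[label] = changed
        states[node] = lin

    # heterozygous leaves: a second allele with an extra lesion, no extra noise
    het_by_leaf = {}
    for leaf_label, ev in config.heterozygous:
        if leaf_label not in ids or not ids[leaf_label].is_leaf():
            raise SimConfigError(
                f"heterozygous spec targets unknown leaf {leaf_label!r}")
        if ev.kind == "insertion":
            raise SimConfigError(
                "heterozygous allele events are limited to substitution or "
                "deletion lesions")
        het_by_leaf.setdefault(leaf_label, []).append(ev)

    # alignment column layout: root coordinates interleaved with insertion blocks
    ins_blocks = [(ev.position, i, ev.length)
                  for i, ev in enumerate(config.planted_events)
                  if ev.kind == "insertion"]
    ins_blocks.sort(key=lambda x: (x[0], x[1]))
    layout: list[tuple[str, int, int]] = []  # ("ref", root_idx, 1)|("ins", idx, len)
    blocks_at: dict[int, list[tuple[int, int]]] = {}
    for pos, i, length in ins_blocks:
        blocks_at.setdefault(pos, []).append((i, length))
    for i, length in blocks_at.get(0, []):
        layout.append(("ins", i, length))
    for p in range(1, len(config.root_sequence) + 1):
        layout.append(("ref", p - 1, 1))
        for i, length in blocks_at.get(p, []):
            layout.append(("ins", i, length))

    def render(lin: _Lineage) -> str:
        parts = []
        for kind, idx, length in layout:
            if kind == "ref":
                v = lin.seq[idx]
                parts.append("-" if v < 0 else _BASES[v])
            else:
                arr = lin.insertions.get(idx)
                parts.append(_decode(arr) if arr is not None else "-" * length)
        return "".join(parts)

    records = []
    leaf_events: dict[str, list[PlantedEvent]] = {}
    inherited: dict[str, list[PlantedEvent]] = {}
    verdicts: dict[str, str] = {}
    if config.include_reference:
        records.append(make_record(config.reference_id, render(root_lin)))

    def add_leaf_record(rec_id: str, lin: _Lineage) -> None:
        records.append(make_record(rec_id, render(lin)))
        raw = [e for e in lin.events if e.kind != "rate_shift"]
        inherited[rec_id] = raw
        eff = _effective_events(raw)
        leaf_events[rec_id] = eff
        verdicts[rec_id] = _expected_verdict(eff)

    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            continue
        label = node._genedecay_id  # type: ignore[attr-defined]
        lin = states[node]
        if label in het_by_leaf:
            add_leaf_record(f"{label}*1", lin)
            allele2 = lin.copy()
            for ev in het_by_leaf[label]:
                _apply_event(allele2, ev, -1, config, rng)
            add_leaf_record(f"{label}*2", allele2)
        else:
            add_leaf_record(label, lin)

    aln = CodingAlignment(records=records, reference_id=config.reference_id
                          if config.include_reference else records[0].id)
    truth = SimTruth(leaf_events=leaf_events, inherited_events=inherited,
                     expected_verdict=verdicts, branch_substitutions=branch_subs)
    return aln, truth


# ---------------------------------------------------------------------------
# canned study conditions


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """A valid CDS: ATG, ``n_codons - 2`` random sense codons, TAA."""
    if n_codons < 3:
        raise SimConfigError("need at least 3 codons (start, one sense, stop)")
    sense = sorted(c for v in _CODONS_BY_RESIDUE.values() for c in v if c != "ATG")
    sense.append("ATG")  # ATG is a sense codon too
    sense.sort()
    middle = [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
    return "ATG" + "".join(middle) + "TAA"


#: the CC-chemokine cysteine pair of the mature protein, codons 53-54
GLIRES_MOTIF = MotifSpec(name="CC_motif", codon_indices=(53, 54),
                         required_residues=("C", "C"))

_GLIRES_TREE = (
    "(((((eur_rabbit:0.015,riv_rabbit:0.015)oryc:0.01,"
    "(hare_a:0.015,hare_b:0.015)lepus:0.01)cladeA:0.01,"
    "(volcano_rabbit:0.02,(cottontail_a:0.01,cottontail_b:0.01)"
    "cottontails:0.01)cladeB:0.01)leporids:0.02,"
    "(pika_a:0.02,(pika_b:0.015,hoffmanni_pika:0.015)pikaB:0.01)pikas:0.02)"
    "lagomorphs:0.02,outgroup:0.06)root;"
)

#: leaves of the pseudogenized ("leporid-like") clade of the preset
GLIRES_PSEUDOGENE_LEAVES = ("eur_rabbit", "riv_rabbit", "hare_a", "hare_b",
                            "volcano_rabbit", "cottontail_a", "cottontail_b")


def glires_preset(seed: int = 42) -> SimConfig:
    """A Glires-like study condition with independently planted lesions.

    One clade of seven leaves shares a stop gain at the first cysteine of the
    CC motif (codon 53) planted on its stem; its two subclades carry
    frame-disrupting signal-peptide-region deletions of 16 and 19 nt; a
    cottontail-like sub-branch replaces the stop with a lysine substitution
    and adds a 20-nt deletion further downstream.  The sister (pika-like)
    clade is intact except for one heterozygous leaf whose second allele
    carries the same codon-53 stop.  An outgroup leaf supplies the
    relative-rate comparator; pseudogenized branches evolve at twice the base
    rate.  Root-to-leaf path lengths stay below 0.3 substitutions/site.
    """
    root_rng = np.random.default_rng(97531)
    root = random_coding_sequence(120, root_rng)
    # plant the Cys-Cys motif at codons 53-54 (cannot create a stop)
    root = root[:156] + "TGCTGC" + root[162:]
    events = [
        stop_gain("leporids", 53),
        deletion("cladeA", position=40, length=16),
        deletion("cladeB", position=40, length=19),
        motif_sub("cottontails", 53, "K"),
        deletion("cottontails", position=170, length=20),
    ]
    return SimConfig(
        tree=_GLIRES_TREE,
        root_sequence=root,
        substitution_model="JC69",
        planted_events=events,
        rate_multiplier_after_loss=2.0,
        heterozygous=[("hoffmanni_pika",
                       PlantedEvent(kind="stop_gain", branch="hoffmanni_pika",
                                    codon_index=53))],
        functional_constraint=True,
        constrained_codons=(53, 54),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# recovery scoring and rate-test calibration helpers


@dataclass(frozen=True)
class RecoveryScore:
    """Precision/recall of detected events against the planted truth."""

    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    recall_by_kind: dict[str, float]


def _event_matches(planted: PlantedEvent, det: DisruptionEvent) -> bool:
    if planted.kind == "stop_gain":
        return (det.kind in ("premature_stop", "motif_stop_loss")
                and det.ref_position == planted.codon_index)
    if planted.kind == "motif_sub":
        return (det.kind == "motif_substitution"
                and det.ref_position == planted.codon_index)
    if planted.kind == "deletion":
        return (det.kind in ("frameshift_indel", "inframe_indel")
                and det.detail.startswith("del")
                and det.ref_position == planted.position
                and det.length == planted.length)
    if planted.kind == "insertion":
        return (det.kind in ("frameshift_indel", "inframe_indel")
                and det.detail.startswith("ins")
                and det.ref_position == planted.position + 1
                and det.length == planted.length)
    return False


def score_recovery(truth: SimTruth,
                   detected: dict[str, list[DisruptionEvent]]) -> RecoveryScore:
    """Match detected events to planted truth, per record, one-to-one.

    Detected events use the ungapped-reference numbering, which coincides with
    root-sequence coordinates.
    """
    tp = fp = fn = 0
    kind_totals: dict[str, int] = {}
    kind_hits: dict[str, int] = {}
    for rec_id, planted in truth.leaf_events.items():
        remaining = list(detected.get(rec_id, []))
        for p in planted:
            kind_totals[p.kind] = kind_totals.get(p.kind, 0) + 1
            hit = next((d for d in remaining if _event_matches(p, d)), None)
            if hit is not None:
                remaining.remove(hit)
                tp += 1
                kind_hits[p.kind] = kind_hits.get(p.kind, 0) + 1
            else:
                fn += 1
        fp += len(remaining)
    for rec_id, dets in detected.items():
        if rec_id not in truth.leaf_events:
            fp += len(dets)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    by_kind = {k: kind_hits.get(k, 0) / n for k, n in kind_totals.items()}
    return RecoveryScore(precision=precision, recall=recall, true_positives=tp,
                         false_positives=fp, false_negatives=fn,
                         recall_by_kind=by_kind)


def recover_events(aln: CodingAlignment,
                   motif: MotifSpec | None = None
                   ) -> dict[str, list[DisruptionEvent]]:
    """Scan a simulated alignment in root (ungapped-reference) coordinates."""
    cmap = build_coordinate_map(aln, mode="ungapped_reference")
    statuses = scan_alignment(aln, cmap, motif=motif)
    return {s.seq_id: s.events for s in statuses}


def rrt_rejection_rate(rate_multiplier: float = 1.0, n_replicates: int = 400,
                       seed: int = 0, n_codons: int = 334, alpha: float = 0.05,
                       branch_ingroup: float = 0.06, branch_anc: float = 0.04,
                       branch_outgroup: float = 0.12) -> float:
    """Monte-Carlo rejection frequency of the relative-rate test.

    Simulates JC69 triples on ``((A,B)anc,OUT)`` where taxon B's terminal
    branch carries a rate shift of ``rate_multiplier`` (none when 1.0, the
    null), then runs the test at level ``alpha``.  Used for level calibration
    and power-monotonicity checks.
    """
    tree = (f"((A:{branch_ingroup},B:{branch_ingroup})anc:{branch_anc},"
            f"OUT:{branch_outgroup})root;")
    root = random_coding_sequence(n_codons, np.random.default_rng(seed))
    events = ([] if rate_multiplier == 1.0
              else [rate_shift("B", rate_multiplier)])
    # bare neutral model: the test's sampling assumptions, no constraint
    config = SimConfig(tree=tree, root_sequence=root, substitution_model="JC69",
                       planted_events=events, functional_constraint=False)
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, n_replicates)
    rejected = 0
    for s in seeds:
        aln, _ = simulate(config, seed=int(s))
        counts = classify_sites(aln.get("A"), aln.get("B"), aln.get("OUT"))
        if counts.n_unique_a + counts.n_unique_b == 0:
            continue
        res = tajima_rrt(counts.n_unique_a, counts.n_unique_b)
        if res.p_value < alpha:
            rejected += 1
    return rejected / n_replicates
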