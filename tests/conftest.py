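"""Shared fixture builders: small coding alignments generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from genedecay.seq_io import CodingAlignment, make_record

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
)


def make_cds(n_codons: int = 60, seed: int = 0,
             cys_motif_at: tuple[int, ...] = ()) -> str:
    """A random valid CDS: ATG ... TAA, optionally with TGC planted at codons."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [SENSE_CODONS[i]
                        for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
    codons.append("TAA")
    for idx in cys_motif_at:
        codons[idx - 1] = "TGC"
    return "".join(codons)


def set_codon(seq: str, codon_index: int, new_codon: str) -> str:
    """Replace codon ``codon_index`` (1-based, CDS frame) of an ungapped CDS."""
    i = 3 * (codon_index - 1)
    return seq[:i] + new_codon + seq[i + 3:]


def alignment_from(seqs: dict[str, str], reference_id: str,
                   coding_start: int = 1) -> CodingAlignment:
    """Build an in-memory alignment from {id: aligned residues}."""
    return CodingAlignment(records=[make_record(k, v) for k, v in seqs.items()],
                           reference_id=reference_id, coding_start=coding_start)


def random_gapped_alignment(rng: np.random.Generator, n_codons: int,
                            n_queries: int = 3) -> CodingAlignment:
    """A reference CDS plus queries carrying random substitutions and indels.

    Insertion blocks appear as reference gap columns; each query independently
    carries or lacks each block, so both-gap columns occur.  Used by the
    oracle-equivalence tests.
    """
    ref = make_cds(n_codons, seed=int(rng.integers(1 << 30)))
    n = len(ref)
    n_blocks = int(rng.integers(0, 3))
    blocks = []  # (position after this many ref nt, length)
    for _ in range(n_blocks):
        blocks.append((int(rng.integers(0, n + 1)), int(rng.integers(1, 7))))
    blocks.sort()

    queries = {}
    for q in range(n_queries):
        seq = list(ref)
        for i in range(n):  # substitutions
            if rng.random() < 0.05:
                seq[i] = "ACGT"[rng.integers(0, 4)]
        for _ in range(int(rng.integers(0, 3))):  # deletion runs
            run = int(rng.integers(1, 9))
            start = int(rng.integers(0, max(1, n - run)))
            for i in range(start, start + run):
                seq[i] = "-"
        queries[f"q{q}"] = seq

    ref_aligned = list(ref)
    for pos, length in reversed(blocks):
        ref_aligned[pos:pos] = ["-"] * length
        for q, seq in queries.items():
            if rng.random() < 0.5:
                ins = ["ACGT"[i] for i in rng.integers(0, 4, length)]
            else:
                ins = ["-"] * length
            seq[pos:pos] = ins
    seqs = {"ref": "".join(ref_aligned)}
    seqs.update({k: "".join(v) for k, v in queries.items()})
    return alignment_from(seqs, "ref")


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


@pytest.fixture
def glires_like_alignment() -> CodingAlignment:
    """A hand-planted mini study: reference plus lesioned and intact alleles.

    The reference carries the Cys-Cys motif (TGC TGC) at codons 53-54; queries
    reproduce the canonical lesions: a codon-53 stop gain, a Cys->Lys motif
    substitution, frameshift deletions, and one intact allele.
    """
    ref = make_cds(60, seed=42, cys_motif_at=(53, 54))
    stop53 = set_codon(ref, 53, "TGA")
    lys53 = set_codon(ref, 53, "AAA")
    del16 = ref[:39] + "-" * 16 + ref[55:]
    return alignment_from({
        "reference": ref,
        "rabbit_like*1": stop53,
        "cottontail_like": lys53,
        "hare_like": del16,
        "pika_like*1": ref,
        "pika_like*2": stop53,
    }, "reference")
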