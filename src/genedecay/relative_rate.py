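"""Tajima's relative-rate test.

Given two ingroup sequences A and B and an outgroup O, each aligned site falls
into one of five categories: unique to A (A differs while B equals O), unique
to B, unique to O, all three distinct, or all identical.  Under equal
evolutionary rates in the two ingroup lineages the unique-difference counts
``nA`` and ``nB`` have the same expectation, and

    chi^2 = (nA - nB)^2 / (nA + nB)

is asymptotically chi-square distributed with one degree of freedom.  The
statistic is used uncorrected (no continuity correction); p-values come from
the upper tail.  Sites containing a gap or ambiguity code in any of the three
sequences are excluded ("complete deletion") before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from genedecay.errors import (
    AlignmentShapeError,
    MissingSequenceError,
    UndefinedTestError,
)
from genedecay.seq_io import CodingAlignment, SequenceRecord

DELETION_POLICIES = ("complete", "pairwise-complete")

_VALID_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SiteCounts:
    """Per-category site tally for one (A, B, outgroup) triple."""

    n_sites_used: int
    n_unique_a: int
    n_unique_b: int
    n_unique_o: int
    n_all_different: int
    n_identical: int

    def __post_init__(self) -> None:
        total = (self.n_unique_a + self.n_unique_b + self.n_unique_o
                 + self.n_all_different + self.n_identical)
        if total != self.n_sites_used:
            raise ValueError(
                f"category counts sum to {total}, not n_sites_used="
                f"{self.n_sites_used}")


@dataclass(frozen=True)
class RRTResult:
    """Relative-rate test outcome for one taxon pair against the outgroup."""

    chi_square: float
    degrees_of_freedom: int
    p_value: float
    counts: SiteCounts | tuple[int, int]
    taxon_a: str = ""
    taxon_b: str = ""
    outgroup: str = ""

    @property
    def n_unique_a(self) -> int:
        if isinstance(self.counts, SiteCounts):
            return self.counts.n_unique_a
        return self.counts[0]

    @property
    def n_unique_b(self) -> int:
        if isinstance(self.counts, SiteCounts):
            return self.counts.n_unique_b
        return self.counts[1]


def _as_bytes(seq: SequenceRecord | str) -> np.ndarray:
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    return np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)


def classify_sites(a: SequenceRecord | str, b: SequenceRecord | str,
                   outgroup: SequenceRecord | str,
                   deletion_policy: str = "complete") -> SiteCounts:
    """Tally the five site categories for one aligned triple.

    Every column containing a gap or an ambiguity code in any of the three
    sequences is excluded from ``n_sites_used``.  For a bare three-sequence
    comparison the two deletion policies coincide (each category needs all
    three residues), so both names are accepted and behave identically here;
    the name records the caller's intent for larger-alignment workflows.
    """
    if deletion_policy not in DELETION_POLICIES:
        raise ValueError(f"deletion_policy must be one of {DELETION_POLICIES}, "
                         f"got {deletion_policy!r}")
    sa, sb, so = _as_bytes(a), _as_bytes(b), _as_bytes(outgroup)
    if not (sa.size == sb.size == so.size):
        raise AlignmentShapeError(
            f"triple lengths differ: {sa.size}, {sb.size}, {so.size}")
    usable = (np.isin(sa, _VALID_BYTES) & np.isin(sb, _VALID_BYTES)
              & np.isin(so, _VALID_BYTES))
    sa, sb, so = sa[usable], sb[usable], so[usable]
    eq_ab = sa == sb
    eq_ao = sa == so
    eq_bo = sb == so
    n_identical = int(np.count_nonzero(eq_ab & eq_ao))
    n_unique_a = int(np.count_nonzero(eq_bo & ~eq_ab))
    n_unique_b = int(np.count_nonzero(eq_ao & ~eq_ab))
    n_unique_o = int(np.count_nonzero(eq_ab & ~eq_ao))
    n_all_diff = int(np.count_nonzero(~eq_ab & ~eq_ao & ~eq_bo))
    return SiteCounts(n_sites_used=int(sa.size), n_unique_a=n_unique_a,
                      n_unique_b=n_unique_b, n_unique_o=n_unique_o,
                      n_all_different=n_all_diff, n_identical=n_identical)


def chi2_survival(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution.

    For df=1 this equals ``erfc(sqrt(x/2))``.
    """
    if x < 0:
        raise ValueError(f"chi-square statistic must be non-negative, got {x}")
    return float(_chi2_dist.sf(x, df))


def tajima_rrt(n_unique_a: int, n_unique_b: int) -> RRTResult:
    """The relative-rate test from the two unique-difference counts."""
    if n_unique_a < 0 or n_unique_b < 0:
        raise ValueError("unique-difference counts must be non-negative")
    total = n_unique_a + n_unique_b
    if total == 0:
        raise UndefinedTestError(
            "nA + nB == 0: the relative-rate test is undefined, not zero")
    chi_square = (n_unique_a - n_unique_b) ** 2 / total
    return RRTResult(chi_square=chi_square, degrees_of_freedom=1,
                     p_value=chi2_survival(chi_square, 1),
                     counts=(n_unique_a, n_unique_b))


def rrt_from_counts(counts: SiteCounts, *, taxon_a: str = "", taxon_b: str = "",
                    outgroup: str = "") -> RRTResult:
    """Run the test on a :class:`SiteCounts`, carrying the full tally and labels."""
    base = tajima_rrt(counts.n_unique_a, counts.n_unique_b)
    return RRTResult(chi_square=base.chi_square, degrees_of_freedom=1,
                     p_value=base.p_value, counts=counts,
                     taxon_a=taxon_a, taxon_b=taxon_b, outgroup=outgroup)


def batch_rrt(aln: CodingAlignment, taxon_a: str, taxon_b_list: Sequence[str],
              outgroup: str, deletion_policy: str = "complete") -> list[RRTResult]:
    """One relative-rate test per taxon B against a fixed taxon A and outgroup."""
    for seq_id in [taxon_a, outgroup, *taxon_b_list]:
        if seq_id not in set(aln.ids()):
            raise MissingSequenceError(
                f"sequence id {seq_id!r} not found in alignment")
    a = aln.get(taxon_a)
    o = aln.get(outgroup)
    results = []
    for tb in taxon_b_list:
        counts = classify_sites(a, aln.get(tb), o, deletion_policy)
        results.append(rrt_from_counts(counts, taxon_a=taxon_a, taxon_b=tb,
                                       outgroup=outgroup))
    return results


def rrt_table(results: Sequence[RRTResult]) -> pd.DataFrame:
    """Presentation table: labels, counts, and 2-dp chi-square / p-value.

    Rounding happens only here; results keep full precision internally.
    """
    rows = [{"taxon_a": r.taxon_a, "taxon_b": r.taxon_b, "outgroup": r.outgroup,
             "n_unique_a": r.n_unique_a, "n_unique_b": r.n_unique_b,
             "chi_square": round(r.chi_square, 2),
             "p_value": round(r.p_value, 2)} for r in results]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "outgroup",
                                       "n_unique_a", "n_unique_b",
                                       "chi_square", "p_value"])
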