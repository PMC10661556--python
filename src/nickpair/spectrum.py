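"""Nick-anchored deletion-length spectra and junction summary metrics.

For a pair of nick junctions NickA < NickB on an amplicon, every
deletion-bearing read is anchored at whichever nick one of its deletion
boundaries sits on (within a small tolerance); the *first nick* is the
anchor and the signed deletion length measures how far the other boundary
extends toward (+) or away from (-) the second nick.  A deletion running
exactly from NickA to NickB therefore has signed length NickB - NickA on
either anchoring; boundary ties are broken toward NickA so each read is
counted once.

Summary metrics over the edited reads:

* full-removal fraction -- % whose deletions cover the whole inter-nick
  interval (up to a small near-full tolerance), i.e. the 3' overhang
  region was removed entirely;
* precise-deletion fraction -- reads deleting exactly nick-to-nick with
  no insertion;
* median deletion length -- median total deleted nt (by default over
  deletion-bearing reads).

Also included: the indel-frequency fold change between two conditions and
ordinary least-squares regression of fold stimulation on overhang length
(Pearson R with its exact two-sided t-based p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats as _scipy_stats

from .caller import EditingStats, IndelCall
from .geometry import InputError

__all__ = [
    "JunctionRecord",
    "SpectrumSummary",
    "RegressionResult",
    "assign_first_nick",
    "deletion_spectrum",
    "summarize",
    "fold_change",
    "overhang_stimulation_regression",
]

_EDITED_EXCLUDED = ("unedited", "low_quality")


@dataclass(frozen=True)
class JunctionRecord:
    read_id: str
    first_nick: str  # NickA | NickB | unassigned
    signed_length_nt: int


@dataclass(frozen=True)
class SpectrumSummary:
    """Deletion-length spectrum plus junction summary metrics.

    ``spectrum`` maps (first_nick, signed_length_nt) -> frequency under
    ``denominator``.  Summary fields are ``None`` when no edited reads
    exist (an empty experiment has no defined spectrum).  Fractions are
    plain fractions in [0, 1] except ``full_removal_fraction`` and
    ``near_full_removal_fraction`` which are percentages, matching how
    overhang-removal is conventionally reported.
    """

    spectrum: Mapping[tuple[str, int], float]
    denominator: str
    total_reads: int
    edited_reads: int
    deletion_reads: int
    non_deletion_edited_fraction: Optional[float]
    full_removal_fraction: Optional[float]
    near_full_removal_fraction: Optional[float]
    near_full_tolerance_nt: int
    median_deletion_length_nt: Optional[float]
    precise_deletion_fraction: Optional[float]
    nick_a: int = 0
    nick_b: int = 0


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def _boundary_candidates(call: IndelCall, nick_a: int, nick_b: int):
    """(distance, nick_rank, -signed, nick_name, signed) per anchorable boundary."""
    for s, e in call.deletions:
        # anchor at NickA: positive direction is toward NickB (rightward)
        for boundary, other in ((s, e), (e, s)):
            yield (abs(boundary - nick_a), 0, -(other - nick_a),
                   "NickA", other - nick_a)
            yield (abs(boundary - nick_b), 1, -(nick_b - other),
                   "NickB", nick_b - other)


def assign_first_nick(call: IndelCall, nick_a: int, nick_b: int,
                      boundary_tol_nt: int = 1) -> JunctionRecord:
    """Anchor a deletion-bearing read at the nick one of its boundaries hits.

    The boundary nearest a nick junction (within ``boundary_tol_nt``)
    defines the first nick; the deletion's other boundary gives the signed
    length, positive toward the second nick.  Ties (e.g. the exact
    nick-to-nick deletion) resolve to NickA, then to the longer toward
    extent.  Reads with no boundary near either nick are ``unassigned``.
    """
    if nick_a >= nick_b:
        raise InputError("need nick_a < nick_b")
    if not call.deletions:
        raise InputError("assign_first_nick requires a deletion-bearing call")
    best = min(_boundary_candidates(call, nick_a, nick_b))
    dist, _, _, nick_name, signed = best
    if dist > boundary_tol_nt:
        return JunctionRecord(call.read_id, "unassigned", 0)
    return JunctionRecord(call.read_id, nick_name, int(signed))


def deletion_spectrum(records: Sequence[JunctionRecord], stats: EditingStats,
                      denominator: str = "edited_reads",
                      ) -> dict[tuple[str, int], float]:
    """Binned frequency of (first_nick, signed deletion length).

    ``denominator`` selects the normalisation: all sequenced reads or only
    edited reads.
    """
    if denominator == "total_reads":
        denom = stats.total_reads
    elif denominator == "edited_reads":
        denom = stats.edited_reads
    else:
        raise InputError("denominator must be 'total_reads' or 'edited_reads'")
    if denom == 0:
        raise InputError("empty experiment: denominator is zero")
    counts: dict[tuple[str, int], int] = {}
    for rec in records:
        key = (rec.first_nick, rec.signed_length_nt)
        counts[key] = counts.get(key, 0) + 1
    return {k: v / denom for k, v in sorted(counts.items())}


def _covered_within(call: IndelCall, lo: int, hi: int) -> int:
    """nt of [lo, hi) covered by the union of the call's deletions."""
    covered = 0
    for s, e in call.deletions:  # canonical calls are non-overlapping
        covered += max(0, min(e, hi) - max(s, lo))
    return covered


def summarize(calls: Sequence[IndelCall], nick_a: int, nick_b: int,
              near_full_tolerance_nt: int = 3,
              boundary_tol_nt: int = 1,
              denominator: str = "edited_reads",
              median_over: str = "deletion_reads",
              stats: Optional[EditingStats] = None) -> SpectrumSummary:
    """Full junction analysis of a call set against one nick pair.

    ``median_over`` selects whether the median deletion length is taken
    over deletion-bearing reads (default) or over all edited reads
    (insertion-only reads then contribute zero deleted nt).
    """
    if nick_a >= nick_b:
        raise InputError("need nick_a < nick_b")
    if near_full_tolerance_nt < 0 or boundary_tol_nt < 0:
        raise InputError("tolerances must be non-negative")
    if median_over not in ("deletion_reads", "edited_reads"):
        raise InputError("median_over must be 'deletion_reads' or 'edited_reads'")
    total = stats.total_reads if stats is not None else len(calls)
    edited = [c for c in calls if c.edit_class not in _EDITED_EXCLUDED]
    n_edited = len(edited)
    with_del = [c for c in edited if c.deletions]
    span = nick_b - nick_a

    if n_edited == 0:
        return SpectrumSummary({}, denominator, total, 0, 0, None, None,
                               None, near_full_tolerance_nt, None, None,
                               nick_a, nick_b)

    records = [assign_first_nick(c, nick_a, nick_b, boundary_tol_nt)
               for c in with_del]
    est = EditingStats(total, n_edited) if stats is None else stats
    spec = deletion_spectrum(records, est, denominator)

    full = sum(1 for c in with_del if _covered_within(c, nick_a, nick_b) >= span)
    near_full = sum(1 for c in with_del
                    if _covered_within(c, nick_a, nick_b)
                    >= span - near_full_tolerance_nt)
    precise = sum(1 for c in with_del
                  if c.deletions == ((nick_a, nick_b),) and not c.insertion_seq)

    if median_over == "deletion_reads":
        lengths = [c.total_deleted_nt for c in with_del]
    else:
        lengths = [c.total_deleted_nt for c in edited]
    lengths.sort()
    if lengths:
        m = len(lengths)
        median = (lengths[m // 2] if m % 2
                  else (lengths[m // 2 - 1] + lengths[m // 2]) / 2)
    else:
        median = None

    return SpectrumSummary(
        spectrum=spec,
        denominator=denominator,
        total_reads=total,
        edited_reads=n_edited,
        deletion_reads=len(with_del),
        non_deletion_edited_fraction=(n_edited - len(with_del)) / n_edited,
        full_removal_fraction=100.0 * full / n_edited,
        near_full_removal_fraction=100.0 * near_full / n_edited,
        near_full_tolerance_nt=near_full_tolerance_nt,
        median_deletion_length_nt=float(median) if median is not None else None,
        precise_deletion_fraction=precise / n_edited,
        nick_a=nick_a,
        nick_b=nick_b,
    )


def fold_change(freq_condition: float, freq_control: float) -> Optional[float]:
    """Ratio of condition to control indel frequency; no pseudocounts.

    A zero control frequency leaves the fold change undefined (``None``),
    never infinite.
    """
    if freq_condition < 0 or freq_control < 0:
        raise InputError("frequencies must be non-negative")
    if freq_control == 0:
        return None
    return freq_condition / freq_control


def overhang_stimulation_regression(
        table: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of fold stimulation on overhang length (or inter-nick distance).

    Returns slope, intercept, Pearson R, and the exact two-sided p-value
    from the t transform of R with n-2 degrees of freedom.
    """
    if len(table) < 3:
        raise InputError("regression needs at least 3 points")
    x = [float(a) for a, _ in table]
    y = [float(b) for _, b in table]
    if max(x) == min(x):
        raise InputError("regression x values are constant")
    res = _scipy_stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r=float(res.rvalue),
                            p_value=float(res.pvalue),
                            n=len(table))
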