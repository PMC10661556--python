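"""Sequential-nicking viability model for overlapping/adjacent nickase pairs.

Two protospacers whose 23-bp footprints overlap cannot be bound by two
Cas9n-sgRNA complexes at once, so a double-strand break requires
*sequential* nicking: the first complex nicks and dissociates, then the
second must still be able to unwind its target, pair >= 18 nt of
PAM-proximal target strand with its spacer, and nick.  The first nick (and
any 3'-5' exonucleolytic resection of the ssDNA it exposes) can defeat the
second binding event.  This module encodes that rule set:

R1  first nick at or inside the second site's PAM -> the second ternary
    complex is never stabilised;
R2  (D10A pairs) first nick on the second site's *nontarget* strand within
    17 nt of its PAM -> target unwinding terminates prematurely;
R3  (H840A pairs) first nick on the second site's *target* strand within
    17 nt of its PAM -> fewer than 18 nt left to pair with the spacer;
R4  (H840A first nicks, with TREX2) the released PAM-distal 17-nt 3'
    nontarget segment is resected from its 3' end, extending the gap
    toward the second PAM; if the intact PAM-proximal pairing region drops
    below 18 nt the second nick fails.  Free TREX2 removes 5-8 nt
    (worst case 8); a nickase-TREX2 fusion removes at least 9.

All distances are nucleotides along the relevant strand between the first
nick junction and the proximal edge of the second site's PAM, positive on
the spacer (PAM-distal) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .geometry import (
    PAM_LEN,
    SPACER_LEN,
    InputError,
    NickSite,
    PairGeometry,
    ProtospacerSite,
    released_ssdna_length,
)

__all__ = [
    "TREX_MODES",
    "RULES",
    "ViabilityParams",
    "ViabilityVerdict",
    "StimulationCall",
    "nick_to_pam_distance",
    "classify_second_nick",
    "second_nick_viability",
    "pair_viability",
    "stimulation_prediction",
    "min_viable_nick_to_pam_distance",
]

TREX_MODES = ("none", "free", "fused")
RULES = (
    "none",
    "nick_in_or_at_second_pam",
    "d10a_nontarget_nick_proximal",
    "h840a_target_strand_nick_proximal",
    "trex2_gap_extension",
    "same_strand_no_dsb",
)

# Empirical distance windows (bp between paired nicks) in which TREX2
# stimulation of 3'-overhang editing was robust, recorded as annotations.
STIMULATION_WINDOW_DEFAULT = (13, 96)
VARIANT_SUBWINDOWS = {
    "D10A_reporter": (14, 81),
    "H840A_reporter": (29, 86),
    "D10A_AAVS1": (13, 43),
    "H840A_EMX1": (34, 96),
}


@dataclass(frozen=True)
class ViabilityParams:
    """Tunable constants of the sequential-nicking model (all nt).

    min_pairing_nt: PAM-proximal spacer:target-strand pairing needed to
        fully activate the nuclease (18 of the 20 spacer nt).
    released_len_nt: PAM-distal nontarget-strand segment released by an
        H840A nick (17 for a 20-nt spacer).
    free_trex2_min/max_degrade_nt: bounds on how far free TREX2 resects
        that released 3' segment (5 and 8).
    fused_trex2_min_degrade_nt: a nickase-fused TREX2 resects at least 9.
    d10a_block_max_dist_nt: a nick on the second site's nontarget strand
        blocks unwinding out to this distance from the PAM (17).
    use_free_min_as_worst_case: evaluate free-mode viability with the
        minimum (5 nt) instead of the maximum (8 nt) resection depth.
    """

    min_pairing_nt: int = 18
    released_len_nt: int = 17
    free_trex2_min_degrade_nt: int = 5
    free_trex2_max_degrade_nt: int = 8
    fused_trex2_min_degrade_nt: int = 9
    d10a_block_max_dist_nt: int = 17
    use_free_min_as_worst_case: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_pairing_nt <= SPACER_LEN):
            raise InputError("min_pairing_nt must be in (0, 20]")
        if not (0 <= self.free_trex2_min_degrade_nt
                <= self.free_trex2_max_degrade_nt
                < self.fused_trex2_min_degrade_nt):
            raise InputError("need 0 <= free min <= free max < fused min")
        if self.released_len_nt < 0 or self.d10a_block_max_dist_nt < 0:
            raise InputError("lengths must be non-negative")

    def degradation_depth(self, trex_mode: str) -> int:
        """Worst-case resection depth (nt) applied under ``trex_mode``."""
        if trex_mode == "none":
            return 0
        if trex_mode == "free":
            return (self.free_trex2_min_degrade_nt
                    if self.use_free_min_as_worst_case
                    else self.free_trex2_max_degrade_nt)
        if trex_mode == "fused":
            return self.fused_trex2_min_degrade_nt
        raise InputError(f"unknown trex_mode {trex_mode!r}; expected one of {TREX_MODES}")


@dataclass(frozen=True)
class ViabilityVerdict:
    """Outcome of asking whether the second nick can still be induced."""

    viable: bool
    rule_triggered: str
    intact_pairing_nt: int
    first_nicker: str = "a"
    trex_mode: str = "none"

    def __post_init__(self) -> None:
        assert self.viable == (self.rule_triggered == "none")
        assert 0 <= self.intact_pairing_nt <= SPACER_LEN


@dataclass(frozen=True)
class StimulationCall:
    status: str  # stimulable | not_stimulable | no_dsb
    inter_nick_distance: int
    overhang_polarity: str
    window: tuple[int, int]
    annotations: dict = field(default_factory=dict)


def nick_to_pam_distance(nick: NickSite, second_site: ProtospacerSite) -> int:
    """Signed nt from a nick junction to the second PAM's proximal edge.

    Positive values place the nick on the spacer (PAM-distal) side of the
    second PAM, i.e. inside the region the second complex must unwind;
    values in [-3, 0] place it at or inside the 3-bp PAM footprint; values
    below -3 place it beyond the PAM, away from the second protospacer.
    """
    q = second_site.pam_proximal_edge
    if second_site.strand == "+":
        return q - nick.junction  # spacer lies left of the PAM
    return nick.junction - q      # spacer lies right of the PAM


def classify_second_nick(nick_to_pam_nt: int, variant: str, trex_mode: str,
                         params: ViabilityParams = ViabilityParams(),
                         first_nicker: str = "a") -> ViabilityVerdict:
    """Apply rules R1-R4 to a first nick at a signed distance from the
    second PAM (see :func:`nick_to_pam_distance` for the sign convention).
    """
    s = int(nick_to_pam_nt)
    depth = params.degradation_depth(trex_mode)  # validates trex_mode
    degrade = depth if variant == "H840A" else 0  # D10A releases no 3' ssDNA

    if -PAM_LEN <= s <= 0:
        return ViabilityVerdict(False, "nick_in_or_at_second_pam",
                                max(0, min(SPACER_LEN, s)),
                                first_nicker, trex_mode)
    if s < -PAM_LEN:
        # Nick beyond the PAM on its far side: unwinding is unaffected.
        return ViabilityVerdict(True, "none", SPACER_LEN, first_nicker, trex_mode)
    if variant == "D10A" and s <= params.d10a_block_max_dist_nt:
        return ViabilityVerdict(False, "d10a_nontarget_nick_proximal",
                                min(SPACER_LEN, s), first_nicker, trex_mode)
    if variant == "H840A" and s <= params.min_pairing_nt - 1:
        return ViabilityVerdict(False, "h840a_target_strand_nick_proximal",
                                min(SPACER_LEN, s), first_nicker, trex_mode)
    intact = max(0, min(SPACER_LEN, s - degrade))
    if intact < params.min_pairing_nt:
        return ViabilityVerdict(False, "trex2_gap_extension", intact,
                                first_nicker, trex_mode)
    return ViabilityVerdict(True, "none", intact, first_nicker, trex_mode)


def second_nick_viability(pair: PairGeometry, first_nicker: str = "a",
                          trex_mode: str = "none",
                          params: ViabilityParams = ViabilityParams(),
                          ) -> ViabilityVerdict:
    """Can the designated second nick still be induced after the first?

    ``first_nicker`` is ``"a"`` or ``"b"`` and names which of the pair's
    two sites is nicked first.
    """
    if first_nicker not in ("a", "b"):
        raise InputError("first_nicker must be 'a' or 'b'")
    if pair.overhang_polarity == "same_strand":
        return ViabilityVerdict(False, "same_strand_no_dsb", 0,
                                first_nicker, trex_mode)
    first = pair.nick_a if first_nicker == "a" else pair.nick_b
    second_site = pair.site_b if first_nicker == "a" else pair.site_a
    s = nick_to_pam_distance(first, second_site)
    return classify_second_nick(s, pair.variant, trex_mode, params,
                                first_nicker=first_nicker)


def pair_viability(pair: PairGeometry, trex_mode: str = "none",
                   params: ViabilityParams = ViabilityParams(),
                   ) -> tuple[ViabilityVerdict, dict[str, ViabilityVerdict]]:
    """Evaluate both nicking orders; the pair is viable if either order is.

    The sequential model does not fix which sgRNA binds first, so a DSB
    forms whenever at least one ordering completes both nicks.  Returns
    (best verdict, per-ordering verdicts).
    """
    verdicts = {o: second_nick_viability(pair, o, trex_mode, params)
                for o in ("a", "b")}
    best = max(verdicts.values(),
               key=lambda v: (v.viable, v.intact_pairing_nt))
    return best, verdicts


def stimulation_prediction(pair: PairGeometry, verdict: ViabilityVerdict,
                           window: tuple[int, int] = STIMULATION_WINDOW_DEFAULT,
                           ) -> StimulationCall:
    """Is this pair a candidate for TREX2-stimulated 3'-overhang disruption?

    Stimulation requires a formable DSB (viable second nick), protruding 3'
    ends, and an inter-nick distance inside the empirically robust window
    (default 13-96 bp).  Variant-specific sub-windows observed at individual
    loci are attached as annotations, not enforced.
    """
    lo, hi = window
    if lo > hi:
        raise InputError("window lower bound exceeds upper bound")
    annotations = {"variant_subwindows_bp": dict(VARIANT_SUBWINDOWS)}
    if pair.overhang_polarity == "same_strand":
        status = "no_dsb"
    elif (verdict.viable and pair.overhang_polarity == "three_prime"
          and lo <= pair.inter_nick_distance <= hi):
        status = "stimulable"
    else:
        status = "not_stimulable"
    return StimulationCall(status, pair.inter_nick_distance,
                           pair.overhang_polarity, (lo, hi), annotations)


def min_viable_nick_to_pam_distance(variant: str = "H840A",
                                    trex_mode: str = "free",
                                    params: ViabilityParams = ViabilityParams(),
                                    max_search_nt: int = 60) -> Optional[int]:
    """Smallest first-nick-to-second-PAM distance with a viable second nick."""
    for d in range(1, max_search_nt + 1):
        if classify_second_nick(d, variant, trex_mode, params).viable:
            return d
    return None
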