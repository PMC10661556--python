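"""Synthetic amplicon references and edited read sets.

The generator plants two nickase targets with an exactly requested cut
geometry into a random background, then emulates the read-level structure
of deep-sequenced edited amplicons: a per-read editing probability, a
mixture of nick-local small deletions, full inter-nick-span deletions with
optional extra resection, and short insertions, followed by uniform
per-base substitution error.  Presets contrast an empty-vector-like
condition (few edits, nick-local nucleotide loss) with TREX2-like
conditions (more edits, dominated by full or near-full removal of the
inter-nick interval) as seen in junction analyses of 3'-overhang repair.

Every run is a pure function of its seed: one RNG stream, reads drawn in
read-id order, edit decisions before error decisions within each read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import geometry as _geo
from .geometry import (
    GeometryError,
    InputError,
    PairGeometry,
    ProtospacerSite,
    pair_geometry,
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SimulatedRead",
    "make_reference",
    "simulate_reads",
    "preset",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
READ_QUALITY_PHRED = 30
_COMPONENTS = ("nick_local", "full_span", "insertion")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated editing condition.

    component_weights are conditional on a read being edited and must sum
    to 1.  Deletion lengths are geometric: nick_local deletions have mean
    1/nick_local_extension_p, and full-span deletions overshoot each nick
    by Geometric(extra_resection_p) - 1 nt.
    """

    edit_rate: float = 0.3
    component_weights: dict = field(
        default_factory=lambda: {"nick_local": 0.25, "full_span": 0.65,
                                 "insertion": 0.10})
    nick_local_extension_p: float = 0.2
    extra_resection_p: float = 0.5
    insertion_length_max: int = 6
    substitution_error_rate: float = 0.001
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("edit_rate", self.edit_rate),
                          ("substitution_error_rate", self.substitution_error_rate)):
            if not (0.0 <= val <= 1.0):
                raise InputError(f"{name} must be in [0, 1]")
        for p in (self.nick_local_extension_p, self.extra_resection_p):
            if not (0.0 < p <= 1.0):
                raise InputError("geometric parameters must be in (0, 1]")
        if set(self.component_weights) != set(_COMPONENTS):
            raise InputError(f"component_weights must have keys {_COMPONENTS}")
        total = sum(self.component_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"component weights sum to {total}, not 1")
        if any(w < 0 for w in self.component_weights.values()):
            raise InputError("component weights must be non-negative")
        if self.insertion_length_max < 1 or self.n_reads < 0:
            raise InputError("insertion_length_max >= 1 and n_reads >= 0 required")

    def weights_vector(self) -> np.ndarray:
        return np.array([self.component_weights[c] for c in _COMPONENTS])


@dataclass(frozen=True)
class GroundTruth:
    """The planted edit of one simulated read (before sequencing error)."""

    read_id: str
    true_class: str  # unedited | deletion | insertion
    del_start: Optional[int] = None
    del_end: Optional[int] = None
    ins_point: Optional[int] = None
    ins_seq: str = ""


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]


PRESETS = {
    # Empty-vector control: editing by 3'-overhang pairs is rare and what
    # indels exist are mostly small losses around a single nick.
    "EV_like": ScenarioConfig(
        edit_rate=0.03,
        component_weights={"nick_local": 0.75, "full_span": 0.10,
                           "insertion": 0.15}),
    # Free-TREX2 co-expression: editing strongly stimulated, spectrum
    # dominated by full/near-full removal of the inter-nick interval.
    "TREX2_like": ScenarioConfig(
        edit_rate=0.30,
        component_weights={"nick_local": 0.25, "full_span": 0.65,
                           "insertion": 0.10}),
    # Nickase-TREX2 fusion: like free TREX2 with slightly deeper resection
    # pressure; modelled as a higher full-span share.
    "fused_like": ScenarioConfig(
        edit_rate=0.35,
        component_weights={"nick_local": 0.15, "full_span": 0.75,
                           "insertion": 0.10}),
}


def preset(name: str) -> ScenarioConfig:
    """A named scenario; see PRESETS for the conditions each emulates."""
    try:
        return PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)].copy()


def _plant_site(seq: np.ndarray, start: int, strand: str) -> None:
    """Write the PAM bases of one site; the spacer keeps the background."""
    if strand == "+":
        g1, g2 = start + _geo.SPACER_LEN + 1, start + _geo.SPACER_LEN + 2
        for pos, want in ((g1, b"G"), (g2, b"G")):
            seq[pos] = want
    else:
        for pos, want in ((start, b"C"), (start + 1, b"C")):
            seq[pos] = want


def _pam_conflicts(plus_start: int, minus_start: int) -> bool:
    """Do the two planted PAMs demand different bases at one position?"""
    plus_gg = {plus_start + _geo.SPACER_LEN + 1, plus_start + _geo.SPACER_LEN + 2}
    minus_cc = {minus_start, minus_start + 1}
    return bool(plus_gg & minus_cc)


def _scrub_extra_cc_gg(seq: np.ndarray, protected: set[int],
                       rng: np.random.Generator) -> None:
    """Break incidental GG/CC dinucleotides so only the planted PAMs scan.

    Keeps planted-site verification independent of background luck; the
    positions written for the two requested targets are left untouched.
    """
    n = len(seq)
    for i in range(n - 1):
        if i in protected or (i + 1) in protected:
            continue
        pair = seq[i] + seq[i + 1]
        if pair in (b"GG", b"CC"):
            repl = b"A" if seq[i + 1] in (b"G", b"C") else b"T"
            seq[i + 1] = repl


def make_reference(length: int = 200, site_layout: str = "pam_out",
                   *, inter_nick_distance: Optional[int] = None,
                   overlap_length: Optional[int] = None,
                   overhang_length: Optional[int] = None,
                   variant: str = "D10A",
                   pam_out_branch: str = "far",
                   seed: int = 0,
                   reference_id: str = "amplicon",
                   clean_background: bool = True,
                   ) -> tuple[str, ProtospacerSite, ProtospacerSite, PairGeometry]:
    """Random amplicon with two planted targets realising a requested geometry.

    site_layout:
        ``pam_in``   non-overlapping, PAMs facing each other (3' overhangs
                     with D10A); give ``inter_nick_distance`` >= 12.
        ``pam_out``  non-overlapping, PAMs facing away (3' overhangs with
                     H840A); give ``inter_nick_distance`` >= 34.
        ``overlapping``  intersecting 23-bp footprints; give
                     ``overlap_length`` (or ``overhang_length``).  D10A
                     uses the PAM-facing arrangement (overhangs 0-11 nt);
                     H840A the PAM-averted one (0-33 nt; ``pam_out_branch``
                     picks the near (overlap 12-23) or far (1-23) branch).

    Raises GeometryError for infeasible requests, including overlaps whose
    two PAMs would require contradictory bases at a shared position.
    Returns (reference, site1, site2, verified PairGeometry).
    """
    _geo._check_variant(variant)
    rng = np.random.default_rng(seed)
    T = _geo.TARGET_LEN

    if site_layout == "overlapping":
        if overlap_length is None:
            if overhang_length is None:
                raise InputError("give overlap_length or overhang_length")
            if variant == "D10A":
                if not (0 <= overhang_length <= 11):
                    raise GeometryError(
                        f"paired D10A on overlapping targets can only make "
                        f"0-11 nt 3' overhangs, not {overhang_length}")
                overlap_length = 12 - overhang_length
            else:
                if not (0 <= overhang_length <= 33):
                    raise GeometryError(
                        f"paired H840A on overlapping targets can only make "
                        f"0-33 nt 3' overhangs, not {overhang_length}")
                if overhang_length <= 11:
                    overlap_length, pam_out_branch = 12 + overhang_length, "near"
                else:
                    overlap_length, pam_out_branch = 34 - overhang_length, "far"
        if not (1 <= overlap_length <= T):
            raise GeometryError(f"overlap must be 1-{T} bp, got {overlap_length}")
        if variant == "D10A":
            delta = T - overlap_length  # minus site right of plus site
            if delta < 11:
                raise GeometryError(
                    "overlaps above 12 bp put both D10A nicks on configurations "
                    "with 5' overhangs; request overlap 1-12")
        else:
            if pam_out_branch == "near":
                if overlap_length < 12:
                    raise GeometryError("near branch needs overlap 12-23 bp")
                delta = T - overlap_length  # 0..11, minus right of plus
            elif pam_out_branch == "far":
                delta = -(T - overlap_length)  # minus left of plus
            else:
                raise InputError("pam_out_branch must be 'near' or 'far'")
        margin = 40
        if delta >= 0:
            plus_start = margin
            minus_start = plus_start + delta
        else:
            minus_start = margin
            plus_start = minus_start - delta
        if _pam_conflicts(plus_start, minus_start):
            raise GeometryError(
                f"overlap {overlap_length} bp in this arrangement places one "
                f"PAM's GG on the other PAM's CC: no real sequence satisfies "
                f"both NGG motifs")
    elif site_layout in ("pam_in", "pam_out"):
        if inter_nick_distance is None:
            raise InputError(f"{site_layout} layout needs inter_nick_distance")
        d = int(inter_nick_distance)
        margin = 40
        if site_layout == "pam_in":
            # plus site left, minus site right: junctions at p+17 and m+6
            delta = d + 11
            if delta < T:
                raise GeometryError(
                    f"pam_in non-overlapping needs inter-nick distance >= "
                    f"{T - 11} bp, got {d}")
            plus_start = margin
            minus_start = plus_start + delta
        else:
            # minus site left, plus site right: junctions at m+6 and p+17
            delta = d - 11
            if delta < T:
                raise GeometryError(
                    f"pam_out non-overlapping needs inter-nick distance >= "
                    f"{T + 11} bp, got {d}")
            minus_start = margin
            plus_start = minus_start + delta
    else:
        raise InputError("site_layout must be pam_in, pam_out, or overlapping")

    needed = max(plus_start + T, minus_start + T) + margin
    if length < needed:
        length = needed
    seq = _random_background(rng, length)
    _plant_site(seq, plus_start, "+")
    _plant_site(seq, minus_start, "-")
    if clean_background:
        protected = {plus_start + _geo.SPACER_LEN + 1,
                     plus_start + _geo.SPACER_LEN + 2,
                     minus_start, minus_start + 1}
        _scrub_extra_cc_gg(seq, protected, rng)
        _plant_site(seq, plus_start, "+")
        _plant_site(seq, minus_start, "-")
    reference = seq.tobytes().decode()

    site_plus = ProtospacerSite(
        reference_id, plus_start, "+",
        reference[plus_start:plus_start + _geo.SPACER_LEN],
        reference[plus_start + _geo.SPACER_LEN:plus_start + T])
    site_minus = ProtospacerSite(
        reference_id, minus_start, "-",
        _geo.reverse_complement(
            reference[minus_start + _geo.PAM_LEN:minus_start + T]),
        _geo.reverse_complement(reference[minus_start:minus_start + _geo.PAM_LEN]))
    for site in (site_plus, site_minus):
        site.validate_against(reference)

    geom = pair_geometry(site_plus, site_minus, variant)
    if site_layout == "overlapping" and geom.overlap_length != overlap_length:
        raise GeometryError("planted overlap does not verify")  # pragma: no cover
    if inter_nick_distance is not None \
            and geom.inter_nick_distance != inter_nick_distance:
        raise GeometryError("planted distance does not verify")  # pragma: no cover
    return reference, site_plus, site_minus, geom


def _geometric(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def _draw_edit(rng: np.random.Generator, reference: str, nicks: tuple[int, int],
               cfg: ScenarioConfig, read_id: str) -> GroundTruth:
    na, nb = nicks
    L = len(reference)
    component = _COMPONENTS[rng.choice(len(_COMPONENTS), p=cfg.weights_vector())]
    if component == "nick_local":
        nick = na if rng.random() < 0.5 else nb
        toward = rng.random() < 0.5
        ext = _geometric(rng, cfg.nick_local_extension_p)
        if nick == na:
            s, e = (nick, nick + ext) if toward else (nick - ext, nick)
        else:
            s, e = (nick - ext, nick) if toward else (nick, nick + ext)
        s, e = max(1, s), min(L - 1, e)
        if e <= s:  # clamped away; keep a 1-nt loss at the nick
            s, e = nick - 1, nick
        return GroundTruth(read_id, "deletion", s, e)
    if component == "full_span":
        extra_l = _geometric(rng, cfg.extra_resection_p) - 1
        extra_r = _geometric(rng, cfg.extra_resection_p) - 1
        s = max(1, na - extra_l)
        e = min(L - 1, nb + extra_r)
        return GroundTruth(read_id, "deletion", s, e)
    ins_len = int(rng.integers(1, cfg.insertion_length_max + 1))
    ins_seq = _BASES[rng.integers(0, 4, size=ins_len)].tobytes().decode()
    point = na if rng.random() < 0.5 else nb
    return GroundTruth(read_id, "insertion", ins_point=point, ins_seq=ins_seq)


def _apply_edit(reference: str, truth: GroundTruth) -> str:
    if truth.true_class == "deletion":
        return reference[:truth.del_start] + reference[truth.del_end:]
    if truth.true_class == "insertion":
        return (reference[:truth.ins_point] + truth.ins_seq
                + reference[truth.ins_point:])
    return reference


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_reads(reference: str, nicks: tuple[int, int],
                   scenario: ScenarioConfig,
                   ) -> tuple[list[SimulatedRead], list[GroundTruth]]:
    """Draw a read set over ``reference`` with nick junctions ``(na, nb)``.

    Each read is the full edited amplicon with constant Q30 qualities.
    Same scenario (including seed) => byte-identical output.
    """
    na, nb = nicks
    if not (0 < na < nb < len(reference)):
        raise InputError("nick junctions must satisfy 0 < nick_a < nick_b < len")
    rng = np.random.default_rng(scenario.seed)
    reads: list[SimulatedRead] = []
    truths: list[GroundTruth] = []
    for i in range(scenario.n_reads):
        read_id = f"read{i:06d}"
        if rng.random() < scenario.edit_rate:
            truth = _draw_edit(rng, reference, (na, nb), scenario, read_id)
        else:
            truth = GroundTruth(read_id, "unedited")
        seq = _apply_edit(reference, truth)
        seq = _substitute(rng, seq, scenario.substitution_error_rate)
        reads.append(SimulatedRead(read_id, seq,
                                   (READ_QUALITY_PHRED,) * len(seq)))
        truths.append(truth)
    return reads, truths
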