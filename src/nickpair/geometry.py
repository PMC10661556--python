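"""Protospacer discovery and paired-nick cut-site geometry for SpCas9 nickases.

SpCas9 recognises a 20-nt protospacer followed by an NGG PAM and cleaves
blunt 3 bp 5' of the PAM (between spacer positions 17 and 18).  The two
nickase mutants each cut only one strand at that same junction:

* D10A (RuvC inactive) nicks the *target* strand -- the strand base-paired
  with the sgRNA spacer, i.e. the strand opposite the protospacer.
* H840A (HNH inactive) nicks the *nontarget* strand -- the PAM-bearing,
  protospacer strand.

Two nicks on opposite strands define a staggered double-strand break whose
overhang polarity follows from the relative order of the two junctions on
the plus strand, and whose overhang length equals the inter-nick distance.
All coordinates are 0-based half-open on the plus strand of the reference;
a nick junction ``j`` lies between reference indices ``j - 1`` and ``j``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SPACER_LEN",
    "PAM_LEN",
    "TARGET_LEN",
    "CUT_OFFSET",
    "VARIANTS",
    "GeometryError",
    "InputError",
    "ProtospacerSite",
    "NickSite",
    "PairGeometry",
    "find_protospacers",
    "nick_position",
    "released_ssdna_length",
    "pair_geometry",
    "enumerate_pairs",
    "overlap_series",
    "reverse_complement",
]

SPACER_LEN = 20
PAM_LEN = 3
TARGET_LEN = SPACER_LEN + PAM_LEN  # 23-bp footprint, spacer + PAM
CUT_OFFSET = 3  # blunt cut 3 bp 5' of the PAM
VARIANTS = ("D10A", "H840A")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

# IUPAC nucleotide codes -> set of concrete bases they match.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class InputError(ValueError):
    """Malformed user input (sequence, coordinates, configuration)."""


class GeometryError(ValueError):
    """A requested cut-site geometry is impossible for 23-bp targets."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_variant(variant: str) -> str:
    if variant not in VARIANTS:
        raise InputError(f"unknown nickase variant {variant!r}; expected one of {VARIANTS}")
    return variant


def _matches(pattern: str, seq: str) -> bool:
    if len(pattern) != len(seq):
        return False
    for p, b in zip(pattern.upper(), seq.upper()):
        allowed = _IUPAC.get(p)
        if allowed is None:
            raise InputError(f"invalid IUPAC code {p!r} in PAM pattern")
        if b not in allowed:  # ambiguous reference bases never match
            return False
    return True


@dataclass(frozen=True)
class ProtospacerSite:
    """A 20-nt spacer match plus its 3-nt PAM on one strand of a reference.

    ``start`` is the 0-based plus-strand coordinate of the leftmost base of
    the full 23-bp footprint.  On the plus strand the layout is
    ``[spacer 20][PAM 3]``; on the minus strand the PAM occupies the first
    three plus-strand bases of the footprint (the reverse complement of an
    NGG reads CCN on the plus strand).
    """

    reference_id: str
    start: int
    strand: str
    spacer_seq: str
    pam_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise InputError("site start must be non-negative")
        if len(self.spacer_seq) != SPACER_LEN:
            raise InputError(f"spacer must be {SPACER_LEN} nt")
        if len(self.pam_seq) != PAM_LEN:
            raise InputError(f"PAM must be {PAM_LEN} nt")

    @property
    def end(self) -> int:
        """Exclusive plus-strand end of the 23-bp footprint."""
        return self.start + TARGET_LEN

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def pam_interval(self) -> tuple[int, int]:
        """Plus-strand interval occupied by the PAM."""
        if self.strand == "+":
            return (self.start + SPACER_LEN, self.end)
        return (self.start, self.start + PAM_LEN)

    @property
    def pam_proximal_edge(self) -> int:
        """Junction between spacer position 20 and the first PAM base."""
        if self.strand == "+":
            return self.start + SPACER_LEN
        return self.start + PAM_LEN

    @classmethod
    def abstract(cls, reference_id: str, start: int, strand: str) -> "ProtospacerSite":
        """A coordinate-only site (placeholder sequence) for geometry sweeps."""
        return cls(reference_id, start, strand, "N" * SPACER_LEN, "NGG")

    def validate_against(self, reference: str) -> None:
        """Check the site's sequence fields against the reference it names."""
        if self.end > len(reference):
            raise InputError("target footprint extends past the reference end")
        window = reference[self.start:self.end].upper()
        if self.strand == "-":
            window = reverse_complement(window)
        if window[:SPACER_LEN] != self.spacer_seq.upper():
            raise InputError("spacer_seq does not match the reference")
        if window[SPACER_LEN:] != self.pam_seq.upper():
            raise InputError("pam_seq does not match the reference")
        if not _matches("NGG", self.pam_seq):
            raise InputError(f"PAM {self.pam_seq!r} does not match NGG")


@dataclass(frozen=True)
class NickSite:
    """A single-strand cut produced by one nickase at one protospacer."""

    strand_nicked: str
    junction: int
    source_site: ProtospacerSite
    variant: str

    def __post_init__(self) -> None:
        _check_variant(self.variant)
        if self.strand_nicked not in "+-":
            raise InputError("strand_nicked must be '+' or '-'")


@dataclass(frozen=True)
class PairGeometry:
    """Joint cut geometry of an ordered pair of nickase sites.

    ``overhang_polarity`` is ``five_prime``/``three_prime`` for staggered
    breaks, ``blunt`` for coincident junctions, and ``same_strand`` when both
    nicks fall on one strand (two nicks, no double-strand break).
    """

    nick_a: NickSite
    nick_b: NickSite
    inter_nick_distance: int
    overlap_length: int
    overhang_polarity: str
    overhang_length: int
    released_ssdna_lengths: tuple[int, int]

    @property
    def variant(self) -> str:
        return self.nick_a.variant

    @property
    def site_a(self) -> ProtospacerSite:
        return self.nick_a.source_site

    @property
    def site_b(self) -> ProtospacerSite:
        return self.nick_b.source_site

    @property
    def nick_junctions(self) -> tuple[int, int]:
        """Both junctions in ascending plus-strand order."""
        return tuple(sorted((self.nick_a.junction, self.nick_b.junction)))


def find_protospacers(reference: str, pam_pattern: str = "NGG",
                      reference_id: str = "ref") -> list[ProtospacerSite]:
    """Scan both strands of ``reference`` for spacer+PAM targets.

    Returns sites sorted by footprint start, plus strand before minus at
    ties.  Ambiguous bases in the reference (e.g. N) never match the PAM
    pattern, so runs of N are silently skipped.
    """
    if not reference:
        raise InputError("empty reference sequence")
    seq = str(reference).upper()
    if any(b not in "ACGTN" for b in seq):
        bad = sorted({b for b in seq if b not in "ACGTN"})
        raise InputError(f"non-nucleotide characters in reference: {bad}")
    if len(seq) < TARGET_LEN:
        return []
    rc_pattern = reverse_complement(pam_pattern)
    sites: list[ProtospacerSite] = []
    for s in range(len(seq) - TARGET_LEN + 1):
        # plus strand: spacer [s, s+20), PAM [s+20, s+23)
        pam = seq[s + SPACER_LEN:s + TARGET_LEN]
        if _matches(pam_pattern, pam):
            sites.append(ProtospacerSite(reference_id, s, "+",
                                         seq[s:s + SPACER_LEN], pam))
        # minus strand: plus-strand CCN at [s, s+3), spacer [s+3, s+23)
        pam_rc = seq[s:s + PAM_LEN]
        if _matches(rc_pattern, pam_rc):
            sites.append(ProtospacerSite(
                reference_id, s, "-",
                reverse_complement(seq[s + PAM_LEN:s + TARGET_LEN]),
                reverse_complement(pam_rc)))
    sites.sort(key=lambda t: (t.start, 0 if t.strand == "+" else 1))
    return sites


def nick_position(site: ProtospacerSite, variant: str) -> NickSite:
    """Nick junction and nicked strand for one nickase at one site.

    Both variants cut at the canonical blunt junction 3 bp 5' of the PAM;
    they differ only in which strand carries the nick.
    """
    _check_variant(variant)
    if site.strand == "+":
        junction = site.start + SPACER_LEN - CUT_OFFSET
    else:
        junction = site.start + PAM_LEN + CUT_OFFSET
    # D10A cuts the target strand (opposite the protospacer strand);
    # H840A cuts the nontarget, protospacer-bearing strand.
    protospacer_strand = site.strand
    other = "-" if protospacer_strand == "+" else "+"
    strand_nicked = other if variant == "D10A" else protospacer_strand
    return NickSite(strand_nicked, junction, site, variant)


def released_ssdna_length(site: ProtospacerSite, variant: str) -> int:
    """nt of PAM-distal nontarget strand freed 3' of the nick on nicking.

    H840A cuts the nontarget strand 17 nt from the PAM-distal end of a
    20-nt protospacer, and SpCas9 locally releases that PAM-distal segment;
    a D10A nick leaves the nontarget strand intact, so nothing is released.
    """
    _check_variant(variant)
    return SPACER_LEN - CUT_OFFSET if variant == "H840A" else 0


def pair_geometry(site1: ProtospacerSite, site2: ProtospacerSite,
                  variant: str) -> PairGeometry:
    """Resolve the double-strand-break geometry of two nicks from one variant.

    Polarity comes from the order of the plus- and minus-strand junctions:
    a plus-strand junction left of the minus-strand junction leaves
    recessed 3' ends (5' overhangs); right of it leaves protruding 3' ends.
    """
    _check_variant(variant)
    if site1.reference_id != site2.reference_id:
        raise InputError("paired sites must lie on the same reference")
    n1 = nick_position(site1, variant)
    n2 = nick_position(site2, variant)
    overlap = max(0, min(site1.end, site2.end) - max(site1.start, site2.start))
    released = (released_ssdna_length(site1, variant),
                released_ssdna_length(site2, variant))
    if n1.strand_nicked == n2.strand_nicked:
        return PairGeometry(n1, n2, abs(n1.junction - n2.junction), overlap,
                            "same_strand", 0, released)
    plus_j = n1.junction if n1.strand_nicked == "+" else n2.junction
    minus_j = n2.junction if n1.strand_nicked == "+" else n1.junction
    dist = abs(plus_j - minus_j)
    if plus_j < minus_j:
        polarity = "five_prime"
    elif plus_j > minus_j:
        polarity = "three_prime"
    else:
        polarity = "blunt"
    return PairGeometry(n1, n2, dist, overlap, polarity,
                        dist if polarity != "blunt" else 0, released)


def enumerate_pairs(sites: Sequence[ProtospacerSite], variant: str,
                    max_distance: int = 200) -> list[PairGeometry]:
    """All opposite-strand site pairs within ``max_distance`` bp of each other.

    Pairs are normalised so ``nick_a`` is the leftmost junction, and sorted
    by (leftmost junction, inter-nick distance).  Same-strand pairs cannot
    form a double-strand break and are excluded.
    """
    _check_variant(variant)
    pairs: list[PairGeometry] = []
    for s1, s2 in itertools.combinations(sites, 2):
        geom = pair_geometry(s1, s2, variant)
        if geom.overhang_polarity == "same_strand":
            continue
        if geom.inter_nick_distance > max_distance:
            continue
        if geom.nick_b.junction < geom.nick_a.junction:
            geom = replace(geom, nick_a=geom.nick_b, nick_b=geom.nick_a,
                           released_ssdna_lengths=geom.released_ssdna_lengths[::-1])
        pairs.append(geom)
    pairs.sort(key=lambda g: (min(g.nick_a.junction, g.nick_b.junction),
                              g.inter_nick_distance))
    return pairs


def overlap_series(variant: str, arrangement: str,
                   reference_id: str = "abstract") -> list[PairGeometry]:
    """Slide two 23-bp targets on opposite strands through every overlap.

    ``arrangement`` is ``pam_in`` (minus-strand target to the right of the
    plus-strand target, the two PAMs facing each other in the middle) or
    ``pam_out`` (minus-strand target to the left, PAMs facing outward).
    Returns one PairGeometry per 1-bp offset with footprint overlap >= 1,
    in increasing offset order.  Purely coordinate arithmetic: the sites are
    abstract, so sequence-level PAM compatibility is not checked here.
    """
    _check_variant(variant)
    if arrangement not in ("pam_in", "pam_out"):
        raise InputError("arrangement must be 'pam_in' or 'pam_out'")
    base = TARGET_LEN  # keep all coordinates non-negative
    plus = ProtospacerSite.abstract(reference_id, base, "+")
    out: list[PairGeometry] = []
    offsets = range(1, TARGET_LEN) if arrangement == "pam_in" \
        else range(-(TARGET_LEN - 1), 1)
    for delta in offsets:
        minus = ProtospacerSite.abstract(reference_id, base + delta, "-")
        out.append(pair_geometry(plus, minus, variant))
    return out
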