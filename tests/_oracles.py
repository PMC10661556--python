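"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a deliberately different route from
the implementation it checks: exhaustive scans, per-base enumeration, a
full Gotoh dynamic programme with traceback, and closed-form statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_force_protospacers(seq: str, pam: str = "NGG"):
    """Exhaustive regex-style scan of both strands for spacer+PAM matches.

    Returns (start, strand, spacer, pam) tuples in (start, +<-) order.
    """
    seq = seq.upper()
    hits = []
    n = len(seq)
    for start in range(n):
        if start + 23 > n:
            break
        plus_pam = seq[start + 20:start + 23]
        if all(b in IUPAC[p] for p, b in zip(pam, plus_pam)):
            hits.append((start, "+", seq[start:start + 20], plus_pam))
        window_rc = revcomp(seq[start:start + 23])
        minus_pam = window_rc[20:23]
        if all(b in IUPAC[p] for p, b in zip(pam, minus_pam)):
            hits.append((start, "-", window_rc[:20], minus_pam))
    hits.sort(key=lambda h: (h[0], 0 if h[1] == "+" else 1))
    return hits


def enumerate_nick(start: int, strand: str, variant: str):
    """Per-base enumeration of the nick junction and nicked strand.

    Walks the 23 footprint positions explicitly, finds the PAM-proximal
    spacer edge, and counts three spacer bases back from it along the
    protospacer strand's 5'->3' direction.
    """
    positions = list(range(start, start + 23))
    if strand == "+":
        spacer = positions[:20]       # 5'->3' left to right
        junction = spacer[17]         # between spacer pos 17 and 18
    else:
        spacer = positions[3:][::-1]  # 5'->3' right to left on minus strand
        junction = spacer[17] + 1     # plus-strand junction right of that base
    protospacer_strand = strand
    target_strand = "-" if strand == "+" else "+"
    nicked = target_strand if variant == "D10A" else protospacer_strand
    return nicked, junction


def strand_separation_polarity(plus_cut: int, minus_cut: int, length: int):
    """Cut both strands of an abstract duplex and inspect the break ends.

    Models the plus strand as coordinates 0..length-1 read 5'->3'
    left-to-right and the minus strand the same coordinates read 5'->3'
    right-to-left, severs each at its junction, and asks which strand of
    the left-hand fragment protrudes and which terminus (5' or 3') sits at
    the protruding tip.
    """
    top_left = set(range(0, plus_cut))
    bottom_left = set(range(0, minus_cut))
    protruding = top_left ^ bottom_left
    if not protruding:
        return "blunt", 0
    if protruding <= top_left:
        # plus-strand tip at max coordinate; plus runs 5'->3' rightward,
        # so the tip is a 3' terminus
        return "three_prime", len(protruding)
    return "five_prime", len(protruding)


NEG = -10 ** 9


def gotoh_align(read: str, ref: str, match=2, mismatch=-3, open_=-6, ext=-1):
    """Full affine-gap global DP with traceback.

    Gap of length L costs open_ + (L-1)*ext, end gaps included.  Returns
    (score, deletions, insertions) where deletions are half-open reference
    intervals and insertions are (reference junction, inserted read seq).
    """
    n, m = len(read), len(ref)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in read (deletion)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in ref (insertion)
    M[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        F[i, 0] = open_ + ext * (i - 1)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    ks = np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        sub = np.where(ref_arr == read[i - 1].encode(), match, mismatch)
        M[i, 1:] = prev_best[:-1] + sub
        F[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], E[i - 1, 1:]) + open_,
                              F[i - 1, 1:] + ext)
        mf = np.maximum(M[i], F[i])
        # E[i, j] = ext*j + max_{k<j}(mf[k] + open_ - ext*(k+1))
        anchor = mf[:-1] + open_ - ext * (ks + 1)
        E[i, 1:] = ext * (ks + 1) + np.maximum.accumulate(anchor)
    score = int(max(M[n, m], E[n, m], F[n, m]))

    # traceback, preferring aligned columns, then deletion, then insertion
    dels: list[int] = []
    inss: list[tuple[int, str]] = []
    i, j = n, m
    state = max((M[n, m], 0), (E[n, m], -1), (F[n, m], -2))[1]
    state = {0: "M", -1: "E", -2: "F"}[state]
    ins_run: list[tuple[int, str]] = []
    while i > 0 or j > 0:
        if state == "M":
            i, j = i - 1, j - 1
            cands = [(M[i, j], "M"), (E[i, j], "E"), (F[i, j], "F")]
            state = max(cands, key=lambda c: (c[0], c[1] == "M", c[1] == "E"))[1]
        elif state == "E":
            dels.append(j - 1)
            if j >= 2 and E[i, j] == E[i, j - 1] + ext:
                j -= 1
            else:
                j -= 1
                cands = [(M[i, j], "M"), (F[i, j], "F")]
                state = max(cands, key=lambda c: (c[0], c[1] == "M"))[1]
        else:  # F: insertion consuming read base i-1 at ref junction j
            ins_run.append((j, read[i - 1]))
            if i >= 2 and F[i, j] == F[i - 1, j] + ext:
                i -= 1
            else:
                i -= 1
                cands = [(M[i, j], "M"), (E[i, j], "E")]
                state = max(cands, key=lambda c: (c[0], c[1] == "M"))[1]
        if state != "F" and ins_run:
            point = ins_run[-1][0]
            seq = "".join(b for _, b in reversed(ins_run))
            inss.append((point, seq))
            ins_run = []
    if ins_run:
        point = ins_run[-1][0]
        inss.append((point, "".join(b for _, b in reversed(ins_run))))

    deletions = []
    for pos in sorted(dels):
        if deletions and deletions[-1][1] == pos:
            deletions[-1] = (deletions[-1][0], pos + 1)
        else:
            deletions.append((pos, pos + 1))
    inss.reverse()
    return score, [tuple(d) for d in deletions], inss


def pearson_closed_form(x, y):
    """Pearson R from raw sums, and its two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    r_clip = max(-1.0, min(1.0, r))
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt((n - 2) / (1 - r_clip ** 2))
        p = 2 * sps.t.sf(abs(t), n - 2)
    return float(r), float(p)


def binomial_ci_contains(count: int, n: int, p: float, alpha=0.05) -> bool:
    """Is ``count`` inside the central (1-alpha) band of Binomial(n, p)?"""
    lo = sps.binom.ppf(alpha / 2, n, p)
    hi = sps.binom.ppf(1 - alpha / 2, n, p)
    return lo <= count <= hi


def median_ci_from_pmf(pmf: dict[int, float], n: int, alpha=0.05):
    """Distribution-free CI for the sample median of n draws from ``pmf``.

    Maps the binomial order-statistic band at probability 1/2 through the
    pmf's quantile function.
    """
    ks = sorted(pmf)
    probs = np.array([pmf[k] for k in ks])
    cdf = np.cumsum(probs) / probs.sum()

    def quantile(q):
        idx = int(np.searchsorted(cdf, q))
        return ks[min(idx, len(ks) - 1)]

    k_lo = sps.binom.ppf(alpha / 2, n, 0.5) / n
    k_hi = sps.binom.ppf(1 - alpha / 2, n, 0.5) / n
    return quantile(k_lo), quantile(k_hi)


def geometric_pmf(p: float, kmax: int) -> dict[int, float]:
    return {k: (1 - p) ** (k - 1) * p for k in range(1, kmax + 1)}


def deletion_length_pmf(span: int, w_local: float, w_full: float,
                        p_local: float, p_extra: float,
                        kmax: int = 400) -> dict[int, float]:
    """Theoretical pmf of total deleted nt among deletion-bearing reads."""
    wl = w_local / (w_local + w_full)
    wf = w_full / (w_local + w_full)
    pmf: dict[int, float] = {}
    for k, pr in geometric_pmf(p_local, kmax).items():
        pmf[k] = pmf.get(k, 0.0) + wl * pr
    g = geometric_pmf(p_extra, kmax)
    for k1, p1 in g.items():
        for k2, p2 in g.items():
            if p1 * p2 < 1e-12:
                continue
            tot = span + (k1 - 1) + (k2 - 1)
            pmf[tot] = pmf.get(tot, 0.0) + wf * p1 * p2
    return pmf
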