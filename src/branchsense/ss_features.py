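"""Sequence features of intron 3' ends.

Everything that distinguishes drug-sensitive from drug-resistant 3'
splice sites at the sequence level is computed here: branch-point (BP)
candidates and their base-pairing potential with U2 snRNA, an SF1-style
PWM binding score, polypyrimidine-tract (Py-tract) strength, GC content,
lengths, and the number of BP-consensus matches near the 3'ss.

Conventions
-----------
* Offsets inside an intron are negative, with -1 the last intron
  nucleotide (the G of the terminal AG).
* A BP heptamer occupies offsets ``o .. o+6``; the branch nucleotide is
  heptamer position 6 (offset ``o+5``), bulged out of the U2 helix.
* Candidates lacking an adenosine at the branch position can pair with
  U2 snRNA but cannot form the lariat bond; they are kept as "decoys"
  for reporting and are never chosen as the best functional BP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np

from .io_formats import BASES, IUPAC, IntronRecord, PwmMatrix, sf1_pwm, three_prime_region

__all__ = [
    "BPCandidate",
    "FeatureVector",
    "match_degenerate",
    "u2_pairing_score",
    "pwm_max_score",
    "pwm_score_at",
    "ppt_score",
    "gc_content",
    "count_bp_matches",
    "bp_candidates",
    "score_intron",
    "flanking_diff",
    "BP_CONSENSUS",
    "PPT_WEIGHTS",
]

#: degenerate BP consensus used for multi-BP counting (paper-style YNYYRAY)
BP_CONSENSUS = "YNYYRAY"

#: short BP consensus of the YUNAY family (scanning only)
BP_CONSENSUS_SHORT = "YUNAY"

# U2 snRNA presents GUAGUA to the BP region; the branch A (heptamer
# position 6, index 5) bulges out and is not scored.  Watson-Crick
# partners required at heptamer indices 0..6 (index 5 skipped):
_WC_PARTNER = {0: "T", 1: "A", 2: "C", 3: "T", 4: "A", 6: "C"}
# G:U wobbles: pre-mRNA G opposite a U of U2 (where WC would be A),
# pre-mRNA T opposite a G of U2 (where WC would be C).
_WOBBLE_PARTNER = {1: "G", 4: "G", 2: "T", 6: "T"}

#: per-base weights of the Py-tract scorer; T-rich tracts outscore C-rich
#: ones, purines are penalized (G slightly more, as the worst U2AF65 context)
PPT_WEIGHTS = {"T": 1.0, "C": 0.5, "A": -1.5, "G": -2.0, "N": -2.0}


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def match_degenerate(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) 0-based offsets where ``pattern`` matches.

    ``pattern`` is an IUPAC degenerate string (U is equivalent to T).  An
    ``N`` in the scanned sequence never matches any pattern symbol.
    """
    seq = seq.upper().replace("U", "T")
    pattern = pattern.upper()
    try:
        classes = [IUPAC[c] for c in pattern]
    except KeyError as exc:
        raise ValueError(f"unknown IUPAC code {exc.args[0]!r} in pattern") from None
    m = len(classes)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(base in cls for base, cls in zip(window, classes)):
            hits.append(i)
    return hits


def u2_pairing_score(heptamer: str) -> float:
    """Base-pairing score of a BP heptamer against U2 snRNA's GUAGUA, in [0, 6].

    The branch nucleotide (heptamer position 6) bulges out of the helix and
    is not scored.  Each of the other six positions contributes +1.0 for a
    Watson-Crick pair, +0.5 for a G:U wobble, 0 otherwise (N scores 0).
    TACTAAC, the optimal BP from yeast to mammals, scores the maximum 6.0.
    """
    heptamer = heptamer.upper().replace("U", "T")
    if len(heptamer) != 7:
        raise ValueError(f"BP heptamer must be exactly 7 nt, got {len(heptamer)}")
    if set(heptamer) - set("ACGTN"):
        raise ValueError(f"heptamer contains non-ACGTN characters: {heptamer}")
    score = 0.0
    for i, base in enumerate(heptamer):
        if i == 5:  # bulged branch nucleotide
            continue
        if base == _WC_PARTNER[i]:
            score += 1.0
        elif _WOBBLE_PARTNER.get(i) == base:
            score += 0.5
    return score


def pwm_score_at(seq: str, pwm: PwmMatrix, offset: int = 0) -> float:
    """Log2-odds PWM score of the window starting at ``offset`` (N scores 0)."""
    lo = pwm.log_odds
    window = seq[offset : offset + pwm.width].upper()
    if len(window) != pwm.width:
        raise ValueError("window extends past end of sequence")
    score = 0.0
    for j, base in enumerate(window):
        if base in BASES:
            score += lo[j, BASES.index(base)]
    return score


def pwm_max_score(seq: str, pwm: PwmMatrix) -> tuple[float, int]:
    """Maximum log2-odds PWM score over all windows of ``seq``.

    Returns ``(score, offset)`` with the 0-based start of the best window;
    ties are broken toward the 3'-most window.
    """
    seq = seq.upper().replace("U", "T")
    n, w = len(seq), pwm.width
    if n < w:
        raise ValueError(f"sequence ({n} nt) shorter than PWM width ({w})")
    lo = pwm.log_odds
    idx = np.full(n, -1, dtype=np.int64)
    for k, base in enumerate(BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = k
    # per-position contributions for each PWM column; N rows contribute 0
    best_score, best_off = -math.inf, 0
    contrib = np.zeros((w, n))
    for j in range(w):
        valid = idx >= 0
        contrib[j, valid] = lo[j, idx[valid]]
    window_scores = np.zeros(n - w + 1)
    for j in range(w):
        window_scores += contrib[j, j : j + n - w + 1]
    best_off = int(np.flatnonzero(window_scores >= window_scores.max() - 1e-12)[-1])
    best_score = float(window_scores[best_off])
    return best_score, best_off


def ppt_score(region: str) -> tuple[float, int, int | None]:
    """Polypyrimidine-tract strength of ``region`` as a best-scoring segment.

    Per-base weights (:data:`PPT_WEIGHTS`): T +1.0, C +0.5, A -1.5, G -2.0.
    The score is the maximum sum over contiguous segments (Kadane); the
    empty segment is allowed, so all-purine regions score 0 with length 0.
    Ties are broken toward the segment closest to the 3' end.

    Returns ``(score, length, start)`` with ``start`` the 0-based offset of
    the segment within ``region`` (None for the empty segment).
    """
    region = region.upper().replace("U", "T")
    if not region:
        raise ValueError("empty region")
    best = (0.0, 0, None)  # score, length, start
    prefix = 0.0
    min_prefix, min_idx = 0.0, 0  # latest index achieving the minimum prefix
    best_score = 0.0
    for j, base in enumerate(region):
        try:
            prefix += PPT_WEIGHTS[base]
        except KeyError:
            raise ValueError(f"invalid base {base!r} in region") from None
        cand = prefix - min_prefix
        # ">=" prefers later end positions; latest min index prefers the
        # shortest / most 3' start among equal-scoring segments
        if cand >= best_score and cand > 0:
            best_score = cand
            best = (cand, j + 1 - min_idx, min_idx)
        if prefix <= min_prefix:
            min_prefix, min_idx = prefix, j + 1
    return best


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N is excluded from both numerator and
    denominator.  Returns NaN for an empty or all-N sequence."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in BASES)
    return gc / acgt if acgt else math.nan


def count_bp_matches(intron: IntronRecord | str, pattern: str = BP_CONSENSUS,
                     window: int = 100) -> int:
    """Number of degenerate BP-consensus matches within the 3' ``window`` nt.

    Events are conventionally partitioned as single-BP (count == 1) versus
    multi-BP (count >= 2); additional matches 5' of the natural BP are the
    feature associated with drug resistance.
    """
    if window < len(pattern):
        raise ValueError("window smaller than pattern")
    region = three_prime_region(intron, window)
    return len(match_degenerate(region, pattern))


# ---------------------------------------------------------------------------
# branch-point candidates and the per-intron feature vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BPCandidate:
    """One candidate branch-point heptamer at a fixed offset from the 3'ss.

    ``offset`` is the (negative) position of the heptamer's first
    nucleotide; the branch nucleotide sits at ``branch_offset = offset + 5``.
    ``functional`` requires an adenosine at the branch position; decoys
    (pairing-competent but branch-less) are flagged ``functional=False``.
    """

    offset: int
    heptamer: str
    pairing_score: float
    pwm_score: float
    matches_consensus: Mapping[str, bool] = field(default_factory=dict)

    @property
    def branch_offset(self) -> int:
        return self.offset + 5

    @property
    def functional(self) -> bool:
        return self.heptamer[5] == "A"


@dataclass
class FeatureVector:
    """All per-event 3'ss sequence features compared between groups."""

    bp_best_pairing: float = math.nan
    bp_best_pwm: float = math.nan
    bp_distance: float = math.nan      # |branch_offset| of the best functional BP
    n_bp_matches_100: int = 0
    ppt_score: float = math.nan
    ppt_length: float = math.nan
    gc_intron: float = math.nan
    gc_exon: float = math.nan
    len_intron: float = math.nan
    len_exon: float = math.nan
    len_transcript: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def bp_candidates(intron: IntronRecord | str, pwm: PwmMatrix | None = None,
                  bp_window: int = 150, min_branch_dist: int = 3) -> list[BPCandidate]:
    """Enumerate BP candidate heptamers whose branch nucleotide lies in the
    3' ``bp_window`` and at least ``min_branch_dist`` nt from the intron end
    (the terminal AG itself is excluded)."""
    seq = (intron.sequence if isinstance(intron, IntronRecord) else str(intron)).upper()
    L = len(seq)
    if L < 7:
        raise ValueError("intron shorter than 7 nt has no BP candidate")
    if pwm is None:
        pwm = sf1_pwm()
    out: list[BPCandidate] = []
    # heptamer start offset o (negative); branch b = o + 5
    lo = max(-L, -bp_window - 5)
    hi = -min_branch_dist - 6  # b <= -(min_branch_dist + 1)
    for o in range(lo, hi + 1):
        hept = seq[L + o : L + o + 7]
        if len(hept) != 7:
            continue
        out.append(BPCandidate(
            offset=o,
            heptamer=hept,
            pairing_score=u2_pairing_score(hept),
            pwm_score=pwm_score_at(hept, pwm) if pwm.width == 7 else math.nan,
            matches_consensus={
                BP_CONSENSUS: bool(match_degenerate(hept, BP_CONSENSUS)),
                BP_CONSENSUS_SHORT: bool(match_degenerate(hept[:5], BP_CONSENSUS_SHORT)),
            },
        ))
    return out


def score_intron(intron: IntronRecord, pwm: PwmMatrix | None = None,
                 bp_window: int = 150, multi_bp_window: int = 100,
                 exon_seq: str | None = None) -> FeatureVector:
    """Compute the full :class:`FeatureVector` for one intron.

    The best functional BP is the candidate maximizing the U2 pairing score
    (ties broken by PWM score, then toward the 3'-most candidate) among
    functional candidates in the 3' ``bp_window``.  The Py-tract is scored
    on the region between the chosen branch nucleotide and position -3,
    excluding the terminal AG.  ``bp_best_pwm`` is the maximal SF1 PWM
    binding score anywhere in the 3' ``bp_window`` region.
    """
    if len(intron) < 7:
        raise ValueError(f"intron {intron.name or intron.interval} shorter than 7 nt")
    if pwm is None:
        pwm = sf1_pwm()
    seq = intron.sequence.upper()
    L = len(seq)

    fv = FeatureVector()
    fv.len_intron = float(L)
    fv.gc_intron = gc_content(seq)
    fv.n_bp_matches_100 = count_bp_matches(intron, window=max(multi_bp_window, 7))
    if intron.downstream_exon_len:
        fv.len_exon = float(intron.downstream_exon_len)
    if intron.transcript_len:
        fv.len_transcript = float(intron.transcript_len)
    if exon_seq:
        fv.gc_exon = gc_content(exon_seq)

    region = three_prime_region(intron, bp_window)
    if len(region) >= pwm.width:
        fv.bp_best_pwm = pwm_max_score(region, pwm)[0]

    functional = [c for c in bp_candidates(intron, pwm, bp_window) if c.functional]
    if functional:
        best = max(functional, key=lambda c: (c.pairing_score, c.pwm_score, c.offset))
        fv.bp_best_pairing = best.pairing_score
        fv.bp_distance = float(-best.branch_offset)
        ppt_region = seq[L + best.branch_offset + 1 : L - 2]
        if ppt_region:
            score, length, _ = ppt_score(ppt_region)
            fv.ppt_score, fv.ppt_length = score, float(length)
        else:
            fv.ppt_score, fv.ppt_length = 0.0, 0.0
    return fv


#: features differenced between the two introns flanking an alternative exon
FLANKING_FEATURES = ("bp_best_pairing", "bp_best_pwm", "ppt_score")


def flanking_diff(upstream: FeatureVector, downstream: FeatureVector,
                  features: Sequence[str] = FLANKING_FEATURES) -> dict[str, float]:
    """Elementwise upstream - downstream feature differences.

    For cassette exons this contrasts the regulated 3'ss (upstream intron)
    with the 3'ss used in both inclusion and skipping (downstream intron).
    Missing values propagate as NaN.
    """
    up, dn = upstream.as_dict(), downstream.as_dict()
    return {name: up[name] - dn[name] for name in features}
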