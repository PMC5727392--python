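"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive results from first
principles (sliding windows, exhaustive segment enumeration, explicit
permutation counting) so that they stay independent of the library code
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from branchsense.io_formats import IUPAC, GenomicInterval, IntronRecord

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

PPT_W = {"T": 1.0, "C": 0.5, "A": -1.5, "G": -2.0, "N": -2.0}


def oracle_match(seq: str, pattern: str) -> list[int]:
    """Brute-force sliding-window IUPAC matcher (sequence N never matches)."""
    seq = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        ok = True
        for c, p in zip(seq[i : i + len(pattern)], pattern.upper()):
            if c not in IUPAC[p]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


def oracle_ppt(region: str) -> float:
    """Exhaustive O(n^2) maximum-sum segment score (empty segment allowed)."""
    w = [PPT_W[c] for c in region.upper()]
    best = 0.0
    for i in range(len(w)):
        s = 0.0
        for j in range(i, len(w)):
            s += w[j]
            best = max(best, s)
    return best


def oracle_pwm_max(seq: str, log_odds: np.ndarray) -> float:
    """Brute-force windowed log-odds sums; N contributes 0."""
    order = "ACGT"
    width = log_odds.shape[0]
    best = -math.inf
    for i in range(len(seq) - width + 1):
        s = sum(log_odds[j, order.index(c)]
                for j, c in enumerate(seq[i : i + width]) if c in order)
        best = max(best, s)
    return best


def oracle_mw_exact_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all C(n1+n2, n1)
    placements of the x-ranks (no ties allowed)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    n1 = len(x)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mean_u = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(c + 1 for c in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)


def make_intron(seq: str, strand: str = "+", name: str = "iv",
                start: int = 0, **kw) -> IntronRecord:
    return IntronRecord(
        interval=GenomicInterval("chr1", start, start + len(seq), strand),
        sequence=seq, name=name, **kw)


@pytest.fixture
def small_event_table():
    """Three-event CE+IR table, two samples, hand-checkable counts."""
    from branchsense.io_formats import EventTable

    df = pd.DataFrame({
        "EVENT_ID": ["ce1", "ce2", "ir1"],
        "GENE_ID": ["gA", "gB", "gC"],
        "TYPE": ["CE", "CE", "IR"],
        "CHROM": ["chr1"] * 3,
        "STRAND": ["+", "-", "+"],
        "COORDS": ["100-200", "300-400", "500-700"],
    })
    counts = {
        # sample: (INC1, INC2, EXC, EI1, EI2, EE) per event
        "S1": [(30, 10, 20), (10, 10, 0), (7, 9, 24)],
        "S2": [(0, 0, 10), (5, 5, 5), (10, 20, 15)],
    }
    for s, rows in counts.items():
        for k, base in enumerate(["INC1", "INC2", "EXC"]):
            df[f"{base}_{s}"] = pd.array(
                [rows[i][k] if df["TYPE"][i] == "CE" else 0 for i in range(3)],
                dtype="Int64")
        for k, base in enumerate(["EI1", "EI2", "EE"]):
            df[f"{base}_{s}"] = pd.array(
                [rows[i][k] if df["TYPE"][i] == "IR" else 0 for i in range(3)],
                dtype="Int64")
        df[f"FPKM_{s}"] = [5.0, 2.5, 10.0]
    return EventTable(df=df, samples=["S1", "S2"])
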