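"""Hexamer clustering, consensus motifs, positional preferences and PWM matching.

The clustering metric is tailored to short k-mers: two hexamers that share
any contiguous 4-mer are treated as variants of the same element (distance
0); otherwise their Levenshtein edit distance is used.  Complete-linkage
agglomeration with flat clusters cut at merge height 4 groups hexamers into
motifs, summarized as consensus strings with degenerate (X/Y) two-base
positions and x for no consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASES, Pwm, validate_hexamer
from .events import IntronEvent, part_sequence


# ---------------------------------------------------------------------------
# distance and clustering
# ---------------------------------------------------------------------------

def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hexamer_distance(a: str, b: str, k: int = 6, share: int = 4) -> int:
    """0 if the two k-mers share any contiguous ``share``-mer; else their
    Levenshtein edit distance."""
    a = validate_hexamer(a, k)
    b = validate_hexamer(b, k)
    amers = {a[i : i + share] for i in range(k - share + 1)}
    if any(b[i : i + share] in amers for i in range(k - share + 1)):
        return 0
    return _levenshtein(a, b)


@dataclass
class HexamerCluster:
    """A flat cluster of hexamers with its complete-linkage merge height."""

    members: list[str]
    height: float
    consensus: str = ""


def cluster_hexamers(
    hexamers: list[str], cut: float = 4, with_consensus: bool = True
) -> list[HexamerCluster]:
    """Complete-linkage agglomeration on :func:`hexamer_distance`, cut at
    merge height ``cut``.

    At every step the pair of clusters with the smallest complete-linkage
    distance is merged, ties broken by the lexicographically smallest member
    pair, so the result is deterministic.  Merging stops when the smallest
    distance exceeds ``cut``; remaining clusters are the flat clusters.
    """
    hexamers = [validate_hexamer(h) for h in hexamers]
    if not hexamers:
        raise ValueError("need at least one hexamer")
    hexamers = sorted(set(hexamers))
    n = len(hexamers)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hexamer_distance(hexamers[i], hexamers[j])
    clusters = [{i} for i in range(n)]
    heights = [0.0] * n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                key = (d, min(hexamers[i] for i in clusters[a] | clusters[b]),
                       min(hexamers[i] for i in clusters[a]),
                       min(hexamers[i] for i in clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, *_), a, b = best
        if d > cut:
            break
        clusters[a] = clusters[a] | clusters[b]
        heights[a] = max(heights[a], heights[b], d)
        del clusters[b], heights[b]
    out = [
        HexamerCluster(members=sorted(hexamers[i] for i in c), height=h)
        for c, h in zip(clusters, heights)
    ]
    out.sort(key=lambda c: c.members[0])
    if with_consensus:
        for c in out:
            c.consensus = consensus_motif(c)
    return out


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def _alignment_offsets(members: list[str]) -> list[int]:
    """Ungapped offset of each member relative to the cluster medoid.

    The medoid is the member minimizing its summed distance to the others;
    every other member is shifted by the offset in -5..+5 maximizing its
    column agreement with the medoid (ties: smallest |offset|, then the
    smaller offset).
    """
    if len(members) == 1:
        return [0]
    sums = [
        sum(hexamer_distance(m, o) for o in members if o != m) for m in members
    ]
    medoid = members[int(np.argmin(sums))]
    offsets = []
    k = len(medoid)
    for m in members:
        best = (0, -1)  # (offset, score)
        for off in range(-(k - 1), k):
            score = sum(
                1
                for i in range(k)
                if 0 <= i + off < k and m[i] == medoid[i + off]
            )
            cand_key = (score, -abs(off), -off)
            best_key = (best[1], -abs(best[0]), -best[0])
            if cand_key > best_key:
                best = (off, score)
        offsets.append(best[0])
    return offsets


def consensus_motif(
    cluster: HexamerCluster | list[str],
    single_threshold: float = 0.75,
    double_threshold: float = 0.75,
) -> str:
    """Consensus string of a hexamer cluster.

    Members are aligned ungapped against the cluster medoid; per column the
    consensus is the top base when its frequency is >= 0.75, ``(X/Y)`` when
    the top two bases jointly reach 0.75, and ``x`` otherwise.  Leading and
    trailing ``x`` columns are trimmed, so consensus strings can be shorter
    than 6 characters.
    """
    members = cluster.members if isinstance(cluster, HexamerCluster) else list(cluster)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    offsets = _alignment_offsets(members)
    k = len(members[0])
    lo = min(offsets)
    hi = max(offsets) + k
    columns = []
    for col in range(lo, hi):
        counts: dict[str, int] = {}
        total = 0
        for m, off in zip(members, offsets):
            i = col - off
            if 0 <= i < k:
                counts[m[i]] = counts.get(m[i], 0) + 1
                total += 1
        if total == 0:
            columns.append("x")
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] / total >= single_threshold:
            columns.append(ranked[0][0])
        elif len(ranked) >= 2 and (ranked[0][1] + ranked[1][1]) / total >= double_threshold:
            columns.append(f"({ranked[0][0]}/{ranked[1][0]})")
        else:
            columns.append("x")
    while columns and columns[0] == "x":
        columns.pop(0)
    while columns and columns[-1] == "x":
        columns.pop()
    return "".join(columns)


# ---------------------------------------------------------------------------
# positional preference
# ---------------------------------------------------------------------------

@dataclass
class PositionalProfile:
    """Histogram of a hexamer group's relative positions within a region."""

    group: str
    region: str
    histogram: np.ndarray
    n_occurrences: int


def positional_preference(
    hexamer_group: list[str],
    events: list[IntronEvent],
    region: str,
    genome: dict[str, str],
    dnase,
    bins: int = 20,
) -> PositionalProfile:
    """Average positional-preference histogram over the group's hexamers.

    Per event and hexamer only one occurrence counts: the one with the
    lowest mean DNase depth over its 6 bases (the same rule the footprint
    profiles use).  Relative position = occurrence start / (region length
    - 6) in transcript orientation.  The group histogram is the mean of
    member-hexamer histograms, each normalized to sum to 1.
    """
    hexamer_group = [validate_hexamer(h) for h in hexamer_group]
    member_hists = []
    total = 0
    for h in hexamer_group:
        hist = np.zeros(bins)
        n = 0
        for event in events:
            iv = event.part(region)
            if len(iv) < 7:
                continue
            seq = part_sequence(event, region, genome)
            cov = dnase.slice_oriented(iv, event.strand)
            best = None
            for off in range(len(seq) - 5):
                if seq[off : off + 6] == h:
                    m = cov[off : off + 6].mean()
                    if best is None or m < best[0]:
                        best = (m, off)
            if best is None:
                continue
            rel = best[1] / (len(seq) - 6) if len(seq) > 6 else 0.0
            b = min(int(rel * bins), bins - 1)
            hist[b] += 1
            n += 1
        if n:
            member_hists.append(hist / n)
            total += n
    if not member_hists:
        return PositionalProfile(
            group="+".join(hexamer_group), region=region,
            histogram=np.zeros(bins), n_occurrences=0,
        )
    return PositionalProfile(
        group="+".join(hexamer_group), region=region,
        histogram=np.mean(member_hists, axis=0), n_occurrences=total,
    )


# ---------------------------------------------------------------------------
# PWM information content and cistrome matching
# ---------------------------------------------------------------------------

def pwm_information_content(pwm: Pwm) -> tuple[np.ndarray, float]:
    """Per-column and total information content in bits, uniform background.

    IC_j = 2 + sum_b p_bj log2 p_bj, with 0*log(0) = 0.
    """
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + terms.sum(axis=1)
    return ic, float(ic.sum())


@dataclass
class CistromeMatch:
    """Result of matching one hexamer against one PWM."""

    hexamer: str
    motif_id: str
    offset: int  # -1 when no qualifying offset
    covered_ic: float
    total_ic: float
    matched: bool


def cistrome_match(hexamer: str, pwm: Pwm, min_ic_fraction: float = 0.5) -> CistromeMatch:
    """Match a hexamer against a PWM consensus under the 50%-IC rule.

    The hexamer matches if it equals the consensus substring at some offset
    AND the information content of the 6 covered columns is at least
    ``min_ic_fraction`` of the motif's total IC.  Among qualifying offsets
    the one with maximal covered IC is reported.  PWMs narrower than 6
    columns never match.
    """
    hexamer = validate_hexamer(hexamer)
    ic, total = pwm_information_content(pwm)
    if pwm.width < 6:
        return CistromeMatch(hexamer, pwm.motif_id, -1, 0.0, total, False)
    consensus = pwm.consensus
    best = None
    for off in range(pwm.width - 5):
        if consensus[off : off + 6] != hexamer:
            continue
        covered = float(ic[off : off + 6].sum())
        if best is None or covered > best[1]:
            best = (off, covered)
    if best is None:
        return CistromeMatch(hexamer, pwm.motif_id, -1, 0.0, total, False)
    off, covered = best
    matched = total > 0 and covered >= min_ic_fraction * total
    return CistromeMatch(hexamer, pwm.motif_id, off, covered, total, matched)


def match_hexamers_to_pwms(
    hexamers: list[str], pwms: list[Pwm], min_ic_fraction: float = 0.5
) -> pd.DataFrame:
    """All-vs-all hexamer/PWM matching table."""
    rows = []
    for h in hexamers:
        for p in pwms:
            m = cistrome_match(h, p, min_ic_fraction)
            rows.append((m.hexamer, m.motif_id, m.offset, m.covered_ic,
                         m.total_ic, m.matched))
    return pd.DataFrame(
        rows,
        columns=["hexamer", "motif_id", "offset", "covered_ic", "total_ic",
                 "matched"],
    )
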