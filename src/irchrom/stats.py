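"""Inferential statistics for the pipeline.

Fisher exact and Mann-Whitney tests, Benjamini-Hochberg adjustment,
per-hexamer IR/IE enrichment, hypergeometric cross-species conservation,
and the exact multi-set intersection test (the statistic behind the
SuperExactTest method: the exact distribution of the intersection size of
independent uniform random subsets of a finite population).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import BASES


@dataclass
class ContingencyTable:
    """A labelled 2x2 table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("negative count in contingency table")
        if self.counts.sum() == 0:
            raise ValueError("all-zero contingency table")


@dataclass
class MultiSetTestResult:
    """Observed vs expected intersection of m subsets of an N-element universe."""

    set_names: tuple[str, ...]
    set_sizes: tuple[int, ...]
    population: int
    observed: int
    expected: float
    p_value: float


def fisher_exact(table: ContingencyTable | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The two-sided p sums, over all tables with
    the observed margins, the hypergeometric probabilities no larger than the
    observed table's (the probability-mass rule, R's default).  A degenerate
    margin (zero row or column) gives p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return np.nan, 1.0
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    return float(odds), float(min(p, 1.0))


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x via midranks (ties shared)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration over all labelings when both groups have <= 8
    observations (ties handled through midranks; two-sided p is the
    probability of a U at least as far from its null mean m*n/2 as observed);
    otherwise the normal approximation with continuity and tie correction.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    u_obs = _rank_sum_u(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return u_obs, 1.0
    if m <= 8 and n <= 8:
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        center = m * n / 2.0
        dev_obs = abs(u_obs - center)
        hits = total = 0
        offset = m * (m + 1) / 2.0
        for idx in itertools.combinations(range(m + n), m):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - center) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hexamer_enrichment(
    events,
    genome: dict[str, str],
    part: str,
    k: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-hexamer IR vs IE presence/absence enrichment in one event part.

    For each of the 4^k hexamers: a = IR events whose ``part`` sequence
    contains the hexamer, b = IR events without, c/d likewise for IE.
    Fisher two-sided p per hexamer; BH adjustment within each
    (part, direction) family.  The counting unit is event-level presence,
    not occurrence counts.
    """
    from .events import part_sequence  # local import to avoid cycle

    ir = [e for e in events if e.label == "IR"]
    ie = [e for e in events if e.label == "IE"]
    if not ir and not ie:
        return pd.DataFrame(
            columns=["hexamer", "part", "a", "b", "c", "d",
                     "odds_ratio", "p", "p_adj", "direction", "significant"]
        )

    def presence_counts(group):
        counts = {}
        for e in group:
            seq = part_sequence(e, part, genome)
            seen = {seq[i : i + k] for i in range(len(seq) - k + 1)}
            for h in seen:
                counts[h] = counts.get(h, 0) + 1
        return counts

    ir_counts = presence_counts(ir)
    ie_counts = presence_counts(ie)
    n_ir, n_ie = len(ir), len(ie)

    all_hex = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    rows = []
    for h in all_hex:
        a = ir_counts.get(h, 0)
        c = ie_counts.get(h, 0)
        b, d = n_ir - a, n_ie - c
        if a + c == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact(np.array([[a, b], [c, d]]))
        # direction from the sample proportions (odds ratio may be 0/inf)
        p_ir = a / n_ir if n_ir else 0.0
        p_ie = c / n_ie if n_ie else 0.0
        direction = "IR-enriched" if p_ir >= p_ie else "IE-enriched"
        rows.append((h, part, a, b, c, d, odds, p, direction))
    df = pd.DataFrame(
        rows,
        columns=["hexamer", "part", "a", "b", "c", "d", "odds_ratio", "p",
                 "direction"],
    )
    df["p_adj"] = np.nan
    for direction in ("IR-enriched", "IE-enriched"):
        mask = df["direction"] == direction
        if mask.any():
            df.loc[mask, "p_adj"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df


def conserved_hexamers(
    set_a, set_b, population: int = 4096
) -> tuple[set, float]:
    """Overlap of two hexamer sets and its hypergeometric tail probability.

    p = P[X >= k] with X ~ Hypergeometric(N=population, K=|A|, n=|B|) and
    k the observed overlap.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > population or len(b) > population:
        raise ValueError("set larger than the population")
    k = len(a & b)
    p = float(sps.hypergeom.sf(k - 1, population, len(a), len(b)))
    return a & b, min(p, 1.0)


def intersection_distribution(sizes, population: int) -> np.ndarray:
    """Exact pmf of |A_1 ∩ ... ∩ A_m| for independent uniform subsets.

    Each A_i is drawn uniformly among subsets of size sizes[i] from a
    population of N elements.  Built by iterated hypergeometric mixing:
    conditional on the running intersection having s elements, intersecting
    with the next subset of size n gives a Hypergeometric(N, s, n) count.
    """
    sizes = list(sizes)
    if any(n > population or n < 0 for n in sizes):
        raise ValueError("subset size outside [0, population]")
    pmf = np.zeros(population + 1)
    pmf[sizes[0]] = 1.0
    support = np.arange(population + 1)
    for n in sizes[1:]:
        new = np.zeros_like(pmf)
        for s in np.flatnonzero(pmf > 0):
            new += pmf[s] * sps.hypergeom.pmf(support, population, s, n)
        pmf = new
    return pmf


def multiset_intersection_test(
    sets: dict[str, set], population: int = 4096
) -> list[MultiSetTestResult]:
    """Exact intersection test for every combination of >= 2 of the input sets.

    For each combination the observed intersection size k is compared with
    the exact null distribution of the intersection of independent uniform
    random subsets of the given sizes (p = P[X >= k]); the expected size is
    prod(n_i) / N^(m-1).  Results are sorted by ascending p.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    for name in names:
        if len(sets[name]) > population:
            raise ValueError(f"set {name!r} larger than the population")
    results = []
    for m in range(2, len(names) + 1):
        for combo in itertools.combinations(names, m):
            members = [sets[c] for c in combo]
            k_obs = len(set.intersection(*members))
            sizes = [len(s) for s in members]
            pmf = intersection_distribution(sizes, population)
            p = float(pmf[k_obs:].sum())
            expected = float(np.prod([s / population for s in sizes]) * population)
            results.append(
                MultiSetTestResult(
                    set_names=combo,
                    set_sizes=tuple(sizes),
                    population=population,
                    observed=k_obs,
                    expected=expected,
                    p_value=min(p, 1.0),
                )
            )
    return sorted(results, key=lambda r: r.p_value)
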