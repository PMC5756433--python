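"""Per-hexamer DNase profile construction and the continuous-HMM footprint caller.

For every occurrence of a hexamer inside an event part (5' exon, intron or
3' exon) the DNase coverage is extracted over the 6 hexamer bases plus 100 bp
up- and downstream (206 slots, transcript orientation), without crossing the
part boundaries.  Occurrences are averaged position-wise and standardized by
the training background coverage ``C_train``.  A 13-state hidden Markov model
with Gaussian emissions decodes the averaged profile into background, down,
footprint and up states (with optional secondary footprint blocks upstream
and downstream of the primary one), and a hexamer is scored by

    S = -log(C_FP / C_BG)

where ``C_FP`` is the mean standardized coverage over positions decoded as
the primary footprint state and ``C_BG`` the mean over background states.
Deeper protection from DNase cleavage gives a larger S.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoverageTrack, validate_hexamer
from .events import IntronEvent, PARTS, part_sequence

WINDOW_FLANK = 100
WINDOW_LEN = 2 * WINDOW_FLANK + 6  # 206
HEX_SLOTS = slice(WINDOW_FLANK, WINDOW_FLANK + 6)  # positions of the hexamer

STATE_NAMES = (
    "BG1", "DNu", "FPu", "UPu", "BGu",
    "DN", "FP", "UP",
    "BGd", "DNd", "FPd", "UPd", "BG2",
)
N_STATES = len(STATE_NAMES)
STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}
BACKGROUND_STATES = frozenset(
    STATE_INDEX[n] for n in ("BG1", "BGu", "BGd", "BG2")
)
FP_PRIMARY = STATE_INDEX["FP"]
CORE_STATES = frozenset(STATE_INDEX[n] for n in ("BG1", "DN", "FP", "UP", "BG2"))

# secondary states borrow emissions from their core counterpart when they
# receive no labelled training positions
_TIE_MAP = {
    "DNu": "DN", "FPu": "FP", "UPu": "UP",
    "DNd": "DN", "FPd": "FP", "UPd": "UP",
    "BGu": "BG1", "BGd": "BG2",
}

# left-to-right topology with self-loops; the optional upstream block sits
# between BG1 and the primary dip, the downstream block between UP and BG2
_EDGES = {
    "BG1": ("BG1", "DNu", "DN"),
    "DNu": ("DNu", "FPu"),
    "FPu": ("FPu", "UPu"),
    "UPu": ("UPu", "BGu"),
    "BGu": ("BGu", "DN"),
    "DN": ("DN", "FP"),
    "FP": ("FP", "UP"),
    "UP": ("UP", "BGd", "BG2"),
    "BGd": ("BGd", "DNd"),
    "DNd": ("DNd", "FPd"),
    "FPd": ("FPd", "UPd"),
    "UPd": ("UPd", "BG2"),
    "BG2": ("BG2",),
}

TOPOLOGY_MASK = np.zeros((N_STATES, N_STATES), dtype=bool)
for _src, _dests in _EDGES.items():
    for _d in _dests:
        TOPOLOGY_MASK[STATE_INDEX[_src], STATE_INDEX[_d]] = True

VARIANCE_FLOOR = 1e-3


@dataclass
class OccurrenceWindow:
    """DNase coverage around one hexamer occurrence, transcript-oriented.

    ``values`` has 206 slots (100 upstream, 6 hexamer, 100 downstream);
    slots clipped at the part boundary are NaN with ``present`` False.
    The 6 hexamer slots are always present.
    """

    hexamer: str
    event_uid: str
    part: str
    values: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != WINDOW_LEN or len(self.present) != WINDOW_LEN:
            raise ValueError(f"window must have {WINDOW_LEN} slots")
        if not self.present[HEX_SLOTS].all():
            raise ValueError("hexamer slots must always be present")


@dataclass
class HexamerProfile:
    """Averaged, standardized 206-position coverage profile of one hexamer."""

    hexamer: str
    part: str
    label: str
    values: np.ndarray  # mean standardized coverage; NaN where support == 0
    support: np.ndarray
    n_occurrences: int
    c_train: float

    def present(self) -> np.ndarray:
        return self.support > 0


@dataclass
class FootprintCall:
    """Decoded state path and footprint score for one hexamer profile."""

    hexamer: str
    part: str
    label: str
    path: np.ndarray  # state index per slot; -1 for absent slots
    c_fp: float
    c_bg: float
    score: float
    is_footprint: bool
    n_occurrences: int = 0


@dataclass
class FootprintHmm:
    """13-state left-to-right continuous HMM with Gaussian emissions.

    ``c_train`` is the training-set background coverage; profiles must be
    standardized by the same constant before decoding.
    """

    transitions: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    c_train: float
    start: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.maximum(
            np.asarray(self.variances, dtype=float), VARIANCE_FLOOR
        )
        if self.transitions.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 13x13")
        if ((self.transitions > 0) & ~TOPOLOGY_MASK).any():
            raise ValueError("transition outside the left-to-right topology")
        rowsum = self.transitions.sum(axis=1)
        if np.abs(rowsum - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if self.start is None:
            self.start = np.zeros(N_STATES)
            self.start[STATE_INDEX["BG1"]] = 1.0

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """Log N(x; mu_s, var_s) for each state; shape (n_states, len(x))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        mu = self.means[:, None]
        var = self.variances[:, None]
        return -0.5 * (np.log(2 * np.pi * var) + (x[None, :] - mu) ** 2 / var)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "states": list(STATE_NAMES),
            "transitions": self.transitions.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "start": self.start.tolist(),
            "c_train": self.c_train,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FootprintHmm":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if tuple(doc["states"]) != STATE_NAMES:
            raise ValueError("state set mismatch")
        return cls(
            transitions=np.array(doc["transitions"]),
            means=np.array(doc["means"]),
            variances=np.array(doc["variances"]),
            start=np.array(doc["start"]),
            c_train=float(doc["c_train"]),
        )


# ---------------------------------------------------------------------------
# occurrence collection and profile construction
# ---------------------------------------------------------------------------

def collect_occurrences(
    hexamer: str,
    events: list[IntronEvent],
    part: str,
    genome: dict[str, str],
    dnase: CoverageTrack,
) -> list[OccurrenceWindow]:
    """One window per event part that contains the hexamer.

    When a part carries several instances of the hexamer, the instance with
    the lowest mean raw coverage over its 6 bases is kept (a bound protein
    should produce the deepest local protection).  Windows are clipped at
    part boundaries so flanking-segment composition cannot leak in.
    """
    hexamer = validate_hexamer(hexamer)
    windows = []
    for event in events:
        seq = part_sequence(event, part, genome)
        if len(seq) < 6:
            continue
        cov = dnase.slice_oriented(event.part(part), event.strand)
        best = None  # (mean coverage, offset)
        for off in _find_all(seq, hexamer):
            m = cov[off : off + 6].mean()
            if best is None or m < best[0]:
                best = (m, off)
        if best is None:
            continue
        windows.append(_make_window(hexamer, event.uid, part, cov, best[1]))
    return windows


def _find_all(seq: str, sub: str):
    start = 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return
        yield i
        start = i + 1


def _make_window(
    hexamer: str, uid: str, part: str, cov: np.ndarray, offset: int
) -> OccurrenceWindow:
    values = np.full(WINDOW_LEN, np.nan)
    lo = max(0, offset - WINDOW_FLANK)
    hi = min(len(cov), offset + 6 + WINDOW_FLANK)
    j0 = lo - (offset - WINDOW_FLANK)
    values[j0 : j0 + (hi - lo)] = cov[lo:hi]
    return OccurrenceWindow(
        hexamer=hexamer,
        event_uid=uid,
        part=part,
        values=values,
        present=~np.isnan(values),
    )


def build_hexamer_profile(
    windows: list[OccurrenceWindow],
    c_train: float,
    label: str = "",
    min_occurrences: int = 10,
) -> HexamerProfile | None:
    """Position-wise mean over present slots, divided by ``c_train``.

    Returns None (hexamer unscored) when there are fewer than
    ``min_occurrences`` windows.
    """
    if len(windows) < min_occurrences:
        return None
    stack = np.stack([w.values for w in windows])
    support = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    mean = np.where(support > 0, sums / np.maximum(support, 1), np.nan)
    return HexamerProfile(
        hexamer=windows[0].hexamer,
        part=windows[0].part,
        label=label,
        values=mean / c_train,
        support=support,
        n_occurrences=len(windows),
        c_train=c_train,
    )


# ---------------------------------------------------------------------------
# supervised training (+ optional Baum-Welch refinement)
# ---------------------------------------------------------------------------

def _as_state_indices(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(int)
    return np.array([STATE_INDEX[str(l)] for l in labels])


def train_footprint_hmm(
    labeled_profiles,
    refine: bool = False,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> FootprintHmm:
    """Supervised maximum-likelihood fit of the 13-state footprint HMM.

    ``labeled_profiles`` is a sequence of ``(values, labels)`` pairs where
    ``values`` is the raw (unstandardized) coverage profile and ``labels``
    gives the generating state per position (names or indices).  ``C_train``
    is the mean raw coverage over background-labelled positions; emissions
    are fitted on values standardized by it.  Transitions come from labelled
    bigrams with add-one smoothing over the topology-allowed edges.  Core
    states with no labelled positions are an error; secondary states borrow
    their core counterpart's emission.  ``refine=True`` runs Baum-Welch
    (topology zeros kept fixed) until the log-likelihood gain drops below
    ``tol`` or ``max_iter`` iterations.
    """
    if not labeled_profiles:
        raise ValueError("no training profiles")
    seqs = []
    for values, labels in labeled_profiles:
        values = np.asarray(values, dtype=float)
        idx = _as_state_indices(labels)
        if len(values) != len(idx):
            raise ValueError("values/labels length mismatch")
        seqs.append((values, idx))

    bg_vals = np.concatenate(
        [v[np.isin(s, list(BACKGROUND_STATES))] for v, s in seqs]
    )
    if bg_vals.size == 0:
        raise ValueError("no background-labelled positions; cannot standardize")
    c_train = float(bg_vals.mean())
    if c_train <= 0:
        raise ValueError("non-positive training background coverage")

    per_state = {s: [] for s in range(N_STATES)}
    bigrams = np.zeros((N_STATES, N_STATES))
    for values, idx in seqs:
        std = values / c_train
        for s in range(N_STATES):
            sel = std[idx == s]
            if sel.size:
                per_state[s].append(sel)
        np.add.at(bigrams, (idx[:-1], idx[1:]), 1)

    if (bigrams[~TOPOLOGY_MASK] > 0).any():
        raise ValueError("training labels contain a transition outside the topology")

    if not any(per_state[s] for s in (FP_PRIMARY,)):
        raise ValueError("no footprint-labelled positions in the training set")
    means = np.zeros(N_STATES)
    variances = np.full(N_STATES, VARIANCE_FLOOR)
    for s in range(N_STATES):
        if per_state[s]:
            vals = np.concatenate(per_state[s])
            means[s] = vals.mean()
            variances[s] = max(vals.var(), VARIANCE_FLOOR)
        else:
            name = STATE_NAMES[s]
            if s in CORE_STATES:
                raise ValueError(f"core state {name} has no labelled positions")
            tied = STATE_INDEX[_TIE_MAP[name]]
            if not per_state[tied]:
                raise ValueError(
                    f"state {name} and its core counterpart are both unlabelled"
                )
            tvals = np.concatenate(per_state[tied])
            means[s] = tvals.mean()
            variances[s] = max(tvals.var(), VARIANCE_FLOOR)

    transitions = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        allowed = TOPOLOGY_MASK[s]
        transitions[s, allowed] = (bigrams[s, allowed] + 1.0) / (
            bigrams[s, allowed].sum() + allowed.sum()
        )

    hmm = FootprintHmm(
        transitions=transitions, means=means, variances=variances, c_train=c_train
    )
    if refine:
        hmm = _baum_welch(hmm, [v / c_train for v, _ in seqs], max_iter, tol)
    return hmm


def _baum_welch(hmm: FootprintHmm, sequences, max_iter: int, tol: float) -> FootprintHmm:
    """EM refinement of emissions and transitions; topology zeros stay zero."""
    from scipy.special import logsumexp

    trans = hmm.transitions.copy()
    means, variances = hmm.means.copy(), hmm.variances.copy()
    log_start = np.log(np.where(hmm.start > 0, hmm.start, 1e-300))
    prev_ll = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_a = np.log(np.where(trans > 0, trans, 1e-300))
        model = FootprintHmm(trans, means, variances, hmm.c_train, hmm.start)
        total_ll = 0.0
        xi_acc = np.zeros_like(trans)
        g_w = np.zeros(N_STATES)
        g_x = np.zeros(N_STATES)
        g_x2 = np.zeros(N_STATES)
        for x in sequences:
            log_b = model.log_emission(x)
            T = len(x)
            alpha = np.zeros((T, N_STATES))
            alpha[0] = log_start + log_b[:, 0]
            for t in range(1, T):
                alpha[t] = logsumexp(alpha[t - 1][:, None] + log_a, axis=0) + log_b[:, t]
            beta = np.zeros((T, N_STATES))
            for t in range(T - 2, -1, -1):
                beta[t] = logsumexp(log_a + (log_b[:, t + 1] + beta[t + 1])[None, :], axis=1)
            ll = logsumexp(alpha[-1])
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)
            for t in range(T - 1):
                xi = alpha[t][:, None] + log_a + (log_b[:, t + 1] + beta[t + 1])[None, :] - ll
                xi_acc += np.exp(xi)
            g_w += gamma.sum(axis=0)
            g_x += gamma.T @ x
            g_x2 += gamma.T @ (x ** 2)
        xi_acc[~TOPOLOGY_MASK] = 0.0
        rows = xi_acc.sum(axis=1)
        new_trans = trans.copy()
        ok = rows > 0
        new_trans[ok] = xi_acc[ok] / rows[ok, None]
        trans = new_trans
        nz = g_w > 0
        means[nz] = g_x[nz] / g_w[nz]
        variances[nz] = np.maximum(
            g_x2[nz] / g_w[nz] - means[nz] ** 2, VARIANCE_FLOOR
        )
        if abs(total_ll - prev_ll) < tol:
            break
        prev_ll = total_ll
    return FootprintHmm(trans, means, variances, hmm.c_train, hmm.start)


# ---------------------------------------------------------------------------
# decoding and scoring
# ---------------------------------------------------------------------------

def viterbi(hmm: FootprintHmm, values: np.ndarray) -> np.ndarray:
    """Viterbi state path over present slots; absent (NaN) slots are skipped
    with the transition composed across the gap.  Returns a state index per
    slot, -1 for absent slots.
    """
    values = np.asarray(values, dtype=float)
    present = np.flatnonzero(np.isfinite(values))
    path = np.full(len(values), -1, dtype=int)
    if present.size == 0:
        return path
    obs = values[present]
    log_b = hmm.log_emission(obs)  # (n_states, T)
    with np.errstate(divide="ignore"):
        log_start = np.log(np.where(hmm.start > 0, hmm.start, 0.0))
    gap_logs: dict[int, np.ndarray] = {}

    def log_trans(gap: int) -> np.ndarray:
        if gap not in gap_logs:
            mat = np.linalg.matrix_power(hmm.transitions, gap + 1)
            with np.errstate(divide="ignore"):
                gap_logs[gap] = np.log(np.where(mat > 0, mat, 0.0))
        return gap_logs[gap]

    T = len(obs)
    delta = log_start + log_b[:, 0]
    back = np.zeros((T, N_STATES), dtype=int)
    for t in range(1, T):
        la = log_trans(present[t] - present[t - 1] - 1)
        scores = delta[:, None] + la
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + log_b[:, t]
    state = int(delta.argmax())
    states = np.zeros(T, dtype=int)
    states[-1] = state
    for t in range(T - 1, 0, -1):
        state = back[t, state]
        states[t - 1] = state
    path[present] = states
    return path


def decode_profile(
    profile: HexamerProfile,
    hmm: FootprintHmm,
    threshold: float = 0.30,
    log_base: float | None = None,
    score_cap: float = 10.0,
) -> FootprintCall:
    """Viterbi-decode a standardized profile and score the footprint.

    ``S = -log(C_FP / C_BG)`` (natural log by default; pass ``log_base`` to
    change the base — the thresholds 0.30 / 0.20 are interpreted in the same
    units).  ``is_footprint`` requires the primary footprint state to cover
    at least one of the 6 hexamer slots AND ``S >= threshold``.  When no
    position decodes to the primary footprint state, S = 0; when C_FP is 0,
    S is capped at ``score_cap``.
    """
    if abs(profile.c_train - hmm.c_train) > 1e-9 * max(1.0, abs(hmm.c_train)):
        raise ValueError(
            "profile was standardized with a different C_train than the model's"
        )
    path = viterbi(hmm, profile.values)
    fp_mask = path == FP_PRIMARY
    bg_mask = np.isin(path, list(BACKGROUND_STATES))
    if not fp_mask.any():
        return FootprintCall(
            hexamer=profile.hexamer, part=profile.part, label=profile.label,
            path=path, c_fp=np.nan, c_bg=np.nan, score=0.0, is_footprint=False,
            n_occurrences=profile.n_occurrences,
        )
    c_fp = float(profile.values[fp_mask].mean())
    c_bg = float(profile.values[bg_mask].mean()) if bg_mask.any() else np.nan
    if not np.isfinite(c_bg) or c_bg <= 0:
        score = 0.0
    elif c_fp <= 0:
        score = score_cap
    else:
        score = -np.log(c_fp / c_bg)
        if log_base is not None:
            score /= np.log(log_base)
        score = float(np.clip(score, -score_cap, score_cap))
    hex_hit = bool(fp_mask[HEX_SLOTS].any())
    return FootprintCall(
        hexamer=profile.hexamer, part=profile.part, label=profile.label,
        path=path, c_fp=c_fp, c_bg=c_bg, score=score,
        is_footprint=hex_hit and score >= threshold,
        n_occurrences=profile.n_occurrences,
    )


def scan_all_hexamers(
    events: list[IntronEvent],
    genome: dict[str, str],
    dnase: CoverageTrack,
    hmm: FootprintHmm,
    threshold: float = 0.30,
    parts=PARTS,
    classes=("IR", "IE"),
    hexamers=None,
    min_occurrences: int = 10,
    log_base: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score hexamers for footprints in each (part, class) combination.

    Returns ``(scored, unscored)`` data frames; ``unscored`` lists hexamers
    seen fewer than ``min_occurrences`` times in a combination.  Restricting
    ``hexamers`` / ``parts`` / ``classes`` limits the scan.
    """
    hexset = None if hexamers is None else {validate_hexamer(h) for h in hexamers}
    scored_rows, unscored_rows = [], []
    for label in classes:
        group = [e for e in events if e.label == label]
        for part in parts:
            sums: dict[str, np.ndarray] = {}
            supp: dict[str, np.ndarray] = {}
            nocc: dict[str, int] = {}
            for event in group:
                seq = part_sequence(event, part, genome)
                L = len(seq)
                if L < 6:
                    continue
                cov = dnase.slice_oriented(event.part(part), event.strand)
                hexmean = np.convolve(cov, np.ones(6), mode="valid") / 6.0
                best: dict[str, int] = {}
                for i in range(L - 5):
                    h = seq[i : i + 6]
                    if hexset is not None and h not in hexset:
                        continue
                    if h not in best or hexmean[i] < hexmean[best[h]]:
                        best[h] = i
                for h, off in best.items():
                    if h not in sums:
                        sums[h] = np.zeros(WINDOW_LEN)
                        supp[h] = np.zeros(WINDOW_LEN, dtype=int)
                        nocc[h] = 0
                    lo = max(0, off - WINDOW_FLANK)
                    hi = min(L, off + 6 + WINDOW_FLANK)
                    j0 = lo - (off - WINDOW_FLANK)
                    sums[h][j0 : j0 + hi - lo] += cov[lo:hi]
                    supp[h][j0 : j0 + hi - lo] += 1
                    nocc[h] += 1
            for h in sorted(sums):
                if nocc[h] < min_occurrences:
                    unscored_rows.append((h, part, label, nocc[h]))
                    continue
                with np.errstate(invalid="ignore"):
                    values = np.where(supp[h] > 0, sums[h] / np.maximum(supp[h], 1), np.nan)
                profile = HexamerProfile(
                    hexamer=h, part=part, label=label,
                    values=values / hmm.c_train, support=supp[h],
                    n_occurrences=nocc[h], c_train=hmm.c_train,
                )
                call = decode_profile(profile, hmm, threshold=threshold, log_base=log_base)
                scored_rows.append(
                    (h, part, label, nocc[h], call.c_fp, call.c_bg,
                     call.score, call.is_footprint)
                )
    scored = pd.DataFrame(
        scored_rows,
        columns=["hexamer", "part", "class", "n_occ", "c_fp", "c_bg", "S",
                 "is_footprint"],
    )
    unscored = pd.DataFrame(
        unscored_rows, columns=["hexamer", "part", "class", "n_occ"]
    )
    return scored, unscored


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------

class FootprintModel:
    """Footprint HMM specified by labelled training profiles.

    ``fit()`` returns a :class:`FootprintResults` wrapping the trained
    :class:`FootprintHmm`, from which profiles can be decoded and full
    hexamer scans run.
    """

    def __init__(self, labeled_profiles):
        self.labeled_profiles = list(labeled_profiles)

    def fit(self, refine: bool = False, max_iter: int = 50, tol: float = 1e-6):
        hmm = train_footprint_hmm(
            self.labeled_profiles, refine=refine, max_iter=max_iter, tol=tol
        )
        return FootprintResults(self, hmm)


class FootprintResults:
    """Trained footprint HMM with decoding and scanning attached."""

    def __init__(self, model: FootprintModel, hmm: FootprintHmm):
        self.model = model
        self.hmm = hmm

    def decode(self, profile: HexamerProfile, **kwargs) -> FootprintCall:
        return decode_profile(profile, self.hmm, **kwargs)

    def scan(self, events, genome, dnase, **kwargs):
        return scan_all_hexamers(events, genome, dnase, self.hmm, **kwargs)

    def summary(self) -> str:
        lines = [
            "Footprint HMM (13 states, Gaussian emissions)",
            f"C_train (background coverage): {self.hmm.c_train:.4f}",
            f"{'state':>6} {'mean':>9} {'std':>9} {'self-loop':>10}",
        ]
        for i, name in enumerate(STATE_NAMES):
            lines.append(
                f"{name:>6} {self.hmm.means[i]:9.4f} "
                f"{np.sqrt(self.hmm.variances[i]):9.4f} "
                f"{self.hmm.transitions[i, i]:10.4f}"
            )
        return "\n".join(lines)
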