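"""Detection and scoring of isoform-switch (IS) events.

An IS event is an isoform pair of one gene whose relative-abundance time
courses cross.  For every pair the algorithm:

1. finds *switch points* — intervals ``(s, s+1)`` where the two courses cross
   in at least a configured fraction of replicates;
2. scores each switch point with a switching probability, the difference of
   relative abundance across the switch, an event importance (abundance of
   the switching pair relative to the gene's most abundant isoform) and a
   dissimilarity coefficient of the two courses;
3. tests significance with a two-sided Mann-Whitney U-test over the samples
   before vs. after the switch point (replicated data) or a time-permutation
   test (single replicate);
4. keeps the best switch point per pair (smallest p-value), corrects the
   best-per-pair p-values for multiple testing, and reports events passing
   all configured thresholds.

Conventions:

* A crossing in replicate ``r`` at interval ``s`` is a strict sign change of
  ``I_a - I_b`` between time points ``s`` and ``s+1``; an exact tie at a time
  point is assigned to the interval ending there.
* Pre/post intervals ``T1``/``T2`` run from the previous qualifying switch
  point (or the series start) to ``s``, and from ``s+1`` to the next
  qualifying switch point (or the series end).
* The pair p-value is the larger of the two per-isoform U-test p-values
  (conservative).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from isoswitch.core_data import RelativeAbundance, TimeCourseMatrix, relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "SwitchPoint",
    "ISEvent",
    "DetectionConfig",
    "find_switch_points",
    "switch_probability",
    "diff_abundance",
    "event_importance",
    "dissimilarity",
    "test_switch_replicated",
    "test_switch_single_replicate",
    "adjust_pvalues",
    "domain_gain_loss",
    "detect_isoform_switches",
    "events_to_frame",
    "write_events",
]


@dataclass
class SwitchPoint:
    """A crossing of two isoform abundance courses between ``s`` and ``s+1``."""

    gene_id: str
    isoform_a: str
    isoform_b: str
    time_index: int  # 0-based interval index: switch between s and s+1
    replicate_support: float


@dataclass
class ISEvent:
    """A fully scored isoform-switch event (one isoform pair of one gene).

    ``isoform_a`` is the pre-switch dominant isoform at the best switch point.
    """

    gene_id: str
    isoform_a: str
    isoform_b: str
    best: SwitchPoint
    all_switch_points: list[SwitchPoint]
    switch_probability: float
    diff_abundance: float
    event_importance: float
    dissimilarity: float
    p_value: float
    adj_p_value: float = float("nan")
    domains_gained: frozenset[str] = frozenset()
    domains_lost: frozenset[str] = frozenset()
    domains_unknown: bool = True


@dataclass
class DetectionConfig:
    """Thresholds and testing parameters for IS detection.

    ``min_dissimilarity`` defaults to 0 (no dissimilarity filter); the
    coefficient is always reported.  ``dissimilarity_mode`` selects between
    ``"r2"`` (1 - r^2) and ``"anticorr"`` ((1 - r)/2, which ranks
    anti-correlated courses as maximally dissimilar).
    """

    min_support: float = 0.6
    min_switch_prob: float = 0.5
    min_diff: float = 0.2
    min_event_importance: float = 0.3
    min_dissimilarity: float = 0.0
    dissimilarity_mode: str = "r2"
    alpha: float = 0.05
    correction: str = "BH"
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_support", "min_switch_prob", "min_dissimilarity", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_diff < 0 or self.min_event_importance < 0:
            raise ValueError("thresholds must be non-negative")
        if self.correction not in ("BH", "holm", "bonferroni"):
            raise ValueError("correction must be one of BH, holm, bonferroni")
        if self.dissimilarity_mode not in ("r2", "anticorr"):
            raise ValueError("dissimilarity_mode must be 'r2' or 'anticorr'")


# ---------------------------------------------------------------------------
# Switch points
# ---------------------------------------------------------------------------

def _crossing_matrix(diff: np.ndarray) -> np.ndarray:
    """Boolean (T-1, R) matrix of crossings of a signed difference course.

    ``diff`` has shape (T, R).  A crossing at interval ``s`` in replicate
    ``r`` is a strict sign change between ``s`` and ``s+1``; an exact zero at
    ``s+1`` after a nonzero value counts as a crossing at ``s`` (tie assigned
    to the earlier interval), and a leading zero followed by a nonzero value
    counts at interval 0.
    """
    sign = np.sign(diff)
    a, b = sign[:-1], sign[1:]
    crossings = (a * b) < 0
    crossings |= (b == 0) & (a != 0)
    if diff.shape[0] >= 2:
        crossings[0] |= (sign[0] == 0) & (sign[1] != 0)
    return crossings


def find_switch_points(
    I: RelativeAbundance,
    gene_id: str,
    isoform_a: str,
    isoform_b: str,
    min_support: float = 0.6,
) -> list[SwitchPoint]:
    """All intervals where the two courses cross in enough replicates.

    For a single replicate any sign change qualifies (support 1.0).
    """
    if I.gene_map.get(isoform_a) != gene_id or I.gene_map.get(isoform_b) != gene_id:
        raise ValueError(f"{isoform_a}/{isoform_b} do not both belong to {gene_id}")
    diff = I.course(isoform_a) - I.course(isoform_b)  # (T, R)
    support = _crossing_matrix(diff).mean(axis=1)
    return [
        SwitchPoint(gene_id, isoform_a, isoform_b, int(s), float(support[s]))
        for s in np.flatnonzero(support >= min_support)
    ]


def _interval_bounds(s: int, qualifying: list[int], T: int) -> tuple[range, range]:
    """T1 and T2 time-point ranges for switch point ``s``.

    T1 runs from just after the previous qualifying switch point (or 0) up to
    and including ``s``; T2 from ``s+1`` to the next qualifying switch point
    (inclusive) or the series end.
    """
    prev = max((q for q in qualifying if q < s), default=-1)
    nxt = min((q for q in qualifying if q > s), default=T - 1)
    return range(prev + 1, s + 1), range(s + 1, nxt + 1)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def switch_probability(
    I_a: np.ndarray, I_b: np.ndarray, T1: range, T2: range
) -> float:
    """Average frequency that ``a`` dominates before and ``b`` after.

    ``I_a``/``I_b`` are (T, R) courses; the isoform labelled ``a`` must be
    the pre-switch dominant one.  Frequencies count all (time, replicate)
    samples within each interval; ties count against the switch.
    """
    if len(T1) == 0 or len(T2) == 0:
        raise ValueError("empty switch interval")
    pre = (I_a[list(T1)] > I_b[list(T1)]).mean()
    post = (I_a[list(T2)] < I_b[list(T2)]).mean()
    return float((pre + post) / 2.0)


def diff_abundance(I_a: np.ndarray, I_b: np.ndarray, s: int) -> float:
    """Average magnitude of the two isoforms' abundance change across ``s``.

    Uses only time points ``s`` and ``s+1``; replicate means are taken per
    isoform before the absolute value.
    """
    da = abs(float(I_a[s + 1].mean() - I_a[s].mean()))
    db = abs(float(I_b[s + 1].mean() - I_b[s].mean()))
    return (da + db) / 2.0


def event_importance(
    I_a: np.ndarray, I_b: np.ndarray, gene_max: np.ndarray, s: int
) -> float:
    """Mean abundance of the switching pair relative to the gene maximum.

    ``gene_max`` is the (T, R) maximum fraction over all isoforms of the
    gene.  Returns NaN (event to be skipped) if the gene has zero total
    abundance at ``s`` or ``s+1`` in any replicate.
    """
    m = gene_max[[s, s + 1]]
    if np.any(m <= 0):
        return float("nan")
    per_rep = (I_a[s] / m[0] + I_a[s + 1] / m[1] + I_b[s] / m[0] + I_b[s + 1] / m[1]) / 4.0
    return float(per_rep.mean())


def dissimilarity(I_a: np.ndarray, I_b: np.ndarray, mode: str = "r2") -> float:
    """Dissimilarity of the replicate-averaged courses.

    ``mode="r2"`` returns ``1 - r**2``; ``mode="anticorr"`` returns
    ``(1 - r)/2``.  Returns NaN when either course has zero variance.
    """
    x, y = I_a.mean(axis=1), I_b.mean(axis=1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if mode == "r2":
        return 1.0 - r * r
    if mode == "anticorr":
        return (1.0 - r) / 2.0
    raise ValueError("mode must be 'r2' or 'anticorr'")


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def test_switch_replicated(
    I_a: np.ndarray, I_b: np.ndarray, T1: range, T2: range
) -> float:
    """Two-sided Mann-Whitney U p-value for the switch at ``s``.

    Each isoform's per-sample abundances within T1 are compared against T2;
    the pair p-value is the larger (more conservative) of the two.  Returns 1
    with a warning when either side has fewer than two samples.
    """
    ps = []
    for course in (I_a, I_b):
        before = course[list(T1)].ravel()
        after = course[list(T2)].ravel()
        if len(before) < 2 or len(after) < 2:
            warnings.warn("too few samples for U-test; p set to 1")
            return 1.0
        if np.ptp(np.concatenate([before, after])) == 0:
            ps.append(1.0)
            continue
        ps.append(float(stats.mannwhitneyu(before, after, alternative="two-sided").pvalue))
    return max(ps)


def _best_crossing_diff(I_a: np.ndarray, I_b: np.ndarray) -> float:
    """Largest diff_abundance over crossing intervals; 0 when none cross."""
    crossings = _crossing_matrix(I_a - I_b).mean(axis=1)
    idx = np.flatnonzero(crossings > 0)
    if len(idx) == 0:
        return 0.0
    return max(diff_abundance(I_a, I_b, int(s)) for s in idx)


def test_switch_single_replicate(
    I_a: np.ndarray,
    I_b: np.ndarray,
    s: int,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    dissimilarity_mode: str = "r2",
) -> float:
    """Time-permutation p-value for single-replicate data.

    Each course's time points are permuted independently; the empirical
    p-value is the add-one-corrected fraction of permutations in which both
    the dissimilarity coefficient and the best-crossing difference of
    relative abundance reach the observed values.
    """
    rng = rng or np.random.default_rng()
    obs_d = dissimilarity(I_a, I_b, dissimilarity_mode)
    obs_diff = diff_abundance(I_a, I_b, s)
    if np.isnan(obs_d):
        return 1.0
    T = I_a.shape[0]
    hits = 0
    eps = 1e-9  # comparison tolerance: degenerate courses give float-dust ties
    for _ in range(n_permutations):
        pa = I_a[rng.permutation(T)]
        pb = I_b[rng.permutation(T)]
        d = dissimilarity(pa, pb, dissimilarity_mode)
        if np.isnan(d) or d < obs_d - eps:
            continue
        if _best_crossing_diff(pa, pb) >= obs_diff - eps:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg, Holm or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p)
    adj = np.empty(m)
    if method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
    elif method == "holm":
        ranked = p[order] * (m - np.arange(m))
        adj[order] = np.minimum(np.maximum.accumulate(ranked), 1.0)
    elif method == "BH":
        ranked = p[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    else:
        raise ValueError("method must be one of BH, holm, bonferroni")
    return adj


def domain_gain_loss(
    old_predominant: str,
    new_predominant: str,
    domain_map: dict[str, frozenset[str]] | None,
) -> tuple[frozenset[str], frozenset[str], bool]:
    """Domains gained/lost by the switch from old to new predominant isoform.

    Returns ``(gained, lost, unknown)``; ``unknown`` is True when either
    isoform is absent from the map (absence means unknown domain content, not
    "no domains").
    """
    if domain_map is None or old_predominant not in domain_map or new_predominant not in domain_map:
        return frozenset(), frozenset(), True
    old, new = domain_map[old_predominant], domain_map[new_predominant]
    return frozenset(new - old), frozenset(old - new), False


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _score_pair(
    I: RelativeAbundance,
    gene_id: str,
    iso_a: str,
    iso_b: str,
    gene_max: np.ndarray,
    cfg: DetectionConfig,
    rng: np.random.Generator,
) -> ISEvent | None:
    points = find_switch_points(I, gene_id, iso_a, iso_b, cfg.min_support)
    if not points:
        return None
    Ia, Ib = I.course(iso_a), I.course(iso_b)
    T = Ia.shape[0]
    qualifying = [p.time_index for p in points]
    single_rep = I.n_replicates == 1

    d = dissimilarity(Ia, Ib, cfg.dissimilarity_mode)
    scored = []
    for p in points:
        s = p.time_index
        T1, T2 = _interval_bounds(s, qualifying, T)
        imp = event_importance(Ia, Ib, gene_max, s)
        if np.isnan(imp):
            warnings.warn(f"{gene_id}: zero gene abundance at switch point {s}; skipped")
            continue
        # orient: 'a' dominates before the switch
        pre_dominant_a = Ia[list(T1)].mean() >= Ib[list(T1)].mean()
        A, B = (Ia, Ib) if pre_dominant_a else (Ib, Ia)
        prob = switch_probability(A, B, T1, T2)
        diff = diff_abundance(Ia, Ib, s)
        if single_rep:
            pval = test_switch_single_replicate(
                Ia, Ib, s, cfg.n_permutations, rng, cfg.dissimilarity_mode
            )
        else:
            pval = test_switch_replicated(Ia, Ib, T1, T2)
        scored.append((pval, diff, s, p, prob, imp, pre_dominant_a))
    if not scored:
        return None
    # best: smallest p, then largest diff, then earliest s
    scored.sort(key=lambda t: (t[0], -t[1], t[2]))
    pval, diff, s, best, prob, imp, pre_dominant_a = scored[0]
    a, b = (iso_a, iso_b) if pre_dominant_a else (iso_b, iso_a)
    return ISEvent(
        gene_id=gene_id,
        isoform_a=a,
        isoform_b=b,
        best=best,
        all_switch_points=points,
        switch_probability=prob,
        diff_abundance=diff,
        event_importance=imp,
        dissimilarity=d,
        p_value=pval,
    )


def detect_isoform_switches(
    m: TimeCourseMatrix,
    cfg: DetectionConfig | None = None,
    domain_map: dict[str, frozenset[str]] | None = None,
) -> list[ISEvent]:
    """Detect, test and filter IS events over all genes and isoform pairs.

    ``m`` is expected to be pre-filtered for low expression.  The
    multiple-testing family is the set of best-per-pair p-values across the
    whole run; reported events satisfy every configured threshold and have an
    adjusted p-value below ``cfg.alpha``.
    """
    cfg = cfg or DetectionConfig()
    rng = np.random.default_rng(cfg.seed)
    I = relative_abundance(m)

    candidates: list[ISEvent] = []
    for gene_id, rows in I.gene_groups().items():
        if len(rows) < 2:
            continue
        if len(rows) > 30:
            logger.warning("gene %s has %d isoforms; enumerating all pairs", gene_id, len(rows))
        block = I.values[rows].reshape(len(rows), I.n_timepoints, -1)
        gene_max = block.max(axis=0)  # (T, R)
        tids = [I.transcript_ids[r] for r in rows]
        for iso_a, iso_b in itertools.combinations(tids, 2):
            ev = _score_pair(I, gene_id, iso_a, iso_b, gene_max, cfg, rng)
            if ev is not None:
                candidates.append(ev)

    if not candidates:
        return []
    adj = adjust_pvalues([ev.p_value for ev in candidates], cfg.correction)
    events: list[ISEvent] = []
    for ev, ap in zip(candidates, adj):
        ev.adj_p_value = float(ap)
        if ap >= cfg.alpha:
            continue
        if ev.switch_probability < cfg.min_switch_prob:
            continue
        if ev.diff_abundance < cfg.min_diff:
            continue
        if ev.event_importance < cfg.min_event_importance:
            continue
        if cfg.min_dissimilarity > 0:
            if np.isnan(ev.dissimilarity) or ev.dissimilarity < cfg.min_dissimilarity:
                continue
        gained, lost, unknown = domain_gain_loss(ev.isoform_a, ev.isoform_b, domain_map)
        ev.domains_gained, ev.domains_lost, ev.domains_unknown = gained, lost, unknown
        events.append(ev)
    return events


def events_to_frame(
    events: list[ISEvent], time_points: list[str] | None = None
) -> pd.DataFrame:
    """Tabular form of a list of events (one row per event)."""
    rows = []
    for ev in events:
        s = ev.best.time_index
        rows.append(
            {
                "gene_id": ev.gene_id,
                "isoform_a": ev.isoform_a,
                "isoform_b": ev.isoform_b,
                "switch_point": time_points[s] if time_points else s,
                "switch_interval_index": s,
                "replicate_support": ev.best.replicate_support,
                "secondary_switch_points": ";".join(
                    str(p.time_index) for p in ev.all_switch_points if p.time_index != s
                ),
                "switch_probability": ev.switch_probability,
                "diff_abundance": ev.diff_abundance,
                "event_importance": ev.event_importance,
                "dissimilarity": ev.dissimilarity,
                "p_value": ev.p_value,
                "adj_p_value": ev.adj_p_value,
                "domains_gained": ";".join(sorted(ev.domains_gained)),
                "domains_lost": ";".join(sorted(ev.domains_lost)),
                "domains_unknown": ev.domains_unknown,
            }
        )
    cols = [
        "gene_id", "isoform_a", "isoform_b", "switch_point", "switch_interval_index",
        "replicate_support", "secondary_switch_points", "switch_probability",
        "diff_abundance", "event_importance", "dissimilarity", "p_value",
        "adj_p_value", "domains_gained", "domains_lost", "domains_unknown",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events(events: list[ISEvent], path, time_points: list[str] | None = None) -> None:
    events_to_frame(events, time_points).to_csv(path, sep="\t", index=False, float_format="%.6g")
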