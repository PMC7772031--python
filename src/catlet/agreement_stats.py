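"""Agreement and reclassification statistics for score validation.

Weighted Cohen's kappa quantifies inter/intra-observer agreement on ordered
score categories: kappa = (p_o − p_e) / (1 − p_e), equivalently
1 − D_o / D_e with disagreement weights d_ij (zero/one, linear |i−j|/(k−1),
or quadratic).  Kappa values are labelled on the conventional scale —
slight 0.0∼0.2, fair 0.2∼0.4, moderate 0.4∼0.6, substantial 0.6∼0.8,
almost perfect 0.8∼1.0 — with touching boundaries assigned to the upper
band and negative values labelled "poor (below chance)".

Category-free (continuous) net reclassification improvement compares an old
and a new score against a binary outcome:

    NRI = [P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)]

with ties counted as no movement, z from the standard large-sample variance
and a two-sided normal p-value.  A tier reclassification table counts
outcome-concordant tier moves (up for events, down for nonevents).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "KAPPA_SCHEMES",
    "AgreementResult",
    "ReclassificationResult",
    "ReclassificationTable",
    "weighted_kappa",
    "kappa_label",
    "category_free_nri",
    "reclassification_table",
]

KAPPA_SCHEMES = ("none", "linear", "quadratic")


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    scheme: str
    label: str
    n: int
    ci: Optional[tuple] = None       # (low, high) bootstrap percentile CI
    ci_level: Optional[float] = None
    warnings: tuple = ()

    def __str__(self) -> str:
        text = f"kappa = {self.kappa:.3f} ({self.scheme} weights): {self.label}"
        if self.ci is not None:
            text += f"; {self.ci_level:.0%} CI [{self.ci[0]:.3f}, {self.ci[1]:.3f}]"
        return text


def _disagreement_weights(k: int, scheme: str) -> np.ndarray:
    idx = np.arange(k, dtype=float)
    diff = np.abs(idx[:, None] - idx[None, :])
    if scheme == "none":
        return (diff > 0).astype(float)
    if k == 1:
        return np.zeros((1, 1))
    if scheme == "linear":
        return diff / (k - 1)
    if scheme == "quadratic":
        return (diff / (k - 1)) ** 2
    raise ValueError(f"unknown weighting scheme {scheme!r}; "
                     f"expected one of {list(KAPPA_SCHEMES)}")


def _encode(a, b, categories):
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError(f"rating sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) < 2:
        raise ValueError("need at least 2 paired ratings")
    if categories is None:
        categories = sorted(set(a) | set(b))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    try:
        ia = np.array([index[x] for x in a])
        ib = np.array([index[x] for x in b])
    except KeyError as exc:
        raise ValueError(f"rating {exc.args[0]!r} not in category set "
                         f"{categories}") from None
    return ia, ib, categories


def _kappa_value(ia: np.ndarray, ib: np.ndarray, k: int, scheme: str):
    """Kappa from index-encoded ratings; returns (kappa, degenerate_flag)."""
    n = len(ia)
    observed = np.zeros((k, k))
    np.add.at(observed, (ia, ib), 1.0)
    observed /= n
    expected = observed.sum(axis=1)[:, None] * observed.sum(axis=0)[None, :]
    d = _disagreement_weights(k, scheme)
    d_obs = float((observed * d).sum())
    d_exp = float((expected * d).sum())
    if d_exp == 0.0:
        # both raters constant and equal (p_e = 1): defined as perfect agreement
        return 1.0, True
    return 1.0 - d_obs / d_exp, False


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    scheme: str = "linear",
    *,
    categories: Optional[Sequence] = None,
    bootstrap: int = 0,
    ci_level: float = 0.95,
    rng=None,
) -> AgreementResult:
    """Weighted Cohen's kappa between two raters over a shared ordered
    category set.

    ``categories`` fixes the ordered set (default: sorted union of observed
    values).  ``scheme`` "none" reduces to unweighted Cohen's kappa.  With
    ``bootstrap`` > 0 a seeded percentile CI over resampled pairs is
    attached.  The degenerate case p_e = 1 (both raters constant and equal)
    is defined as kappa = 1 with a warning.
    """
    ia, ib, cats = _encode(ratings_a, ratings_b, categories)
    k = len(cats)
    kappa, degenerate = _kappa_value(ia, ib, k, scheme)
    warnings = ()
    if degenerate:
        warnings = ("both raters are constant and identical (p_e = 1); "
                    "kappa defined as 1.0",)
    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(rng)
        n = len(ia)
        reps = np.empty(bootstrap)
        for r in range(bootstrap):
            pick = rng.integers(0, n, size=n)
            reps[r], _ = _kappa_value(ia[pick], ib[pick], k, scheme)
        alpha = 1.0 - ci_level
        ci = (float(np.quantile(reps, alpha / 2)),
              float(np.quantile(reps, 1 - alpha / 2)))
    return AgreementResult(
        kappa=float(kappa),
        scheme=scheme,
        label=kappa_label(kappa),
        n=len(ia),
        ci=ci,
        ci_level=ci_level if ci is not None else None,
        warnings=warnings,
    )


_LABEL_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
)


def kappa_label(kappa: float) -> str:
    """Agreement label for a kappa value.

    Bands: slight 0.0∼0.2, fair 0.2∼0.4, moderate 0.4∼0.6, substantial
    0.6∼0.8, almost perfect 0.8∼1.0.  A value sitting exactly on a shared
    boundary is assigned to the upper band (0.2 -> "fair"); values below 0
    are "poor (below chance)".
    """
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0:
        return "poor (below chance)"
    for upper, label in _LABEL_BANDS:
        if kappa < upper:
            return label
    return "almost perfect"


# --------------------------------------------------------------------------
# Category-free NRI and tier reclassification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReclassificationResult:
    """Continuous NRI with its movement counts and large-sample z / p."""

    nri: float
    z: float
    p_value: float
    up_event: int
    down_event: int
    up_nonevent: int
    down_nonevent: int
    n_event: int
    n_nonevent: int

    @property
    def nri_percent(self) -> float:
        return 100.0 * self.nri

    def __str__(self) -> str:
        return (f"category-free NRI = {self.nri_percent:.1f}% "
                f"(z = {self.z:.2f}, P = {self.p_value:.3g})")


def category_free_nri(
    old_scores: Sequence[float],
    new_scores: Sequence[float],
    outcomes: Sequence[int],
) -> ReclassificationResult:
    """Category-free (continuous) net reclassification improvement.

    Convention: a higher score means higher predicted risk, so an upward
    score move is concordant for events and discordant for nonevents.  Ties
    (new == old) count as no movement.  z uses the standard large-sample
    variance of the two group-wise net proportions; p is two-sided normal.
    """
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    y = np.asarray(outcomes)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old_scores, new_scores, outcomes must have equal length")
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("outcomes must be binary (0/1)")
    events = y == 1
    n_event = int(events.sum())
    n_nonevent = int((~events).sum())
    if n_event == 0:
        raise ValueError("no events in the cohort; NRI event component undefined")
    if n_nonevent == 0:
        raise ValueError("no nonevents in the cohort; NRI nonevent component undefined")

    up = new > old
    down = new < old
    up_e = int(np.sum(up & events))
    down_e = int(np.sum(down & events))
    up_ne = int(np.sum(up & ~events))
    down_ne = int(np.sum(down & ~events))

    net_e = (up_e - down_e) / n_event
    net_ne = (down_ne - up_ne) / n_nonevent
    nri = net_e + net_ne

    var_e = ((up_e + down_e) / n_event - net_e ** 2) / n_event
    var_ne = ((up_ne + down_ne) / n_nonevent - net_ne ** 2) / n_nonevent
    var = var_e + var_ne
    if var > 0:
        z = nri / math.sqrt(var)
    elif nri == 0:
        z = 0.0
    else:
        z = math.copysign(math.inf, nri)
    p = float(2.0 * _scipy_stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return ReclassificationResult(
        nri=float(nri), z=float(z), p_value=p,
        up_event=up_e, down_event=down_e,
        up_nonevent=up_ne, down_nonevent=down_ne,
        n_event=n_event, n_nonevent=n_nonevent,
    )


@dataclass(frozen=True)
class ReclassificationTable:
    """Per-outcome-group tier cross-tables and correct-reclassification rates."""

    tiers: tuple
    events_table: np.ndarray       # rows: old tier, cols: new tier
    nonevents_table: np.ndarray
    pct_correct_events: float      # % of events moved to a higher tier
    pct_correct_nonevents: float   # % of nonevents moved to a lower tier


def reclassification_table(
    old_tiers: Sequence[str],
    new_tiers: Sequence[str],
    outcomes: Sequence[int],
    tiers: Sequence[str] = ("low", "intermediate", "high"),
) -> ReclassificationTable:
    """Tier cross-tables per outcome group with correct-reclassification %.

    "Correctly reclassified" means moved toward the tier concordant with the
    outcome: up for events, down for nonevents; percentages are of each
    group's n.
    """
    tiers = tuple(tiers)
    index = {t: i for i, t in enumerate(tiers)}
    old = list(old_tiers)
    new = list(new_tiers)
    y = np.asarray(outcomes)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old_tiers, new_tiers, outcomes must have equal length")
    for label in (*old, *new):
        if label not in index:
            raise ValueError(f"unknown tier label {label!r}; expected one of "
                             f"{list(tiers)}")
    k = len(tiers)
    tables = {0: np.zeros((k, k), dtype=int), 1: np.zeros((k, k), dtype=int)}
    for o, nw, out in zip(old, new, y):
        tables[int(out)][index[o], index[nw]] += 1

    def _pct(table: np.ndarray, direction: str) -> float:
        n = int(table.sum())
        if n == 0:
            return 0.0
        moved = 0
        for i in range(k):
            for j in range(k):
                if (direction == "up" and j > i) or (direction == "down" and j < i):
                    moved += int(table[i, j])
        return 100.0 * moved / n

    return ReclassificationTable(
        tiers=tiers,
        events_table=tables[1],
        nonevents_table=tables[0],
        pct_correct_events=_pct(tables[1], "up"),
        pct_correct_nonevents=_pct(tables[0], "down"),
    )
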