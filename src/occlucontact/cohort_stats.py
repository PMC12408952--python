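"""Cohort statistics: outlier exclusion, correlation profile, group tests.

The analysis mirrors the study design: per-group descriptives of X50 and
of all 18 OCA evaluation strategies; one-pass exclusion of subjects whose
X50 deviates more than 2 group SDs from the group mean (applied to the
correlation analysis only); a Pearson correlation of X50 against every
(offset, projection) strategy; identification of the strategy with the
strongest correlation in the expected direction (negative — a lower X50
means better masticatory performance); and a Mann–Whitney U comparison of
X50 between the normal-occlusion and malocclusion groups, exact by full
enumeration for small samples.

No multiple-testing correction is applied across the 18 strategies in the
headline profile; a Bonferroni-adjusted column is emitted alongside for
transparency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("normal_occlusion", "malocclusion")
STRONG_R_THRESHOLD = 0.7
SIGNIFICANCE_LEVEL = 0.05
EXACT_ENUMERATION_MAX_N = 12


class CohortContentError(ValueError):
    """Not enough records (or strategies) for the requested statistic."""


StrategyKey = tuple  # (offset_um: float, projection: "2d" | "3d")


@dataclass
class SubjectRecord:
    """One subject: group label, X50 (mm) and the OCA strategy map (mm^2)."""

    subject_id: str
    group: str
    x50: float
    oca: dict  # StrategyKey -> area in mm^2

    def __post_init__(self) -> None:
        if self.x50 <= 0:
            raise ValueError(f"{self.subject_id}: x50 must be positive")
        if any(v < 0 for v in self.oca.values()):
            raise ValueError(f"{self.subject_id}: OCA areas must be >= 0")


def strategy_column(key: StrategyKey) -> str:
    t, proj = key
    return f"oca_{t:g}um_{proj}_mm2"


def column_strategy(col: str) -> StrategyKey:
    body = col.removeprefix("oca_").removesuffix("_mm2")
    t, proj = body.rsplit("_", 1)
    return (float(t.removesuffix("um")), proj)


def records_to_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject": r.subject_id, "group": r.group, "x50_mm": r.x50}
        for key, v in sorted(r.oca.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            row[strategy_column(key)] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list:
    required = {"subject", "group", "x50_mm"}
    missing = required - set(df.columns)
    if missing:
        raise CohortContentError(f"cohort table missing columns: {sorted(missing)}")
    strat_cols = [c for c in df.columns if c.startswith("oca_")]
    if not strat_cols:
        raise CohortContentError("cohort table has no oca_* strategy columns")
    records = []
    for _, row in df.iterrows():
        oca = {column_strategy(c): float(row[c]) for c in strat_cols}
        records.append(SubjectRecord(subject_id=str(row["subject"]),
                                     group=str(row["group"]),
                                     x50=float(row["x50_mm"]), oca=oca))
    return records


def _common_strategies(records: list) -> list:
    keys = set(records[0].oca)
    for r in records[1:]:
        if set(r.oca) != keys:
            raise CohortContentError(
                f"subject {r.subject_id} has a different strategy set")
    return sorted(keys, key=lambda k: (k[0], k[1]))


# ---------------------------------------------------------------------------
# outlier exclusion


def exclude_outliers(records: list, variable: str = "x50",
                     k_sd: float = 2.0) -> tuple[list, list]:
    """One pass per group: drop records with |x - mean| > k_sd * sample SD.

    The candidate is included in the mean/SD it is tested against, and the
    rule is not re-applied after removal (recursive trimming is unstable).
    Returns (kept records, excluded subject ids).
    """
    kept, excluded = [], []
    for group in sorted({r.group for r in records}):
        grp = [r for r in records if r.group == group]
        vals = np.array([getattr(r, variable) for r in grp])
        if len(grp) < 3 or not math.isfinite(k_sd):
            kept.extend(grp)
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            if np.ptp(vals) > 0:
                log.warning("group %s: zero SD with distinct values", group)
            kept.extend(grp)
            continue
        dev = np.abs(vals - vals.mean())
        for r, d in zip(grp, dev):
            if d > k_sd * sd:
                excluded.append(r.subject_id)
            else:
                kept.append(r)
    return kept, excluded


# ---------------------------------------------------------------------------
# correlation profile


@dataclass
class CorrelationEntry:
    r: float
    p: float
    n: int
    defined: bool = True


@dataclass
class CorrelationProfile:
    """Pearson r and two-sided p of X50 vs. every OCA strategy."""

    entries: dict  # StrategyKey -> CorrelationEntry
    group: str = "all"

    def defined_items(self) -> list:
        return [(k, e) for k, e in self.entries.items() if e.defined]

    def to_frame(self) -> pd.DataFrame:
        m = len(self.entries)
        rows = []
        for key in sorted(self.entries, key=lambda k: (k[0], k[1])):
            e = self.entries[key]
            rows.append({
                "group": self.group,
                "offset_um": key[0],
                "projection": key[1].upper(),
                "r": e.r, "p": e.p, "n": e.n,
                "p_bonferroni": min(e.p * m, 1.0) if e.defined else float("nan"),
                "strong": bool(e.defined and abs(e.r) > STRONG_R_THRESHOLD),
                "significant": bool(e.defined and e.p < SIGNIFICANCE_LEVEL),
            })
        return pd.DataFrame(rows)


def pearson_profile(records: list, group: str = "all") -> CorrelationProfile:
    """Correlate X50 with each strategy across subjects.

    Strategies with zero variance are reported as undefined (NaN), never
    as r = 0.
    """
    if len(records) < 3:
        raise CohortContentError("need at least 3 records for correlation")
    keys = _common_strategies(records)
    x = np.array([r.x50 for r in records])
    entries = {}
    for key in keys:
        y = np.array([r.oca[key] for r in records])
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            log.warning("strategy %s: zero variance, correlation undefined", key)
            entries[key] = CorrelationEntry(float("nan"), float("nan"),
                                            len(x), defined=False)
            continue
        res = stats.pearsonr(x, y)
        entries[key] = CorrelationEntry(float(res.statistic),
                                        float(res.pvalue), len(x))
    return CorrelationProfile(entries=entries, group=group)


def best_strategy(profile: CorrelationProfile,
                  expected_sign: str = "negative") -> tuple[StrategyKey, float]:
    """Strategy with the strongest correlation in the expected direction.

    Default direction is negative (lower X50 = better performance, so more
    contact area should mean lower X50). Exact ties break toward the
    smaller offset, then 3D before 2D. If no entry has the expected sign,
    the extreme in that direction is still returned with a warning.
    """
    items = profile.defined_items()
    if not items:
        raise CohortContentError("no defined correlation entries")

    def order(item):
        key, e = item
        tie = (key[0], 0 if key[1] == "3d" else 1)
        if expected_sign == "negative":
            return (e.r, *tie)
        if expected_sign == "positive":
            return (-e.r, *tie)
        if expected_sign == "either":
            return (-abs(e.r), *tie)
        raise ValueError(f"unknown expected_sign {expected_sign!r}")

    key, e = min(items, key=order)
    if expected_sign == "negative" and e.r > 0:
        log.warning("no negative correlations; returning least positive")
    if expected_sign == "positive" and e.r < 0:
        log.warning("no positive correlations; returning least negative")
    return key, e.r


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class GroupComparison:
    u_stat: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    descriptives: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {"U": self.u_stat, "p": self.p_value, "method": self.method,
                "n_a": self.n_a, "n_b": self.n_b}


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann–Whitney U with midranks for ties.

    ``exact`` enumerates all C(n_a+n_b, n_a) group assignments of the
    pooled sample (correct under ties); ``normal_approx`` uses the
    tie-corrected normal approximation with continuity correction; ``auto``
    enumerates when n_a + n_b <= 12.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise CohortContentError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_ENUMERATION_MAX_N else "normal_approx"

    mu = n1 * n2 / 2.0
    if mode == "exact":
        dev = abs(u1 - mu)
        count = total = 0
        rank_sum_base = n1 * (n1 + 1) / 2.0
        for comb in combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - rank_sum_base
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        p = count / total
    elif mode == "normal_approx":
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                    if n > 1 else 0.0)
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(u_stat=u1, p_value=float(p), method=mode,
                           n_a=n1, n_b=n2)


# ---------------------------------------------------------------------------
# descriptives


def _describe(vals: np.ndarray) -> dict:
    """Mean/SD/median/quartiles/range; quartiles by linear interpolation."""
    v = np.asarray(vals, dtype=float)
    sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return {
        "n": len(v),
        "mean": float(v.mean()),
        "sd": sd,
        "median": float(np.median(v)),
        "q1": float(np.quantile(v, 0.25)),
        "q3": float(np.quantile(v, 0.75)),
        "min": float(v.min()),
        "max": float(v.max()),
        "median_range": f"{np.median(v):.2f} ({v.min():.2f}-{v.max():.2f})",
    }


def summarize_groups(records: list) -> GroupComparison:
    """Per-group descriptive table plus the X50 Mann–Whitney comparison.

    The descriptive table covers X50 and every OCA strategy; the group
    comparison of X50 uses all records (outlier exclusion applies to the
    correlation analysis only).
    """
    if not records:
        raise CohortContentError("no records")
    groups = sorted({r.group for r in records})
    keys = _common_strategies(records)
    rows = []
    for group in groups:
        grp = [r for r in records if r.group == group]
        variables = [("x50_mm", [r.x50 for r in grp])]
        variables += [(strategy_column(k), [r.oca[k] for r in grp]) for k in keys]
        for varname, vals in variables:
            row = {"group": group, "variable": varname}
            row.update(_describe(np.asarray(vals)))
            rows.append(row)
    table = pd.DataFrame(rows)

    if len(groups) == 2:
        a = [r.x50 for r in records if r.group == groups[0]]
        b = [r.x50 for r in records if r.group == groups[1]]
        comp = mann_whitney_u(a, b, mode="auto")
    else:
        comp = GroupComparison(u_stat=float("nan"), p_value=float("nan"),
                               method="none", n_a=len(records), n_b=0)
    comp.descriptives = table
    return comp
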