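"""Longitudinal cohort assembly and group statistics.

Each subject contributes three timepoints (T1 before surgery, T2 ~1 week
after, T3 ~6 weeks after, gestational age in decimal weeks).  Every measured
parameter is converted to paired weekly rates over three windows:

* immediate  = (x(T2) − x(T1)) / (ga2 − ga1)
* long-term  = (x(T3) − x(T2)) / (ga3 − ga2)
* global     = (x(T3) − x(T1)) / (ga3 − ga1)   (default definition; a
  "difference of the two period rates" variant is available)

Group comparisons report per-group medians and IQRs and use the
Kruskal–Wallis H-test after an Anderson–Darling normality gate, with Dunn's
pairwise post-hoc tests corrected for multiple comparisons (Holm by
default).  The nonparametric route is the only one implemented: the
reported cohort statistics are all nonparametric.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .curvature import CurvatureField
from .surface_io import SurfaceMesh
from .spectral import similarity_align
from .synthetic import LOBE_NAMES

log = logging.getLogger(__name__)

ALPHA = 0.05


def decimal_weeks(weeks: int, days: int) -> float:
    """Gestational age 'weeks + days' -> decimal weeks (23 + 3 -> 23.4286)."""
    if days < 0 or days > 6:
        raise ValueError("days must be in 0..6")
    return weeks + days / 7.0


# ---------------------------------------------------------------------------
# Period rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodRates:
    immediate: float
    longterm: float
    global_: float


def period_rates(
    x1: float, x2: float, x3: float,
    ga: tuple[float, float, float],
    global_definition: str = "t1_t3",
) -> PeriodRates:
    """Weekly rates of change over the immediate, long-term and global windows.

    ``global_definition='t1_t3'`` is the overall T1→T3 rate;
    ``'difference'`` is the long-term minus immediate rate.
    """
    ga1, ga2, ga3 = ga
    if not (ga1 < ga2 < ga3):
        raise ValueError(f"gestational ages must be strictly increasing, got {ga}")
    imm = (x2 - x1) / (ga2 - ga1)
    lt = (x3 - x2) / (ga3 - ga2)
    if global_definition == "t1_t3":
        glob = (x3 - x1) / (ga3 - ga1)
    elif global_definition == "difference":
        glob = lt - imm
    else:
        raise ValueError(f"unknown global_definition {global_definition!r}")
    return PeriodRates(immediate=imm, longterm=lt, global_=glob)


# ---------------------------------------------------------------------------
# Ventriculomegaly severity
# ---------------------------------------------------------------------------

def classify_ventriculomegaly(atrial_diameter_mm: float) -> str:
    """Severity from the atrial diameter: none <10, mild 10–12, moderate
    13–15, severe >15 mm (rounded half-up to integer millimetres first,
    matching the integer banding of the clinical classes)."""
    if atrial_diameter_mm < 0:
        raise ValueError("atrial diameter cannot be negative")
    d = math.floor(atrial_diameter_mm + 0.5)
    if d < 10:
        return "none"
    if d <= 12:
        return "mild"
    if d <= 15:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# Lobe parcellation
# ---------------------------------------------------------------------------

@dataclass
class LobeParcellation:
    """Per-vertex label indices into LOBE_NAMES (4 lobes x 2 hemispheres)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= len(LOBE_NAMES):
            raise ValueError("lobe labels out of range")

    def region_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i).sum()) for i, name in enumerate(LOBE_NAMES)
        }


def parcellate_lobes(mesh: SurfaceMesh, atlas: SurfaceMesh) -> LobeParcellation:
    """Transfer the atlas's 8 lobe labels to a subject surface.

    Similarity-transform (Procrustes) alignment of the atlas onto the
    subject, then nearest-neighbour label transfer.  With equal vertex
    counts (shared parameterisation) the index pairing seeds the alignment.
    """
    if atlas.lobe_labels is None:
        raise ValueError("atlas carries no lobe labels")
    present = np.unique(atlas.lobe_labels)
    if len(present) < len(LOBE_NAMES):
        raise ValueError("atlas is missing lobe labels")
    atlas_aligned = similarity_align(atlas.vertices, mesh.vertices)
    _, nn = cKDTree(atlas_aligned).query(mesh.vertices)
    return LobeParcellation(labels=np.asarray(atlas.lobe_labels)[nn])


def subject_curvature_summary(
    field_values: np.ndarray | CurvatureField,
    parcellation: LobeParcellation,
    statistic: str = "median",
) -> dict[str, dict]:
    """Per-region and whole-surface summaries of a per-vertex field.

    ``field_values`` may be a raw per-vertex array or a CurvatureField (its
    curvedness is summarised).  Values are summarised signed, by the median
    (``statistic='mean'`` optional).  Empty regions are reported with value
    ``None``.
    """
    if isinstance(field_values, CurvatureField):
        field_values = field_values.curvedness
    values = np.asarray(field_values, dtype=float)
    if len(values) != len(parcellation.labels):
        raise ValueError("field length does not match parcellation")
    reduce = np.median if statistic == "median" else np.mean
    out: dict[str, dict] = {
        "whole": {"value": float(reduce(values)), "n_vertices": len(values)}
    }
    for i, name in enumerate(LOBE_NAMES):
        sel = parcellation.labels == i
        n = int(sel.sum())
        if n == 0:
            log.warning("region %s is empty; summary absent", name)
            out[name] = {"value": None, "n_vertices": 0}
        else:
            out[name] = {"value": float(reduce(values[sel])), "n_vertices": n}
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AndersonDarlingResult:
    statistic: float
    critical_value: float
    reject_normality: bool
    degenerate: bool = False


def anderson_darling_normal(sample, alpha: float = ALPHA) -> AndersonDarlingResult:
    """Anderson–Darling test of normality with estimated mean/variance.

    Degenerate (constant) samples are flagged and treated as non-normal.
    Requires n >= 8 for the case-adjusted critical values to be meaningful.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise ValueError(f"need at least 8 observations, got {len(x)}")
    if np.ptp(x) == 0:
        return AndersonDarlingResult(
            statistic=np.inf, critical_value=np.nan,
            reject_normality=True, degenerate=True,
        )
    import warnings

    with warnings.catch_warnings():
        # stay on the classical critical-value API (scipy >= 1.17 warns in
        # favour of interpolated p-values; the decision rule is the same)
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    idx = int(np.argmin(np.abs(res.significance_level - 100 * alpha)))
    crit = float(res.critical_values[idx])
    return AndersonDarlingResult(
        statistic=float(res.statistic),
        critical_value=crit,
        reject_normality=bool(res.statistic > crit),
    )


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value.

    All-identical data across groups make H undefined (0/0); that case is
    returned as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("each group needs at least one observation")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    samples: dict[str, np.ndarray], correction: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after a Kruskal–Wallis omnibus.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)), with the
    tie correction T = Σ(t³−t)/(12(N−1)); two-sided normal p-values adjusted
    by the requested method (holm, bonferroni or fdr_bh).
    """
    names = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for k, a in zip(names, arrays):
        mean_ranks[k] = ranks[start:start + len(a)].mean()
        sizes[k] = len(a)
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        _, adj, _, _ = multipletests(df["p_raw"], method=correction)
        df["p_adjusted"] = np.maximum(adj, df["p_raw"])
    return df


@dataclass
class GroupComparison:
    parameter: str
    period: str
    groups: list[str]
    medians: dict[str, float]
    iqrs: dict[str, tuple[float, float]]
    n: dict[str, int]
    h_statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    significant: bool
    nonnormal: bool
    posthoc: pd.DataFrame | None = None
    skipped_reason: str | None = None


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def compare_groups(
    table: pd.DataFrame,
    grouping: str = "group",
    parameter: str = "parameter",
    period: str = "period",
    value: str = "rate",
    correction: str = "holm",
    alpha: float = ALPHA,
) -> list[GroupComparison]:
    """Kruskal–Wallis group comparisons of weekly rates, one per
    (parameter, period) cell of a tidy table.

    Empty grouping levels are dropped with a warning; cells where any group
    has a single subject report medians but skip the test.
    """
    results = []
    for (param, per), sub in table.groupby([parameter, period], sort=True):
        samples: dict[str, np.ndarray] = {}
        for gname, g in sub.groupby(grouping, sort=True):
            vals = np.asarray(g[value].dropna(), dtype=float)
            if len(vals) == 0:
                log.warning("empty group %r for %s/%s dropped", gname, param, per)
                continue
            samples[str(gname)] = vals
        if len(samples) < 2:
            continue
        med = {}
        iqr = {}
        ns = {}
        for k, v in samples.items():
            med[k], iqr[k] = _median_iqr(v)
            ns[k] = len(v)
        if min(ns.values()) < 2:
            log.warning(
                "%s/%s: a group has a single subject; test skipped", param, per
            )
            results.append(GroupComparison(
                parameter=param, period=per, groups=list(samples), medians=med,
                iqrs=iqr, n=ns, h_statistic=None, p_raw=None, p_adjusted=None,
                significant=False, nonnormal=True,
                skipped_reason="group with n < 2",
            ))
            continue
        nonnormal = any(
            len(v) >= 8 and anderson_darling_normal(v).reject_normality
            for v in samples.values()
        )
        h, p = kruskal_wallis(*samples.values())
        posthoc = None
        p_adj = p
        if len(samples) > 2 and p < alpha:
            posthoc = dunn_posthoc(samples, correction=correction)
        elif len(samples) == 2:
            p_adj = p  # omnibus on two groups is the pairwise test itself
        results.append(GroupComparison(
            parameter=param, period=per, groups=list(samples), medians=med,
            iqrs=iqr, n=ns, h_statistic=h, p_raw=p, p_adjusted=p_adj,
            significant=bool(p_adj < alpha), nonnormal=nonnormal,
            posthoc=posthoc,
        ))
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison objects into a tidy results table."""
    rows = []
    for r in results:
        row = {
            "parameter": r.parameter,
            "period": r.period,
            "H": r.h_statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "nonnormal_gate": r.nonnormal,
            "skipped_reason": r.skipped_reason,
        }
        for g in r.groups:
            row[f"median_{g}"] = r.medians[g]
            row[f"iqr_lo_{g}"] = r.iqrs[g][0]
            row[f"iqr_hi_{g}"] = r.iqrs[g][1]
            row[f"n_{g}"] = r.n[g]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tidy rate tables
# ---------------------------------------------------------------------------

def rates_table(
    measures: pd.DataFrame,
    global_definition: str = "t1_t3",
) -> pd.DataFrame:
    """Per-subject weekly rates from a tidy per-timepoint measures table.

    ``measures`` columns: subject_id, group, timepoint (1..3), ga_weeks,
    parameter, value.  Subjects missing any timepoint for a parameter are
    excluded with a logged reason.
    """
    rows = []
    for (sid, group, param), sub in measures.groupby(
        ["subject_id", "group", "parameter"], sort=True
    ):
        sub = sub.sort_values("timepoint")
        if list(sub["timepoint"]) != [1, 2, 3]:
            log.warning("%s/%s: incomplete timepoints; excluded", sid, param)
            continue
        ga = tuple(sub["ga_weeks"].to_numpy())
        x1, x2, x3 = sub["value"].to_numpy()
        pr = period_rates(x1, x2, x3, ga, global_definition)
        for period, rate in (
            ("immediate", pr.immediate),
            ("longterm", pr.longterm),
            ("global", pr.global_),
        ):
            rows.append({
                "subject_id": sid, "group": group, "parameter": param,
                "period": period, "rate": rate,
            })
    return pd.DataFrame(rows)
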