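"""Cohort statistics for biofilm pH before and after a sugar rinse.

The clinical readout per tooth surface is the triplet-averaged biofilm pH at
rest (``rest``), one minute after a sucrose rinse (``drop``), and their
difference ``diff = rest - drop`` (positive when the biofilm acidified, the
initial downslope of the Stephan curve).  Surfaces belong to subjects grouped
by recent professional-cleaning history (``pre_cleaning`` = no cleaning for
over three months and hence heavier biofilm, ``post_cleaning`` = recently
cleaned, plus an optional caries-free ``control``), and each surface carries
a binary caries rank (0 sound, 1 carious).  Saliva pH measured per subject
with a conventional meter provides an optional normalisation
(``biofilm pH / saliva pH``).

Group comparisons use Welch's t-test where both groups pass a Shapiro-Wilk
normality check, and a two-sided permutation test on the absolute difference
of group means always (exhaustive enumeration when the label-assignment
count is small, seeded random shuffles otherwise).

Because the underlying patient data are not public, :func:`synth_cohort`
generates synthetic cohorts whose defaults reproduce the study's published
summary statistics: group sizes 40/45 surfaces over 7/18 subjects, rest pH
near 6.7, group mean diff pH 0.84 (pre) vs 0.48 (post), replicate noise at
the instrument's 0.23 pooled SD, readings clipped to the trusted 4-7.5
range.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import aggregate_replicates

__all__ = [
    "GroupParams",
    "CohortParams",
    "SynthCohort",
    "ComparisonResult",
    "diff_ph",
    "normalize_by_saliva",
    "welch_t_test",
    "permutation_test",
    "EXHAUSTIVE_LIMIT",
    "synth_cohort",
    "aggregate_readings",
    "analyze_cohort",
]

logger = logging.getLogger(__name__)

#: Exhaustive enumeration is used when C(n_a + n_b, n_a) is at most this.
EXHAUSTIVE_LIMIT = 20_000


# ---------------------------------------------------------------------------
# elementary metrics


def diff_ph(rest: float | None, drop: float | None) -> float:
    """``rest - drop``; positive when acidification occurred.  NaN if either is missing."""
    if rest is None or drop is None:
        return float("nan")
    rest = float(rest)
    drop = float(drop)
    if math.isnan(rest) or math.isnan(drop):
        return float("nan")
    return rest - drop


def normalize_by_saliva(ph: float, saliva_ph: float) -> float:
    """Biofilm pH divided by the subject's saliva pH (a unitless ratio near 1)."""
    if saliva_ph is None or (isinstance(saliva_ph, float) and math.isnan(saliva_ph)):
        return float("nan")
    if saliva_ph <= 0:
        raise ValueError("saliva_ph must be > 0")
    if ph is None or (isinstance(ph, float) and math.isnan(ph)):
        return float("nan")
    return float(ph) / float(saliva_ph)


# ---------------------------------------------------------------------------
# two-sample tests


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _mean_diff_stat(a: np.ndarray, b: np.ndarray) -> float:
    return abs(float(a.mean()) - float(b.mean()))


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    method: str = "auto",
) -> float:
    """Two-sided permutation test on group labels.

    The default statistic is the absolute difference of group means.  When
    the number of distinct label assignments ``C(n_a + n_b, n_a)`` is at most
    :data:`EXHAUSTIVE_LIMIT` every assignment is enumerated and the exact
    proportion with a statistic at least as extreme as observed is returned.
    Otherwise ``n_perm`` seeded random shuffles are drawn and the p-value is
    ``(count + 1) / (n_perm + 1)`` (never exactly zero).  ``method`` forces
    ``"exhaustive"`` or ``"sampled"`` instead of the ``"auto"`` choice.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("auto", "exhaustive", "sampled"):
        raise ValueError("method must be auto, exhaustive or sampled")
    pool = np.concatenate([a, b])
    n_a = a.size
    n_total = pool.size
    use_exhaustive = (
        method == "exhaustive"
        or (method == "auto" and math.comb(n_total, n_a) <= EXHAUSTIVE_LIMIT)
    )

    if statistic is None:
        observed = _mean_diff_stat(a, b)
        tol = 1e-12 * max(1.0, abs(observed))
        if use_exhaustive:
            count = 0
            total = 0
            idx = np.arange(n_total)
            pool_sum = pool.sum()
            for combo in itertools.combinations(idx, n_a):
                sel = np.fromiter(combo, dtype=int, count=n_a)
                sum_a = pool[sel].sum()
                stat = abs(sum_a / n_a - (pool_sum - sum_a) / (n_total - n_a))
                count += stat >= observed - tol
                total += 1
            return count / total
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # vectorised random shuffles
        order = np.argsort(rng.random((n_perm, n_total)), axis=1)
        perm = pool[order]
        stat = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
        count = int(np.sum(stat >= observed - tol))
        return (count + 1) / (n_perm + 1)

    # generic (non-vectorised) path for custom statistics
    observed = float(statistic(a, b))
    tol = 1e-12 * max(1.0, abs(observed))
    if use_exhaustive:
        count = total = 0
        idx = np.arange(n_total)
        for combo in itertools.combinations(idx, n_a):
            sel = np.fromiter(combo, dtype=int, count=n_a)
            mask = np.zeros(n_total, dtype=bool)
            mask[sel] = True
            count += float(statistic(pool[mask], pool[~mask])) >= observed - tol
            total += 1
        return count / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        count += float(statistic(perm[:n_a], perm[n_a:])) >= observed - tol
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# synthetic cohort generator


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters of one cleaning group.

    ``rest_mean``/``diff_mean`` are the group-level mean resting pH and mean
    Stephan drop; per-surface true values are drawn around them with
    ``surface_sd``.  ``rank1_offset`` shifts both rest and drop true pH of
    carious (rank 1) surfaces.  ``n_drop_only`` adds surfaces with a drop
    measurement but no resting one (spots where the resting reading failed
    QC, as happened for ~10 surfaces in the study).
    """

    name: str
    n_subjects: int
    n_surfaces: int
    rest_mean: float
    diff_mean: float
    n_drop_only: int = 0
    rank1_fraction: float = 0.15
    rank1_offset: float = 0.0
    surface_sd: float = 0.30

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_surfaces < 0 or self.n_drop_only < 0:
            raise ValueError("group sizes must be nonnegative (and n_subjects >= 1)")
        if not 0.0 <= self.rank1_fraction <= 1.0:
            raise ValueError("rank1_fraction must be in [0, 1]")
        if self.surface_sd < 0:
            raise ValueError("surface_sd must be >= 0")


def _default_groups() -> tuple[GroupParams, ...]:
    return (
        GroupParams(
            name="pre_cleaning",
            n_subjects=7,
            n_surfaces=40,
            rest_mean=6.70,
            diff_mean=0.84,
            rank1_offset=-0.25,
        ),
        GroupParams(
            name="post_cleaning",
            n_subjects=18,
            n_surfaces=45,
            rest_mean=6.75,
            diff_mean=0.48,
            n_drop_only=10,
            rank1_offset=0.10,
        ),
    )


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generating parameters.

    ``replicate_sd`` defaults to the instrument's published 0.23 pooled SD;
    ``n_replicates`` to the study's triplicate protocol.  Readings are
    clipped to the trusted ``ph_bounds``.  Saliva pH is drawn per subject
    from a normal distribution around neutrality, truncated to a plausible
    band.
    """

    groups: tuple[GroupParams, ...] = field(default_factory=_default_groups)
    replicate_sd: float = 0.23
    n_replicates: int = 3
    saliva_mean: float = 7.0
    saliva_sd: float = 0.2
    saliva_bounds: tuple[float, float] = (5.5, 8.5)
    ph_bounds: tuple[float, float] = (4.0, 7.5)

    def __post_init__(self) -> None:
        if self.replicate_sd < 0 or self.n_replicates < 1:
            raise ValueError("invalid replicate parameters")
        if not self.ph_bounds[0] < self.ph_bounds[1]:
            raise ValueError("ph_bounds must be increasing")


class SynthCohort(NamedTuple):
    """Synthetic cohort tables.

    ``readings``: one row per replicate pH reading; ``surfaces``: one row per
    tooth surface with triplet-aggregated rest/drop pH; ``subjects``: one row
    per subject with saliva pH.
    """

    readings: pd.DataFrame
    surfaces: pd.DataFrame
    subjects: pd.DataFrame


def synth_cohort(
    params: CohortParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> SynthCohort:
    """Draw a synthetic cohort emulating the clinical study's structure.

    Surface-level true pH values are drawn from group/rank-specific normal
    distributions, replicate readings add instrument noise at the pooled-SD
    level and are clipped to the trusted range, and surfaces are assigned
    round-robin to the group's subjects.  Fully reproducible under ``seed``.
    """
    params = params or CohortParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = params.ph_bounds

    reading_rows = []
    surface_rows = []
    subject_rows = []
    for group in params.groups:
        subject_ids = [f"{group.name}_s{j + 1:02d}" for j in range(group.n_subjects)]
        for sid in subject_ids:
            saliva = float(
                np.clip(rng.normal(params.saliva_mean, params.saliva_sd), *params.saliva_bounds)
            )
            subject_rows.append({"subject_id": sid, "group": group.name, "saliva_ph": saliva})

        n_total = group.n_surfaces + group.n_drop_only
        for i in range(n_total):
            sid = subject_ids[i % len(subject_ids)]
            surface_id = f"{group.name}_t{i + 1:03d}"
            rank = int(rng.random() < group.rank1_fraction)
            rest_true = rng.normal(group.rest_mean + rank * group.rank1_offset, group.surface_sd)
            drop_true = rng.normal(
                group.rest_mean - group.diff_mean + rank * group.rank1_offset, group.surface_sd
            )
            has_rest = i < group.n_surfaces  # trailing surfaces are drop-only
            row = {
                "subject_id": sid,
                "group": group.name,
                "surface_id": surface_id,
                "rank": rank,
            }
            for phase, true_ph, present in (("rest", rest_true, has_rest), ("drop", drop_true, True)):
                if not present:
                    row[f"{phase}_ph"] = float("nan")
                    row[f"{phase}_sd"] = float("nan")
                    row[f"{phase}_n"] = 0
                    continue
                reps = np.clip(
                    true_ph + rng.normal(0.0, params.replicate_sd, size=params.n_replicates), lo, hi
                )
                for r_idx, value in enumerate(reps, start=1):
                    reading_rows.append(
                        {
                            "subject_id": sid,
                            "group": group.name,
                            "surface_id": surface_id,
                            "rank": rank,
                            "phase": phase,
                            "replicate": r_idx,
                            "ph": float(value),
                        }
                    )
                mean, sd, n = aggregate_replicates(reps)
                row[f"{phase}_ph"] = mean
                row[f"{phase}_sd"] = float("nan") if sd is None else sd
                row[f"{phase}_n"] = n
            surface_rows.append(row)

    readings = pd.DataFrame(reading_rows)
    surfaces = pd.DataFrame(surface_rows)
    subjects = pd.DataFrame(subject_rows)
    return SynthCohort(readings=readings, surfaces=surfaces, subjects=subjects)


def aggregate_readings(readings: pd.DataFrame) -> pd.DataFrame:
    """Collapse a replicate-level readings table to one row per surface."""
    required = {"subject_id", "group", "surface_id", "rank", "phase", "ph"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    rows = {}
    for (sid, grp, surf, rank, phase), sub in readings.groupby(
        ["subject_id", "group", "surface_id", "rank", "phase"], sort=True
    ):
        row = rows.setdefault(
            surf,
            {
                "subject_id": sid,
                "group": grp,
                "surface_id": surf,
                "rank": rank,
                "rest_ph": float("nan"),
                "rest_sd": float("nan"),
                "rest_n": 0,
                "drop_ph": float("nan"),
                "drop_sd": float("nan"),
                "drop_n": 0,
            },
        )
        mean, sd, n = aggregate_replicates(sub["ph"].to_numpy())
        row[f"{phase}_ph"] = mean
        row[f"{phase}_sd"] = float("nan") if sd is None else sd
        row[f"{phase}_n"] = n
    return pd.DataFrame(list(rows.values()))


# ---------------------------------------------------------------------------
# the comparison grid


class ComparisonResult(NamedTuple):
    metric: str
    normalization: str
    comparison: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    normal_ok: bool
    welch_t: float
    welch_df: float
    welch_p: float
    perm_p: float
    alpha: float
    significant: bool


_METRICS = ("rest", "drop", "diff")
_NORMALIZATIONS = ("raw", "saliva")


def _shapiro_p(values: np.ndarray) -> float:
    if values.size < 3 or np.ptp(values) == 0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def analyze_cohort(
    surfaces: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the full grid of group and rank comparisons on a cohort.

    For every metric (rest, drop, diff pH) and normalisation (raw,
    saliva-normalised) the grid contains, in deterministic order:

    * every pair of groups overall, then restricted to rank-0 and to rank-1
      surfaces,
    * within each group, rank 0 vs rank 1.

    Cells with fewer than two surfaces on either side are skipped with a
    logged warning.  Welch's t-test is reported only when both sides pass the
    Shapiro-Wilk normality check at ``alpha`` (otherwise its fields are NaN);
    the permutation test is always run, and drives the ``significant`` flag
    (``perm_p < alpha``).  All permutation randomness derives from ``seed``.
    """
    surfaces = surfaces.copy()
    missing = {"subject_id", "group", "surface_id", "rank"} - set(surfaces.columns)
    if missing:
        raise ValueError(f"surfaces table missing columns: {sorted(missing)}")
    saliva = subjects.set_index("subject_id")["saliva_ph"] if len(subjects) else pd.Series(dtype=float)

    surfaces["diff_ph"] = surfaces["rest_ph"] - surfaces["drop_ph"]
    surfaces["saliva_ph"] = surfaces["subject_id"].map(saliva)
    for metric in _METRICS:
        surfaces[f"{metric}_saliva"] = surfaces[f"{metric}_ph"] / surfaces["saliva_ph"]
        surfaces[f"{metric}_raw"] = surfaces[f"{metric}_ph"]

    groups = sorted(surfaces["group"].unique())
    cells: list[tuple[str, pd.DataFrame, pd.DataFrame]] = []
    for g_a, g_b in itertools.combinations(groups, 2):
        sub_a = surfaces[surfaces["group"] == g_a]
        sub_b = surfaces[surfaces["group"] == g_b]
        cells.append((f"{g_a}_vs_{g_b}", sub_a, sub_b))
        for rank in (0, 1):
            cells.append(
                (
                    f"{g_a}_vs_{g_b}_rank{rank}",
                    sub_a[sub_a["rank"] == rank],
                    sub_b[sub_b["rank"] == rank],
                )
            )
    for g in groups:
        sub = surfaces[surfaces["group"] == g]
        cells.append(
            (f"within_{g}_rank0_vs_rank1", sub[sub["rank"] == 0], sub[sub["rank"] == 1])
        )

    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for metric in _METRICS:
        for norm in _NORMALIZATIONS:
            column = f"{metric}_{norm}"
            for name, sub_a, sub_b in cells:
                rng = np.random.default_rng(seed_seq.spawn(1)[0])
                a = sub_a[column].dropna().to_numpy()
                b = sub_b[column].dropna().to_numpy()
                if a.size < 2 or b.size < 2:
                    logger.warning(
                        "skipping %s / %s / %s: fewer than 2 surfaces per cell", metric, norm, name
                    )
                    continue
                p_a, p_b = _shapiro_p(a), _shapiro_p(b)
                normal_ok = bool(p_a > alpha and p_b > alpha) if not (
                    math.isnan(p_a) or math.isnan(p_b)
                ) else False
                if normal_ok:
                    welch_t, welch_df, welch_p = welch_t_test(a, b)
                else:
                    welch_t = welch_df = welch_p = float("nan")
                perm_p = permutation_test(a, b, n_perm=n_perm, seed=rng)
                rows.append(
                    ComparisonResult(
                        metric=metric,
                        normalization=norm,
                        comparison=name,
                        n_a=int(a.size),
                        n_b=int(b.size),
                        mean_a=float(a.mean()),
                        mean_b=float(b.mean()),
                        shapiro_p_a=p_a,
                        shapiro_p_b=p_b,
                        normal_ok=normal_ok,
                        welch_t=welch_t,
                        welch_df=welch_df,
                        welch_p=welch_p,
                        perm_p=perm_p,
                        alpha=alpha,
                        significant=bool(perm_p < alpha),
                    )
                )
    return pd.DataFrame(rows, columns=ComparisonResult._fields)
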