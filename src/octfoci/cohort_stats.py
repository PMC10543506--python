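"""Longitudinal per-eye and cohort statistics for per-slab foci counts.

Computes baseline -> month-24 changes per eye, categorizes each eye (and each
slab) as increase / decrease / no_change, summarizes the cohort (means with
sample SD, ranges, medians, category percentages, per-slab distribution of all
foci), and tests the change with paired t-tests (raw p per slab and total,
Holm-adjusted p alongside).

Percentages are rounded half-up to one decimal for display, the convention of
the clinical reports this mirrors; raw proportions are retained in the same
structures.  Eyes are treated as independent observations even when a subject
contributes both eyes — the convention of the source analyses; see the methods
note for the caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .foci_detector import SlabCounts

CATEGORIES = ("increase", "decrease", "no_change")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, decimals: int = 1) -> float:
    """``part / whole`` as a percentage rounded half-up to ``decimals``."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty stratum")
    return round_half_up(100.0 * part / whole, decimals)


def _category(delta: int | float) -> str:
    if delta > 0:
        return "increase"
    if delta < 0:
        return "decrease"
    return "no_change"


@dataclass
class LongitudinalRecord:
    """Baseline and month-24 counts for one eye plus deltas and categories."""

    eye_id: str
    baseline: np.ndarray
    month24: np.ndarray
    delta_per_slab: np.ndarray
    delta_total: int
    category_total: str
    category_per_slab: list[str]

    @property
    def baseline_total(self) -> int:
        return int(self.baseline.sum())

    @property
    def month24_total(self) -> int:
        return int(self.month24.sum())


def change_per_eye(baseline: SlabCounts, m24: SlabCounts) -> LongitudinalRecord:
    """Per-slab and total change for one eye between baseline and month 24."""
    if baseline.eye_id != m24.eye_id:
        raise ValueError(f"eye_id mismatch: {baseline.eye_id!r} vs {m24.eye_id!r}")
    if baseline.visit != "baseline" or m24.visit != "month24":
        raise ValueError(
            f"expected visits (baseline, month24), got ({baseline.visit!r}, {m24.visit!r})"
        )
    if baseline.k != m24.k:
        raise ValueError("slab counts have different K")
    delta = m24.counts - baseline.counts
    delta_total = int(delta.sum())
    return LongitudinalRecord(
        eye_id=baseline.eye_id,
        baseline=baseline.counts.copy(),
        month24=m24.counts.copy(),
        delta_per_slab=delta,
        delta_total=delta_total,
        category_total=_category(delta_total),
        category_per_slab=[_category(x) for x in delta],
    )


@dataclass
class PairedTestResult:
    """Paired t-test on per-eye differences.

    ``degenerate`` marks an all-constant difference vector: zero mean gives
    p = 1 by convention; nonzero mean with zero variance gives an infinite-t
    flag with p reported as 0 (both logged in the ``note``).
    """

    t: float
    df: int
    p: float
    n: int
    degenerate: bool = False
    note: str = ""


def paired_t_test(differences) -> PairedTestResult:
    """Two-sided paired t-test: ``t = mean(d) / (sd(d)/sqrt(n))``, sample SD.

    The p-value comes from the t distribution with n-1 degrees of freedom via
    the regularized incomplete beta function:
    ``p = I_{df/(df+t^2)}(df/2, 1/2)``.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return PairedTestResult(t=0.0, df=df, p=1.0, n=n, degenerate=True,
                                    note="all differences zero; p=1 by convention")
        return PairedTestResult(t=math.inf if mean > 0 else -math.inf, df=df,
                                p=0.0, n=n, degenerate=True,
                                note="zero variance with nonzero mean; infinite t")
    t = mean / (sd / math.sqrt(n))
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return PairedTestResult(t=float(t), df=df, p=p, n=n)


@dataclass
class CohortSummary:
    """Cohort-level descriptive statistics, categories and slab distribution."""

    n_eyes: int
    k: int
    visit_stats: pd.DataFrame      # rows baseline/month24/delta: mean, sd, min, max, median
    category_counts: pd.DataFrame  # rows total + slab1..K: counts per category
    category_percent: pd.DataFrame  # same layout, percentages (half-up, 1 dp)
    distribution_percent: pd.DataFrame  # percent of all foci per slab per visit
    n_eyes_any_slab_decrease: int
    tests: pd.DataFrame            # t, df, p, p_holm per slab and total

    @property
    def pct_eyes_any_slab_decrease(self) -> float:
        return percent(self.n_eyes_any_slab_decrease, self.n_eyes)


def _describe(values: np.ndarray) -> dict:
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
    }


def cohort_summary(records: list[LongitudinalRecord]) -> CohortSummary:
    """Summarize a cohort of longitudinal records.

    Uses sample (n-1) SD, midpoint medians, half-up one-decimal percentages.
    The slab distribution is the share of all foci (summed across eyes) per
    slab at each visit.  Raises on an empty cohort.
    """
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    k = len(records[0].baseline)
    base_tot = np.array([r.baseline_total for r in records], dtype=float)
    m24_tot = np.array([r.month24_total for r in records], dtype=float)
    delta_tot = np.array([r.delta_total for r in records], dtype=float)
    visit_stats = pd.DataFrame(
        [_describe(base_tot), _describe(m24_tot), _describe(delta_tot)],
        index=["baseline", "month24", "delta"],
    )

    strata = ["total"] + [f"slab{j}" for j in range(1, k + 1)]
    counts = {c: [] for c in CATEGORIES}
    for c in CATEGORIES:
        counts[c].append(sum(r.category_total == c for r in records))
        for j in range(k):
            counts[c].append(sum(r.category_per_slab[j] == c for r in records))
    category_counts = pd.DataFrame(counts, index=strata)
    category_percent = category_counts.apply(
        lambda col: [percent(v, n) for v in col]
    )

    base_slab = np.array([r.baseline for r in records]).sum(axis=0)
    m24_slab = np.array([r.month24 for r in records]).sum(axis=0)
    dist = {}
    for name, slab_sums in (("baseline", base_slab), ("month24", m24_slab)):
        grand = slab_sums.sum()
        dist[name] = [
            percent(v, grand, 2) if grand else float("nan") for v in slab_sums
        ]
    distribution_percent = pd.DataFrame(dist, index=[f"slab{j}" for j in range(1, k + 1)])

    n_any_dec = sum(any(c == "decrease" for c in r.category_per_slab) for r in records)

    rows = []
    deltas = [delta_tot] + [
        np.array([r.delta_per_slab[j] for r in records], dtype=float) for j in range(k)
    ]
    for name, dvec in zip(strata, deltas):
        if n < 2:  # a single eye supports no inference
            rows.append({"stratum": name, "t": np.nan, "df": 0, "p": np.nan,
                         "n": n, "degenerate": True})
            continue
        res = paired_t_test(dvec)
        rows.append({"stratum": name, "t": res.t, "df": res.df, "p": res.p,
                     "n": res.n, "degenerate": res.degenerate})
    tests = pd.DataFrame(rows).set_index("stratum")
    finite = np.isfinite(tests["p"].to_numpy())
    p_holm = np.full(len(tests), np.nan)
    if finite.any():
        p_holm[finite] = multipletests(tests["p"].to_numpy()[finite], method="holm")[1]
    tests["p_holm"] = p_holm

    return CohortSummary(
        n_eyes=n, k=k, visit_stats=visit_stats,
        category_counts=category_counts, category_percent=category_percent,
        distribution_percent=distribution_percent,
        n_eyes_any_slab_decrease=n_any_dec, tests=tests,
    )


def eligibility_filter(eyes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the study's eligibility rules to a screening table.

    ``eyes`` needs columns ``eye_id``, ``iamd`` (bool), ``baseline_total``
    (int), ``excluded`` (bool: any exclusion flag — other retinal disease,
    gross segmentation error, poor image quality).  The analysis cohort keeps
    eyes with intermediate AMD, at least one baseline focus, and no exclusion
    flag.  Returns the cohort and a screening ledger of counts.
    """
    required = {"eye_id", "iamd", "baseline_total", "excluded"}
    missing = required - set(eyes.columns)
    if missing:
        raise ValueError(f"eligibility table missing columns {sorted(missing)}")
    not_excluded = eyes[~eyes["excluded"].astype(bool)]
    iamd = not_excluded[not_excluded["iamd"].astype(bool)]
    cohort = iamd[iamd["baseline_total"] >= 1]
    ledger = {
        "screened": int(len(eyes)),
        "not_excluded": int(len(not_excluded)),
        "iamd": int(len(iamd)),
        "iamd_with_ihrf": int(len(cohort)),
    }
    if ledger["iamd"]:
        ledger["pct_iamd_with_ihrf"] = percent(ledger["iamd_with_ihrf"], ledger["iamd"])
    return cohort.reset_index(drop=True), ledger


# ---------------------------------------------------------------------------
# report writers

def write_report(summary: CohortSummary, out_dir) -> None:
    """Write summary.csv, table1.csv, distribution.csv and tests.csv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.visit_stats.to_csv(out / "summary.csv", index_label="visit")
    # Table-1 layout: % increase / decrease / no change per slab
    slab_rows = summary.category_percent.loc[
        [f"slab{j}" for j in range(1, summary.k + 1)]
    ]
    slab_rows.to_csv(out / "table1.csv", index_label="slab")
    summary.distribution_percent.to_csv(out / "distribution.csv", index_label="slab")
    summary.tests.to_csv(out / "tests.csv", index_label="stratum")
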