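"""Nonparametric group statistics for the frequency-tagging analysis.

The battery mirrors the study design: one-tailed one-sample Wilcoxon
signed-rank tests of the group-mean noise-subtracted amplitudes against
zero at each task x target frequency; paired contrasts of each imagery
task against marker viewing at the beat frequency over occipital and
non-occipital electrode groups; a Friedman test of the three imagery
tasks per target frequency, followed (when significant) by pairwise
Wilcoxon tests with Holm correction; a frontal-pair (Fp1/Fp2) Friedman
control against ocular artifacts; and the within-ternary harmonic-decay
contrasts (0.8 vs 1.6 Hz, 1.6 vs 3.2 Hz).

With nine subjects the exact signed-rank distribution is used (the
smallest attainable one-tailed p is 1/512 ~ 0.0020); a normal-
approximation z statistic is reported alongside for comparability with
conventional software output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import IMAGERY_CONDITIONS

__all__ = [
    "StatsConfig",
    "StatResult",
    "StatBatteryReport",
    "wilcoxon_signed_rank",
    "friedman_test",
    "holm_adjust",
    "run_stat_battery",
]

# significance ladder used in the reports: trend / significant / strong
_MARK_LEVELS = ((0.01, "**"), (0.05, "*"), (0.10, "+"))


def _marks(p: float) -> str:
    for level, mark in _MARK_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass(frozen=True)
class StatsConfig:
    """Significance gates of the battery."""

    alpha_gate: float = 0.10       # Friedman gate for the pairwise follow-up
    always_pairwise: bool = False  # run pairwise tests regardless of the gate


@dataclass
class StatResult:
    """One test's outcome: method label, statistic, p, tail, n, marks."""

    method: str
    statistic: float
    p_value: float
    tail: str
    n: int
    marks: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        self.marks = _marks(self.p_value)


def wilcoxon_signed_rank(
    values: Sequence[float], tail: str = "greater"
) -> StatResult:
    """One-sample Wilcoxon signed-rank test (one-tailed 'greater' by default).

    Zero values are dropped before ranking; tied absolute values get
    mid-ranks.  The p-value comes from the exact signed-rank distribution
    whenever n <= 25 and the absolute values are tie-free, else from the
    normal approximation.  The reported statistic is the (tie-corrected)
    normal-approximation z, signed so that positive z means a positive
    location shift.  For a paired contrast, pass the per-subject differences.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    arr = np.asarray(values, dtype=float)
    arr = arr[arr != 0.0]
    if arr.size == 0:
        raise ValueError("all values are zero; the signed-rank test is undefined")
    if arr.size < 5:
        raise ValueError(f"need >= 5 non-zero values, got {arr.size}")
    n = arr.size
    ranks = sps.rankdata(np.abs(arr))
    w_plus = float(ranks[arr > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var) if var > 0 else 0.0

    has_ties = np.unique(np.abs(arr)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    alternative = "greater" if tail == "greater" else "two-sided"
    res = sps.wilcoxon(arr, alternative=alternative, method=method)
    return StatResult(
        method=f"wilcoxon_signed_rank[{method}]",
        statistic=float(z),
        p_value=float(res.pvalue),
        tail=tail,
        n=n,
    )


def _friedman_statistic(ranks: np.ndarray, tie_term: float) -> float:
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:  # every row constant
        return 0.0
    return max(stat / correction, 0.0)


def friedman_test(
    matrix: np.ndarray | pd.DataFrame, method: str = "chi2"
) -> StatResult:
    """Friedman rank test over a subjects x treatments matrix.

    Within-subject mid-ranks; the chi-square statistic uses the standard
    tie correction.  ``method='chi2'`` (default) refers it to a chi-square
    with k-1 df — the convention behind conventionally reported
    chi-square/p pairs; ``method='exact'`` enumerates all within-row rank
    permutations instead (tie-free small instances only).  Works for k = 2
    treatments, where it reduces to a two-sided sign-test analogue.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 treatments")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    stat = _friedman_statistic(ranks, tie_term)

    if method == "chi2":
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    elif method == "exact":
        if tie_term:
            raise ValueError("exact Friedman p requires tie-free rows")
        from itertools import permutations, product

        perms = [np.array(p) for p in permutations(range(1, k + 1))]
        if len(perms) ** n > 2_000_000:
            raise ValueError("instance too large for exact enumeration")
        hits = total = 0
        for combo in product(perms, repeat=n):
            s = _friedman_statistic(np.vstack(combo), 0.0)
            hits += s >= stat - 1e-12
            total += 1
        p = hits / total
    else:
        raise ValueError("method must be 'chi2' or 'exact'")
    return StatResult(
        method=f"friedman[{method}]", statistic=float(stat),
        p_value=min(float(p), 1.0), tail="two-sided", n=n,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="holm")[1]


@dataclass
class StatBatteryReport:
    """All result tables of the statistical battery."""

    table1: pd.DataFrame            # task x frequency one-sample tests
    visual_contrasts: pd.DataFrame  # imagery-vs-marker at 2.4 Hz per group
    friedman: pd.DataFrame          # per target frequency across imagery tasks
    pairwise: pd.DataFrame          # Holm-adjusted task pairs per frequency
    controls: pd.DataFrame          # Fp1/Fp2 Friedman per frequency
    harmonic_contrasts: pd.DataFrame  # ternary 0.8 vs 1.6, 1.6 vs 3.2

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "table1": self.table1,
            "visual_contrasts": self.visual_contrasts,
            "friedman": self.friedman,
            "pairwise": self.pairwise,
            "controls": self.controls,
            "harmonic_contrasts": self.harmonic_contrasts,
        }


_TASKS = ("marker_viewing",) + IMAGERY_CONDITIONS
_ONE_SAMPLE_TARGETS = (0.8, 1.2, 1.6, 2.4)
_PAIRWISE_TARGETS = (0.8, 1.2, 1.6)
_REQUIRED_GROUPS = ("all", "occipital", "non_occipital", "frontal_pair")
_REQUIRED_FREQS = (0.8, 1.2, 1.6, 2.4, 3.2)


def _cell(table: pd.DataFrame, task: str, freq: float, group: str) -> pd.Series:
    sel = table[
        (table["condition"] == task)
        & (np.isclose(table["frequency"], freq))
        & (table["group"] == group)
    ].sort_values("subject")
    return sel.set_index("subject")["amplitude"]


def _check_complete(table: pd.DataFrame) -> None:
    subjects = sorted(table["subject"].unique())
    missing = []
    for task in _TASKS:
        for f in _REQUIRED_FREQS:
            for g in _REQUIRED_GROUPS:
                cell = _cell(table, task, f, g)
                if len(cell) != len(subjects):
                    missing.append(f"{task}/{f}Hz/{g}")
    if missing:
        raise ValueError("missing amplitude cells: " + ", ".join(missing))


def run_stat_battery(
    amplitudes: pd.DataFrame, config: StatsConfig | None = None
) -> StatBatteryReport:
    """Run the full battery on a long-format amplitude table.

    ``amplitudes`` needs columns subject, condition, group, frequency,
    amplitude covering every subject x task x target frequency (0.8, 1.2,
    1.6, 2.4, 3.2 Hz) x electrode group; amplitudes are group-mean
    noise-subtracted values per subject.
    """
    config = config or StatsConfig()
    _check_complete(amplitudes)

    rows = []
    for task in _TASKS:
        for f in _ONE_SAMPLE_TARGETS:
            res = wilcoxon_signed_rank(_cell(amplitudes, task, f, "all"), "greater")
            rows.append(
                {"task": task, "frequency": f, "z": res.statistic,
                 "p": res.p_value, "marks": res.marks}
            )
    table1 = pd.DataFrame(rows)

    rows = []
    for task in IMAGERY_CONDITIONS:
        for group in ("occipital", "non_occipital"):
            diff = (
                _cell(amplitudes, task, 2.4, group)
                - _cell(amplitudes, "marker_viewing", 2.4, group)
            )
            res = wilcoxon_signed_rank(diff, "greater")
            rows.append(
                {"task": task, "group": group, "frequency": 2.4,
                 "z": res.statistic, "p": res.p_value, "marks": res.marks}
            )
    visual = pd.DataFrame(rows)

    fried_rows = []
    fried_p: dict[float, float] = {}
    for f in _ONE_SAMPLE_TARGETS:
        mat = np.column_stack(
            [_cell(amplitudes, t, f, "all").to_numpy() for t in IMAGERY_CONDITIONS]
        )
        res = friedman_test(mat)
        fried_p[f] = res.p_value
        fried_rows.append(
            {"frequency": f, "chi_square": res.statistic, "p": res.p_value,
             "marks": res.marks}
        )
    friedman = pd.DataFrame(fried_rows)

    pair_rows = []
    for f in _PAIRWISE_TARGETS:
        gated = config.always_pairwise or fried_p[f] < config.alpha_gate
        raw, metas = [], []
        for a, b in combinations(IMAGERY_CONDITIONS, 2):
            meta = {"frequency": f, "task_a": a, "task_b": b, "gated": gated}
            if gated:
                diff = _cell(amplitudes, a, f, "all") - _cell(amplitudes, b, f, "all")
                res = wilcoxon_signed_rank(diff, "two-sided")
                meta.update(z=res.statistic, p_raw=res.p_value,
                            direction=">" if diff.median() > 0 else "<")
                raw.append(res.p_value)
            else:
                meta.update(z=np.nan, p_raw=np.nan, direction="")
            metas.append(meta)
        adj = holm_adjust(raw) if raw else []
        it = iter(adj)
        for meta in metas:
            meta["p_holm"] = float(next(it)) if meta["gated"] else np.nan
            meta["marks"] = _marks(meta["p_holm"]) if meta["gated"] else ""
        pair_rows.extend(metas)
    pairwise = pd.DataFrame(pair_rows)

    rows = []
    for f in _PAIRWISE_TARGETS:
        mat = np.column_stack(
            [
                _cell(amplitudes, t, f, "frontal_pair").to_numpy()
                for t in IMAGERY_CONDITIONS
            ]
        )
        res = friedman_test(mat)
        rows.append(
            {"frequency": f, "chi_square": res.statistic, "p": res.p_value,
             "marks": res.marks}
        )
    controls = pd.DataFrame(rows)

    rows = []
    for f_hi, f_lo in ((0.8, 1.6), (1.6, 3.2)):
        diff = (
            _cell(amplitudes, "ternary_meter", f_hi, "all")
            - _cell(amplitudes, "ternary_meter", f_lo, "all")
        )
        res = wilcoxon_signed_rank(diff, "greater")
        rows.append(
            {"task": "ternary_meter", "frequency_a": f_hi, "frequency_b": f_lo,
             "z": res.statistic, "p": res.p_value, "marks": res.marks}
        )
    harmonic = pd.DataFrame(rows)

    return StatBatteryReport(
        table1=table1,
        visual_contrasts=visual,
        friedman=friedman,
        pairwise=pairwise,
        controls=controls,
        harmonic_contrasts=harmonic,
    )
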