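"""Group statistics for transport metrics and dispersion profiles.

Transport metrics are compared across conditions by one-way ANOVA with
Tukey's HSD post hoc test, the cell being the unit of replication.
Dispersion profiles are compared bin-by-bin with a two-tailed unpaired
Student's t-test (equal-variance by default; Welch optional); no
multiple-testing correction is applied across bins by default, with
Benjamini-Hochberg available behind a flag. Significance stars follow
the conventional thresholds 0.05, 0.01, 0.001, 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from punctaquant.golgi import DispersionProfile

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


def significance_stars(p: float) -> str:
    """Star annotation as a pure function of the p-value and thresholds."""
    if np.isnan(p):
        return ""
    stars = sum(p < th for th in STAR_THRESHOLDS)
    return "*" * stars


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return m, s


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD over >= 2 groups of one metric."""

    metric: str
    labels: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sem: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float]
    stars: dict[tuple[str, str], str] = field(init=False)

    def __post_init__(self) -> None:
        self.stars = {pair: significance_stars(p) for pair, p in self.tukey_p.items()}


def anova_tukey(groups: dict[str, np.ndarray], metric: str = "value") -> GroupComparison:
    """One-way ANOVA with Tukey's HSD post hoc pairwise comparisons.

    ``groups`` maps condition label -> per-cell values. Every group needs
    n >= 2. With exactly two groups the single Tukey p-value coincides
    with the ANOVA p.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {k!r} has n={len(a)} < 2")
    f, p = sps.f_oneway(*arrays)
    res = sps.tukey_hsd(*arrays)
    tukey = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            tukey[(labels[i], labels[j])] = float(res.pvalue[i, j])
    ms = {k: _mean_sem(a) for k, a in zip(labels, arrays)}
    return GroupComparison(
        metric=metric,
        labels=labels,
        n={k: len(a) for k, a in zip(labels, arrays)},
        mean={k: ms[k][0] for k in labels},
        sem={k: ms[k][1] for k in labels},
        anova_f=float(f),
        anova_p=float(p),
        tukey_p=tukey,
    )


@dataclass
class BinwiseComparison:
    """Per-bin unpaired t-tests between two groups of dispersion profiles."""

    bin_lo: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    significant: np.ndarray = field(init=False)  # p < 0.05 flags
    skipped_bins: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.significant = self.p < 0.05

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant[~np.isnan(self.p)]))


def binwise_ttests(
    group_a: list[DispersionProfile],
    group_b: list[DispersionProfile],
    equal_var: bool = True,
    correction: str | None = None,
) -> BinwiseComparison:
    """Two-tailed unpaired t-test at every binned distance.

    ``equal_var=True`` gives the classic Student's test; ``False`` Welch.
    Bins present in fewer than two cells of either group are skipped and
    listed in ``skipped_bins``. ``correction="bh"`` applies
    Benjamini-Hochberg across the tested bins (off by default).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 cells")
    bin_lo = group_a[0].bin_lo
    mat_a = np.vstack([c.mean_intensity for c in group_a])
    mat_b = np.vstack([c.mean_intensity for c in group_b])
    nb = len(bin_lo)
    t = np.full(nb, np.nan)
    p = np.full(nb, np.nan)
    ma = np.full(nb, np.nan)
    sa = np.full(nb, np.nan)
    mb = np.full(nb, np.nan)
    sb = np.full(nb, np.nan)
    na = np.zeros(nb, dtype=int)
    nbn = np.zeros(nb, dtype=int)
    skipped = []
    for b in range(nb):
        va = mat_a[:, b][~np.isnan(mat_a[:, b])]
        vb = mat_b[:, b][~np.isnan(mat_b[:, b])]
        na[b], nbn[b] = len(va), len(vb)
        if len(va) < 2 or len(vb) < 2:
            skipped.append(float(bin_lo[b]))
            continue
        ma[b], sa[b] = _mean_sem(va)
        mb[b], sb[b] = _mean_sem(vb)
        if np.std(va) == 0 and np.std(vb) == 0 and np.mean(va) == np.mean(vb):
            t[b], p[b] = 0.0, 1.0
        else:
            res = sps.ttest_ind(va, vb, equal_var=equal_var)
            t[b], p[b] = float(res.statistic), float(res.pvalue)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(p)
        if ok.any():
            p_adj = multipletests(p[ok], method="fdr_bh")[1]
            p = p.copy()
            p[ok] = p_adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return BinwiseComparison(
        bin_lo=bin_lo, t=t, p=p, mean_a=ma, sem_a=sa, mean_b=mb, sem_b=sb, n_a=na, n_b=nbn,
        skipped_bins=skipped,
    )


def format_mean_sem(mean: float, sem: float, digits: int = 2) -> str:
    if np.isnan(mean):
        return "--"
    if np.isnan(sem):
        return f"{mean:.{digits}f}"
    return f"{mean:.{digits}f} ± {sem:.{digits}f}"


def transport_table(summaries: dict[str, "TransportSummary"]) -> pd.DataFrame:
    """Numeric transport table: one row per condition x metric x category."""
    rows = []
    for label, s in summaries.items():
        for cat in ("all", "anterograde", "retrograde"):
            c = s.category(cat)
            rows.append(
                {
                    "condition": label,
                    "category": cat,
                    "flux_per_min": c.flux,
                    "velocity_um_s": c.velocity_mean,
                    "velocity_sem": c.velocity_sem,
                    "run_length_um": c.run_length_mean,
                    "run_length_sem": c.run_length_sem,
                    "n_runs": c.n_runs,
                    "n_puncta": s.n_puncta,
                    "n_cells": s.n_cells,
                }
            )
    return pd.DataFrame(rows)


def comparison_table(comp: GroupComparison) -> pd.DataFrame:
    """Pairwise Tukey results with star annotations, plus the ANOVA row."""
    rows = [
        {
            "metric": comp.metric,
            "comparison": "ANOVA",
            "statistic": comp.anova_f,
            "p": comp.anova_p,
            "stars": significance_stars(comp.anova_p),
        }
    ]
    for (a, b), p in comp.tukey_p.items():
        rows.append(
            {
                "metric": comp.metric,
                "comparison": f"{a} vs {b}",
                "statistic": float("nan"),
                "p": p,
                "stars": comp.stars[(a, b)],
            }
        )
    return pd.DataFrame(rows)


def binwise_table(comp: BinwiseComparison) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "bin_lo": comp.bin_lo,
            "t": comp.t,
            "p": comp.p,
            "mean_a": comp.mean_a,
            "sem_a": comp.sem_a,
            "mean_b": comp.mean_b,
            "sem_b": comp.sem_b,
            "n_a": comp.n_a,
            "n_b": comp.n_b,
        }
    )
    df["stars"] = [significance_stars(x) for x in comp.p]
    return df
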