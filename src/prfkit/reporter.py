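"""Dual-reporter frameshifting-efficiency quantification.

In the dual-reporter design an upstream beta-galactosidase is translated
constitutively and a downstream firefly luciferase only when the ribosome
shifts frame inside the test insert.  Frameshifting efficiency is the
ratio-of-ratios

    efficiency% = 100 * mean(luc/bgal | test) / mean(luc/bgal | control)

with the in-frame control construct defining 100%.  Construct differences
are tested with an exact two-sided Mann-Whitney test (full enumeration of
labelings, mid-ranks for ties), appropriate for the six-replicate designs
typical of these assays.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "ReporterDataset",
    "EfficiencyEstimate",
    "efficiency",
    "mann_whitney_exact",
    "load_reporter_tsv",
    "summarize",
]


@dataclass(frozen=True)
class ReporterDataset:
    """Replicate (beta_gal, luciferase) activity pairs for one construct."""

    construct: str
    replicates: tuple  # of (beta_gal, luciferase)

    def __post_init__(self):
        if not self.replicates:
            raise ValueError(f"construct {self.construct!r} has no replicates")
        for i, (bg, _luc) in enumerate(self.replicates):
            if bg <= 0:
                raise ValueError(
                    f"construct {self.construct!r} replicate {i}: "
                    f"beta-gal activity {bg} is not positive; ratio undefined"
                )

    @property
    def ratios(self) -> np.ndarray:
        return np.array([luc / bg for bg, luc in self.replicates], dtype=float)


@dataclass(frozen=True)
class EfficiencyEstimate:
    percent: float
    se_percent: float
    n_test: int
    n_ctrl: int


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return m, se


def efficiency(test: ReporterDataset, ctrl: ReporterDataset) -> EfficiencyEstimate:
    """Ratio-of-ratio-means efficiency with first-order-propagated SE.

    The two constructs are measured in independent extracts, so the
    construct-level ratio means are divided (not per-replicate ratios of
    ratios); the SE combines the two relative standard errors in quadrature.
    """
    mt, st = _mean_se(test.ratios)
    mc, sc = _mean_se(ctrl.ratios)
    if mc == 0:
        raise ValueError("control ratio mean is zero; efficiency undefined")
    pct = 100.0 * mt / mc
    se = abs(pct) * math.sqrt((st / mt) ** 2 + (sc / mc) ** 2) if mt != 0 else 100.0 * st / mc
    return EfficiencyEstimate(percent=pct, se_percent=se,
                              n_test=len(test.replicates), n_ctrl=len(ctrl.replicates))


def _u_statistic(x, y) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """(U, two-sided p) for the Mann-Whitney test.

    For n_x + n_y <= 20 the p-value is exact: every C(n_x+n_y, n_x)
    relabeling of the pooled values is enumerated and a labeling counts as
    at-least-as-extreme when its min(U', n_x*n_y - U') does not exceed the
    observed one (ties handled by mid-ranking, hence half-integer U).
    Larger samples fall back to the normal approximation with tie
    correction.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if nx + ny <= 20:
        pooled = x + y
        idx = range(nx + ny)
        obs_extreme = min(u_obs, nx * ny - u_obs)
        hits = total = 0
        for comb in itertools.combinations(idx, nx):
            chosen = set(comb)
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in idx if i not in chosen]
            u = _u_statistic(xs, ys)
            if min(u, nx * ny - u) <= obs_extreme + 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total
    res = _scipy_stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def load_reporter_tsv(path: str | Path) -> dict[str, ReporterDataset]:
    """TSV with columns construct, replicate, beta_gal, luciferase."""
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "replicate", "beta_gal", "luciferase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reporter table missing column(s): {sorted(missing)}")
    out = {}
    for construct, grp in df.groupby("construct", sort=False):
        grp = grp.sort_values("replicate")
        reps = tuple(zip(grp["beta_gal"].tolist(), grp["luciferase"].tolist()))
        out[str(construct)] = ReporterDataset(construct=str(construct), replicates=reps)
    return out


def _holm(pvals: list[float]) -> list[float]:
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adj = [0.0] * len(pvals)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (len(pvals) - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def summarize(datasets: dict[str, ReporterDataset], control: str) -> pd.DataFrame:
    """Per-construct efficiency vs the named control, with exact tests.

    Unadjusted p-values are primary (one comparison per construct against
    the control); a Holm-adjusted column is included for transparency.
    """
    if control not in datasets:
        raise KeyError(f"control construct {control!r} not in dataset")
    ctrl = datasets[control]
    rows = []
    pvals = []
    for name, ds in datasets.items():
        est = efficiency(ds, ctrl)
        if name == control:
            u, p = float(len(ds.replicates) ** 2 / 2), 1.0
        else:
            u, p = mann_whitney_exact(list(ds.ratios), list(ctrl.ratios))
        rows.append({
            "construct": name, "efficiency_percent": est.percent,
            "se_percent": est.se_percent, "n": est.n_test,
            "U": u, "p_exact": p,
        })
        pvals.append(p)
    df = pd.DataFrame(rows)
    df["p_holm"] = _holm(pvals)
    return df
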