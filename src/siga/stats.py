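"""Two-group comparison machinery for morphometry tables.

Per (measure, generation, breathing-state) cell: Shapiro-Wilk normality
screening and a two-sided Mann-Whitney U test between the groups, exact for
small samples (n <= 8 per group, appropriate for cohorts of six subjects),
with a significance flag at p < 0.05.  No multiple-testing correction is
applied by default; Holm adjustment is available as an option.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["normality_check", "compare_groups", "holm_adjust"]


def normality_check(values):
    """Shapiro-Wilk statistic and p-value; requires n >= 3 and nonzero variance."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("all observations identical: normality test undefined")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _mwu(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if (min(len(a), len(b)) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    measures=None,
    by=("generation", "state"),
    alpha: float = 0.05,
    holm: bool = False,
    subject_level: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney U per (measure, generation, state) cell between two groups.

    ``table`` holds one row per branch (or per subject) with a two-level
    ``group_col``.  With ``subject_level=True`` branch values are first
    averaged per subject (requires a ``subject`` column); otherwise branches
    are the observations.  Cells where either group is empty are marked
    untestable rather than dropped.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two group labels, got {groups}")
    if measures is None:
        measures = [c for c in table.columns if c.endswith(("_mm3", "_mm2", "_mm-1", "_mm")) or c == "eccen"]
    by = [c for c in by if c in table.columns]

    work = table
    if subject_level:
        if "subject" not in table.columns:
            raise ValueError("subject_level=True requires a 'subject' column")
        work = (
            table.groupby([group_col, "subject", *by], dropna=False)[measures].mean().reset_index()
        )

    rows = []
    cells = work.groupby(by, dropna=False) if by else [((), work)]
    for cell_key, cell in cells:
        if not isinstance(cell_key, tuple):
            cell_key = (cell_key,)
        for m in measures:
            a = cell.loc[cell[group_col] == groups[0], m].dropna().to_numpy()
            b = cell.loc[cell[group_col] == groups[1], m].dropna().to_numpy()
            row = dict(zip(by, cell_key))
            row.update({"measure": m, "n_a": len(a), "n_b": len(b)})
            if len(a) == 0 or len(b) == 0:
                row.update({"U": np.nan, "p": np.nan, "significant": False, "testable": False})
            else:
                U, p = _mwu(a, b)
                row.update({"U": U, "p": p, "significant": bool(p < alpha), "testable": True})
            rows.append(row)
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["p_holm"] < alpha
    return out


def holm_adjust(p):
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    out[mask] = adj
    return out
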