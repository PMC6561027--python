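"""Killing-assay categorisation, class I-IV assignment, many-to-one tests.

Predation proceeds through ordered stages — attach, kill, round, exit — and
a mutant's class is the first stage at which it fails: class I mutants
cannot attach, class II attach but cannot kill, class III kill but cannot
round their prey into bdelloplasts, class IV round but cannot exit.  Prey
survival S (%) after infection categorises killing with strict boundaries:
S > 50 means no killing, S < 1 means killing, anything between (the
boundaries included) is intermediate.

``group_compare`` implements the field-standard analysis for the validation
assays: ordinary one-way ANOVA plus Dunnett-style many-to-one comparisons
against a control group.  The parametric path evaluates the exact
equicoordinate multivariate-t box probability; a max-|t| permutation test
is available as the distribution-free contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("attach", "kill", "round", "exit")


def survival_percent(cfu_infected: float, cfu_uninfected: float) -> float:
    """Prey survival S = 100 * CFU(infected) / CFU(uninfected).

    Can exceed 100 when prey grew during the assay.
    """
    if cfu_uninfected <= 0:
        raise ValueError("uninfected CFU count must be positive")
    if cfu_infected < 0:
        raise ValueError("CFU counts cannot be negative")
    return 100.0 * cfu_infected / cfu_uninfected


def killing_category(s: float) -> str:
    """Categorise prey survival: > 50% no_kill, < 1% kills, else intermediate.

    The boundaries are strict, so S = 50 and S = 1 are both intermediate.
    """
    if s > 50.0:
        return "no_kill"
    if s < 1.0:
        return "kills"
    return "intermediate"


def assign_class(attach: str, kill: str, round_: str, exit_: str = "ND"):
    """Class I-IV label from per-stage activity calls ('+', '-', 'ND').

    The class is the first deficient stage; 'ND' at or before the first
    determinable failure makes the mutant ``unclassified``, while 'ND'
    *after* the deciding stage is harmless (classes are routinely assigned
    with the exit stage untested).  A '+' downstream of a '-' is
    biologically inconsistent (a mutant that cannot attach cannot kill)
    and is flagged, with the class still taken from the first '-'.

    Returns ``(class_label, inconsistent)`` where ``class_label`` is
    1-4 or ``"unclassified"``.
    """
    calls = [attach, kill, round_, exit_]
    for c in calls:
        if c not in ("+", "-", "ND"):
            raise ValueError(f"activity call must be '+', '-' or 'ND', got {c!r}")
    cls: int | str = "unclassified"
    for i, c in enumerate(calls):
        if c == "ND":
            break
        if c == "-":
            cls = i + 1
            break
    inconsistent = False
    if isinstance(cls, int):
        downstream = calls[cls:]
        inconsistent = "+" in downstream
    return cls, inconsistent


def classify_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`assign_class` over a mutant table.

    ``calls`` needs columns ``attach``, ``kill``, ``round`` (and optionally
    ``exit`` and ``survival_pct``); returns the table with ``class`` and
    ``inconsistent`` columns appended, plus ``killing`` when survival is
    present.
    """
    out = calls.copy()
    exits = out["exit"] if "exit" in out.columns else pd.Series("ND", index=out.index)
    res = [
        assign_class(a, k, r, e)
        for a, k, r, e in zip(out["attach"], out["kill"], out["round"], exits)
    ]
    out["class"] = [c for c, _ in res]
    out["inconsistent"] = [f for _, f in res]
    if "survival_pct" in out.columns:
        out["killing"] = out["survival_pct"].map(killing_category)
    return out


# ---------------------------------------------------------------------------
# many-to-one comparisons
# ---------------------------------------------------------------------------

def _dunnett_prob_inside(t: float, corr: np.ndarray, df: int, seed: int = 0) -> float:
    """P(max_i |T_i| <= t) for a central multivariate t with the given
    correlation structure (the Dunnett equicoordinate probability)."""
    k = corr.shape[0]
    if t <= 0:
        return 0.0
    return float(
        stats.multivariate_t.cdf(
            np.full(k, t),
            loc=np.zeros(k),
            shape=corr,
            df=df,
            lower_limit=np.full(k, -t),
            maxpts=200_000 * k,
            random_state=np.random.default_rng(seed),
        )
    )


def dunnett_correlation(n_groups: np.ndarray, n_control: int) -> np.ndarray:
    """Correlation of the k treatment-vs-control t statistics."""
    lam = np.sqrt(np.asarray(n_groups) / (np.asarray(n_groups) + n_control))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def dunnett_critical(
    k: int, df: int, n_groups=None, n_control: int | None = None, alpha: float = 0.05
) -> float:
    """Two-sided Dunnett critical value |t| for k comparisons.

    Balanced designs (the default) use the classic rho = 0.5
    equicorrelation; pass group sizes for the general case.  Solved by
    bisection on the multivariate-t box probability.
    """
    if n_groups is None:
        corr = np.full((k, k), 0.5)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = dunnett_correlation(np.asarray(n_groups), int(n_control))
    lo, hi = 0.5, 15.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if _dunnett_prob_inside(mid, corr, df) < 1 - alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class GroupCompareResult:
    """One-way ANOVA plus Dunnett-adjusted many-to-one comparisons."""

    anova_f: float
    anova_p: float
    comparisons: pd.DataFrame  # group, n, mean_diff, t, p_adj
    method: str

    def summary(self) -> str:
        lines = [
            "Many-to-one group comparison",
            "=" * 34,
            f"method:   {self.method}",
            f"ANOVA:    F = {self.anova_f:.3f}, p = {self.anova_p:.4g}",
            self.comparisons.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _t_statistics(groups: list[np.ndarray], control: np.ndarray):
    ns = np.array([len(g) for g in groups])
    n0 = len(control)
    means = np.array([g.mean() for g in groups])
    m0 = control.mean()
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss += ((control - m0) ** 2).sum()
    df = int(ns.sum() + n0 - len(groups) - 1)
    s2 = ss / df if df > 0 else 0.0
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    diffs = means - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diffs / se, 0.0)
    return diffs, t, df, ns, n0


def group_compare(
    values: pd.Series | dict,
    control: str,
    method: str = "mvt",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GroupCompareResult:
    """Compare every group against a control with family-wise error control.

    Parameters
    ----------
    values : mapping of group name -> array of measurements, or a Series
        with a group-label index.
    control : name of the control group.
    method : "mvt" (exact multivariate-t Dunnett probabilities) or
        "permutation" (max-|t| permutation null; distribution-free).

    Degenerate inputs (zero pooled variance) give t = 0 and adjusted
    p = 1 for exact ties with the control, by convention.
    """
    if isinstance(values, pd.Series):
        values = {g: sub.to_numpy(dtype=float) for g, sub in values.groupby(level=0)}
    values = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if control not in values:
        raise ValueError(f"control group {control!r} not present")
    if len(values) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in values.values()):
        raise ValueError("every group needs at least two values")
    names = [g for g in values if g != control]
    groups = [values[g] for g in names]
    ctrl = values[control]

    f_stat, f_p = stats.f_oneway(ctrl, *groups)
    if not np.isfinite(f_stat):  # zero variance everywhere
        f_stat, f_p = 0.0, 1.0
    diffs, t, df, ns, n0 = _t_statistics(groups, ctrl)

    if method == "mvt":
        corr = dunnett_correlation(ns, n0)
        p_adj = np.array(
            [1.0 - _dunnett_prob_inside(abs(ti), corr, df) for ti in t]
        )
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([ctrl] + groups)
        sizes = [len(ctrl)] + [len(g) for g in groups]
        edges = np.cumsum(sizes)
        max_t = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, edges[:-1])
            _, tb, _, _, _ = _t_statistics(parts[1:], parts[0])
            max_t[b] = np.abs(tb).max()
        p_adj = np.array(
            [(1 + (max_t >= abs(ti)).sum()) / (n_permutations + 1) for ti in t]
        )
    else:
        raise ValueError("method must be 'mvt' or 'permutation'")
    p_adj = np.clip(p_adj, 0.0, 1.0)
    comparisons = pd.DataFrame(
        {"group": names, "n": ns, "mean_diff": diffs, "t": t, "p_adj": p_adj}
    ).set_index("group")
    return GroupCompareResult(
        anova_f=float(f_stat), anova_p=float(f_p), comparisons=comparisons, method=method
    )
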