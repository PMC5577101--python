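"""Plate statistics: unpaired Student's t, one-way ANOVA, Dunnett's post hoc.

These are the comparisons used to call treatment effects on plate-level
endpoints (normalised ECM signal, branch counts): a pooled-variance
two-sided t-test for two groups, one-way ANOVA across several, and
Dunnett's many-to-one procedure for comparing every treatment against a
single control with family-wise error control.

Dunnett adjusted p-values are computed by seeded Monte-Carlo integration of
the null multivariate-t distribution of the comparison statistics (default
100 000 draws, accuracy about +/-0.002 in p). Zero-variance degeneracies are
reported explicitly instead of propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass(frozen=True)
class GroupData:
    """One experimental group: id plus replicate measurements."""

    group_id: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, np.float64))
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ParameterError(f"group {self.group_id!r} needs >= 2 replicate values")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"group {self.group_id!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float  # integer for pooled, Satterthwaite (fractional) for Welch
    p_two_sided: float
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def students_t(a: GroupData, b: GroupData, welch: bool = False) -> TTestResult:
    """Unpaired two-sided t-test: pooled variance (Student's) by default.

    ``welch=True`` switches to Welch's unequal-variance form with
    Satterthwaite degrees of freedom. Zero variance is handled explicitly:
    equal means give t=0, p=1; unequal means give p=0 flagged degenerate
    (an infinite-t limit).
    """
    diff = a.mean - b.mean
    if welch:
        va = float(a.values.var(ddof=1)) / a.n
        vb = float(b.values.var(ddof=1)) / b.n
        if va + vb == 0.0:
            df = a.n + b.n - 2
            if diff == 0.0:
                return TTestResult(t=0.0, df=df, p_two_sided=1.0, degenerate=True)
            return TTestResult(t=float(np.sign(diff)) * np.inf, df=df, p_two_sided=0.0, degenerate=True)
        t = diff / np.sqrt(va + vb)
        df_w = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        p = 2.0 * float(sps.t.sf(abs(t), df_w))
        return TTestResult(t=float(t), df=df_w, p_two_sided=p)
    df = a.n + b.n - 2
    ss = float(((a.values - a.mean) ** 2).sum() + ((b.values - b.mean) ** 2).sum())
    pooled_var = ss / df
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p_two_sided=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=df, p_two_sided=0.0, degenerate=True)
    t = diff / np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p_two_sided=p)


def one_way_anova(groups: list[GroupData]) -> AnovaResult:
    """Classical one-way between/within sum-of-squares decomposition."""
    if len(groups) < 2:
        raise ParameterError("one-way ANOVA needs >= 2 groups")
    all_values = np.concatenate([g.values for g in groups])
    grand = all_values.mean()
    ss_between = float(sum(g.n * (g.mean - grand) ** 2 for g in groups))
    ss_within = float(sum(((g.values - g.mean) ** 2).sum() for g in groups))
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0, degenerate=True)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    if ss_between == 0.0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


@lru_cache(maxsize=16)
def _max_abs_null_t(ns: tuple[int, ...], df: int, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo draws of max_j |T_j| under the Dunnett null.

    ``ns`` is (n_control, n_1, ..., n_k). Group normal draws are generated
    group-by-group from one stream and the pooled-sd draws by inverse-CDF
    from a second, so that appending a comparison group reuses identical
    draws for the existing ones (the family maximum can then only grow).
    Results are cached: the draw set is a pure function of the arguments,
    and repeated tests on same-shaped designs (e.g. null simulations) reuse it.
    """
    ss = np.random.SeedSequence(seed)
    child_z, child_u = ss.spawn(2)
    rng_z = np.random.default_rng(child_z)
    rng_u = np.random.default_rng(child_u)
    z = [rng_z.standard_normal(n_draws) / np.sqrt(n) for n in ns]
    u = rng_u.random(n_draws)
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    tmax = np.zeros(n_draws)
    for j in range(1, len(ns)):
        tj = np.abs(z[j] - z[0]) / (s * np.sqrt(1.0 / ns[j] + 1.0 / ns[0]))
        np.maximum(tmax, tj, out=tmax)
    return tmax


def dunnett(
    groups: list[GroupData],
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of every group against the control.

    Returns one row per non-control group with the mean difference, the
    pooled-variance t statistic, raw two-sided p, and the family-wise
    adjusted p = P(max_j |T_j| >= |t|) under the null multivariate t,
    estimated by seeded Monte Carlo and clipped to be >= the raw p.
    With a single comparison the adjusted p equals the raw p exactly.
    """
    ids = [g.group_id for g in groups]
    if control not in ids:
        raise ParameterError(f"control group {control!r} not among groups {ids}")
    if len(groups) < 2:
        raise ParameterError("Dunnett needs the control plus >= 1 comparison group")
    ctrl = groups[ids.index(control)]
    others = [g for g in groups if g.group_id != control]

    N = sum(g.n for g in groups)
    df = N - len(groups)
    ss_within = float(sum(((g.values - g.mean) ** 2).sum() for g in groups))
    pooled_var = ss_within / df

    rows = []
    tstats = []
    for g in others:
        diff = g.mean - ctrl.mean
        if pooled_var == 0.0:
            t = 0.0 if diff == 0.0 else float(np.sign(diff)) * np.inf
            p_raw = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / np.sqrt(pooled_var * (1.0 / g.n + 1.0 / ctrl.n))
            p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        tstats.append(t)
        rows.append({"comparison": f"{g.group_id} - {control}", "estimate": diff, "t": float(t),
                     "df": df, "p_raw": p_raw})

    if len(others) == 1 or pooled_var == 0.0:
        adj = [r["p_raw"] for r in rows]
    else:
        tmax = _max_abs_null_t(tuple([ctrl.n] + [g.n for g in others]), df, n_draws, seed)
        adj = [
            min(1.0, max(r["p_raw"], float(np.mean(tmax >= abs(t)))))
            for r, t in zip(rows, tstats)
        ]
    for r, p in zip(rows, adj):
        r["p_adjusted"] = p
    return pd.DataFrame(rows, columns=["comparison", "estimate", "t", "df", "p_raw", "p_adjusted"])


def groups_from_tidy(df: pd.DataFrame, group_col: str = "group", value_col: str = "value",
                     control: str | None = None) -> list[GroupData]:
    """Build GroupData objects from a tidy (group, value) table."""
    out = []
    for gid, sub in df.groupby(group_col, sort=True):
        out.append(GroupData(group_id=str(gid), values=sub[value_col].to_numpy(),
                             is_control=(str(gid) == control)))
    return out
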