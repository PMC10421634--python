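"""Timescales of behavioral organization and statistical testing.

Modularity (or module-stability AMI) as a function of transition lag
decays roughly exponentially; the fitted model M = a * exp(b * T) + c
(b < 0) gives a half-life H = -log(2) / b measuring how many
transitions into the future behavioral organization persists.  This
module also implements the label-shuffle null for modularity/Dasgupta
significance and session-level group comparisons (two-way ANOVA,
pairwise-session AMI with permutation p-values, partialled t-tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hierarchy import ami, best_cut, dasgupta_score, paris_dendrogram
from .transitions import PostureRunSequence, transition_matrix


@dataclass
class MetricCurve:
    lags: np.ndarray
    values: np.ndarray
    metric: str = "modularity"
    session_id: str = ""
    subject_id: str = ""
    task_condition: str = ""

    def __post_init__(self):
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class TimescaleFit:
    a: float
    b: float
    c: float
    half_life: float | None
    adj_r2: float
    degenerate: bool = False

    def predict(self, lags: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(lags, float)) + self.c


@dataclass
class NullDistribution:
    metric: str
    observed: float
    permuted: np.ndarray
    p_value: float

    @property
    def n_permutations(self) -> int:
        return len(self.permuted)


def _graph_metric(runs: PostureRunSequence, lag: int, n_postures: int, metric: str):
    """(value, partition) of one metric on the lag-T transition graph."""
    g = transition_matrix(runs, T=lag, n_postures=n_postures).active_subgraph()
    dend = paris_dendrogram(g)
    if metric == "dasgupta":
        return dasgupta_score(dend, g), None
    part = best_cut(dend, g)
    return part.Q, part


def metric_curve(
    runs: PostureRunSequence,
    lags,
    metric: str = "modularity",
    n_postures: int | None = None,
) -> MetricCurve:
    """Modularity or consecutive-lag stability (AMI) across transition lags.

    modularity: best-cut Q of the lag-T graph per lag.  stability: AMI
    between the best-cut module assignments at consecutive requested
    lags (value stored at the smaller lag; the last lag is dropped).
    """
    lags = [int(T) for T in lags if T < runs.n_runs]
    n = int(n_postures if n_postures is not None else runs.postures.max() + 1)
    if metric == "modularity":
        vals = [_graph_metric(runs, T, n, "modularity")[0] for T in lags]
        return MetricCurve(np.asarray(lags), np.asarray(vals), metric="modularity")
    if metric == "stability":
        parts = [_graph_metric(runs, T, n, "modularity")[1] for T in lags]
        vals = [ami(parts[i], parts[i + 1]) for i in range(len(parts) - 1)]
        return MetricCurve(np.asarray(lags[:-1]), np.asarray(vals), metric="stability")
    raise ValueError(f"unknown metric '{metric}'")


def fit_half_life(curve: MetricCurve) -> TimescaleFit:
    """Fit M = a*exp(b*T) + c with b < 0 and extract H = -log(2)/b.

    Trust-region least squares initialized from a log-linear regression
    on (value - min).  A flat curve (amplitude ~ 0 or no decay) is
    flagged degenerate with the half-life reported as missing.
    """
    T = np.asarray(curve.lags, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    if len(np.unique(T)) < 4:
        raise ValueError("need at least 4 distinct lags")
    if np.allclose(y, y[0]):
        return TimescaleFit(0.0, 0.0, float(y[0]), None, 0.0, degenerate=True)
    # log-linear initialization
    shifted = y - y.min() + 1e-9
    slope, intercept = np.polyfit(T, np.log(shifted), 1)
    b0 = float(np.clip(slope, -10.0, -1e-6))
    a0 = float(max(np.exp(intercept), 1e-9))
    c0 = float(y.min())

    def model(t, a, b, c):
        return a * np.exp(b * t) + c

    try:
        popt, _ = optimize.curve_fit(
            model,
            T,
            y,
            p0=(a0, b0, c0),
            bounds=([-np.inf, -10.0, -np.inf], [np.inf, -1e-6, np.inf]),
            method="trf",
            maxfev=20000,
        )
    except RuntimeError:
        return TimescaleFit(0.0, 0.0, float(y.mean()), None, 0.0, degenerate=True)
    a, b, c = (float(v) for v in popt)
    resid = y - model(T, a, b, c)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = len(y), 3
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
    if abs(a) < 1e-9:
        return TimescaleFit(a, b, c, None, adj_r2, degenerate=True)
    return TimescaleFit(a, b, c, -np.log(2.0) / b, adj_r2)


def shuffle_null(
    runs: PostureRunSequence,
    metric: str = "modularity",
    n: int = 100,
    seed: int = 0,
    lag: int = 1,
    n_postures: int | None = None,
) -> NullDistribution:
    """Label-shuffle significance test for modularity or Dasgupta score.

    Permutes the run-level posture labels (preserving label frequencies
    and run count), rebuilds the lag-T transition graph, re-clusters and
    recomputes the metric, ``n`` times.  p uses the add-one convention
    p = (1 + #{null >= observed}) / (1 + n).
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    n_post = int(n_postures if n_postures is not None else runs.postures.max() + 1)
    observed, _ = _graph_metric(runs, lag, n_post, metric)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for k in range(n):
        perm = _dc_replace(runs, postures=rng.permutation(runs.postures))
        null[k] = _graph_metric(perm, lag, n_post, metric)[0]
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n)
    return NullDistribution(metric=metric, observed=float(observed), permuted=null, p_value=float(p))


def two_way_anova(df: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Type-II two-way ANOVA (subject + task, no interaction).

    ``df`` needs columns 'subject', 'task' and the value column.
    Returns the statsmodels ANOVA table (F and p per factor).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in ("subject", "task", value):
        if col not in df.columns:
            raise ValueError(f"missing column '{col}'")
    if df["subject"].nunique() < 2 or df["task"].nunique() < 2:
        raise ValueError("need >= 2 levels per factor for a two-way ANOVA")
    model = ols(f"{value} ~ C(subject) + C(task)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def pairwise_session_ami(
    assignments: dict[str, dict],
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AMI between module assignments of all session pairs + permutation p.

    Per-cell significance randomizes one side's module labels
    ``n_permutations`` times; p-values (off-diagonal, upper triangle)
    are Benjamini-Hochberg corrected within the family.
    """
    from statsmodels.stats.multitest import multipletests

    names = sorted(assignments)
    rng = np.random.default_rng(seed)
    amis = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pvals = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    raw_p, cells = [], []
    for i, s1 in enumerate(names):
        for j, s2 in enumerate(names):
            if j <= i:
                continue
            a, b = assignments[s1], assignments[s2]
            obs = ami(a, b)
            keys = sorted(set(a) & set(b))
            bvals = np.asarray([b[k] for k in keys])
            null = np.empty(n_permutations)
            for k in range(n_permutations):
                null[k] = ami(
                    {kk: a[kk] for kk in keys},
                    dict(zip(keys, rng.permutation(bvals).tolist())),
                )
            p = (1.0 + np.sum(null >= obs)) / (1.0 + n_permutations)
            amis.loc[s1, s2] = amis.loc[s2, s1] = obs
            raw_p.append(p)
            cells.append((s1, s2))
    if raw_p:
        _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
        for (s1, s2), p in zip(cells, p_adj):
            pvals.loc[s1, s2] = pvals.loc[s2, s1] = p
    return amis, pvals


def partialled_ttest(
    pair_df: pd.DataFrame,
    group_col: str,
    partial_col: str,
    value: str = "ami",
) -> dict:
    """Unpaired t-test between two groups after partialling a nuisance factor.

    Subtracts the mean value of each ``partial_col`` level (e.g. task
    pair) from every observation, then compares the two levels of
    ``group_col`` (e.g. within- vs between-subject pairs).
    """
    df = pair_df.copy()
    df["_partialled"] = df[value] - df.groupby(partial_col)[value].transform("mean")
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, got {levels}")
    x = df.loc[df[group_col] == levels[0], "_partialled"]
    y = df.loc[df[group_col] == levels[1], "_partialled"]
    t, p = stats.ttest_ind(x, y)
    return {
        "groups": levels,
        "t": float(t),
        "p": float(p),
        "mean_diff": float(x.mean() - y.mean()),
        "n": (int(len(x)), int(len(y))),
    }


def compare_sessions(
    session_metrics: pd.DataFrame | None = None,
    comparison: str = "anova",
    assignments: dict[str, dict] | None = None,
    pair_df: pd.DataFrame | None = None,
    **kwargs,
) -> object:
    """Dispatch session-level comparisons.

    comparison='anova': two-way ANOVA on per-session metric values
    (columns subject, task, value).  'paired_ami': pairwise-session AMI
    matrix with permutation p-values (needs ``assignments``).
    'partialled_ttest': group t-test on partialled pair values (needs
    ``pair_df`` plus group_col/partial_col kwargs).
    """
    if comparison == "anova":
        return two_way_anova(session_metrics, **kwargs)
    if comparison == "paired_ami":
        if assignments is None:
            raise ValueError("paired_ami needs module assignments per session")
        return pairwise_session_ami(assignments, **kwargs)
    if comparison == "partialled_ttest":
        if pair_df is None:
            raise ValueError("partialled_ttest needs a pair table")
        return partialled_ttest(pair_df, **kwargs)
    raise ValueError(f"unknown comparison '{comparison}'")
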