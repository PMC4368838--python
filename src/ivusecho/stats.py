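"""Downstream statistics: correlation with molecular weight, regression,
Ward clustering, ICC reproducibility, ANOVA.

These relate the echogenicity volumetrics (notably hyper+upper volume in
the scaffold-vessel compartment) to the residual polymer molecular weight
of a bioresorbable scaffold, and quantify reader agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


class ConstantInputError(ValueError):
    """A statistic is undefined because an input vector is constant."""


def _check_vector_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x, y = _check_vector_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LinregResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linreg(x, y) -> LinregResult:
    """Ordinary least-squares simple linear regression of y on x."""
    x, y = _check_vector_pair(x, y)
    if np.ptp(x) == 0:
        raise ConstantInputError("regression undefined for constant predictor")
    res = sps.linregress(x, y)
    return LinregResult(float(res.slope), float(res.intercept), float(res.rvalue) ** 2, float(res.pvalue))


def ward_cluster(observations, k: int, return_merges: bool = False):
    """Agglomerative Ward clustering on squared Euclidean distances.

    Implements the Lance-Williams update for Ward's minimum-variance
    linkage starting from pairwise squared Euclidean distances; at every
    step the pair with the smallest merge cost is joined (cost equals twice
    the increase in total within-cluster sum of squares), with ties broken
    by the lexicographically smallest index pair, so the tree is fully
    deterministic.  Cutting the tree at ``k`` clusters returns 0-based
    labels in order of first cluster appearance.

    With ``return_merges=True`` additionally returns the merge history as a
    list of ``(members_a, members_b, cost)`` tuples.
    """
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")

    # active clusters: index -> (size, member tuple)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = sq[i, j]
    size = {i: 1 for i in range(n)}
    members = {i: (i,) for i in range(n)}
    next_id = n
    merges = []
    id_order: list[int] = []

    while len(size) > max(k, 1):
        (a, b), cost = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((members[a], members[b], cost))
        na, nb = size[a], size[b]
        new = next_id
        next_id += 1
        for c in list(size):
            if c in (a, b):
                continue
            nc = size[c]
            dac = d.pop((min(a, c), max(a, c)))
            dbc = d.pop((min(b, c), max(b, c)))
            d[(min(new, c), max(new, c))] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * cost
            ) / (na + nb + nc)
        d.pop((a, b))
        size[new] = na + nb
        members[new] = tuple(sorted(members[a] + members[b]))
        del size[a], size[b], members[a], members[b]

    labels = np.empty(n, dtype=int)
    for lab, cid in enumerate(sorted(members, key=lambda c: members[c][0])):
        for m in members[cid]:
            labels[m] = lab
    if return_merges:
        return labels, merges
    return labels


def icc(readings, model: str = "ICC2") -> float:
    """Intraclass correlation coefficient between two readings per subject.

    ``readings`` is an (n, 2) array-like (reader 1 / reader 2, or read 1 /
    read 2).  The default ``ICC2`` is the two-way random-effects,
    absolute-agreement, single-measure coefficient — the standard choice
    for method-agreement studies in imaging; ``ICC3`` (consistency) is also
    selectable.
    """
    R = np.asarray(readings, dtype=float)
    if R.ndim != 2 or R.shape[1] != 2:
        raise ValueError("readings must be an (n, 2) table")
    n = R.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired readings")
    if np.allclose(R, R.flat[0]):
        raise ConstantInputError("ICC undefined with zero total variance")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile([0, 1], n),
            "score": R.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # pingouin labels single-measure models ICC(1,1)/ICC(A,1)/ICC(C,1)
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}
    wanted = {model, aliases.get(model, model)}
    value = table.loc[table["Type"].isin(wanted), "ICC"]
    if value.empty:
        raise ValueError(f"unknown ICC model {model!r}")
    return float(value.iloc[0])


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def pairwise_comparisons(groups: dict, correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise two-sample t-tests with multiple-testing correction.

    ``groups`` maps group label -> 1-D sample.  Returns a DataFrame with
    raw and corrected p-values (Bonferroni by default, or 'holm', 'none').
    """
    labels = list(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p = sps.ttest_ind(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    m = len(df)
    if correction == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    elif correction == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif correction == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def degradation_report(summary: pd.DataFrame, mw_col: str = "molecular_weight_kda") -> dict:
    """Correlation/regression report linking echogenicity to molecular weight.

    ``summary`` is the cohort table from :func:`ivusecho.volumetrics.cohort_summary`
    joined with a molecular-weight column.  Reports Pearson r and OLS fits
    for scaffold-vessel hyper, upper and hyper+upper volumes against Mw,
    in both regression directions.
    """
    mw = summary[mw_col].to_numpy(dtype=float)
    report = {}
    for key, col in {
        "hyper": "scaffold_vessel_hyper_mm3",
        "upper": "scaffold_vessel_upper_mm3",
        "hyper_upper": "scaffold_vessel_hyper_upper_mm3",
    }.items():
        x = summary[col].to_numpy(dtype=float)
        r, p = pearson_r(x, mw)
        fit = linreg(x, mw)  # Mw predicted from echogenicity
        report[key] = {
            "pearson_r": r,
            "pearson_p": p,
            "r_squared": fit.r_squared,
            "slope": fit.slope,
            "intercept": fit.intercept,
        }
    return report
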