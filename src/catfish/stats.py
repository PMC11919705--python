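"""Inferential layer: stratified rank tests, multiplicity corrections and
significant Spearman correlation networks between brain structures.

Group contrasts (recent vs remote recall, chemogenetic suppression vs
control) use the two-sided Mann-Whitney-Wilcoxon test, stratified over brain
structures with van Elteren's combination when observations from several
structures enter one comparison. Families of tests are corrected with Holm's
step-down procedure, except the cross-structure correlation analysis which
uses Benjamini-Hochberg FDR control. Correlation networks connect structures
whose descriptor values (one descriptor class per network) show a
significant monotonic association; edges carry the Spearman rho, its sign
and the adjusted p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


@dataclass(frozen=True)
class MWWResult:
    u: float
    p: float
    method: str  # "exact" | "asymptotic"
    degenerate: bool = False


def mww_test(
    x: Sequence[float],
    y: Sequence[float],
    use_continuity: bool = True,
    exact_max_n: int = 10,
) -> MWWResult:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact null distribution when both groups have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with tie correction (and continuity correction by default). Two samples
    identical as multisets yield p = 1 with a degeneracy flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MWWResult(u=len(x) * len(y) / 2.0, p=1.0, method="degenerate",
                         degenerate=True)
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(x) <= exact_max_n and len(y) <= exact_max_n:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MWWResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic",
        use_continuity=use_continuity,
    )
    return MWWResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


@dataclass(frozen=True)
class StratifiedResult:
    statistic: float  # combined standard-normal statistic
    p: float
    n_strata_used: int
    skipped_strata: tuple[str, ...] = ()


def _rank_sum_moments(values: np.ndarray, is_group1: np.ndarray):
    """Mid-rank sum of group 1 plus its null mean and tie-corrected variance."""
    n_all = len(values)
    m = int(is_group1.sum())
    n = n_all - m
    ranks = sps.rankdata(values)  # mid-ranks
    w = float(ranks[is_group1].sum())
    mean = m * (n_all + 1) / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = m * n * (n_all + 1) / 12.0
    if n_all > 1:
        var -= m * n * tie_term / (12.0 * n_all * (n_all - 1))
    return w, mean, var


def stratified_mww(
    data: pd.DataFrame | Iterable[tuple[float, str, str]],
    value_col: str = "value",
    group_col: str = "group",
    stratum_col: str = "stratum",
) -> StratifiedResult:
    """Van Elteren's stratified two-sided Mann-Whitney-Wilcoxon test.

    Per-stratum rank sums are centred, combined with the locally-best
    weights 1/(n_s + 1) (n_s = stratum size) and referred to the standard
    normal null. Strata missing either group are skipped and reported.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(data, columns=[value_col, group_col, stratum_col])
    if data.empty:
        raise ParameterError("no data")
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ParameterError(f"need exactly 2 groups, got {groups}")
    g1 = groups[0]
    num = 0.0
    var = 0.0
    used = 0
    skipped: list[str] = []
    for stratum, sub in data.groupby(stratum_col):
        is_g1 = (sub[group_col] == g1).to_numpy()
        if is_g1.all() or not is_g1.any():
            skipped.append(str(stratum))
            continue
        values = sub[value_col].to_numpy(dtype=float)
        w_s, mean_s, var_s = _rank_sum_moments(values, is_g1)
        if var_s <= 0:  # all values tied within the stratum: no information
            skipped.append(str(stratum))
            continue
        weight = 1.0 / (len(values) + 1.0)
        num += weight * (w_s - mean_s)
        var += weight**2 * var_s
        used += 1
    if used == 0:
        raise ParameterError("no stratum contains both groups")
    z = num / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return StratifiedResult(
        statistic=float(z), p=float(min(p, 1.0)), n_strata_used=used,
        skipped_strata=tuple(skipped),
    )


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvals, dtype=float)
    _validate_pvals(p)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(pvals, dtype=float)
    _validate_pvals(p)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _validate_pvals(p: np.ndarray) -> None:
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in [0, 1]")


def spearman_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Two-sided Spearman rank-correlation test with mid-ranks for ties.

    Exact permutation null for n <= ``exact_max_n``; t-approximation
    otherwise. Constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ParameterError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        obs = float((rx_c * ry_c).sum())
        stats = rx_c[perms] @ ry_c
        p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
        return rho, min(p, 1.0)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def correlation_network(
    features: pd.DataFrame,
    descriptor_class: str,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> nx.Graph:
    """Significant-correlation graph over structures for one descriptor class.

    Every unordered structure pair is tested with the two-sided Spearman test
    on pairwise-complete observations of the ``<structure>__<class>``
    columns; p-values are Benjamini-Hochberg adjusted within the class, and
    edges with adjusted p < alpha carry rho, sign and p_adjusted. Structures
    with an all-missing column keep their node but gain no edges.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    suffix = f"__{descriptor_class}"
    cols = [c for c in features.columns if c.endswith(suffix)]
    if not cols:
        raise ParameterError(f"no columns for descriptor class {descriptor_class!r}")
    structures = [c[: -len(suffix)] for c in cols]
    g = nx.Graph(descriptor_class=descriptor_class, alpha=alpha)
    g.add_nodes_from(structures)

    tested: list[tuple[str, str, float, float]] = []
    for (s1, c1), (s2, c2) in itertools.combinations(zip(structures, cols), 2):
        sub = features[[c1, c2]].dropna()
        if len(sub) < min_pairs:
            continue
        rho, p = spearman_test(sub[c1].to_numpy(), sub[c2].to_numpy())
        if math.isnan(rho):
            continue
        tested.append((s1, s2, rho, p))
    if tested:
        p_adj = bh_adjust([t[3] for t in tested])
        for (s1, s2, rho, p), pa in zip(tested, p_adj):
            if pa < alpha:
                g.add_edge(
                    s1, s2, rho=rho, p=p, p_adjusted=float(pa),
                    sign=1 if rho >= 0 else -1, weight=abs(rho),
                )
    return g


def group_tests(
    features: pd.DataFrame,
    y: pd.Series,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Per-descriptor two-group MWW tests with multiplicity correction.

    One test per feature column (structure x descriptor), missing values
    dropped per column; returns a tidy table
    (family, item, stat, p, p_adj, significant).
    """
    rows = []
    groups = sorted(y.dropna().unique())
    if len(groups) != 2:
        raise ParameterError("response must have exactly 2 groups")
    for col in features.columns:
        sub = pd.concat([features[col], y], axis=1).dropna()
        a = sub.loc[sub[y.name] == groups[0], col].to_numpy()
        b = sub.loc[sub[y.name] == groups[1], col].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = mww_test(a, b)
        rows.append({"family": "group_mww", "item": col, "stat": res.u, "p": res.p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    adjuster = {"holm": holm_adjust, "bh": bh_adjust}[adjust]
    out["p_adj"] = adjuster(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < 0.05
    return out


def graph_to_json(g: nx.Graph) -> dict:
    return {
        "descriptor_class": g.graph.get("descriptor_class"),
        "alpha": g.graph.get("alpha"),
        "nodes": sorted(g.nodes),
        "edges": [
            {
                "u": u, "v": v,
                "rho": d["rho"], "p": d["p"], "p_adjusted": d["p_adjusted"],
                "sign": d["sign"],
            }
            for u, v, d in g.edges(data=True)
        ],
    }
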