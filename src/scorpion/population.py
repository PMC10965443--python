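"""Population-level statistics over collections of comparable networks.

Because every per-sample network lives in the same z-score units over the
same TF and gene universes, ordinary statistical machinery applies
directly: paired edge-weight differences between two conditions, per-edge
OLS trends across ordered disease stages, Welch tests on TF targeting
(outdegree) between groups, and preranked gene-set enrichment on
edge-difference rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import Network

__all__ = [
    "degrees",
    "ComparisonResult",
    "compare_networks",
    "edge_trend",
    "tf_association",
    "differential_targeting",
    "EnrichmentResult",
    "preranked_gsea",
]


def _as_frame(net: Network | pd.DataFrame) -> pd.DataFrame:
    if isinstance(net, Network):
        return net.to_frame()
    return net


def degrees(net: Network | pd.DataFrame, mode: str) -> pd.Series:
    """Weighted degrees of a TF x gene network.

    ``indegree``: per-gene column sums (total regulation a gene receives);
    ``outdegree``: per-TF row sums (a TF's total targeting activity).
    """
    frame = _as_frame(net)
    if mode == "indegree":
        return frame.sum(axis=0)
    if mode == "outdegree":
        return frame.sum(axis=1)
    raise ValueError(f"mode must be 'indegree' or 'outdegree', got {mode!r}")


@dataclass
class ComparisonResult:
    """Paired comparison of one TF's edge weights between two networks."""

    tf: str
    genes: np.ndarray
    paired_deltas: np.ndarray  # net_b - net_a on the shared genes
    mean_delta: float
    t_stat: float
    p_value: float
    ci_low: float  # 2.5th percentile of the delta distribution
    ci_high: float  # 97.5th percentile
    outliers_up: list[str] = field(default_factory=list)
    outliers_down: list[str] = field(default_factory=list)
    spearman_rho: float = np.nan
    spearman_p: float = np.nan


def compare_networks(
    net_a: Network | pd.DataFrame,
    net_b: Network | pd.DataFrame,
    tf: str,
) -> ComparisonResult:
    """Paired edge-weight differences for one TF between two conditions.

    Deltas are ``net_b[tf] - net_a[tf]`` on the shared gene set, tested
    against zero with a one-sample two-sided t-test.  The "95% interval"
    for outlier calling is the 2.5–97.5 percentile band of the empirical
    delta distribution: genes strictly above it are ``outliers_up``,
    strictly below are ``outliers_down``.  ``spearman_rho`` is the rank
    correlation between the two TF rows.
    """
    a = _as_frame(net_a)
    b = _as_frame(net_b)
    for name, frame in (("first", a), ("second", b)):
        if tf not in frame.index:
            raise ValueError(f"TF {tf!r} absent from the {name} network")
    shared = a.columns.intersection(b.columns)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared genes between the networks; need >= 3"
        )
    wa = a.loc[tf, shared].to_numpy(dtype=float)
    wb = b.loc[tf, shared].to_numpy(dtype=float)
    deltas = wb - wa

    if np.allclose(deltas.std(), 0.0):
        # zero-variance deltas: no evidence against the null
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = scipy.stats.ttest_1samp(deltas, 0.0)
    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    up = deltas > ci_high
    down = deltas < ci_low

    if np.array_equal(wa, wb):
        rho, rho_p = 1.0, 0.0
    elif wa.std() == 0 or wb.std() == 0:
        rho, rho_p = 0.0, 1.0  # rank correlation undefined for a constant row
    else:
        rho, rho_p = scipy.stats.spearmanr(wa, wb)
    return ComparisonResult(
        tf=tf,
        genes=shared.to_numpy(dtype=object),
        paired_deltas=deltas,
        mean_delta=float(deltas.mean()),
        t_stat=float(t_stat),
        p_value=float(p_value),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        outliers_up=list(shared[up]),
        outliers_down=list(shared[down]),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )


def _shared_universe(frames: list[pd.DataFrame]) -> tuple[pd.Index, pd.Index]:
    tfs = frames[0].index
    genes = frames[0].columns
    for frame in frames[1:]:
        tfs = tfs.intersection(frame.index)
        genes = genes.intersection(frame.columns)
    if len(tfs) == 0 or len(genes) == 0:
        raise ValueError("networks share no common TF x gene universe")
    return tfs, genes


def edge_trend(
    networks: list[Network | pd.DataFrame],
    stage_codes: np.ndarray,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-edge OLS of weight on an ordered stage code.

    Each shared edge's weights across the network collection are regressed
    on the integer stage codes (e.g. healthy=1, border=2, core=3,
    metastasis=4).  The slope beta is the average rate of change per
    stage; its significance comes from the regression F-test, and p-values
    are BH-adjusted across all edges jointly.  A zero-variance edge gets
    beta=0, p=1 (no-evidence convention).

    Returns a DataFrame with columns tf, gene, beta, intercept, p_value,
    fdr, significant.
    """
    if len(networks) < 3:
        raise ValueError("need >= 3 networks for a trend")
    x = np.asarray(stage_codes, dtype=float)
    if len(x) != len(networks):
        raise ValueError("stage_codes must align with networks")
    if len(np.unique(x)) < 2:
        raise ValueError("all networks are at a single stage")

    frames = [_as_frame(net) for net in networks]
    tfs, genes = _shared_universe(frames)
    # edges x samples response matrix
    Y = np.stack(
        [f.loc[tfs, genes].to_numpy(dtype=float).ravel() for f in frames], axis=1
    )
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    y_mean = Y.mean(axis=1)
    beta = (Y @ xc) / sxx
    intercept = y_mean - beta * x.mean()
    fitted = intercept[:, None] + beta[:, None] * x[None, :]
    sse = ((Y - fitted) ** 2).sum(axis=1)
    sst = ((Y - y_mean[:, None]) ** 2).sum(axis=1)

    p = np.ones(len(beta))
    nonzero = sst > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (sst[nonzero] - sse[nonzero]) / (sse[nonzero] / (n - 2))
    p[nonzero] = scipy.stats.f.sf(f_stat, 1, n - 2)
    beta[~nonzero] = 0.0

    fdr = multipletests(p, method="fdr_bh")[1]
    tf_col = np.repeat(tfs.to_numpy(dtype=object), len(genes))
    gene_col = np.tile(genes.to_numpy(dtype=object), len(tfs))
    return pd.DataFrame(
        {
            "tf": tf_col,
            "gene": gene_col,
            "beta": beta,
            "intercept": intercept,
            "p_value": p,
            "fdr": fdr,
            "significant": (np.abs(beta) > 0) & (fdr < fdr_threshold),
        }
    )


def tf_association(
    trend: pd.DataFrame, significant_only: bool = False
) -> pd.Series:
    """Per-TF overall association: the (outdegree) sum of its edge betas.

    With ``significant_only`` the sum is restricted to BH-significant
    edges; the default sums all edges.
    """
    table = trend
    if significant_only:
        table = trend[trend["significant"]]
    sums = table.groupby("tf", sort=True)["beta"].sum()
    return sums.reindex(sorted(trend["tf"].unique()), fill_value=0.0)


def differential_targeting(
    nets_group_a: list[Network | pd.DataFrame],
    nets_group_b: list[Network | pd.DataFrame],
) -> pd.DataFrame:
    """Welch t-test per TF on outdegrees between two groups of networks.

    Direction is the sign of ``mean(group_b) - mean(group_a)``; p-values
    are BH-adjusted across TFs.
    """
    if len(nets_group_a) < 2 or len(nets_group_b) < 2:
        raise ValueError("each group needs >= 2 networks")
    frames_a = [_as_frame(n) for n in nets_group_a]
    frames_b = [_as_frame(n) for n in nets_group_b]
    tfs = frames_a[0].index
    for frame in frames_a[1:] + frames_b:
        tfs = tfs.intersection(frame.index)
    if len(tfs) == 0:
        raise ValueError("no shared TFs between the groups")
    out_a = np.stack([degrees(f, "outdegree").loc[tfs].to_numpy() for f in frames_a])
    out_b = np.stack([degrees(f, "outdegree").loc[tfs].to_numpy() for f in frames_b])

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = scipy.stats.ttest_ind(out_b, out_a, axis=0, equal_var=False)
    diff = out_b.mean(axis=0) - out_a.mean(axis=0)
    # identical zero-variance groups give nan: no evidence
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "tf": tfs.to_numpy(dtype=object),
            "mean_diff": diff,
            "t_stat": t_stat,
            "p_value": p,
            "fdr": fdr,
            "direction": np.sign(diff).astype(int),
        }
    )
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Preranked GSEA result for one gene set."""

    set_name: str
    es: float
    nes: float
    p_value: float
    p_adj: float
    n_members: int
    leading_edge: list[str] = field(default_factory=list)


def _running_sum_es(
    in_set: np.ndarray, weights: np.ndarray, decrement: float
) -> tuple[float, int]:
    """Signed enrichment score and extremum index of the running sum."""
    norm = weights[in_set].sum()
    steps = np.where(in_set, 0.0, -decrement)
    if norm > 0:
        steps = np.where(in_set, weights / norm, steps)
    else:  # all in-set weights zero: uniform positive steps
        steps = np.where(in_set, 1.0 / in_set.sum(), steps)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> list[EnrichmentResult]:
    """Weighted Kolmogorov–Smirnov enrichment over a ranked gene list.

    The ranking (e.g. paired edge-weight differences for one TF) is sorted
    descending; a running sum increments by |score| (weight exponent 1,
    normalized within the set) at set members and decrements uniformly
    elsewhere.  The enrichment score ES is the signed extremum.  The null
    is gene-label permutation: random same-size sets drawn from the
    ranking.  NES divides ES by the mean |ES| of same-sign permutations;
    the p-value is the two-sided empirical tail on |ES|, BH-adjusted
    across the collection.  Sets with fewer than ``min_size`` ranked
    members are skipped with a warning.
    """
    if len(ranking) < 10:
        raise ValueError("ranking needs >= 10 genes")
    order = np.lexsort((ranking.index.astype(str), -ranking.to_numpy(dtype=float)))
    genes = ranking.index.to_numpy(dtype=object)[order]
    scores = ranking.to_numpy(dtype=float)[order]
    weights = np.abs(scores)
    n = len(genes)
    position = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for name in sorted(gene_sets):
        members = [g for g in set(gene_sets[name]) if g in position]
        m = len(members)
        if m < min_size:
            warnings.warn(
                f"gene set {name!r} has {m} ranked members (< {min_size}); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        if m >= n:
            warnings.warn(
                f"gene set {name!r} covers the whole ranking; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[[position[g] for g in members]] = True
        decrement = 1.0 / (n - m)
        es, idx = _running_sum_es(in_set, weights, decrement)

        # gene-label permutation null, vectorized over permutations
        rand = rng.random((n_perm, n)).argsort(axis=1)[:, :m]
        perm_w = weights[rand]
        norms = perm_w.sum(axis=1)
        steps = np.full((n_perm, n), -decrement)
        safe = norms > 0
        fills = np.where(
            safe[:, None], perm_w / np.where(safe, norms, 1.0)[:, None], 1.0 / m
        )
        np.put_along_axis(steps, rand, fills, axis=1)
        running = np.cumsum(steps, axis=1)
        perm_es = np.take_along_axis(
            running, np.argmax(np.abs(running), axis=1)[:, None], axis=1
        ).ravel()

        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)

        if es >= 0:
            leading = [g for g in genes[: idx + 1] if position[g] < n and in_set[position[g]]]
        else:
            leading = [g for g in genes[idx:] if in_set[position[g]]]
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es,
                nes=float(nes),
                p_value=float(p),
                p_adj=np.nan,
                n_members=m,
                leading_edge=leading,
            )
        )
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    return results
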