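"""Two-group cohort analyses of the signalling entropy rate.

A cohort is a genes x samples expression matrix with a binary group label
per sample (A = "normal", B = "cancer").  The analyses here quantify the
entropy-rate contrast between groups, decompose it into per-gene
differentials of the walk's components (expression, local entropy,
stationary mass, local entropy rate) as a function of node degree, and
provide the hub-centric statistics: the degree>316 hub-vs-leaf
expression-skew test, the rank correlation between differential expression
and degree, and the neighbour-centile view of a hub's local dominance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .entropy import entropy_rate
from .graphs import Network, NetworkInputError

__all__ = [
    "Cohort",
    "per_sample_entropy",
    "permutation_control",
    "gene_differentials",
    "degree_bin_summary",
    "hub_skew_test",
    "expression_degree_correlation",
    "neighbor_rank_centile",
    "top_k_by_foldchange",
    "CohortEntropy",
    "CohortResults",
]

GROUP_A = "A"
GROUP_B = "B"

# log10-spaced degree-bin edges; 10^2.5 ~ 316 reproduces the hub cut
DEGREE_BIN_EDGES = 10.0 ** np.arange(0, 4.5, 0.5)


@dataclass(frozen=True)
class Cohort:
    """Expression matrix (genes x samples) plus an A/B group label per sample."""

    expression: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        groups = self.groups.reindex(self.expression.columns)
        if groups.isna().any():
            missing = groups.index[groups.isna()][0]
            raise NetworkInputError(f"no group label for sample {missing!r}")
        bad = set(groups.unique()) - {GROUP_A, GROUP_B}
        if bad:
            raise NetworkInputError(f"group labels must be 'A'/'B', got {bad}")
        for g in (GROUP_A, GROUP_B):
            if (groups == g).sum() < 2:
                raise NetworkInputError(f"group {g!r} needs at least 2 samples")
        object.__setattr__(self, "groups", groups)

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def align(self, net: Network) -> tuple[Network, "Cohort"]:
        """Intersect genes with the network (largest connected component)."""
        from .entropy import align_expression

        sub, expr = align_expression(net, self.expression)
        return sub, Cohort(expr, self.groups)


def _states(cohort: Cohort, net: Network):
    expr = cohort.expression.loc[list(net.node_ids)]
    return {
        s: entropy_rate(net, expr[s].to_numpy(), sample_id=s)
        for s in expr.columns
    }


def per_sample_entropy(cohort: Cohort, net: Network) -> tuple[pd.DataFrame, dict]:
    """Entropy rate per sample and the one-tailed rank-sum test B > A.

    Returns (frame with columns group and SR, stats dict with the
    Mann-Whitney/Wilcoxon one-tailed p-value, the AUC of SR as a score for
    group B, and group medians).
    """
    states = _states(cohort, net)
    df = pd.DataFrame(
        {
            "group": cohort.groups,
            "SR": [states[s].SR for s in cohort.groups.index],
        },
        index=cohort.groups.index,
    )
    stats = sr_group_test(df)
    return df, stats


def sr_group_test(sr_frame: pd.DataFrame) -> dict:
    """One-tailed Wilcoxon rank-sum (B > A) and the equivalent AUC."""
    a = sr_frame.loc[sr_frame.group == GROUP_A, "SR"].to_numpy()
    b = sr_frame.loc[sr_frame.group == GROUP_B, "SR"].to_numpy()
    U, p = st.mannwhitneyu(b, a, alternative="greater")
    return {
        "p_value": float(p),
        "auc": float(U / (len(a) * len(b))),
        "median_A": float(np.median(a)),
        "median_B": float(np.median(b)),
        "n_A": int(len(a)),
        "n_B": int(len(b)),
    }


def permutation_control(
    cohort: Cohort, net: Network, seed: int, shared: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Per-sample SR after permuting expression profiles over the nodes.

    One node relabelling is drawn per seed and applied to every sample
    (``shared=True``, the default), preserving inter-sample structure while
    destroying the placement of expression on the topology.  With
    ``shared=False`` an independent permutation is drawn per sample.
    """
    rng = np.random.default_rng(seed)
    expr = cohort.expression.loc[list(net.node_ids)]
    if shared:
        perm = rng.permutation(net.V)
        permuted = pd.DataFrame(
            expr.to_numpy()[perm], index=expr.index, columns=expr.columns
        )
    else:
        cols = {}
        for s in expr.columns:
            cols[s] = expr[s].to_numpy()[rng.permutation(net.V)]
        permuted = pd.DataFrame(cols, index=expr.index)
    return per_sample_entropy(Cohort(permuted, cohort.groups), net)


def gene_differentials(cohort: Cohort, net: Network) -> pd.DataFrame:
    """Per-gene group-mean differentials of E, LS, pi and LSR (B minus A).

    dLSR decomposes the entropy-rate change gene by gene; dpi sums to zero
    because both stationary distributions normalise.
    """
    states = _states(cohort, net)
    comps = {"E": {}, "LS": {}, "pi": {}, "LSR": {}}
    for s, state in states.items():
        comps["E"][s] = state.expression
        comps["LS"][s] = state.LS
        comps["pi"][s] = state.pi
        comps["LSR"][s] = state.LSR
    a, b = cohort.samples(GROUP_A), cohort.samples(GROUP_B)
    out = {"degree": net.degrees}
    for name, per_sample in comps.items():
        mat = np.column_stack([per_sample[s] for s in a + b])
        mean_a = mat[:, : len(a)].mean(axis=1)
        mean_b = mat[:, len(a) :].mean(axis=1)
        out[f"d{name}"] = mean_b - mean_a
    df = pd.DataFrame(out, index=pd.Index(list(net.node_ids), name="gene"))
    return df


def degree_bin_summary(differentials: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style summaries of each differential within log10 degree bins."""
    bins = pd.cut(differentials["degree"], DEGREE_BIN_EDGES, include_lowest=True)
    rows = []
    for interval, grp in differentials.groupby(bins, observed=True):
        row = {"bin": str(interval), "k_lo": interval.left, "k_hi": interval.right,
               "n_genes": len(grp)}
        for col in ("dE", "dLS", "dpi", "dLSR"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_median"] = grp[col].median()
            row[f"{col}_q25"] = grp[col].quantile(0.25)
            row[f"{col}_q75"] = grp[col].quantile(0.75)
        rows.append(row)
    return pd.DataFrame(rows)


def hub_skew_test(differentials: pd.DataFrame, hub_threshold: int = 316) -> dict:
    """KS test comparing dE of hubs (degree > threshold) against k = 1 nodes.

    If either stratum is empty at the given threshold, the threshold falls
    back to the top-decile degree with a warning.
    """
    k = differentials["degree"]
    thr = hub_threshold
    hubs = differentials.loc[k > thr, "dE"]
    leaves = differentials.loc[k == 1, "dE"]
    if hubs.empty or leaves.empty:
        thr = int(np.quantile(k, 0.9))
        warnings.warn(
            f"hub threshold {hub_threshold} leaves an empty stratum; "
            f"falling back to top-decile degree {thr}",
            stacklevel=2,
        )
        hubs = differentials.loc[k > thr, "dE"]
        leaves = differentials.loc[k <= max(1, int(np.quantile(k, 0.1))), "dE"]
    if hubs.empty or leaves.empty:
        raise NetworkInputError("empty hub or leaf stratum even after fallback")
    stat, p = st.ks_2samp(hubs, leaves)
    return {
        "ks_statistic": float(stat),
        "p_value": float(p),
        "hub_threshold": int(thr),
        "n_hubs": int(len(hubs)),
        "n_leaves": int(len(leaves)),
        "mean_dE_hubs": float(hubs.mean()),
        "mean_dE_leaves": float(leaves.mean()),
    }


def expression_degree_correlation(differentials: pd.DataFrame) -> dict:
    """Spearman rank correlation between differential expression and degree."""
    if len(differentials) < 10:
        raise NetworkInputError("need at least 10 genes for a rank correlation")
    de, k = differentials["dE"], differentials["degree"]
    if de.nunique() == 1 or k.nunique() == 1:
        raise NetworkInputError("rank correlation undefined for constant input")
    rho, p = st.spearmanr(de, k)
    return {"rho": float(rho), "p_value": float(p)}


def neighbor_rank_centile(
    net: Network,
    differentials: pd.DataFrame,
    hub: str,
    top_centile: float = 0.02,
) -> dict:
    """How dominant is a hub in its neighbours' own differential rankings?

    For each neighbour j of the hub, j's neighbours are ranked by dE
    (descending, ties broken by node id); the hub's centile is
    rank/|N(j)|.  Returns the fraction of neighbours for which the hub
    falls within the top centile.
    """
    nbrs = net.neighbors(hub)
    if not nbrs:
        raise NetworkInputError(f"{hub!r} has no neighbours")
    de = differentials["dE"]
    hits = 0
    centiles = {}
    for j in nbrs:
        ranked = sorted(net.neighbors(j), key=lambda n: (-de[n], n))
        centile = (ranked.index(hub) + 1) / len(ranked)
        centiles[j] = centile
        if centile <= top_centile:
            hits += 1
    return {
        "hub": hub,
        "n_neighbors": len(nbrs),
        "fraction_top_centile": hits / len(nbrs),
        "top_centile": top_centile,
        "centiles": centiles,
    }


def top_k_by_foldchange(cohort: Cohort, k: int = 100) -> pd.DataFrame:
    """Top-k genes by absolute group-mean difference.

    On a log-like expression scale the mean difference is the log
    fold-change, so |dE| ranks by fold-change magnitude.  Ties (including
    the all-zero case of identical groups) fall back to gene-id order.
    """
    if k > len(cohort.expression):
        raise NetworkInputError(f"k={k} exceeds gene count {len(cohort.expression)}")
    a, b = cohort.samples(GROUP_A), cohort.samples(GROUP_B)
    de = cohort.expression[b].mean(axis=1) - cohort.expression[a].mean(axis=1)
    df = pd.DataFrame({"dE": de, "abs_dE": de.abs()})
    # stable sort on a lexicographically pre-sorted index makes ties id-ordered
    df = df.sort_index().sort_values("abs_dE", ascending=False, kind="stable")
    return df.head(k).drop(columns="abs_dE")


class CohortEntropy:
    """Model: entropy-rate contrast of a two-group cohort on a network.

    ``fit()`` aligns the cohort to the network, computes every sample's
    entropy state and returns a :class:`CohortResults` carrying the
    per-sample rates, the rank-sum test, the per-gene differentials and the
    hub statistics.
    """

    def __init__(self, network: Network, cohort: Cohort):
        self.network, self.cohort = cohort.align(network)

    @classmethod
    def from_dataframe(
        cls, network: Network, expression: pd.DataFrame, groups: pd.Series
    ) -> "CohortEntropy":
        return cls(network, Cohort(expression, groups))

    def fit(self) -> "CohortResults":
        sr, stats = per_sample_entropy(self.cohort, self.network)
        diffs = gene_differentials(self.cohort, self.network)
        return CohortResults(self, sr, stats, diffs)


class CohortResults:
    def __init__(self, model, sr_frame, test, differentials):
        self.model = model
        self.sr = sr_frame
        self.test = test
        self.differentials = differentials

    def hub_skew(self, hub_threshold: int = 316) -> dict:
        return hub_skew_test(self.differentials, hub_threshold)

    def degree_correlation(self) -> dict:
        return expression_degree_correlation(self.differentials)

    def degree_bins(self) -> pd.DataFrame:
        return degree_bin_summary(self.differentials)

    def permutation_control(self, seed: int, shared: bool = True):
        return permutation_control(self.model.cohort, self.model.network, seed, shared)

    def top_hub(self) -> str:
        """Gene with the largest increase in local entropy rate."""
        return str(self.differentials["dLSR"].idxmax())

    def summary(self) -> str:
        t = self.test
        rho = self.degree_correlation()
        lines = [
            "Cohort signalling-entropy contrast (B vs A)",
            "=" * 46,
            f"network:        V={self.model.network.V}, "
            f"<k>={self.model.network.mean_degree:.3f}",
            f"samples:        {t['n_A']} A, {t['n_B']} B",
            f"median SR A:    {t['median_A']:.6f}",
            f"median SR B:    {t['median_B']:.6f}",
            f"one-tailed p:   {t['p_value']:.3g}  (Wilcoxon rank-sum, B > A)",
            f"AUC (SR -> B):  {t['auc']:.4f}",
            f"Spearman(dE,k): {rho['rho']:.4f}  (p={rho['p_value']:.3g})",
        ]
        return "\n".join(lines)
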