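"""Correlation of turnover scores with environmental parameters.

With only a handful of seasonal samples, parametric p-values for
Pearson correlations are not meaningful, so strong correlations are
called against an empirical null built by randomized re-sampling:
repeatedly draw one series from each table, destroy their pairing by
permuting one series' sample order, and record the PCC. An observed PCC
at or beyond the null's 5th/95th percentile is a *strong* correlation.
Spearman's rank correlation is deliberately not offered: with three
samples rho takes only six values, too granular to interpret.

A cumulative-normal band probability quantifies how unlikely it is that
k observed correlations all fall inside a band [lo, hi], assuming
PCCs follow the normal distribution fitted to the null. No
multiple-testing correction is applied — the percentile call itself is
the (informal) confidence device, by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .emm import MetabolicNetwork

logger = logging.getLogger(__name__)

PARAMETER_CLASSES = (
    "environmental-metabolite",
    "taxon-abundance",
    "subsystem-abundance",
)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two series plus its null context."""

    a_id: str
    b_id: str
    pcc: float
    percentile: float | None = None
    strong: bool | None = None

    @property
    def sign(self) -> str:
        return "pos" if self.pcc >= 0 else "neg"


@dataclass(frozen=True)
class NullDistribution:
    """Sorted PCC values from randomized re-sampling."""

    values: np.ndarray
    iterations: int
    seed: int

    def thresholds(self, lower: float = 5.0, upper: float = 95.0) -> tuple[float, float]:
        # linear interpolation between order statistics, the numpy default
        lo, hi = np.percentile(self.values, [lower, upper])
        return float(lo), float(hi)


@dataclass
class SubnetworkSet:
    """Per-phylum connected subnetworks of co-correlated metabolites."""

    #: phylum -> list of (node set, edge list), sorted by size descending
    components: dict[str, list[tuple[set[str], list[tuple[str, str, str, str]]]]]


def log_relative_abundance(
    params: pd.DataFrame, pseudocount: float | str | None = None
) -> pd.DataFrame:
    """log2 of each measurement relative to its across-sample mean.

    Rows are parameters, columns samples. Values must be positive;
    with ``pseudocount="auto"`` a pseudocount of half the smallest
    positive observed value is added to any series containing
    non-positive entries (loud warning), with a float the given value
    is used. The transformed series is not re-centered: the mean of
    log-ratios is not zero in general.
    """
    values = params.astype(float).copy()
    nonpos = values <= 0
    if nonpos.any().any():
        if pseudocount is None:
            col = nonpos.any(axis=0).idxmax()
            row = nonpos[col].idxmax()
            raise ValueError(
                f"non-positive measurement for parameter {row!r} in sample "
                f"{col!r}; enable a pseudocount to proceed"
            )
        if pseudocount == "auto":
            positive = values.to_numpy()[values.to_numpy() > 0]
            eps = 0.5 * positive.min() if positive.size else 1.0
        else:
            eps = float(pseudocount)
        rows = values.index[nonpos.any(axis=1)]
        values.loc[rows] = values.loc[rows] + eps
        logger.warning(
            "added pseudocount %g to %d series with non-positive values",
            eps,
            len(rows),
        )
    return np.log2(values.div(values.mean(axis=1), axis=0))


def pearson(a, b) -> float:
    """Product-moment correlation; NaN signals a degenerate (zero-variance) pair."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.debug("zero-variance series in correlation; returning NaN")
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def correlate_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> list[CorrelationResult]:
    """All pairwise PCCs between rows of two aligned tables.

    Degenerate (zero-variance) series yield NaN results, which
    ``classify_strong`` never flags and network builders skip.
    """
    common = table_a.columns.intersection(table_b.columns)
    if len(common) < 3:
        raise ValueError("tables share fewer than 3 samples")
    a = table_a[common]
    b = table_b[common]
    out = []
    for ia in a.index:
        for ib in b.index:
            out.append(CorrelationResult(ia, ib, pearson(a.loc[ia], b.loc[ib])))
    return out


def build_null(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    iterations: int = 10_000,
    seed: int = 0,
    max_retries: int = 100,
) -> NullDistribution:
    """Randomized re-sampling null distribution of PCC values.

    Each iteration draws one series uniformly from each table and
    permutes one series' sample order uniformly over permutations
    before correlating, preserving the marginal distributions while
    destroying the pairing. Deterministic given ``seed``. Degenerate
    draws are redrawn up to ``max_retries`` times.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    common = set_a.columns.intersection(set_b.columns)
    if len(common) < 3:
        raise ValueError("tables share fewer than 3 samples")
    a = set_a[common].to_numpy(dtype=float)
    b = set_b[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    values = np.empty(iterations)
    for it in range(iterations):
        for attempt in range(max_retries):
            row_a = a[rng.integers(len(a))]
            row_b = b[rng.integers(len(b))][rng.permutation(len(common))]
            if np.ptp(row_a) > 0 and np.ptp(row_b) > 0:
                values[it] = stats.pearsonr(row_a, row_b).statistic
                break
        else:
            raise RuntimeError(
                f"could not draw a non-degenerate pair in {max_retries} tries"
            )
    values.sort()
    return NullDistribution(values=values, iterations=iterations, seed=seed)


def classify_strong(
    observed: list[CorrelationResult], null: NullDistribution
) -> list[CorrelationResult]:
    """Flag observed correlations at or beyond the null 5th/95th percentiles.

    Thresholds use the linear-interpolation percentile convention and
    the boundary is inclusive: a PCC exactly at a threshold is strong.
    NaN (degenerate) correlations are never strong.
    """
    if null.values.size == 0:
        raise ValueError("null distribution is empty")
    lo, hi = null.thresholds()
    out = []
    for res in observed:
        if np.isnan(res.pcc):
            out.append(replace(res, percentile=float("nan"), strong=False))
            continue
        pct = 100.0 * np.searchsorted(null.values, res.pcc, side="right") / null.values.size
        out.append(replace(res, percentile=pct, strong=res.pcc <= lo or res.pcc >= hi))
    return out


def joint_band_probability(
    observed_pccs: list[float],
    band: tuple[float, float],
    reference: NullDistribution,
) -> float:
    """P(all k observed PCCs fall in [lo, hi]) under a fitted normal.

    A normal is fitted to the reference distribution (sample mean and
    sample standard deviation); the per-correlation band mass
    Phi((hi-mu)/sigma) - Phi((lo-mu)/sigma) is raised to the number of
    observed correlations. An empty observation list gives 1.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    mu = float(np.mean(reference.values))
    sigma = float(np.std(reference.values, ddof=1))
    if sigma == 0:
        raise ValueError("reference distribution is degenerate (sd = 0)")
    p_one = float(stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma))
    return p_one ** len(observed_pccs)


def extract_correlated_subnetworks(
    net: MetabolicNetwork, strong_by_phylum: dict[str, set[str]]
) -> SubnetworkSet:
    """Connected subnetworks whose metabolites all track one phylum.

    For each phylum, keep exactly the network edges joining two
    metabolites both strongly correlated with that phylum's abundance,
    then split into connected components (sorted by size descending).
    Connected components imply partial or complete pathways rather than
    isolated metabolites. Flagged ids absent from the network are logged.
    """
    out: dict[str, list[tuple[set[str], list[tuple[str, str, str, str]]]]] = {}
    for phylum, flagged in strong_by_phylum.items():
        unknown = flagged - net.nodes
        if unknown:
            logger.info(
                "phylum %s: %d flagged metabolites not in network", phylum, len(unknown)
            )
        keep = [e for e in net.edges if e[0] in flagged and e[1] in flagged]
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b, _, _ in keep)
        comps = []
        for comp in nx.connected_components(g):
            comp_edges = [e for e in keep if e[0] in comp]
            comps.append((set(comp), comp_edges))
        comps.sort(key=lambda c: (len(c[0]), len(c[1])), reverse=True)
        out[phylum] = comps
    return SubnetworkSet(components=out)


def build_correlation_network(
    flagged: list[CorrelationResult], node_classes: dict[str, str] | None = None
) -> nx.Graph:
    """Undirected graph of strong correlations.

    Nodes are measurements typed via ``node_classes`` (e.g. a Table-1
    style environmental metabolite, a taxon abundance, a SEED-subsystem
    abundance, or a scored metabolite); each strong correlation becomes
    one edge carrying its sign and PCC. Duplicate (A,B)/(B,A) pairs
    collapse to a single edge.
    """
    node_classes = node_classes or {}
    g = nx.Graph()
    for res in flagged:
        if not res.strong or np.isnan(res.pcc):
            continue
        for node in (res.a_id, res.b_id):
            if node not in g:
                g.add_node(node, type=node_classes.get(node, "unknown"))
        g.add_edge(res.a_id, res.b_id, sign=res.sign, pcc=res.pcc)
    return g
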