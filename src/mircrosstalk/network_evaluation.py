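"""Topology, expression-based quality evaluation, stress and climate tests.

Topology: node degree and unnormalized shortest-path betweenness (fractional
counting over equally short paths, the standard convention), with hubs /
bottlenecks / bridges defined as the descending top ceil(15% * N) elements
extended through value ties, and the four hub/bottleneck node classes.

Expression: replicate-averaged, log2-transformed miRNA abundance profiles
(zeros are treated as missing, matching presence/absence semantics); miRNAs
quantified in fewer than 6 samples are dropped.  Pairwise Pearson
correlations over common samples feed the coreg threshold sweep, which
partitions shared-target miRNA pairs into "final" (>=1 surviving target)
and "deleted" (all targets removed) sets at each threshold.

Stress sharing: the fraction of network edges whose endpoints respond to at
least one common stress type, with an empirical p from uniformly sampled
same-size pair sets.  Climate: a group of ecotypes shares a climatic
variable when its standard deviation is small compared with same-size
random ecotype groups (empirical p = fraction of permutations with a
strictly smaller SD; zero is a legal p-value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .crosstalk_network import build_network
from .fate_engine import FateProfile, RegulationKey
from .stats_enrichment import bh_adjust

logger = logging.getLogger(__name__)

#: Bioclimatic variables used by default in climate analyses.
DEFAULT_CLIMATE_VARIABLES = (
    "temperature_seasonality",
    "max_temp_warmest_month",
    "mean_temp_wettest_quarter",
    "mean_temp_coldest_quarter",
    "precip_wettest_month",
    "precip_driest_month",
    "precip_seasonality",
)


# ------------------------------------------------------------------ topology

@dataclass
class TopologyReport:
    degree: Dict[str, int]
    node_betweenness: Dict[str, float]
    edge_betweenness: Dict[FrozenSet[str], float]
    hubs: Set[str]
    bottlenecks: Set[str]
    bridges: Set[FrozenSet[str]]
    node_class: Dict[str, str]


def _top_fraction(values: Mapping, fraction: float) -> set:
    """Keys ranked in the descending top ceil(fraction*N), ties extended."""
    if not values:
        return set()
    n_top = math.ceil(fraction * len(values))
    ranked = sorted(values.items(), key=lambda kv: -kv[1])
    cut = ranked[n_top - 1][1]
    return {k for k, v in values.items() if v >= cut}


def topology(graph: nx.Graph, percentile: float = 0.15) -> TopologyReport:
    """Degree/betweenness report with hub, bottleneck and bridge flags."""
    if graph.number_of_nodes() == 0:
        raise ValueError("topology of an empty graph is undefined")
    degree = dict(graph.degree())
    node_bt = nx.betweenness_centrality(graph, normalized=False)
    edge_bt = {
        frozenset(e): v
        for e, v in nx.edge_betweenness_centrality(graph, normalized=False).items()
    }
    hubs = _top_fraction(degree, percentile)
    bottlenecks = _top_fraction(node_bt, percentile)
    bridges = _top_fraction(edge_bt, percentile)
    node_class = {}
    for n in graph.nodes:
        h = n in hubs
        b = n in bottlenecks
        node_class[n] = (
            "hub-bottleneck"
            if h and b
            else "hub-nonbottleneck"
            if h
            else "nonhub-bottleneck"
            if b
            else "nonhub-nonbottleneck"
        )
    return TopologyReport(
        degree=degree,
        node_betweenness=node_bt,
        edge_betweenness=edge_bt,
        hubs=hubs,
        bottlenecks=bottlenecks,
        bridges=bridges,
        node_class=node_class,
    )


def write_topology_tsv(report: TopologyReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tdegree\tbetweenness\thub\tbottleneck\tnode_class\n")
        for n in sorted(report.degree):
            fh.write(
                f"{n}\t{report.degree[n]}\t{report.node_betweenness[n]:.6g}\t"
                f"{int(n in report.hubs)}\t{int(n in report.bottlenecks)}\t"
                f"{report.node_class[n]}\n"
            )


# ---------------------------------------------------------------- expression

def preprocess_expression(raw: pd.DataFrame, min_samples: int = 6) -> pd.DataFrame:
    """miRNA x sample matrix of replicate-averaged log2 abundances.

    *raw* is long-form with columns mirna, sample, value (several rows per
    (mirna, sample) are replicates and are averaged before the log).  Zero
    abundance is treated as not-quantified; miRNAs with values in fewer than
    *min_samples* samples are removed.
    """
    required = {"mirna", "sample", "value"}
    if not required <= set(raw.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if (raw["value"] < 0).any():
        raise ValueError("negative abundance values")
    mean = raw.groupby(["mirna", "sample"])["value"].mean().unstack("sample")
    mean = mean.where(mean > 0)  # zeros -> missing
    logged = np.log2(mean)
    keep = logged.notna().sum(axis=1) >= min_samples
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d miRNAs quantified in <%d samples", dropped, min_samples)
    return logged.loc[keep]


def pair_correlations(
    matrix: pd.DataFrame,
    pairs: Iterable[Tuple[str, str]],
    min_common: int = 3,
) -> pd.DataFrame:
    """Pearson r over common samples for each miRNA pair, with BH-adjusted p."""
    rows = []
    for i, j in pairs:
        if i not in matrix.index or j not in matrix.index:
            logger.warning("pair (%s, %s): missing expression profile; skipped", i, j)
            continue
        xi, xj = matrix.loc[i], matrix.loc[j]
        common = xi.notna() & xj.notna()
        n = int(common.sum())
        if n < min_common:
            logger.warning("pair (%s, %s): only %d common samples; skipped", i, j, n)
            continue
        a, b = xi[common], xj[common]
        if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
            r, p = math.nan, 1.0
        else:
            r, p = stats.pearsonr(a, b)
        rows.append({"mirna_i": i, "mirna_j": j, "n": n, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows, columns=["mirna_i", "mirna_j", "n", "r", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    else:
        df["p_adj"] = []
    return df


def threshold_sweep(
    profiles: Mapping[RegulationKey, FateProfile],
    matrix: pd.DataFrame,
    grid: Sequence[float],
    mode: str = "extended",
) -> pd.DataFrame:
    """Mean expression correlation of final vs deleted pairs per threshold.

    At each coreg threshold, miRNA pairs sharing >=1 target split into the
    "final" pairs (some target survives) and the "deleted" pairs (all
    removed); the mean pairwise Pearson r of each set is reported (nan when
    a set is empty).
    """
    # correlations are threshold-independent; compute once on the universe
    universe = build_network(profiles, threshold=0.0, mode=mode)
    all_pairs = sorted(tuple(sorted(p)) for p in universe.unfiltered_pairs)
    corr = pair_correlations(matrix, all_pairs)
    r_of = {
        frozenset((row.mirna_i, row.mirna_j)): row.r for row in corr.itertuples()
    }
    rows = []
    for thr in grid:
        net = build_network(profiles, threshold=thr, mode=mode)
        final_r = [r_of[p] for p in net.edges if p in r_of]
        deleted_r = [r_of[p] for p in net.deleted_pairs if p in r_of]
        rows.append(
            {
                "threshold": thr,
                "mean_r_final": float(np.nanmean(final_r)) if final_r else math.nan,
                "mean_r_deleted": float(np.nanmean(deleted_r)) if deleted_r else math.nan,
                "n_final_pairs": len(net.edges),
                "n_deleted_pairs": len(net.deleted_pairs),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- stress test

def stress_share_fraction(
    pairs: Iterable[Tuple[str, str]], stress_table: Mapping[str, Set[str]]
) -> float:
    pairs = list(pairs)
    if not pairs:
        return math.nan
    shared = sum(
        1
        for i, j in pairs
        if stress_table.get(i, set()) & stress_table.get(j, set())
    )
    return shared / len(pairs)


def stress_share_test(
    edges: Iterable[Tuple[str, str]],
    stress_table: Mapping[str, Set[str]],
    universe: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """(fraction of edges sharing >=1 stress type, empirical p).

    The null draws the same number of unordered miRNA pairs uniformly from
    the all-pairs universe (default: the edge endpoints); p is the fraction
    of permutations whose sharing fraction reaches the observed one.
    """
    edges = [tuple(e) for e in edges]
    if rng is None:
        rng = np.random.default_rng()
    observed = stress_share_fraction(edges, stress_table)
    if math.isnan(observed) or observed == 0.0:
        return (0.0 if edges else math.nan), 1.0
    if universe is None:
        universe = sorted({n for e in edges for n in e})
    universe = list(universe)
    n_nodes = len(universe)
    has = np.array(
        [1 if stress_table.get(n) else 0 for n in universe], dtype=bool
    )
    k = len(edges)
    count = 0
    for _ in range(n_perm):
        ii = rng.integers(0, n_nodes, size=k)
        jj = rng.integers(0, n_nodes - 1, size=k)
        jj = np.where(jj >= ii, jj + 1, jj)  # uniform pairs without self-pairs
        frac = (
            sum(
                1
                for a, b in zip(ii, jj)
                if has[a]
                and has[b]
                and stress_table[universe[a]] & stress_table[universe[b]]
            )
            / k
        )
        if frac >= observed:
            count += 1
    return observed, count / n_perm


# -------------------------------------------------------------- climate test

@dataclass
class ClimateTestResult:
    group_label: str
    variable: str
    group: FrozenSet[str]
    sd_observed: float
    p_empirical: float
    p_adj: float = math.nan


def climate_sd_test(
    group: Iterable[str],
    climate_table: pd.DataFrame,
    variable: str,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    group_label: str = "group",
) -> ClimateTestResult:
    """Is a group of ecotypes climatically tighter than random same-size groups?

    p_empirical is the fraction of uniform same-size ecotype samples whose
    SD of *variable* is strictly smaller than the group's.
    """
    group = sorted(set(group))
    if len(group) < 2:
        raise ValueError("climate test needs a group of >=2 ecotypes")
    if variable not in climate_table.columns:
        raise ValueError(f"variable {variable!r} not in climate table")
    if rng is None:
        rng = np.random.default_rng()
    values = climate_table[variable]
    sd_obs = float(values.loc[group].std(ddof=1))
    pool = values.to_numpy(dtype=float)
    k = len(group)
    sds = np.empty(n_perm)
    for r in range(n_perm):
        pick = rng.choice(pool.shape[0], size=k, replace=False)
        sds[r] = pool[pick].std(ddof=1)
    p = float(np.mean(sds < sd_obs))
    return ClimateTestResult(
        group_label=group_label,
        variable=variable,
        group=frozenset(group),
        sd_observed=sd_obs,
        p_empirical=p,
    )


def climate_sd_tests(
    groups: Mapping[str, Iterable[str]],
    climate_table: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_CLIMATE_VARIABLES,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> List[ClimateTestResult]:
    """Run the SD test for every (group, variable) with joint BH adjustment."""
    if rng is None:
        rng = np.random.default_rng()
    results = [
        climate_sd_test(
            members, climate_table, var, n_perm=n_perm, rng=rng, group_label=label
        )
        for label, members in groups.items()
        for var in variables
        if var in climate_table.columns
    ]
    if results:
        adjusted = bh_adjust([r.p_empirical for r in results])
        for r, p in zip(results, adjusted):
            r.p_adj = float(p)
    return results


# ----------------------------------------------------- dynamic ecotype groups

def dynamic_ecotype_groups(
    profiles: Mapping[RegulationKey, FateProfile], target: str
) -> Dict[RegulationKey, FrozenSet[str]]:
    """Per dynamic regulation on *target*: its gain (G) or loss (KL) ecotypes."""
    out: Dict[RegulationKey, FrozenSet[str]] = {}
    for key, p in profiles.items():
        if key[1] != target:
            continue
        gf = p.general_fate
        if gf == "G":
            out[key] = frozenset(p.ecotypes_with("g"))
        elif gf == "KL":
            out[key] = frozenset(p.ecotypes_with("l"))
    if not out:
        raise ValueError(f"target {target!r} has no dynamic regulation")
    return out


def group_overlap_summary(
    groups: Mapping[RegulationKey, FrozenSet[str]]
) -> pd.DataFrame:
    """Pairwise Jaccard overlap of the dynamic ecotype groups of one target."""
    keys = sorted(groups)
    rows = []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ga, gb = groups[keys[a]], groups[keys[b]]
            union = len(ga | gb)
            rows.append(
                {
                    "regulation_a": "-".join(keys[a]),
                    "regulation_b": "-".join(keys[b]),
                    "n_a": len(ga),
                    "n_b": len(gb),
                    "n_shared": len(ga & gb),
                    "jaccard": len(ga & gb) / union if union else math.nan,
                }
            )
    return pd.DataFrame(rows)
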