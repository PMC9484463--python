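"""Randomization Z-score enrichment, Fisher tests, and BH correction.

For a category pair (a "cell" of an enrichment matrix) the observed edge
count is compared with its distribution over randomized networks:

    Z = (X_observed - mean(X_rand)) / SD(X_rand)

with a normal-tail p-value (two-sided by default, since both over- and
under-representation are of interest) and Benjamini-Hochberg adjustment
across all cells of one matrix jointly.  Three randomization schemes are
provided:

    fate_shuffle  -- permute edge labels (general fates / crosstalk types)
                     over a fixed topology; the label multiset is preserved
    label_permute -- permute node identifiers over a fixed topology, which
                     preserves the degree sequence and the multiset of node
                     categories (ages, conservation)
    edge_sample   -- per label stratum, draw the same number of edges
                     uniformly without replacement from the whole edge set

All randomness flows through an explicit numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

RANDOMIZATION_SCHEMES = ("fate_shuffle", "label_permute", "edge_sample")


@dataclass(frozen=True)
class EnrichmentCell:
    row_category: str
    col_category: str
    stratum: Optional[str]
    x_observed: int
    rand_mean: float
    rand_sd: float
    z: float  # nan when rand_sd == 0
    p_raw: float
    p_adj: float


def zscore(
    x_obs: float, rand_counts: Sequence[float], two_sided: bool = True
) -> Tuple[float, float]:
    """Z-score of an observed count against its randomized distribution.

    SD is the sample standard deviation (ddof=1).  Degenerate randomizations
    (SD == 0) yield z = nan and the conservative p = 1.
    """
    rand_counts = np.asarray(rand_counts, dtype=float)
    if rand_counts.size == 0:
        raise ValueError("rand_counts must be nonempty")
    mean = float(rand_counts.mean())
    sd = float(rand_counts.std(ddof=1)) if rand_counts.size > 1 else 0.0
    if sd == 0.0:
        return math.nan, 1.0
    z = (x_obs - mean) / sd
    cdf = stats.norm.cdf(z)
    p = 2 * min(cdf, 1 - cdf) if two_sided else 1 - cdf
    return z, min(1.0, float(p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p for a 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# --------------------------------------------------------- randomization ops

def randomize_fate_assignment(
    labels: Sequence[str], rng: np.random.Generator
) -> List[str]:
    """Uniformly permute edge labels; the multiset is preserved."""
    labels = list(labels)
    return [labels[i] for i in rng.permutation(len(labels))]


def randomize_node_labels(
    node_labels: Mapping[str, str], rng: np.random.Generator
) -> Dict[str, str]:
    """Permute node identities over fixed topology (degree + label multiset kept)."""
    nodes = sorted(node_labels)
    values = [node_labels[n] for n in nodes]
    perm = rng.permutation(len(nodes))
    return {nodes[i]: values[perm[i]] for i in range(len(nodes))}


def randomize_edge_sample(
    edges: Sequence[Tuple[str, str]], k: int, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Uniform sample of k edges without replacement."""
    if k > len(edges):
        raise ValueError(f"cannot sample {k} of {len(edges)} edges")
    idx = rng.choice(len(edges), size=k, replace=False)
    return [edges[i] for i in idx]


# ------------------------------------------------------- enrichment matrices

def _cell_layout(
    row_cats: Sequence[str], col_cats: Sequence[str], ordered: bool
) -> Tuple[List[Tuple[str, str]], Dict[Tuple[str, str], int]]:
    if ordered:
        cells = list(product(row_cats, col_cats))
        index = {c: i for i, c in enumerate(cells)}
    else:
        cells = list(combinations_with_replacement(sorted(set(row_cats)), 2))
        index = {}
        for i, (a, b) in enumerate(cells):
            index[(a, b)] = i
            index[(b, a)] = i
    return cells, index


def enrichment_matrix(
    edges: Sequence[Tuple[str, str]],
    row_of: Mapping[str, str],
    col_of: Mapping[str, str],
    scheme: str = "fate_shuffle",
    edge_labels: Optional[Sequence[str]] = None,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    ordered: Optional[bool] = None,
    two_sided: bool = True,
) -> List[EnrichmentCell]:
    """Full Z-score enrichment matrix under one randomization scheme.

    ``row_of``/``col_of`` map edge endpoints to categories; when they are the
    same mapping the matrix is unordered (category pairs are canonical).
    ``edge_labels`` attaches one stratum label per edge (general fate or
    crosstalk type); fate_shuffle and edge_sample require it.  BH adjustment
    spans every emitted cell of the matrix jointly.
    """
    if scheme not in RANDOMIZATION_SCHEMES:
        raise ValueError(f"unknown randomization scheme {scheme!r}")
    if rng is None:
        rng = np.random.default_rng()
    if ordered is None:
        ordered = row_of is not col_of
    edges = list(edges)
    n_edges = len(edges)
    row_cats = sorted(set(row_of.values()))
    col_cats = sorted(set(col_of.values()))
    cells, cell_index = _cell_layout(row_cats, col_cats, ordered)
    n_cells = len(cells)

    edge_cell = np.array(
        [cell_index[(row_of[u], col_of[v])] for u, v in edges], dtype=np.int64
    )

    if scheme in ("fate_shuffle", "edge_sample"):
        if edge_labels is None:
            raise ValueError(f"{scheme} requires edge_labels")
        strata = sorted(set(edge_labels))
        label_idx = {s: i for i, s in enumerate(strata)}
        lab = np.array([label_idx[l] for l in edge_labels], dtype=np.int64)
        n_strata = len(strata)
        flat = lab * n_cells + edge_cell
        observed = np.bincount(flat, minlength=n_strata * n_cells)
        rand = np.empty((n_reps, n_strata * n_cells), dtype=np.int64)
        if scheme == "fate_shuffle":
            for r in range(n_reps):
                perm = rng.permutation(n_edges)
                rand[r] = np.bincount(
                    lab[perm] * n_cells + edge_cell,
                    minlength=n_strata * n_cells,
                )
        else:  # edge_sample
            stratum_sizes = np.bincount(lab, minlength=n_strata)
            for r in range(n_reps):
                row = np.zeros(n_strata * n_cells, dtype=np.int64)
                for s in range(n_strata):
                    k = int(stratum_sizes[s])
                    if k == 0:
                        continue
                    pick = rng.choice(n_edges, size=k, replace=False)
                    row[s * n_cells : (s + 1) * n_cells] = np.bincount(
                        edge_cell[pick], minlength=n_cells
                    )
                rand[r] = row
        return _cells_from_counts(
            cells, strata, observed, rand, n_cells, two_sided
        )

    # label_permute: permute node categories over fixed topology
    nodes = sorted(set(row_of) | set(col_of))
    node_pos = {n: i for i, n in enumerate(nodes)}
    cats = np.array(
        [ (row_of.get(n) if n in row_of else col_of[n]) for n in nodes]
    )
    cat_codes = {c: i for i, c in enumerate(sorted(set(cats)))}
    code_of = np.array([cat_codes[c] for c in cats], dtype=np.int64)
    code_cell = np.full((len(cat_codes), len(cat_codes)), -1, dtype=np.int64)
    for (a, b), i in cell_index.items():
        if a in cat_codes and b in cat_codes:
            code_cell[cat_codes[a], cat_codes[b]] = i
    ui = np.array([node_pos[u] for u, _ in edges], dtype=np.int64)
    vi = np.array([node_pos[v] for _, v in edges], dtype=np.int64)
    observed = np.bincount(edge_cell, minlength=n_cells)
    rand = np.empty((n_reps, n_cells), dtype=np.int64)
    for r in range(n_reps):
        perm_codes = code_of[rng.permutation(len(nodes))]
        rand[r] = np.bincount(
            code_cell[perm_codes[ui], perm_codes[vi]], minlength=n_cells
        )
    return _cells_from_counts(cells, [None], observed, rand, n_cells, two_sided)


def _cells_from_counts(
    cells: List[Tuple[str, str]],
    strata: Sequence[Optional[str]],
    observed: np.ndarray,
    rand: np.ndarray,
    n_cells: int,
    two_sided: bool,
) -> List[EnrichmentCell]:
    out: List[EnrichmentCell] = []
    raw_ps: List[float] = []
    partial = []
    for s_i, stratum in enumerate(strata):
        for c_i, (rcat, ccat) in enumerate(cells):
            flat = s_i * n_cells + c_i
            counts = rand[:, flat]
            z, p = zscore(observed[flat], counts, two_sided=two_sided)
            partial.append(
                (
                    rcat,
                    ccat,
                    stratum,
                    int(observed[flat]),
                    float(counts.mean()),
                    float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
                    z,
                    p,
                )
            )
            raw_ps.append(p)
    adjusted = bh_adjust(raw_ps)
    for row, p_adj in zip(partial, adjusted):
        out.append(EnrichmentCell(*row, p_adj=float(p_adj)))
    return out


def write_enrichment_tsv(cells: Iterable[EnrichmentCell], path) -> None:
    with open(path, "w") as fh:
        fh.write("row\tcol\tstratum\tx_obs\trand_mean\trand_sd\tz\tp_raw\tp_adj\n")
        for c in cells:
            z = "NA" if math.isnan(c.z) else f"{c.z:.4g}"
            fh.write(
                f"{c.row_category}\t{c.col_category}\t{c.stratum or '.'}\t"
                f"{c.x_observed}\t{c.rand_mean:.4g}\t{c.rand_sd:.4g}\t{z}\t"
                f"{c.p_raw:.4g}\t{c.p_adj:.4g}\n"
            )
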