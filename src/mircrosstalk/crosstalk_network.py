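"""Co-regulation scoring and the miRNA-miRNA crosstalk network.

Two miRNAs that share a target form a co-regulation motif whose *coreg*
score is the fraction of the shared ecotype universe in which the two
regulations present the same fate:

    coreg(i,j,t) = (|EcoK| + |EcoL| + |EcoG| [+ |EcoN|]) / |Eco(i,j,t)|

Eco(i,j,t) is the set of ecotypes where miRNA_i, miRNA_j and target_t are
all available (wild- or mutant-type); EcoK/EcoL/EcoG are the ecotypes where
both fates are k / l / g.  Two guard rules prevent coincidental agreement:
when both general fates are KL the motif scores 0 unless the two losses
co-occur in at least one ecotype (EcoL nonempty), and -- in the default
"extended" mode -- when both are G the motif scores 0 unless the two gains
co-occur (EcoG nonempty).

The extended mode also counts joint absence (both fates n, EcoN) as
agreement, so that a pair of regulations gained together in a small ecotype
cluster scores 1 rather than |cluster|/|panel|.  The "literal" mode drops
the EcoN term and the G/G guard.  Joint (o,o) never counts: an ambiguous
detection is not a fate match.

Motifs carry a co-regulation type from the two general fates (ss, sd, dd;
mixed K/G and KL/G combinations can never show per-ecotype fate equality
and are excluded), edges carry a crosstalk type (SS/SD/DD) when a strict
majority of their surviving motifs agree, else "unclassified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .fate_engine import FateProfile, RegulationKey

logger = logging.getLogger(__name__)

COREG_MODES = ("extended", "literal")
DEFAULT_THRESHOLD = 0.85


@dataclass(frozen=True)
class CoregMotif:
    mirna_i: str
    mirna_j: str
    target: str
    coreg: float
    coreg_type: str  # "ss" | "sd" | "dd" | "excluded"
    n_eco: int


@dataclass
class CrosstalkEdge:
    mirna_i: str
    mirna_j: str
    surviving: List[CoregMotif] = field(default_factory=list)

    @property
    def crosstalk_type(self) -> str:
        return crosstalk_type(self)


@dataclass
class CrosstalkNetwork:
    graph: nx.Graph
    threshold: float
    edges: Dict[FrozenSet[str], CrosstalkEdge]
    unfiltered_pairs: Set[FrozenSet[str]]
    deleted_pairs: Set[FrozenSet[str]]
    motifs: List[CoregMotif] = field(default_factory=list)


def shared_targets(
    profiles: Mapping[RegulationKey, FateProfile], mirna_i: str, mirna_j: str
) -> Set[str]:
    """Targets with a fate profile for both miRNAs."""
    if mirna_i == mirna_j:
        raise ValueError("a miRNA does not share targets with itself")
    ti = {t for (m, t) in profiles if m == mirna_i}
    tj = {t for (m, t) in profiles if m == mirna_j}
    return ti & tj


def coreg_score(
    profile_i: FateProfile,
    profile_j: FateProfile,
    mode: str = "extended",
) -> Optional[float]:
    """Co-occurrence score of two regulations toward one target.

    Returns None (motif dropped) when the shared ecotype universe is empty.
    """
    if mode not in COREG_MODES:
        raise ValueError(f"unknown coreg mode {mode!r}")
    if profile_i.transcript_id != profile_j.transcript_id:
        raise ValueError("profiles must reference the same target")
    eco = profile_i.fates.keys() & profile_j.fates.keys()
    if not eco:
        logger.warning(
            "empty ecotype universe for motif (%s, %s, %s); dropped",
            profile_i.mirna_id,
            profile_j.mirna_id,
            profile_i.transcript_id,
        )
        return None
    n_k = n_l = n_g = n_n = 0
    for e in eco:
        fi, fj = profile_i.fates[e], profile_j.fates[e]
        if fi != fj:
            continue
        if fi == "k":
            n_k += 1
        elif fi == "l":
            n_l += 1
        elif fi == "g":
            n_g += 1
        elif fi == "n":
            n_n += 1
    gf_i, gf_j = profile_i.general_fate, profile_j.general_fate
    if gf_i == gf_j == "KL" and n_l == 0:
        return 0.0
    if mode == "extended":
        if gf_i == gf_j == "G" and n_g == 0:
            return 0.0
        numerator = n_k + n_l + n_g + n_n
    else:
        numerator = n_k + n_l + n_g
    return numerator / len(eco)


def motif_coreg_type(general_fate_i: str, general_fate_j: str) -> str:
    """ss/sd/dd label from the two general fates; mixed combos are excluded."""
    pair = frozenset((general_fate_i, general_fate_j))
    if "L" in pair:
        return "excluded"
    if pair == {"K"}:
        return "ss"
    if pair == {"K", "KL"}:
        return "sd"
    if pair == {"KL"} or pair == {"G"}:
        return "dd"
    return "excluded"  # K/G and KL/G can never match per-ecotype fates


def build_network(
    profiles: Mapping[RegulationKey, FateProfile],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "extended",
) -> CrosstalkNetwork:
    """Score all motifs and keep miRNA pairs with >=1 surviving shared target.

    A motif survives when coreg >= threshold (a score exactly at the
    threshold is kept; the filter removes strictly smaller scores).  Also
    records the "unfiltered" pair universe (>=1 shared target) and the
    "deleted" pairs (all shared targets removed) for evaluation.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    by_target: Dict[str, List[FateProfile]] = {}
    for (m, t), p in profiles.items():
        by_target.setdefault(t, []).append(p)

    motifs: List[CoregMotif] = []
    pair_motifs: Dict[FrozenSet[str], List[CoregMotif]] = {}
    for target, plist in by_target.items():
        plist = sorted(plist, key=lambda p: p.mirna_id)
        for pi, pj in combinations(plist, 2):
            score = coreg_score(pi, pj, mode=mode)
            if score is None:
                continue
            motif = CoregMotif(
                mirna_i=pi.mirna_id,
                mirna_j=pj.mirna_id,
                target=target,
                coreg=score,
                coreg_type=motif_coreg_type(pi.general_fate, pj.general_fate),
                n_eco=len(pi.fates.keys() & pj.fates.keys()),
            )
            motifs.append(motif)
            pair_motifs.setdefault(
                frozenset((pi.mirna_id, pj.mirna_id)), []
            ).append(motif)

    edges: Dict[FrozenSet[str], CrosstalkEdge] = {}
    deleted: Set[FrozenSet[str]] = set()
    graph = nx.Graph()
    for pair, mlist in pair_motifs.items():
        surviving = [m for m in mlist if m.coreg >= threshold]
        i, j = sorted(pair)
        if surviving:
            edge = CrosstalkEdge(mirna_i=i, mirna_j=j, surviving=surviving)
            edges[pair] = edge
            graph.add_edge(
                i,
                j,
                crosstalk_type=edge.crosstalk_type,
                n_targets=len(surviving),
            )
        else:
            deleted.add(pair)
    return CrosstalkNetwork(
        graph=graph,
        threshold=threshold,
        edges=edges,
        unfiltered_pairs=set(pair_motifs),
        deleted_pairs=deleted,
        motifs=motifs,
    )


def crosstalk_type(edge: CrosstalkEdge) -> str:
    """Capitalized co-regulation type held by a strict majority of motifs."""
    if not edge.surviving:
        raise ValueError("edge has no surviving motifs")
    counts: Dict[str, int] = {}
    for m in edge.surviving:
        counts[m.coreg_type] = counts.get(m.coreg_type, 0) + 1
    total = len(edge.surviving)
    for ctype, n in counts.items():
        if ctype != "excluded" and n * 2 > total:
            return ctype.upper()
    return "unclassified"


def write_edges_tsv(network: CrosstalkNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_i\tmirna_j\tcrosstalk_type\tn_targets\n")
        for pair in sorted(network.edges, key=sorted):
            e = network.edges[pair]
            fh.write(
                f"{e.mirna_i}\t{e.mirna_j}\t{e.crosstalk_type}\t{len(e.surviving)}\n"
            )


def write_motifs_tsv(network: CrosstalkNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_i\tmirna_j\ttarget\tcoreg\tcoreg_type\tn_eco\n")
        for m in sorted(
            network.motifs, key=lambda m: (m.mirna_i, m.mirna_j, m.target)
        ):
            fh.write(
                f"{m.mirna_i}\t{m.mirna_j}\t{m.target}\t{m.coreg:.6g}\t"
                f"{m.coreg_type}\t{m.n_eco}\n"
            )


def write_graphml(network: CrosstalkNetwork, path) -> None:
    nx.write_graphml(network.graph, str(path))
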