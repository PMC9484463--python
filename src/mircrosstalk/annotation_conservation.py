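"""Evolutionary ages, conservation labels, and miRNA families.

Genes are dated through ortholog groups: the age of a group (and of its
member genes) is the oldest lineage represented among the members, on an
11-step ladder from Cellular organisms down to Arabidopsis thaliana.  A gene
is conserved when its group has any non-A. thaliana member.

miRNAs are dated through cross-species sequence hits: a miRNA is conserved
when at least one hit passes all of E-value <= 0.01, >= 90% coverage of
both query and subject, and <= 2 mismatches; its age is the oldest passing
subject lineage, clamped at Land plants (no plant miRNA evidence predates
land plants, so older subject lineages are treated as Land plants with a
logged note).

Families with more than half of their members conserved are conserved
families (an exact 50/50 split is non-conserved; the rule is strict).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

#: Oldest -> youngest lineage ladder.
LINEAGE_LADDER: Tuple[str, ...] = (
    "Cellular organisms",
    "Eukaryota",
    "Green plants",
    "Land plants",
    "Vascular plants",
    "Seed plants",
    "Flowering plants",
    "Eudicots",
    "Rosids",
    "Brassicaceae",
    "Arabidopsis thaliana",
)

MIRNA_AGE_FLOOR = "Land plants"


@dataclass(frozen=True)
class OrthoGroup:
    group_id: str
    members: Tuple[Tuple[str, str], ...]  # (gene_id, lineage label)


@dataclass(frozen=True)
class BlastHitRecord:
    query_mirna: str
    subject_mirna: str
    subject_lineage: str
    e_value: float
    query_coverage: float
    subject_coverage: float
    mismatches: int


def _lineage_rank(label: str, ladder: Sequence[str]) -> int:
    try:
        return ladder.index(label)  # type: ignore[union-attr]
    except ValueError:
        raise ValueError(f"unknown lineage label {label!r}") from None


def assign_gene_age(
    group: OrthoGroup, ladder: Sequence[str] = LINEAGE_LADDER
) -> Tuple[str, bool]:
    """(age label, conserved flag) of an ortholog group.

    Age is the oldest member lineage; the group is conserved when any member
    comes from a lineage other than A. thaliana itself.
    """
    if not group.members:
        raise ValueError(f"{group.group_id}: empty ortholog group")
    ranks = [_lineage_rank(lin, ladder) for _, lin in group.members]
    age = ladder[min(ranks)]
    conserved = any(lin != ladder[-1] for _, lin in group.members)
    return age, conserved


def filter_mirna_hits(
    hits: Iterable[BlastHitRecord],
    ladder: Sequence[str] = LINEAGE_LADDER,
    e_value_max: float = 0.01,
    coverage_min: float = 0.9,
    mismatch_max: int = 2,
) -> Dict[str, str]:
    """Conserved miRNAs with ages from a cross-species hit table.

    Returns ``{mirna_id: age label}`` for every miRNA with >=1 passing hit;
    miRNAs absent from the result are non-conserved.  Both coverages must
    pass (conjunctive reading of the >=90% rule).
    """
    floor_rank = _lineage_rank(MIRNA_AGE_FLOOR, ladder)
    best: Dict[str, int] = {}
    for h in hits:
        if h.e_value > e_value_max:
            continue
        if h.query_coverage < coverage_min or h.subject_coverage < coverage_min:
            continue
        if h.mismatches > mismatch_max:
            continue
        rank = _lineage_rank(h.subject_lineage, ladder)
        if rank < floor_rank:
            logger.info(
                "miRNA %s: subject lineage %s older than %s; clamped",
                h.query_mirna,
                h.subject_lineage,
                MIRNA_AGE_FLOOR,
            )
            rank = floor_rank
        if rank < best.get(h.query_mirna, len(ladder)):
            best[h.query_mirna] = rank
    return {mirna: ladder[rank] for mirna, rank in best.items()}


def classify_family(
    family_members: Sequence[str], conserved: Set[str]
) -> str:
    """'conserved_family' when strictly more than half of members are conserved."""
    if len(family_members) < 2:
        raise ValueError("family analyses require >=2 members")
    n_cons = sum(1 for m in family_members if m in conserved)
    return (
        "conserved_family"
        if n_cons * 2 > len(family_members)
        else "non_conserved_family"
    )


def pair_family_relation(
    mirna_i: str, mirna_j: str, family_map: Mapping[str, str]
) -> str:
    """'intra' when both miRNAs belong to the same family, else 'inter'."""
    if mirna_i == mirna_j:
        raise ValueError("self-pairs have no family relation")
    fi, fj = family_map.get(mirna_i), family_map.get(mirna_j)
    if fi is None or fj is None:
        missing = [m for m, f in ((mirna_i, fi), (mirna_j, fj)) if f is None]
        logger.warning("miRNA(s) %s not in family map; labelled inter", missing)
        return "inter"
    return "intra" if fi == fj else "inter"


# ---------------------------------------------------------------- I/O helpers

def read_ortho_groups(path) -> List[OrthoGroup]:
    """TSV with columns group_id, gene_id, lineage."""
    members: Dict[str, List[Tuple[str, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            members.setdefault(row["group_id"], []).append(
                (row["gene_id"], row["lineage"])
            )
    return [OrthoGroup(gid, tuple(m)) for gid, m in sorted(members.items())]


def read_blast_hits(path) -> List[BlastHitRecord]:
    """TSV hit table (outfmt-6-like plus lineage and coverage columns)."""
    out: List[BlastHitRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                BlastHitRecord(
                    query_mirna=row["query_mirna"],
                    subject_mirna=row["subject_mirna"],
                    subject_lineage=row["subject_lineage"],
                    e_value=float(row["e_value"]),
                    query_coverage=float(row["query_coverage"]),
                    subject_coverage=float(row["subject_coverage"]),
                    mismatches=int(row["mismatches"]),
                )
            )
    return out


def read_family_map(path) -> Dict[str, str]:
    """TSV with columns mirna_id, family_id."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["mirna_id"]] = row["family_id"]
    return out
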