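"""Per-ecotype regulation fates and population-level fate profiles.

For a directed miRNA -> transcript regulation, four booleans describe its
detection: by scheme A and scheme B in the reference genome, and by scheme A
and scheme B in one ecotype.  The per-ecotype fate symbol is

    k  kept    -- both schemes agree in the reference AND in the ecotype
    l  lost    -- both schemes agree in the reference, neither finds it in
                  the ecotype
    g  gained  -- neither scheme finds it in the reference, both agree in
                  the ecotype
    o  ambiguous -- exactly one scheme detects it in whichever genome is
                  decisive (the ecotype when the reference call is settled,
                  the reference when the ecotype shows agreement)
    n  absent  -- detected nowhere relevant

which matches the set identities

    Lost   = (T_ref & P_ref) - (T_eco | P_eco)
    Gained = (T_eco & P_eco) - (T_ref | P_ref)
    Kept   = (T_ref & P_ref) & (T_eco & P_eco)

with T and P the pair sets of the two schemes.  The full 16-row decision
table is in docs/methods.md and tested exhaustively.

A regulation fate profile collects the symbols over every ecotype whose
sequences are available (ecotypes carrying an indel in any involved sequence
are omitted) plus a population-level general fate:

    K   in the reference and never lost          ("static")
    KL  in the reference, lost in >=1 ecotype    ("dynamic")
    G   absent from the reference, gained in >=1 ecotype ("dynamic")
    L   in the reference, lost wherever defined  (legal, rarely observed)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

from .target_scan import PredictionSet

RegulationKey = Tuple[str, str]  # (mirna_id, transcript_id)

FATE_SYMBOLS = ("k", "l", "g", "o", "n")
GENERAL_FATES = ("K", "KL", "G", "L")


def classify_pair_in_ecotype(
    in_ref_a: bool, in_ref_b: bool, in_eco_a: bool, in_eco_b: bool
) -> str:
    """Fate symbol from the four scheme/genome detection booleans."""
    ref_both = in_ref_a and in_ref_b
    ref_none = not (in_ref_a or in_ref_b)
    eco_both = in_eco_a and in_eco_b
    eco_none = not (in_eco_a or in_eco_b)
    if ref_both:
        if eco_both:
            return "k"
        if eco_none:
            return "l"
        return "o"  # scheme disagreement in the decisive (ecotype) genome
    if ref_none:
        if eco_both:
            return "g"
        if eco_none:
            return "n"
        return "o"
    # scheme disagreement in the reference: never settles to k/l/g
    return "n" if eco_none else "o"


@dataclass
class FateProfile:
    """Fate symbols of one regulation across the ecotype panel."""

    key: RegulationKey
    fates: Dict[str, str]  # ecotype -> symbol; omitted => sequence discarded
    in_reference: bool

    @property
    def mirna_id(self) -> str:
        return self.key[0]

    @property
    def transcript_id(self) -> str:
        return self.key[1]

    def ecotypes_with(self, symbol: str) -> Set[str]:
        return {e for e, f in self.fates.items() if f == symbol}

    @property
    def general_fate(self) -> str:
        return general_fate(self)

    @property
    def is_dynamic(self) -> bool:
        return self.general_fate in ("KL", "G")


def general_fate(profile: FateProfile) -> str:
    """Population-level summary fate of one profile.

    Ambiguous 'o' symbols do not count against K: a reference regulation is
    K unless genuinely lost somewhere, KL when both kept and lost occur, and
    L when lost wherever a settled call exists.
    """
    if not profile.fates:
        raise ValueError(f"{profile.key}: profile has no defined fates")
    symbols = set(profile.fates.values())
    if profile.in_reference:
        if "l" not in symbols:
            return "K"
        if "k" not in symbols:
            return "L"
        return "KL"
    if "g" in symbols:
        return "G"
    raise ValueError(
        f"{profile.key}: not in reference and never gained; no general fate"
    )


def build_fate_profiles(
    ref_predictions_a: PredictionSet,
    ref_predictions_b: PredictionSet,
    per_ecotype_predictions: Mapping[str, Mapping[str, PredictionSet]],
    discarded: Optional[Mapping[str, Set[str]]] = None,
) -> Dict[RegulationKey, FateProfile]:
    """Assemble fate profiles from reference and per-ecotype prediction sets.

    per_ecotype_predictions maps ecotype -> {"A": PredictionSet, "B": ...}.
    *discarded* maps ecotype -> set of sequence ids unavailable there (indel
    carriers); those ecotypes carry no fate for the affected regulations.

    A profile is emitted for every key found by both schemes in the reference
    plus every key gained (fate g) in at least one ecotype.
    """
    discarded = discarded or {}
    ref_a = ref_predictions_a.pairs
    ref_b = ref_predictions_b.pairs
    ref_union = ref_a | ref_b
    ref_both = ref_a & ref_b

    eco_pairs: Dict[str, Tuple[Set[RegulationKey], Set[RegulationKey]]] = {}
    keys: Set[RegulationKey] = set(ref_both)
    for eco, psets in per_ecotype_predictions.items():
        pa, pb = psets["A"].pairs, psets["B"].pairs
        eco_pairs[eco] = (pa, pb)
        keys |= (pa & pb) - ref_union  # gained candidates

    profiles: Dict[RegulationKey, FateProfile] = {}
    for key in sorted(keys):
        mirna_id, transcript_id = key
        in_ref_a = key in ref_a
        in_ref_b = key in ref_b
        fates: Dict[str, str] = {}
        for eco, (pa, pb) in eco_pairs.items():
            gone = discarded.get(eco, ())
            if mirna_id in gone or transcript_id in gone:
                continue
            fates[eco] = classify_pair_in_ecotype(
                in_ref_a, in_ref_b, key in pa, key in pb
            )
        profile = FateProfile(key=key, fates=fates, in_reference=key in ref_both)
        if not profile.fates:
            continue
        if not profile.in_reference and not profile.ecotypes_with("g"):
            continue  # only reachable via an o-only ecotype set
        profiles[key] = profile
    return profiles


def write_fate_matrix(
    profiles: Mapping[RegulationKey, FateProfile], ecotypes: Iterable[str], path
) -> None:
    """TSV matrix: rows regulations, columns ecotypes, '.' for discarded."""
    ecotypes = list(ecotypes)
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\tgeneral_fate\t" + "\t".join(ecotypes) + "\n")
        for key in sorted(profiles):
            p = profiles[key]
            row = [p.fates.get(e, ".") for e in ecotypes]
            fh.write(f"{key[0]}\t{key[1]}\t{p.general_fate}\t" + "\t".join(row) + "\n")


def fate_summary(profiles: Mapping[RegulationKey, FateProfile]) -> Dict[str, int]:
    counts = {f: 0 for f in GENERAL_FATES}
    for p in profiles.values():
        counts[p.general_fate] += 1
    return counts
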