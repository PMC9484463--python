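"""Fully synthetic ecotype panels with known ground truth.

The generator emulates the statistical structure the crosstalk method
assumes: transcripts carry planted complementary miRNA binding sites, and
ecotype SNPs create or destroy those sites in designated ecotype clusters,
so that pairs of regulations are co-inherited (high fate-profile agreement)
or discordant (losses in largely disjoint ecotype groups).  Singleton
variants and indel-bearing decoy transcripts are sprinkled in to exercise
the variant filters.  Expression and climate tables with matching planted
structure are generated alongside.

Site geometry.  A single SNP changes one duplex position, whose largest
penalty (a core mismatch) is smaller than scheme A's cutoff, so a perfect
site cannot be destroyed by one SNP.  Planted sites therefore sit just
under both cutoffs:

  loss sites: G:U wobbles at miRNA positions 3, 8 (core) and 15
              -> scores A=2.5/B=2.25; a core mismatch SNP (position 10)
              raises them to A=4.5/B=3.75, past both cutoffs;
  gain sites: wobbles at 5 and 15 plus one 3' mismatch (position >= 19)
              -> A=2.5/B=2.5; the reference additionally carries a core
              mismatch at position 10 (A=4.5/B=4.0, undetected) which the
              cluster SNP reverts to Watson-Crick.

All planted miRNAs carry G at positions 3, 5, 8 and 15 so the wobbles are
constructible.  Scores are sums of 0.5/0.75/1/1.5/2 and therefore exact in
floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .network_evaluation import DEFAULT_CLIMATE_VARIABLES
from .population_genomes import (
    EcotypePanel,
    SequenceRecord,
    VariantRecord,
    write_fasta,
)

MIRNA_LEN = 21

# 1-based miRNA positions of the planted-site geometry
LOSS_WOBBLES = (3, 8, 15)
GAIN_WOBBLES = (5, 15)
SNP_MIRNA_POS = 10
GAIN_MISMATCH_POS = 19
_FORCED_G = (3, 5, 8, 15)

_WC_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}  # miRNA base -> site base
# site base that neither Watson-Crick-pairs nor wobbles the miRNA base
_MISMATCH_SITE = {"A": "C", "C": "A", "G": "A", "U": "C"}
# miRNA bases that mismatch a given site base (no WC, no wobble)
_MIRNA_MISMATCH_OPTIONS = {"A": "ACG", "C": "ACU", "G": "AG", "T": "CU"}

PLANTED_KINDS = ("ss", "sd", "dd_loss", "dd_gain")
_EXPECTED_CROSSTALK = {"ss": "SS", "sd": "SD", "dd_loss": "DD", "dd_gain": "DD"}


@dataclass
class FixtureSpec:
    """Study conditions of one synthetic panel (all sizes and rates)."""

    seed: int
    n_ecotypes: int = 100
    n_mirnas: int = 30
    n_transcripts: int = 60
    n_planted_coop_pairs: int = 10
    n_discordant_pairs: int = 10
    agreement_planted: float = 1.0
    agreement_discordant: float = 0.3
    cluster_size: int = 10
    targets_per_pair: int = 2
    planted_kind_cycle: Tuple[str, ...] = (
        "ss", "sd", "dd_loss", "dd_gain", "ss", "sd", "dd_loss", "ss", "sd", "dd_loss",
    )
    n_singletons: int = 30
    n_indels: int = 5
    transcript_len: int = 240
    expression_samples: int = 30
    expression_replicates: int = 2
    rho_high: float = 0.9
    rho_low: float = 0.0
    climate_cluster_sd: float = 0.1
    climate_background_sd: float = 10.0

    def __post_init__(self):
        for rate in (self.agreement_planted, self.agreement_discordant,
                     self.rho_high, self.rho_low):
            if not 0 <= rate <= 1:
                raise ValueError("rates and agreements must lie in [0, 1]")
        if self.transcript_len < 120:
            raise ValueError("transcripts too short to host two planted sites")
        if self.expression_samples < 6:
            raise ValueError(
                "expression needs >=6 samples (shorter panels are filtered out "
                "downstream)"
            )
        for kind in self.planted_kind_cycle:
            if kind not in PLANTED_KINDS:
                raise ValueError(f"unknown planted pair kind {kind!r}")


@dataclass
class PlantedPair:
    mirna_i: str
    mirna_j: str
    targets: Tuple[str, ...]
    kind: str  # ss | sd | dd_loss | dd_gain | discordant
    expected_crosstalk: Optional[str]
    agreement: float
    group_i: FrozenSet[str]  # loss/gain ecotypes of regulation i
    group_j: FrozenSet[str]
    shared_group: FrozenSet[str]


@dataclass
class PlantedRegulation:
    mirna_id: str
    target_id: str
    general_fate: str
    dynamic_ecotypes: FrozenSet[str]


@dataclass
class SyntheticPanel:
    spec: FixtureSpec
    panel: EcotypePanel
    planted_pairs: List[PlantedPair]
    regulations: List[PlantedRegulation]
    cooperative_pairs: List[PlantedPair] = field(init=False)

    def __post_init__(self):
        self.cooperative_pairs = [
            p for p in self.planted_pairs if p.kind != "discordant"
        ]


# ----------------------------------------------------------------- helpers

def _rand_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _planted_mirna(rng: np.random.Generator) -> str:
    seq = list(_rand_seq(rng, MIRNA_LEN, "ACGU"))
    for p in _FORCED_G:
        seq[p - 1] = "G"
    return "".join(seq)


def _perfect_site(mirna: str) -> List[str]:
    """DNA site 5'->3' perfectly complementary to the miRNA (antiparallel)."""
    L = len(mirna)
    site = [""] * L
    for p in range(1, L + 1):
        site[L - p] = _WC_DNA[mirna[p - 1]]
    return site


def _site_index(mirna_pos: int, length: int = MIRNA_LEN) -> int:
    """0-based site index pairing the given 1-based miRNA position."""
    return length - mirna_pos


def _apply_wobble(site: List[str], mirna: str, pos: int) -> None:
    base = mirna[pos - 1]
    idx = _site_index(pos)
    if base == "G":
        site[idx] = "T"  # G:U wobble
    elif base == "U":
        site[idx] = "G"
    else:
        raise ValueError(f"cannot wobble miRNA base {base!r} at position {pos}")


def _build_site(mirna: str, geometry: str) -> Tuple[str, int, str, str]:
    """Planted site plus its switch SNP.

    Returns (site 5'->3', 0-based site index of the SNP, ref base, alt base).
    For 'loss' geometry the reference site is detected and the SNP destroys
    it; for 'gain' the reference carries the mismatch and the SNP restores
    the pairing.
    """
    site = _perfect_site(mirna)
    snp_idx = _site_index(SNP_MIRNA_POS)
    m_base = mirna[SNP_MIRNA_POS - 1]
    if geometry == "loss":
        for p in LOSS_WOBBLES:
            _apply_wobble(site, mirna, p)
        ref, alt = _WC_DNA[m_base], _MISMATCH_SITE[m_base]
    elif geometry == "gain":
        for p in GAIN_WOBBLES:
            _apply_wobble(site, mirna, p)
        mm_idx = _site_index(GAIN_MISMATCH_POS)
        site[mm_idx] = _MISMATCH_SITE[mirna[GAIN_MISMATCH_POS - 1]]
        ref, alt = _MISMATCH_SITE[m_base], _WC_DNA[m_base]
    else:
        raise ValueError(f"unknown site geometry {geometry!r}")
    site[snp_idx] = ref
    return "".join(site), snp_idx, ref, alt


def _loss_groups(
    ecotypes: Sequence[str],
    agreement: float,
    shared_size: int,
    rng: np.random.Generator,
) -> Tuple[FrozenSet[str], FrozenSet[str], FrozenSet[str]]:
    """Two ecotype groups whose symmetric difference sets the coreg agreement.

    agreement = 1 - |group_i ^ group_j| / n_ecotypes; the intersection has
    *shared_size* members so co-occurrence is never empty.
    """
    n = len(ecotypes)
    d = round((1 - agreement) * n)
    if shared_size + d > n:
        raise ValueError("agreement/shared_size combination infeasible")
    sel = rng.choice(n, size=shared_size + d, replace=False)
    shared = frozenset(ecotypes[i] for i in sel[:shared_size])
    extra_i = frozenset(ecotypes[i] for i in sel[shared_size : shared_size + d // 2])
    extra_j = frozenset(ecotypes[i] for i in sel[shared_size + d // 2 :])
    return shared | extra_i, shared | extra_j, shared


# ------------------------------------------------------------ panel builder

def generate_panel(spec: FixtureSpec) -> SyntheticPanel:
    """Build the full synthetic panel (sequences, variants, truth tables)."""
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_planted_coop_pairs + spec.n_discordant_pairs
    needed_targets = n_pairs * spec.targets_per_pair
    if needed_targets > spec.n_transcripts:
        raise ValueError(
            f"{spec.n_transcripts} transcripts cannot host "
            f"{n_pairs} pairs x {spec.targets_per_pair} targets"
        )
    site_offsets = (30, 90)
    if site_offsets[1] + MIRNA_LEN > spec.transcript_len:
        raise ValueError("planted sites do not fit in the transcript")

    ecotypes = [f"eco{i:04d}" for i in range(spec.n_ecotypes)]
    mirna_ids = [f"mir{i:03d}" for i in range(spec.n_mirnas)]
    transcript_ids = [f"tr{i:03d}" for i in range(spec.n_transcripts)]

    mirna_seqs = {mid: _planted_mirna(rng) for mid in mirna_ids}
    transcript_seqs = {
        tid: list(_rand_seq(rng, spec.transcript_len, "ACGT"))
        for tid in transcript_ids
    }

    # pair allocation: cooperative pairs take distinct miRNAs; discordant
    # pairs reuse the remaining miRNAs in rotated combinations
    pair_mirnas: List[Tuple[str, str]] = []
    for p in range(spec.n_planted_coop_pairs):
        pair_mirnas.append((mirna_ids[2 * p], mirna_ids[2 * p + 1]))
    pool = mirna_ids[2 * spec.n_planted_coop_pairs :]
    disc_candidates = list(combinations(pool, 2))
    if len(disc_candidates) < spec.n_discordant_pairs:
        raise ValueError("not enough miRNAs for the requested discordant pairs")
    pair_mirnas.extend(disc_candidates[: spec.n_discordant_pairs])

    variants: List[VariantRecord] = []
    planted_pairs: List[PlantedPair] = []
    regulations: List[PlantedRegulation] = []
    target_cursor = 0

    def _add_site_snps(tid, offset, site, snp_idx, ref, alt, carriers):
        transcript_seqs[tid][offset : offset + MIRNA_LEN] = list(site)
        if carriers:
            variants.append(
                VariantRecord(
                    seq_id=tid,
                    position=offset + snp_idx + 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    carriers=frozenset(carriers),
                )
            )

    for p in range(n_pairs):
        mi, mj = pair_mirnas[p]
        discordant = p >= spec.n_planted_coop_pairs
        kind = (
            "discordant"
            if discordant
            else spec.planted_kind_cycle[p % len(spec.planted_kind_cycle)]
        )
        agreement = (
            spec.agreement_discordant if discordant else spec.agreement_planted
        )
        targets = tuple(
            transcript_ids[target_cursor + k] for k in range(spec.targets_per_pair)
        )
        target_cursor += spec.targets_per_pair

        if kind == "ss":
            gi = gj = shared = frozenset()
        elif kind in ("dd_loss", "dd_gain", "discordant"):
            gi, gj, shared = _loss_groups(
                ecotypes, agreement, spec.cluster_size, rng
            )
        else:  # sd: only regulation j is dynamic
            gj = frozenset(
                ecotypes[i]
                for i in rng.choice(
                    spec.n_ecotypes, size=spec.cluster_size, replace=False
                )
            )
            gi, shared = frozenset(), frozenset()

        geometry = "gain" if kind == "dd_gain" else "loss"
        for tid in targets:
            site_i, idx_i, ref_i, alt_i = _build_site(mirna_seqs[mi], geometry)
            site_j, idx_j, ref_j, alt_j = _build_site(mirna_seqs[mj], geometry)
            carriers_i = gi if kind != "sd" else frozenset()
            carriers_j = gj if kind != "sd" else frozenset()
            _add_site_snps(
                tid, site_offsets[0], site_i, idx_i, ref_i, alt_i, carriers_i
            )
            _add_site_snps(
                tid, site_offsets[1], site_j, idx_j, ref_j, alt_j, carriers_j
            )

        if kind == "sd":
            # one SNP in the dynamic miRNA's core destroys all its sites
            m_seq = mirna_seqs[mj]
            site_base = _WC_DNA[m_seq[SNP_MIRNA_POS - 1]]
            alt_base = _MIRNA_MISMATCH_OPTIONS[site_base][0]
            variants.append(
                VariantRecord(
                    seq_id=mj,
                    position=SNP_MIRNA_POS,
                    ref_allele=m_seq[SNP_MIRNA_POS - 1],
                    alt_allele=alt_base,
                    carriers=gj,
                )
            )

        if kind == "dd_gain":
            fate_i = fate_j = "G"
        elif kind == "ss":
            fate_i = fate_j = "K"
        elif kind == "sd":
            fate_i, fate_j = "K", "KL"
        else:
            fate_i = fate_j = "KL"
        for tid in targets:
            regulations.append(PlantedRegulation(mi, tid, fate_i, gi))
            regulations.append(PlantedRegulation(mj, tid, fate_j, gj))
        planted_pairs.append(
            PlantedPair(
                mirna_i=mi,
                mirna_j=mj,
                targets=targets,
                kind=kind,
                expected_crosstalk=None
                if discordant
                else _EXPECTED_CROSSTALK[kind],
                agreement=agreement,
                group_i=gi,
                group_j=gj,
                shared_group=shared,
            )
        )

    # decoy transcripts host singleton SNPs and indels
    decoys = transcript_ids[target_cursor:]
    for _ in range(spec.n_singletons):
        tid = decoys[rng.integers(len(decoys))] if decoys else transcript_ids[0]
        pos = int(rng.integers(1, spec.transcript_len + 1))
        if not decoys and (
            site_offsets[0] < pos <= site_offsets[1] + MIRNA_LEN
        ):
            continue  # never perturb planted sites with noise variants
        ref = transcript_seqs[tid][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variants.append(
            VariantRecord(
                seq_id=tid,
                position=pos,
                ref_allele=ref,
                alt_allele=str(alt),
                carriers=frozenset([ecotypes[rng.integers(spec.n_ecotypes)]]),
            )
        )
    for _ in range(spec.n_indels):
        if not decoys:
            break
        tid = decoys[rng.integers(len(decoys))]
        pos = int(rng.integers(1, spec.transcript_len))
        ref = "".join(transcript_seqs[tid][pos - 1 : pos + 1])
        n_carriers = int(rng.integers(2, 5))
        carriers = frozenset(
            ecotypes[i]
            for i in rng.choice(spec.n_ecotypes, size=n_carriers, replace=False)
        )
        variants.append(
            VariantRecord(
                seq_id=tid,
                position=pos,
                ref_allele=ref,
                alt_allele=ref[0],
                carriers=carriers,
            )
        )

    sequences: Dict[str, SequenceRecord] = {}
    for mid in mirna_ids:
        sequences[mid] = SequenceRecord(mid, "mirna", mirna_seqs[mid])
    for tid in transcript_ids:
        sequences[tid] = SequenceRecord(
            tid, "transcript", "".join(transcript_seqs[tid]), gene_id=tid.replace("tr", "g")
        )
    panel = EcotypePanel(ecotypes=ecotypes, sequences=sequences, variants=variants)
    return SyntheticPanel(
        spec=spec, panel=panel, planted_pairs=planted_pairs, regulations=regulations
    )


# --------------------------------------------------------- expression/climate

def generate_expression(
    truth: SyntheticPanel, spec: Optional[FixtureSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long-form expression table with planted pair correlation structure.

    Cooperative pairs share log-abundance profiles at rho_high; discordant
    and background miRNAs are uncorrelated (rho_low = 0 by construction; a
    nonzero rho_low is applied to discordant pairs).  Replicates add small
    independent noise and are averaged downstream.
    """
    spec = spec or truth.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n_s = spec.expression_samples
    mirnas = sorted(truth.panel.mirnas())
    z: Dict[str, np.ndarray] = {m: rng.normal(size=n_s) for m in mirnas}
    for pair in truth.planted_pairs:
        rho = spec.rho_high if pair.kind != "discordant" else spec.rho_low
        if rho == 0:
            continue
        base = z[pair.mirna_i]
        z[pair.mirna_j] = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=n_s)
    rows = []
    for m in mirnas:
        abundance = 2.0 ** (8.0 + 2.0 * z[m])
        for s in range(n_s):
            for _ in range(spec.expression_replicates):
                noisy = abundance[s] * 2.0 ** rng.normal(scale=0.05)
                rows.append(
                    {"mirna": m, "sample": f"s{s:02d}", "value": float(noisy)}
                )
    return pd.DataFrame(rows)


def generate_climate(
    spec: FixtureSpec,
    clusters: Mapping[str, Set[str]],
    rng: Optional[np.random.Generator] = None,
    variables: Sequence[str] = DEFAULT_CLIMATE_VARIABLES,
) -> pd.DataFrame:
    """Climate table with geographically clustered ecotype groups.

    Ecotypes in a cluster draw each variable around a cluster-specific mean
    with climate_cluster_sd; everyone else draws from a broad background
    (climate_background_sd).  Returns a DataFrame indexed by ecotype with
    lat/lon plus the requested variables.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    ecotypes = [f"eco{i:04d}" for i in range(spec.n_ecotypes)]
    df = pd.DataFrame(index=pd.Index(ecotypes, name="ecotype"))
    df["lat"] = rng.uniform(35, 65, size=spec.n_ecotypes)
    df["lon"] = rng.uniform(-10, 30, size=spec.n_ecotypes)
    for var in variables:
        base_mean = rng.uniform(0, 100)
        col = rng.normal(base_mean, spec.climate_background_sd, size=spec.n_ecotypes)
        series = pd.Series(col, index=df.index)
        for label, members in clusters.items():
            mean = rng.uniform(0, 100)
            members = [m for m in members if m in series.index]
            series.loc[members] = rng.normal(
                mean, spec.climate_cluster_sd, size=len(members)
            )
        df[var] = series
    return df


# ----------------------------------------------------------- named fixtures

def worked_example_pair(
    n_ecotypes: int = 100, cluster_size: int = 20, seed: int = 7
) -> SyntheticPanel:
    """Two miRNAs sharing 18 targets: 2 ss motifs and 16 dd motifs.

    All motifs are perfectly co-inherited (losses of both regulations occur
    in one shared ecotype cluster), so every motif survives a 0.85 filter
    and the edge's crosstalk type is decided by the 16/18 dd majority.
    """
    spec = FixtureSpec(
        seed=seed,
        n_ecotypes=n_ecotypes,
        n_mirnas=2,
        n_transcripts=18,
        n_planted_coop_pairs=1,
        n_discordant_pairs=0,
        targets_per_pair=18,
        cluster_size=cluster_size,
        planted_kind_cycle=("dd_loss",),
        n_singletons=0,
        n_indels=0,
    )
    truth = generate_panel(spec)
    # turn the first two targets static: drop their site-switch SNPs
    pair = truth.planted_pairs[0]
    static = set(pair.targets[:2])
    truth.panel.variants = [
        v for v in truth.panel.variants if v.seq_id not in static
    ]
    fixed_regs = []
    for reg in truth.regulations:
        if reg.target_id in static:
            reg = replace(reg, general_fate="K", dynamic_ecotypes=frozenset())
        fixed_regs.append(reg)
    truth.regulations = fixed_regs
    return truth


def family_gain_cluster(
    n_members: int = 7,
    n_ecotypes: int = 100,
    cluster_size: int = 22,
    seed: int = 11,
) -> SyntheticPanel:
    """Homologous miRNAs gaining one shared target in the same ecotype cluster.

    The members share the core-complementary region of a single 3'UTR-style
    binding site and differ only at one 3' position each; the reference site
    carries a core mismatch, and a single site SNP (carried by one cluster
    of ecotypes) restores pairing for every member simultaneously, so all
    regulations are gained in exactly the same ecotype group.
    """
    if not 2 <= n_members <= 9:
        raise ValueError("supported family size is 2..9")
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        seed=seed,
        n_ecotypes=n_ecotypes,
        n_mirnas=n_members,
        n_transcripts=1,
        n_planted_coop_pairs=0,
        n_discordant_pairs=0,
        cluster_size=cluster_size,
        n_singletons=0,
        n_indels=0,
    )
    ecotypes = [f"eco{i:04d}" for i in range(n_ecotypes)]
    core = list(_planted_mirna(rng))
    # site bases pairing positions 19-21 must allow three mismatch choices
    core[18], core[19], core[20] = "U", "G", "U"
    core = "".join(core)
    site, snp_idx, ref, alt = _build_site(core, "gain")
    # pre-SNP the site already mismatches position 19 of the core; rebuild
    # without that extra mismatch so each member carries exactly one
    site = list(site)
    site[_site_index(GAIN_MISMATCH_POS)] = _WC_DNA[core[GAIN_MISMATCH_POS - 1]]

    members: Dict[str, str] = {}
    combos = [
        (pos, base)
        for pos in (19, 20, 21)
        for base in _MIRNA_MISMATCH_OPTIONS[site[_site_index(pos)]]
        if base != core[pos - 1]
    ]
    for k in range(n_members):
        pos, base = combos[k]
        seq = list(core)
        seq[pos - 1] = base
        members[f"fam{k}"] = "".join(seq)

    offset = 30
    transcript = list(_rand_seq(rng, spec.transcript_len, "ACGT"))
    transcript[offset : offset + MIRNA_LEN] = site
    cluster = frozenset(
        ecotypes[i] for i in rng.choice(n_ecotypes, size=cluster_size, replace=False)
    )
    variants = [
        VariantRecord(
            seq_id="tr000",
            position=offset + snp_idx + 1,
            ref_allele=ref,
            alt_allele=alt,
            carriers=cluster,
        )
    ]
    sequences: Dict[str, SequenceRecord] = {
        mid: SequenceRecord(mid, "mirna", seq) for mid, seq in members.items()
    }
    sequences["tr000"] = SequenceRecord(
        "tr000", "transcript", "".join(transcript), gene_id="g000"
    )
    panel = EcotypePanel(ecotypes=ecotypes, sequences=sequences, variants=variants)
    regulations = [
        PlantedRegulation(mid, "tr000", "G", cluster) for mid in sorted(members)
    ]
    pairs = [
        PlantedPair(
            mirna_i=a,
            mirna_j=b,
            targets=("tr000",),
            kind="dd_gain",
            expected_crosstalk="DD",
            agreement=1.0,
            group_i=cluster,
            group_j=cluster,
            shared_group=cluster,
        )
        for i, a in enumerate(sorted(members))
        for b in sorted(members)[i + 1 :]
    ]
    return SyntheticPanel(
        spec=spec, panel=panel, planted_pairs=pairs, regulations=regulations
    )


# ------------------------------------------------------------------- output

def write_panel(truth: SyntheticPanel, out_dir) -> Dict[str, Path]:
    """Write FASTA/VCF/truth files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_fasta": out / "mirnas.fasta",
        "transcript_fasta": out / "transcripts.fasta",
        "vcf": out / "variants.vcf",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_regulations": out / "truth_regulations.tsv",
    }
    panel = truth.panel
    write_fasta(panel.mirnas().values(), paths["mirna_fasta"])
    write_fasta(panel.transcripts().values(), paths["transcript_fasta"])
    _write_vcf(panel, paths["vcf"])
    with open(paths["truth_pairs"], "w") as fh:
        fh.write(
            "mirna_i\tmirna_j\tkind\texpected_crosstalk\tagreement\t"
            "targets\tgroup_i\tgroup_j\n"
        )
        for p in truth.planted_pairs:
            fh.write(
                f"{p.mirna_i}\t{p.mirna_j}\t{p.kind}\t"
                f"{p.expected_crosstalk or '.'}\t{p.agreement:g}\t"
                f"{','.join(p.targets)}\t{','.join(sorted(p.group_i)) or '.'}\t"
                f"{','.join(sorted(p.group_j)) or '.'}\n"
            )
    with open(paths["truth_regulations"], "w") as fh:
        fh.write("mirna_id\ttarget_id\tgeneral_fate\tdynamic_ecotypes\n")
        for r in truth.regulations:
            fh.write(
                f"{r.mirna_id}\t{r.target_id}\t{r.general_fate}\t"
                f"{','.join(sorted(r.dynamic_ecotypes)) or '.'}\n"
            )
    return paths


def _write_vcf(panel: EcotypePanel, path) -> None:
    """Sequence-local VCF (CHROM = sequence id, POS 1-based, GT per ecotype)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for seq_id, rec in sorted(panel.sequences.items()):
            fh.write(f"##contig=<ID={seq_id},length={len(rec.sequence)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.ecotypes)
            + "\n"
        )
        def as_dna(allele: str) -> str:
            return allele.replace("U", "T")
        for v in sorted(panel.variants, key=lambda v: (v.seq_id, v.position)):
            gts = [
                "1|1" if eco in v.carriers else "0|0" for eco in panel.ecotypes
            ]
            fh.write(
                f"{v.seq_id}\t{v.position}\t.\t{as_dna(v.ref_allele)}\t"
                f"{as_dna(v.alt_allele)}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
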