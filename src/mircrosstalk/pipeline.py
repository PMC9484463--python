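"""Stage orchestration: materialize -> scan -> fates -> network -> annotate ->
enrich -> evaluate, with a JSON run manifest.

Stages consume the outputs of earlier stages in memory, write their own
results into the configured output directory, and never mutate another
stage's files.  Stages whose optional inputs are missing are skipped with a
logged notice.  Reruns with identical configuration and seeds are
byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import annotation_conservation as ac
from . import network_evaluation as ev
from .config import RunConfig
from .crosstalk_network import (
    CrosstalkNetwork,
    build_network,
    write_edges_tsv,
    write_graphml,
    write_motifs_tsv,
)
from .fate_engine import (
    FateProfile,
    RegulationKey,
    build_fate_profiles,
    fate_summary,
    write_fate_matrix,
)
from .population_genomes import (
    EcotypePanel,
    SequenceRecord,
    filter_singletons,
    materialize_all,
    read_fasta,
    read_variants,
)
from .stats_enrichment import enrichment_matrix, write_enrichment_tsv
from .target_scan import (
    DEFAULT_SCHEMES,
    PredictionSet,
    ScanCache,
    predict_all,
    write_sites_tsv,
)

logger = logging.getLogger(__name__)

STAGES = (
    "materialize",
    "scan",
    "fates",
    "network",
    "annotate",
    "enrich",
    "evaluate",
)


@dataclass
class PipelineState:
    config: RunConfig
    panel: Optional[EcotypePanel] = None
    discarded: Dict[str, Set[str]] = field(default_factory=dict)
    ref_predictions: Dict[str, PredictionSet] = field(default_factory=dict)
    eco_predictions: Dict[str, Dict[str, PredictionSet]] = field(default_factory=dict)
    profiles: Dict[RegulationKey, FateProfile] = field(default_factory=dict)
    network: Optional[CrosstalkNetwork] = None
    mirna_ages: Dict[str, str] = field(default_factory=dict)
    gene_ages: Dict[str, str] = field(default_factory=dict)
    family_map: Dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def predict_panel(
    panel: EcotypePanel,
    discarded_override: Optional[Mapping[str, Set[str]]] = None,
) -> Tuple[
    Dict[str, PredictionSet],
    Dict[str, Dict[str, PredictionSet]],
    Dict[str, Set[str]],
]:
    """Reference and per-ecotype prediction sets for both schemes.

    Wild x wild scans are shared with the reference run through a sequence
    content cache; only mutant-type sequences trigger new scans.
    """
    cache: ScanCache = {}
    mirnas = panel.mirnas()
    transcripts = panel.transcripts()
    ref = {
        name: predict_all(mirnas, transcripts, scheme, "reference", cache)
        for name, scheme in DEFAULT_SCHEMES.items()
    }
    materialized = materialize_all(panel)
    eco_pred: Dict[str, Dict[str, PredictionSet]] = {}
    discarded: Dict[str, Set[str]] = {}
    for eco in panel.ecotypes:
        seqs = materialized[eco]
        gone = {sid for sid, m in seqs.items() if m.status == "discarded"}
        discarded[eco] = gone
        eco_mirnas = {
            sid: SequenceRecord(sid, "mirna", seqs[sid].sequence)
            for sid in mirnas
            if sid not in gone
        }
        eco_transcripts = {
            sid: SequenceRecord(
                sid, "transcript", seqs[sid].sequence, transcripts[sid].gene_id
            )
            for sid in transcripts
            if sid not in gone
        }
        eco_pred[eco] = {
            name: predict_all(eco_mirnas, eco_transcripts, scheme, eco, cache)
            for name, scheme in DEFAULT_SCHEMES.items()
        }
    if discarded_override:
        discarded.update(discarded_override)
    return ref, eco_pred, discarded


def run_pipeline(
    config: RunConfig,
    panel: Optional[EcotypePanel] = None,
    upto: str = "evaluate",
) -> PipelineState:
    """Run the pipeline through stage *upto* and write the manifest.

    A preloaded *panel* may be supplied instead of FASTA/VCF paths (the
    simulate subcommand and the test-suite use this).
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config=config)
    completed: List[str] = []
    last = STAGES.index(upto)

    # ---- materialize
    if panel is None:
        if not (config.mirna_fasta and config.transcript_fasta and config.vcf):
            raise ValueError("mirna_fasta, transcript_fasta and vcf are required")
        sequences = {}
        sequences.update(read_fasta(config.mirna_fasta, "mirna"))
        mirna_count = len(sequences)
        transcripts = read_fasta(config.transcript_fasta, "transcript")
        overlap = set(sequences) & set(transcripts)
        if overlap:
            raise ValueError(f"sequence ids shared between kinds: {sorted(overlap)}")
        sequences.update(transcripts)
        variants = read_variants(config.vcf, sequences)
        ecotypes = _vcf_samples(config.vcf)
        panel = EcotypePanel(ecotypes=ecotypes, sequences=sequences, variants=variants)
        logger.info(
            "loaded %d miRNAs, %d transcripts, %d variants, %d ecotypes",
            mirna_count, len(transcripts), len(variants), len(ecotypes),
        )
    if config.remove_singletons:
        panel.variants = filter_singletons(panel.variants)
    state.panel = panel
    completed.append("materialize")

    # ---- scan
    if last >= STAGES.index("scan"):
        ref, eco_pred, discarded = predict_panel(panel)
        state.ref_predictions = ref
        state.eco_predictions = eco_pred
        state.discarded = discarded
        for name, pset in ref.items():
            write_sites_tsv(pset, out / f"sites_reference_{name}.tsv")
        completed.append("scan")

    # ---- fates
    if last >= STAGES.index("fates"):
        state.profiles = build_fate_profiles(
            state.ref_predictions["A"],
            state.ref_predictions["B"],
            state.eco_predictions,
            state.discarded,
        )
        write_fate_matrix(state.profiles, panel.ecotypes, out / "fate_matrix.tsv")
        with open(out / "fate_summary.json", "w") as fh:
            json.dump(fate_summary(state.profiles), fh, indent=2, sort_keys=True)
        completed.append("fates")

    # ---- network
    if last >= STAGES.index("network"):
        state.network = build_network(
            state.profiles,
            threshold=config.coreg_threshold,
            mode=config.coreg_mode,
        )
        write_edges_tsv(state.network, out / "edges.tsv")
        write_motifs_tsv(state.network, out / "motifs.tsv")
        write_graphml(state.network, out / "network.graphml")
        completed.append("network")

    # ---- annotate
    if last >= STAGES.index("annotate"):
        if config.blast_tsv and Path(config.blast_tsv).exists():
            state.mirna_ages = ac.filter_mirna_hits(ac.read_blast_hits(config.blast_tsv))
        if config.ortho_tsv and Path(config.ortho_tsv).exists():
            for group in ac.read_ortho_groups(config.ortho_tsv):
                age, conserved = ac.assign_gene_age(group)
                for gene_id, _ in group.members:
                    state.gene_ages[gene_id] = age
        if config.family_tsv and Path(config.family_tsv).exists():
            state.family_map = ac.read_family_map(config.family_tsv)
        if state.mirna_ages or state.gene_ages or state.family_map:
            with open(out / "annotation.json", "w") as fh:
                json.dump(
                    {
                        "mirna_ages": state.mirna_ages,
                        "gene_ages": state.gene_ages,
                        "family_map": state.family_map,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            completed.append("annotate")
        else:
            logger.info("annotate: no annotation inputs supplied; skipped")

    # ---- enrich
    if last >= STAGES.index("enrich"):
        rng = np.random.default_rng(config.seed)
        did = False
        net = state.network
        if net is not None and net.edges and state.mirna_ages:
            conservation = {
                n: ("conserved" if n in state.mirna_ages else "non-conserved")
                for n in net.graph.nodes
            }
            edges = [tuple(sorted(p)) for p in sorted(net.edges, key=sorted)]
            labels = [net.edges[frozenset(e)].crosstalk_type for e in edges]
            cells = enrichment_matrix(
                edges,
                conservation,
                conservation,
                scheme="edge_sample",
                edge_labels=labels,
                n_reps=config.n_reps,
                rng=rng,
            )
            write_enrichment_tsv(cells, out / "enrichment_conservation.tsv")
            ages = {
                n: state.mirna_ages.get(n, "Arabidopsis thaliana")
                for n in net.graph.nodes
            }
            cells = enrichment_matrix(
                edges,
                ages,
                ages,
                scheme="label_permute",
                n_reps=config.n_reps,
                rng=rng,
            )
            write_enrichment_tsv(cells, out / "enrichment_age.tsv")
            did = True
        if state.profiles and state.gene_ages and state.mirna_ages:
            reg_edges = []
            reg_labels = []
            for (m, t), profile in sorted(state.profiles.items()):
                gene = state.panel.sequences[t].gene_id or t
                if gene not in state.gene_ages:
                    continue
                reg_edges.append((m, t))
                reg_labels.append(profile.general_fate)
            if reg_edges:
                mirna_age_of = {
                    m: state.mirna_ages.get(m, "Arabidopsis thaliana")
                    for m, _ in reg_edges
                }
                gene_age_of = {
                    t: state.gene_ages[state.panel.sequences[t].gene_id or t]
                    for _, t in reg_edges
                }
                cells = enrichment_matrix(
                    reg_edges,
                    mirna_age_of,
                    gene_age_of,
                    scheme="fate_shuffle",
                    edge_labels=reg_labels,
                    n_reps=config.n_reps,
                    rng=rng,
                )
                write_enrichment_tsv(cells, out / "enrichment_fate_age.tsv")
                did = True
        if did:
            completed.append("enrich")
        else:
            logger.info("enrich: annotation inputs missing; skipped")

    # ---- evaluate
    if last >= STAGES.index("evaluate"):
        rng = np.random.default_rng(config.seed + 1)
        net = state.network
        if net is not None and net.graph.number_of_nodes():
            report = ev.topology(net.graph, percentile=config.topology_percentile)
            ev.write_topology_tsv(report, out / "topology.tsv")
        if config.expression_tsv and Path(config.expression_tsv).exists():
            raw = pd.read_csv(config.expression_tsv, sep="\t")
            matrix = ev.preprocess_expression(raw)
            grid = [round(0.05 * i, 2) for i in range(21)]
            sweep = ev.threshold_sweep(
                state.profiles, matrix, grid, mode=config.coreg_mode
            )
            sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
            if net is not None:
                pairs = sorted(tuple(sorted(p)) for p in net.edges)
                corr = ev.pair_correlations(matrix, pairs)
                corr.to_csv(out / "edge_correlations.tsv", sep="\t", index=False)
        else:
            logger.info("evaluate: no expression table; sweep skipped")
        if config.stress_tsv and Path(config.stress_tsv).exists() and net is not None:
            stress = _read_stress(config.stress_tsv)
            pairs = sorted(tuple(sorted(p)) for p in net.edges)
            frac, p = ev.stress_share_test(
                pairs, stress, n_perm=config.n_reps, rng=rng
            )
            with open(out / "stress_share.json", "w") as fh:
                json.dump({"fraction_sharing": frac, "p_empirical": p}, fh, indent=2)
        if config.climate_csv and Path(config.climate_csv).exists() and state.profiles:
            climate = pd.read_csv(config.climate_csv, index_col=0)
            groups = _dynamic_groups_for_network(state)
            if groups:
                results = ev.climate_sd_tests(
                    groups, climate, n_perm=config.n_reps, rng=rng
                )
                pd.DataFrame(
                    [
                        {
                            "group": r.group_label,
                            "variable": r.variable,
                            "n_ecotypes": len(r.group),
                            "sd_observed": r.sd_observed,
                            "p_empirical": r.p_empirical,
                            "p_adj": r.p_adj,
                        }
                        for r in results
                    ]
                ).to_csv(out / "climate_tests.tsv", sep="\t", index=False)
        completed.append("evaluate")

    state.manifest = {
        "stages_completed": completed,
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(state.manifest, fh, indent=2, sort_keys=True)
    return state


def _dynamic_groups_for_network(state: PipelineState) -> Dict[str, List[str]]:
    """Per-target union of dynamic (gain/loss) ecotype groups, size >= 2."""
    groups: Dict[str, Set[str]] = {}
    net = state.network
    targets = (
        {m.target for e in net.edges.values() for m in e.surviving}
        if net is not None and net.edges
        else {t for (_, t) in state.profiles}
    )
    for target in sorted(targets):
        try:
            per_reg = ev.dynamic_ecotype_groups(state.profiles, target)
        except ValueError:
            continue
        union: Set[str] = set()
        for members in per_reg.values():
            union |= members
        if len(union) >= 2:
            groups[target] = sorted(union)
    return groups


def _read_stress(path) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples():
        out.setdefault(row.mirna_id, set()).add(row.stress_type)
    return out


def _vcf_samples(path) -> List[str]:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
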