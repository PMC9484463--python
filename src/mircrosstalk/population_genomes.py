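"""Sequence and variant panel handling.

Reads mature miRNA / transcript FASTA files and a per-ecotype variant table
(VCF dialect whose CHROM column is a sequence identifier and whose POS is
1-based within that sequence), filters singleton variants, and materializes
per-ecotype ("mutant-type") sequences by substituting SNPs.  Ecotypes that
carry any indel in a sequence have that sequence discarded, since a short
indel in a mature miRNA or coding transcript generally inactivates it.

Internal alphabets: miRNAs are RNA (A,C,G,U), transcripts are DNA (A,C,G,T).
VCF alleles are accepted in DNA letters and mapped onto the record alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

MIRNA_MIN_LEN = 18
MIRNA_MAX_LEN = 26

_VALID = set("ACGUTN")


class PanelError(ValueError):
    """Inconsistent panel input (ref mismatch, bad coordinates, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One reference sequence: a mature miRNA or a transcript."""

    id: str
    kind: str  # "mirna" | "transcript"
    sequence: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("mirna", "transcript"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        if self.kind == "mirna" and not (
            MIRNA_MIN_LEN <= len(self.sequence) <= MIRNA_MAX_LEN
        ):
            raise ValueError(
                f"{self.id}: mature miRNA length {len(self.sequence)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalize(seq: str, kind: str) -> str:
    """Uppercase and map to the internal alphabet of *kind* (RNA for miRNAs)."""
    seq = seq.upper()
    if kind == "mirna":
        return seq.replace("T", "U")
    return seq.replace("U", "T")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant local to one sequence (1-based position)."""

    seq_id: str
    position: int
    ref_allele: str
    alt_allele: str
    carriers: frozenset

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp


@dataclass
class MaterializedSequence:
    seq_id: str
    ecotype_id: str
    status: str  # "wild" | "mutant" | "discarded"
    sequence: Optional[str] = None


@dataclass
class EcotypePanel:
    """The full input universe: ecotypes, sequences, and filtered variants."""

    ecotypes: list
    sequences: dict = field(default_factory=dict)  # seq_id -> SequenceRecord
    variants: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.ecotypes)) != len(self.ecotypes):
            raise PanelError("duplicate ecotype identifiers")
        eco = set(self.ecotypes)
        for v in self.variants:
            if not v.carriers <= eco:
                raise PanelError(
                    f"variant {v.seq_id}:{v.position} carried by unknown "
                    f"ecotypes {sorted(v.carriers - eco)}"
                )

    def variants_for(self, seq_id: str) -> list:
        return [v for v in self.variants if v.seq_id == seq_id]

    def mirnas(self) -> dict:
        return {k: s for k, s in self.sequences.items() if s.kind == "mirna"}

    def transcripts(self) -> dict:
        return {k: s for k, s in self.sequences.items() if s.kind == "transcript"}


def read_fasta(path, kind: str) -> dict:
    """Read a FASTA file into ``{id: SequenceRecord}`` with canonicalization.

    U and T are treated as equivalent: miRNAs are stored as RNA, transcripts
    as DNA.  Duplicate identifiers and malformed files raise errors.
    """
    path = Path(path)
    records: dict[str, SequenceRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise PanelError(
                        f"{path}: line {lineno}: expected FASTA header '>'"
                    )
                break
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in records:
            raise PanelError(f"{path}: duplicate sequence id {entry.id!r}")
        records[entry.id] = SequenceRecord(
            id=entry.id, kind=kind, sequence=canonicalize(str(entry.seq), kind)
        )
    if not records:
        logger.warning("%s: no FASTA entries found", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    out = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_variants(path, sequences: Mapping[str, SequenceRecord]) -> list:
    """Read a sequence-local VCF into VariantRecords.

    CHROM must be a known sequence id and POS 1-based within it.  Multi-allelic
    rows are split into biallelic records.  An ecotype carries an allele if its
    genotype contains it (heterozygous calls count: A. thaliana is selfing and
    presence of the alternate allele is the relevant signal).
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            seq_id = rec.chrom
            if seq_id not in sequences:
                raise PanelError(f"{path}: unknown sequence {seq_id!r} in CHROM")
            seq = sequences[seq_id]
            pos = rec.pos  # pysam gives 1-based POS
            ref = canonicalize(rec.ref, seq.kind)
            if pos < 1 or pos + len(ref) - 1 > len(seq):
                raise PanelError(
                    f"{seq_id}:{pos}: position outside sequence (len {len(seq)})"
                )
            if seq.sequence[pos - 1 : pos - 1 + len(ref)] != ref:
                raise PanelError(
                    f"{seq_id}:{pos}: REF {rec.ref!r} disagrees with the "
                    f"reference sequence"
                )
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                carriers = frozenset(
                    s
                    for s in samples
                    if alt_index in (rec.samples[s].get("GT") or ())
                )
                out.append(
                    VariantRecord(
                        seq_id=seq_id,
                        position=pos,
                        ref_allele=ref,
                        alt_allele=canonicalize(alt, seq.kind),
                        carriers=carriers,
                    )
                )
    return out


def filter_singletons(variants: Sequence[VariantRecord]) -> list:
    """Drop biallelic variants whose alternate allele occurs in one ecotype."""
    kept = [v for v in variants if len(v.carriers) != 1]
    removed = len(variants) - len(kept)
    if removed:
        logger.info("singleton filter removed %d of %d variants", removed, len(variants))
    return kept


def materialize(
    panel: EcotypePanel, seq_id: str, ecotype_id: str
) -> MaterializedSequence:
    """Build the ecotype's copy of one sequence.

    Any carried indel discards the sequence for this ecotype; otherwise all
    carried SNPs are substituted.  Two different SNP alleles at one position
    for the same ecotype are a multi-allelic conflict and raise.
    """
    if seq_id not in panel.sequences:
        raise PanelError(f"unknown sequence {seq_id!r}")
    if ecotype_id not in panel.ecotypes:
        raise PanelError(f"unknown ecotype {ecotype_id!r}")
    carried = [
        v for v in panel.variants_for(seq_id) if ecotype_id in v.carriers
    ]
    if any(v.is_indel for v in carried):
        return MaterializedSequence(seq_id, ecotype_id, "discarded", None)
    if not carried:
        return MaterializedSequence(
            seq_id, ecotype_id, "wild", panel.sequences[seq_id].sequence
        )
    seq = list(panel.sequences[seq_id].sequence)
    seen: dict[int, str] = {}
    for v in carried:
        if v.position in seen and seen[v.position] != v.alt_allele:
            raise PanelError(
                f"{seq_id}:{v.position}: conflicting SNP alleles for "
                f"ecotype {ecotype_id}"
            )
        seen[v.position] = v.alt_allele
        seq[v.position - 1] = v.alt_allele
    return MaterializedSequence(seq_id, ecotype_id, "mutant", "".join(seq))


def materialize_all(panel: EcotypePanel) -> dict:
    """Materialize every (sequence, ecotype) pair.

    Returns ``{ecotype: {seq_id: MaterializedSequence}}``.  Only sequences
    with at least one carried variant differ from the reference, so wild
    copies share the reference string.
    """
    by_seq: dict[str, list[VariantRecord]] = {}
    for v in panel.variants:
        by_seq.setdefault(v.seq_id, []).append(v)
    out: dict[str, dict[str, MaterializedSequence]] = {
        eco: {} for eco in panel.ecotypes
    }
    for seq_id, record in panel.sequences.items():
        variants = by_seq.get(seq_id, ())
        touched = set()
        for v in variants:
            touched |= v.carriers
        for eco in panel.ecotypes:
            if eco in touched:
                out[eco][seq_id] = materialize(panel, seq_id, eco)
            else:
                out[eco][seq_id] = MaterializedSequence(
                    seq_id, eco, "wild", record.sequence
                )
    return out


def variant_density(
    variants: Sequence[VariantRecord], seq_id: Optional[str], span_bp: int
) -> float:
    """Variants per kilobase over *span_bp* (optionally for one sequence)."""
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    if seq_id is not None:
        variants = [v for v in variants if v.seq_id == seq_id]
    return len(variants) * 1000.0 / span_bp
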