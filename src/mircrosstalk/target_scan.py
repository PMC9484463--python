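"""Complementarity-based miRNA target-site scanning.

Two independent penalty schemes (A and B) score every gapless antiparallel
duplex between a mature miRNA and a transcript window of the same length.
Watson-Crick pairs cost nothing, G:U wobbles a small penalty, mismatches a
larger one, and positions inside the 5' core region are up-weighted, in the
style of plant-miRNA target rules.  A window is a predicted site when its
total penalty does not exceed the scheme cutoff.  Downstream analysis only
ever uses the intersection of the two schemes, so neither scheme needs to
reproduce any particular external predictor site-for-site.

Duplexes are gapless (no bulges); this keeps the scorer exactly checkable
against brute-force window enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .population_genomes import SequenceRecord

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# Watson-Crick partners on the 0..3 index (A,C,G,U/T)
_WC = {0: 3, 1: 2, 2: 1, 3: 0}
# G:U wobble pairs
_WOBBLE = {(2, 3), (3, 2)}


@dataclass(frozen=True)
class ScoringScheme:
    """Position-weighted duplex penalty scheme.

    core_start/core_end are 1-based inclusive positions counted from the
    miRNA 5' end; penalties at those positions are multiplied by
    core_multiplier.  A duplex is accepted when its score is <= cutoff.
    """

    name: str
    mismatch_penalty: float = 1.0
    gu_wobble_penalty: float = 0.5
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0
    cutoff: float = 4.0

    def __post_init__(self):
        if self.mismatch_penalty < 0 or self.gu_wobble_penalty < 0:
            raise ValueError("penalties must be nonnegative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.core_start < 1 or self.core_end < self.core_start:
            raise ValueError("invalid core region")

    def penalty_matrix(self) -> np.ndarray:
        """5x5 per-pair penalty lookup (miRNA base x site base)."""
        pen = np.full((5, 5), self.mismatch_penalty)
        for m, s in _WC.items():
            pen[m, s] = 0.0
        for m, s in _WOBBLE:
            pen[m, s] = self.gu_wobble_penalty
        pen[4, :] = self.mismatch_penalty
        pen[:, 4] = self.mismatch_penalty
        return pen

    def weights(self, length: int) -> np.ndarray:
        w = np.ones(length)
        lo = min(self.core_start - 1, length)
        hi = min(self.core_end, length)
        w[lo:hi] = self.core_multiplier
        return w


#: Allen-style scheme: strong 5' core 2-13, lenient cutoff.
SCHEME_A = ScoringScheme("A", 1.0, 0.5, 2, 13, 2.0, 4.0)
#: Stricter 5'-weighted scheme with an extended core 2-17.
SCHEME_B = ScoringScheme("B", 1.0, 0.5, 2, 17, 1.5, 2.5)

DEFAULT_SCHEMES: Dict[str, ScoringScheme] = {"A": SCHEME_A, "B": SCHEME_B}

_EPS = 1e-9


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive transcript coordinates
    end: int
    score: float
    scheme_name: str

    def alignment(self, mirna_seq: str, site_seq: str) -> Tuple[str, str, str]:
        """(miRNA 5'->3', pairing line, site 3'->5') for display."""
        site_rev = site_seq[::-1]
        line = []
        for m, s in zip(mirna_seq, site_rev):
            mi, si = _BASE_INDEX[m], _BASE_INDEX[s]
            if _WC.get(mi) == si:
                line.append("|")
            elif (mi, si) in _WOBBLE:
                line.append("o")
            else:
                line.append(" ")
        return mirna_seq, "".join(line), site_rev


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def score_duplex(mirna_seq: str, site_seq: str, scheme: ScoringScheme) -> float:
    """Penalty of the gapless antiparallel duplex of a miRNA on a site.

    *site_seq* is given 5'->3' on the transcript; miRNA position p (1..L from
    the miRNA 5' end) pairs with site position L+1-p.
    """
    if len(mirna_seq) != len(site_seq):
        raise ValueError("miRNA and site must have equal length")
    m = _encode(mirna_seq)
    s = _encode(site_seq)[::-1]
    pen = scheme.penalty_matrix()
    w = scheme.weights(len(m))
    return float(np.sum(w * pen[m, s]))


def scan_transcript(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    scheme: ScoringScheme,
) -> List[TargetSite]:
    """All transcript windows whose duplex score is within the scheme cutoff.

    Exhaustive over every gapless window of miRNA length; overlapping sites
    are all reported.
    """
    L = len(mirna.sequence)
    T = len(transcript.sequence)
    if T < L:
        logger.warning(
            "transcript %s shorter than miRNA %s; no windows",
            transcript.id,
            mirna.id,
        )
        return []
    m = _encode(mirna.sequence)
    t = _encode(transcript.sequence)
    pen = scheme.penalty_matrix()
    w = scheme.weights(L)
    n_windows = T - L + 1
    scores = np.zeros(n_windows)
    # miRNA position p (0-based) pairs with transcript offset L-1-p in the window
    for p in range(L):
        scores += w[p] * pen[m[p], t[L - 1 - p : L - 1 - p + n_windows]]
    hits = np.flatnonzero(scores <= scheme.cutoff + _EPS)
    return [
        TargetSite(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            start=int(i) + 1,
            end=int(i) + L,
            score=float(scores[i]),
            scheme_name=scheme.name,
        )
        for i in hits
    ]


@dataclass
class PredictionSet:
    """Sites predicted by one scheme on one genome (reference or ecotype)."""

    genome_label: str
    scheme_name: str
    sites: List[TargetSite] = field(default_factory=list)

    @property
    def pairs(self) -> Set[Tuple[str, str]]:
        return {(s.mirna_id, s.transcript_id) for s in self.sites}


ScanCache = Dict[Tuple[str, str, str], Tuple[Tuple[int, int, float], ...]]


def predict_all(
    mirnas: Mapping[str, SequenceRecord],
    transcripts: Mapping[str, SequenceRecord],
    scheme: ScoringScheme,
    genome_label: str = "reference",
    cache: Optional[ScanCache] = None,
) -> PredictionSet:
    """Scan every miRNA against every transcript.

    When a *cache* dict is supplied, scans are memoized on the actual
    sequence contents, so an ecotype run recomputes only the pairs in which
    the miRNA or the transcript is mutant-type; wild x wild results are
    reused from the reference run.
    """
    pset = PredictionSet(genome_label=genome_label, scheme_name=scheme.name)
    for mid, mir in mirnas.items():
        for tid, tr in transcripts.items():
            if cache is not None:
                key = (mir.sequence, tr.sequence, scheme.name)
                hit = cache.get(key)
                if hit is None:
                    sites = scan_transcript(mir, tr, scheme)
                    cache[key] = tuple((s.start, s.end, s.score) for s in sites)
                else:
                    sites = [
                        TargetSite(mid, tid, a, b, sc, scheme.name)
                        for a, b, sc in hit
                    ]
                    pset.sites.extend(sites)
                    continue
            else:
                sites = scan_transcript(mir, tr, scheme)
            # re-label cached coordinates with the current ids
            pset.sites.extend(
                TargetSite(mid, tid, s.start, s.end, s.score, scheme.name)
                for s in sites
            )
    return pset


def write_sites_tsv(pset: PredictionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\tstart\tend\tscore\tscheme\n")
        for s in sorted(pset.sites, key=lambda x: (x.mirna_id, x.transcript_id, x.start)):
            fh.write(
                f"{s.mirna_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t"
                f"{s.score:g}\t{s.scheme_name}\n"
            )


def read_sites_tsv(path, genome_label: str, scheme_name: str) -> PredictionSet:
    """Load a site report (ours, or converted external-tool output)."""
    pset = PredictionSet(genome_label=genome_label, scheme_name=scheme_name)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            pset.sites.append(
                TargetSite(
                    mirna_id=f[idx["mirna_id"]],
                    transcript_id=f[idx["transcript_id"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    score=float(f[idx["score"]]),
                    scheme_name=scheme_name,
                )
            )
    return pset


def parse_external_pairs(path, genome_label: str, scheme_name: str) -> PredictionSet:
    """Adapter for external predictor output.

    Accepts a tab-separated table whose first two columns are miRNA id and
    transcript id (header lines starting with '#' or 'miRNA' are skipped);
    site coordinates and scores are optional columns 3-5.  This is enough to
    substitute genuine predictions for either scheme, since the pipeline's
    fate logic only consumes pair-level existence.
    """
    pset = PredictionSet(genome_label=genome_label, scheme_name=scheme_name)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("mirna"):
                continue
            f = line.split("\t")
            start = int(f[2]) if len(f) > 3 and f[2].isdigit() else 1
            end = int(f[3]) if len(f) > 3 and f[3].isdigit() else start
            try:
                score = float(f[4]) if len(f) > 4 else 0.0
            except ValueError:
                score = 0.0
            pset.sites.append(
                TargetSite(f[0], f[1], start, end, score, scheme_name)
            )
    return pset
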