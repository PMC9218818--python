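"""IUPAC motif scanning over 500-bp promoter sequences.

Promoters are supplied 5'->3' on the gene's strand with the last base
adjacent to the transcription start site.  Hit offsets are measured in
bp upstream of the TSS, 1-based, at the TSS-proximal end of the match
footprint, so position 1 is the base immediately upstream of the TSS.
Both strands are scanned; overlapping matches are counted.  Degenerate
bases (N) in a promoter never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO

PROMOTER_LENGTH = 500

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class IUPACMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern {self.pattern!r}: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


# Recognized circadian cis elements.  The morning element's canonical
# core (CCACAC) is used; the remaining patterns are the elements as
# commonly reported, with reverse-complement variants collapsed to one
# motif each (the scanner covers both strands).
PAPER_MOTIFS: dict[str, IUPACMotif] = {
    m.name: m for m in [
        IUPACMotif("evening_element", "AAAATATC"),
        IUPACMotif("TBS_GGTCC", "GGTCC"),
        IUPACMotif("TBS_GGCCCA", "GGCCCA"),
        IUPACMotif("G_box", "CACGTG"),
        IUPACMotif("fbs", "CACGCGC"),
        IUPACMotif("GA_motif_1", "GAGAGAGAGA"),
        IUPACMotif("GA_motif_2", "RRAGAAGAAG"),
        IUPACMotif("morning_element", "CCACAC"),
    ]
}


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif: str
    strand: str  # "+" or "-"
    offset_bp_upstream: int


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC degenerate-code support."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc.args[0]!r}") from None


def read_promoters(fasta: str | Path, length: int = PROMOTER_LENGTH) -> dict[str, str]:
    """Read promoter FASTA into a gene -> uppercase sequence map.

    Sequences longer than ``length`` are truncated to the TSS-proximal
    (3') end; shorter ones are kept as-is.
    """
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in promoters:
            raise ValueError(f"duplicate promoter record id: {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - {"A", "C", "G", "T", "N"}
        if bad:
            raise ValueError(f"invalid bases in promoter {record.id!r}: {sorted(bad)}")
        if len(seq) > length:
            seq = seq[-length:]
        promoters[record.id] = seq
    if not promoters:
        raise ValueError(f"no FASTA records in {fasta}")
    return promoters


def _match_starts(seq_bytes: np.ndarray, pattern: str) -> np.ndarray:
    """Start indices of all IUPAC matches of ``pattern`` (position-wise AND)."""
    L, k = seq_bytes.size, len(pattern)
    n_starts = L - k + 1
    ok = np.ones(n_starts, dtype=bool)
    for off, code in enumerate(pattern):
        allowed = np.zeros(256, dtype=bool)
        for base in IUPAC_CODES[code]:
            allowed[ord(base)] = True
        ok &= allowed[seq_bytes[off:off + n_starts]]
    return np.flatnonzero(ok)


def scan_sequence(seq: str, motif: IUPACMotif, gene: str = "") -> list[MotifHit]:
    """All exact IUPAC matches of ``motif`` on both strands of ``seq``.

    Overlaps are allowed.  Hits are ordered by ascending offset with
    "+" before "-" at equal offsets.  An N in the promoter matches no
    pattern position (an N in the *pattern* matches any base).
    """
    seq = seq.upper()
    L, k = len(seq), len(motif)
    if L < k:
        return []
    seq_bytes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[MotifHit] = []
    for strand, pattern in (("+", motif.pattern), ("-", reverse_complement(motif.pattern))):
        for start in _match_starts(seq_bytes, pattern):
            offset = L - (int(start) + k) + 1  # TSS-proximal end of the footprint
            hits.append(MotifHit(gene=gene, motif=motif.name, strand=strand,
                                 offset_bp_upstream=offset))
    hits.sort(key=lambda h: (h.offset_bp_upstream, h.strand))
    return hits


def gene_motif_table(
    promoters: dict[str, str], motifs: dict[str, IUPACMotif] | list[IUPACMotif]
) -> pd.DataFrame:
    """Gene x motif hit-count matrix.

    Presence (count >= 1) is derived with :func:`presence_table`; counts
    include both strands with overlaps.
    """
    if isinstance(motifs, dict):
        motifs = list(motifs.values())
    counts = {
        gene: {m.name: len(scan_sequence(seq, m, gene=gene)) for m in motifs}
        for gene, seq in promoters.items()
    }
    table = pd.DataFrame.from_dict(counts, orient="index")
    table.index.name = "gene"
    return table[[m.name for m in motifs]]


def presence_table(count_table: pd.DataFrame) -> pd.DataFrame:
    return count_table >= 1


def positional_distribution(
    hits: list[MotifHit], bin_edges_bp: list[float] | np.ndarray,
    proximal_window: tuple[float, float] = (50, 100),
) -> tuple[np.ndarray, float]:
    """Histogram of hit offsets plus the fraction in the proximal window.

    Returns (counts per bin, fraction of hits with offset inside
    ``proximal_window`` inclusive).  The fraction is NaN when there are
    no hits.
    """
    offsets = np.array([h.offset_bp_upstream for h in hits], dtype=float)
    edges = np.asarray(bin_edges_bp, dtype=float)
    counts, _ = np.histogram(offsets, bins=edges)
    if offsets.size == 0:
        return counts, float("nan")
    lo, hi = proximal_window
    frac = float(((offsets >= lo) & (offsets <= hi)).mean())
    return counts, frac


def set_enrichment(
    gene_set: list[str], background_set: list[str], presence: pd.Series
) -> tuple[float, float]:
    """Fold enrichment and hypergeometric upper-tail p for one motif.

    ``presence`` maps gene -> carrier boolean over the background.
    fold = (carrier fraction in set) / (carrier fraction in background);
    p = P[X >= observed] for X ~ Hypergeom(N, K, n).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    background = set(background_set)
    extra = set(gene_set) - background
    if extra:
        raise ValueError(f"gene set not contained in background: {sorted(extra)[:5]}")
    N = len(background)
    K = int(presence.loc[list(background)].sum())
    n = len(gene_set)
    k = int(presence.loc[list(gene_set)].sum())
    bg_frac = K / N
    fold = float("inf") if (bg_frac == 0 and k > 0) else (
        (k / n) / bg_frac if bg_frac > 0 else float("nan")
    )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return fold, p


def hits_to_tsv(hits: list[MotifHit], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)
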