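"""Binding-site alignment, degenerate IUPAC consensus derivation, and scanning.

The operative notion of a motif here is the one used for bacterial
repressor sites mapped by footprinting: a set of equal-length, ungapped
binding sites is tallied into a position-frequency matrix (PFM), each
column is summarized by the minimal IUPAC code covering the bases seen at
or above a frequency threshold, and genomic windows are called hits when
they differ from the consensus at no more than a small number of positions.
Mismatch counting, not log-odds scoring, is the match criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .genome import PromoterRegion, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC code -> frozenset of bases it covers (e.g. R -> {A, G}).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(expansion) for code, expansion in ambiguous_dna_values.items()
}
#: frozenset of bases -> minimal IUPAC code covering exactly that set.
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
_SET_TO_CODE[frozenset(BASES)] = "N"  # biopython also lists X for the full set


@dataclass(frozen=True)
class BindingSite:
    sequence: str
    source_gene: str = ""
    source_kind: str = "table"  # footprint | table | planted

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(BASES):
            raise ValueError(f"binding site {self.sequence!r}: alphabet must be ACGT")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts over an ungapped set of equal-length sites."""

    counts: np.ndarray  # shape (L, 4), columns ordered ACGT
    n_sites: int

    def __post_init__(self) -> None:
        if not np.all(self.counts.sum(axis=1) == self.n_sites):
            raise ValueError("PFM column sums must equal the number of sites")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sites

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.length + 1))
        return df


@dataclass(frozen=True)
class IUPACConsensus:
    code_string: str

    def __post_init__(self) -> None:
        bad = [c for c in self.code_string if c not in IUPAC_SETS]
        if not self.code_string or bad:
            raise ValueError(f"invalid IUPAC codes {bad} in {self.code_string!r}")

    def __len__(self) -> int:
        return len(self.code_string)

    def __str__(self) -> str:
        return self.code_string

    def position_sets(self) -> list[frozenset[str]]:
        return [IUPAC_SETS[c] for c in self.code_string]


@dataclass(frozen=True)
class MotifHit:
    """A consensus-like window within a promoter region.

    ``offset`` is 0-based relative to the promoter's 5'->3' sequence;
    ``strand`` is the match orientation relative to that sequence.
    ``genomic_start`` is the 1-based genomic coordinate of the window's
    leftmost base on the reference (+) strand, when known.
    """

    gene_id: str
    offset: int
    strand: str
    matched_sequence: str
    mismatches: int
    genomic_start: Optional[int] = None


def load_sites(path) -> list[BindingSite]:
    """Read binding sites: plain one-per-line, or TSV with a sequence column."""
    sites: list[BindingSite] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and "sequence" in fields:
                header = fields
                continue
            if header is not None:
                row = dict(zip(header, fields))
                sites.append(
                    BindingSite(
                        row["sequence"].upper(),
                        row.get("gene", ""),
                        row.get("kind", "table"),
                    )
                )
            else:
                sites.append(BindingSite(fields[0].upper()))
    return sites


def build_pfm(sites: Sequence[BindingSite]) -> PositionFrequencyMatrix:
    """Tally an ungapped, fixed-length site set into a PFM."""
    if not sites:
        raise ValueError("cannot build a PFM from zero sites")
    length = len(sites[0].sequence)
    odd = [s.sequence for s in sites if len(s.sequence) != length]
    if odd:
        raise ValueError(f"sites of mixed length (expected {length}): {odd}")
    counts = np.zeros((length, 4), dtype=int)
    for site in sites:
        for j, base in enumerate(site.sequence):
            counts[j, _BASE_INDEX[base]] += 1
    return PositionFrequencyMatrix(counts, len(sites))


def derive_iupac_consensus(
    pfm: PositionFrequencyMatrix, min_frequency: float = 0.25
) -> IUPACConsensus:
    """Summarize each PFM column as the minimal covering IUPAC code.

    A base enters a position's code when it occurs in at least
    ``min_frequency`` of the sites; if no base reaches the threshold the
    code covers every base observed at that position.
    """
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    freqs = pfm.frequencies()
    codes = []
    for j in range(pfm.length):
        chosen = frozenset(b for b, f in zip(BASES, freqs[j]) if f >= min_frequency)
        if not chosen:
            chosen = frozenset(b for b, f in zip(BASES, freqs[j]) if f > 0)
        codes.append(_SET_TO_CODE[chosen])
    return IUPACConsensus("".join(codes))


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` is in the degenerate set of ``code``.

    The ambiguity base N in genomic sequence matches nothing, including
    the N code itself: an unknown base is never evidence for a site.
    """
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return False
    if base not in _BASE_INDEX:
        raise ValueError(f"invalid sequence base {base!r}")
    return base in IUPAC_SETS[code]


def count_mismatches(seq: str, consensus: IUPACConsensus | str) -> int:
    """Number of positions of ``seq`` failing the consensus code."""
    if isinstance(consensus, str):
        consensus = IUPACConsensus(consensus)
    if len(seq) != len(consensus):
        raise ValueError(
            f"length mismatch: sequence {len(seq)} vs consensus {len(consensus)}"
        )
    return sum(
        0 if iupac_match(b, c) else 1 for b, c in zip(seq, consensus.code_string)
    )


def _allowed_table(consensus: IUPACConsensus) -> np.ndarray:
    """(L, 5) boolean: does base index (A,C,G,T,N) satisfy consensus pos j."""
    table = np.zeros((len(consensus), 5), dtype=bool)
    for j, code in enumerate(consensus.code_string):
        for b in IUPAC_SETS[code]:
            table[j, _BASE_INDEX[b]] = True
    return table  # N column stays False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode("ascii").translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def _window_mismatches(seq: str, consensus: IUPACConsensus) -> np.ndarray:
    """Mismatch count of every L-window of ``seq`` against the consensus."""
    L = len(consensus)
    n_windows = len(seq) - L + 1
    enc = _encode(seq)
    allowed = _allowed_table(consensus)
    mm = np.zeros(n_windows, dtype=np.int32)
    for j in range(L):
        mm += ~allowed[j, enc[j : j + n_windows]]
    return mm


def scan_sequence(
    region: PromoterRegion | str,
    consensus: IUPACConsensus | str,
    max_mismatch: int = 1,
    both_strands: bool = True,
    gene_id: str = "",
) -> list[MotifHit]:
    """Report every consensus-like window of a promoter region.

    All windows within the mismatch budget are reported (overlaps
    included), ordered by offset with + strand before - at equal offset.
    A region shorter than the consensus yields no hits and a warning.
    """
    if isinstance(consensus, str):
        consensus = IUPACConsensus(consensus)
    if isinstance(region, PromoterRegion):
        seq, gene_id = region.sequence, region.gene_id
    else:
        seq, region = region.upper(), None
    L = len(consensus)
    if len(seq) < L:
        logger.warning("%s: region shorter than consensus (%d < %d)", gene_id, len(seq), L)
        return []

    hits: list[MotifHit] = []

    def genomic_start(offset: int) -> Optional[int]:
        if region is None:
            return None
        if region.strand == "+":
            return region.start + offset
        return region.end - offset - (L - 1)

    fwd = _window_mismatches(seq, consensus)
    strands = [("+", fwd)]
    if both_strands:
        # a window's reverse complement matches iff the same window of the
        # reverse-complemented sequence matches, at mirrored offset
        rc = _window_mismatches(reverse_complement(seq), consensus)
        strands.append(("-", rc[::-1]))

    n_windows = len(seq) - L + 1
    for offset in range(n_windows):
        for strand, mm in strands:
            m = int(mm[offset])
            if m <= max_mismatch:
                window = seq[offset : offset + L]
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        offset=offset,
                        strand=strand,
                        matched_sequence=window if strand == "+" else reverse_complement(window),
                        mismatches=m,
                        genomic_start=genomic_start(offset),
                    )
                )
    return hits


def scan_promoters(
    promoters: Iterable[PromoterRegion],
    consensus: IUPACConsensus | str,
    max_mismatch: int = 1,
    both_strands: bool = True,
) -> dict[str, list[MotifHit]]:
    """Scan a promoter set; returns gene_id -> hits (genes with >=1 hit)."""
    out: dict[str, list[MotifHit]] = {}
    for region in promoters:
        hits = scan_sequence(region, consensus, max_mismatch, both_strands)
        if hits:
            out[region.gene_id] = hits
    return out


def consensus_match_probability(
    consensus: IUPACConsensus | str, max_mismatch: int = 1
) -> float:
    """Probability a uniform-random L-mer matches within the budget.

    Under independent uniform bases each position passes with probability
    p_j = |set_j|/4; the total is the Poisson-binomial tail
    P(#failures <= max_mismatch), computed by dynamic programming. Used
    for analytic false-positive expectations on random backgrounds.
    """
    if isinstance(consensus, str):
        consensus = IUPACConsensus(consensus)
    p_pass = [len(s) / 4 for s in consensus.position_sets()]
    # dp[k] = P(exactly k failures so far)
    dp = np.zeros(max_mismatch + 2)
    dp[0] = 1.0
    for p in p_pass:
        new = np.zeros_like(dp)
        new[: -1] = dp[:-1] * p
        new[1:] += dp[:-1] * (1 - p)
        new[-1] += dp[-1]
        dp = new
    return float(dp[: max_mismatch + 1].sum())


def hits_to_frame(hits_by_gene: dict[str, list[MotifHit]]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": h.gene_id,
            "offset": h.offset,
            "genomic_start": h.genomic_start,
            "strand": h.strand,
            "sequence": h.matched_sequence,
            "mismatches": h.mismatches,
        }
        for hits in hits_by_gene.values()
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "offset", "genomic_start", "strand", "sequence", "mismatches"]
    )
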