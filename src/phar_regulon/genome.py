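"""Genome, annotation and TSS input handling, and promoter-window extraction.

Promoter regions are strand-aware windows anchored on a transcription start
site (TSS) when one is known, and on the translation start codon otherwise.
External files use 1-based inclusive coordinates (GFF convention); all
conversions to Python slices are confined to this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return str(Seq(seq).reverse_complement())


def _clean_sequence(raw: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    s = raw.upper()
    if set(s) <= _VALID_BASES:
        return s
    return "".join(c if c in _VALID_BASES else "N" for c in s)


@dataclass(frozen=True)
class GenomeSequence:
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus; start/end are 1-based inclusive on the + strand."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TSSRecord:
    """Experimentally mapped or start-codon-inferred +1 position."""

    gene_id: str
    position: int
    strand: str
    source: str = "experimental"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS {self.gene_id}: invalid strand {self.strand!r}")
        if self.source not in ("experimental", "inferred_from_start_codon"):
            raise ValueError(f"TSS {self.gene_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class PromoterRegion:
    """TSS-anchored window, sequence oriented 5'->3' on the coding strand."""

    gene_id: str
    contig_id: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str
    sequence: str
    anchor: int  # genomic position of the +1 (or start codon) used
    anchor_source: str = "experimental"
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# readers


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into a mapping contig_id -> GenomeSequence.

    Lowercase is folded to uppercase and any non-ACGT letter becomes N.
    Duplicate contig ids and empty files are hard errors.
    """
    records: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        records[rec.id] = GenomeSequence(rec.id, _clean_sequence(str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


_TSV_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "product"]


def _annotations_from_tsv(path: Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    genes = []
    for i, row in df.iterrows():
        try:
            genes.append(
                GeneAnnotation(
                    gene_id=row["gene_id"],
                    contig_id=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    product=str(row.get("product", "")) if "product" in df.columns else "",
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return genes


def _annotations_from_gff3(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            gid = (
                feat.attributes.get("locus_tag", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or feat.attributes.get("gene", [None])[0]
            )
            if gid is None:
                raise ValueError(f"{path}: feature without locus_tag/ID at {feat.start}")
            if gid in seen:
                continue  # gene already captured; its CDS duplicates it
            seen.add(gid)
            product = feat.attributes.get("product", [""])[0]
            genes.append(
                GeneAnnotation(gid, feat.seqid, feat.start, feat.end, feat.strand, product)
            )
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def load_annotations(
    path: str | Path,
    genome: Optional[Mapping[str, GenomeSequence]] = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (.gff/.gff3) or 6-column TSV.

    When a genome mapping is supplied, coordinates are bounds-checked
    against the contig lengths.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("%s: empty annotation file", path)
        return []
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _annotations_from_gff3(path)
    else:
        genes = _annotations_from_tsv(path)
    if not genes:
        logger.warning("%s: no gene annotations parsed", path)
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene ids {dup}")
    if genome is not None:
        for g in genes:
            if g.contig_id not in genome:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig_id!r}")
            if g.end > len(genome[g.contig_id]):
                raise ValueError(
                    f"{g.gene_id}: end {g.end} beyond contig "
                    f"{g.contig_id} length {len(genome[g.contig_id])}"
                )
    return genes


def load_tss(path: str | Path) -> dict[str, TSSRecord]:
    """Read a TSS table (columns: gene_id, position, strand, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["gene_id", "position", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TSS columns {missing}")
    out: dict[str, TSSRecord] = {}
    for i, row in df.iterrows():
        rec = TSSRecord(
            gene_id=row["gene_id"],
            position=int(row["position"]),
            strand=row["strand"],
            source=row.get("source", "experimental") if "source" in df.columns else "experimental",
        )
        if rec.gene_id in out:
            raise ValueError(f"{path}: line {i + 2}: duplicate TSS for {rec.gene_id}")
        out[rec.gene_id] = rec
    return out


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoter(
    gene: GeneAnnotation,
    tss: Optional[TSSRecord],
    genome: Mapping[str, GenomeSequence],
    upstream: int = 200,
    downstream: int = 20,
) -> PromoterRegion:
    """Extract the promoter window around a gene's TSS (or start codon).

    For a + strand gene the genomic window is [anchor-upstream,
    anchor+downstream]; for a - strand gene it is [anchor-downstream,
    anchor+upstream] and the sequence is reverse-complemented so it always
    reads 5'->3' on the coding strand. Windows are clipped at contig
    boundaries and flagged as truncated.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if gene.contig_id not in genome:
        raise ValueError(f"{gene.gene_id}: unknown contig {gene.contig_id!r}")
    contig = genome[gene.contig_id]

    if tss is not None:
        if tss.strand != gene.strand:
            raise ValueError(
                f"{gene.gene_id}: TSS strand {tss.strand} != gene strand {gene.strand}"
            )
        anchor, source = tss.position, tss.source
    else:
        anchor = gene.start if gene.strand == "+" else gene.end
        source = "inferred_from_start_codon"
        logger.debug("%s: no TSS, anchoring on start codon at %d", gene.gene_id, anchor)

    if not 1 <= anchor <= len(contig):
        raise ValueError(
            f"{gene.gene_id}: anchor {anchor} outside contig of length {len(contig)}"
        )

    if gene.strand == "+":
        start, end = anchor - upstream, anchor + downstream
    else:
        start, end = anchor - downstream, anchor + upstream

    truncated = start < 1 or end > len(contig)
    if truncated:
        logger.warning(
            "%s: promoter window %d..%d truncated to contig bounds", gene.gene_id, start, end
        )
        start, end = max(start, 1), min(end, len(contig))

    seq = contig.sequence[start - 1 : end]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterRegion(
        gene_id=gene.gene_id,
        contig_id=gene.contig_id,
        start=start,
        end=end,
        strand=gene.strand,
        sequence=seq,
        anchor=anchor,
        anchor_source=source,
        truncated=truncated,
    )


def extract_promoters(
    genes: Iterable[GeneAnnotation],
    tss_map: Mapping[str, TSSRecord],
    genome: Mapping[str, GenomeSequence],
    upstream: int = 200,
    downstream: int = 20,
) -> list[PromoterRegion]:
    """Vector version of :func:`extract_promoter` over an annotation set."""
    return [
        extract_promoter(g, tss_map.get(g.gene_id), genome, upstream, downstream)
        for g in genes
    ]


def promoters_to_frame(promoters: Sequence[PromoterRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in promoters],
            "contig": [p.contig_id for p in promoters],
            "start": [p.start for p in promoters],
            "end": [p.end for p in promoters],
            "strand": [p.strand for p in promoters],
            "anchor": [p.anchor for p in promoters],
            "anchor_source": [p.anchor_source for p in promoters],
            "truncated": [p.truncated for p in promoters],
            "sequence": [p.sequence for p in promoters],
        }
    )
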