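"""Regulon candidate inference and end-to-end pipeline orchestration.

A gene is a regulon candidate when its promoter carries at least one
consensus-like binding-site hit AND its expression responds to loss of the
regulator beyond a fold-change threshold. For a repressor like PhaR, genes
up in the deletion mutant are the repressed candidates and genes down are
the activated candidates. Genes bound but not differentially expressed
(the regulator's own promoter is the published example) go to a separate
bound-no-DE table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import datasets
from .expression import (
    DERecord,
    ExpressionRecord,
    UP,
    DOWN,
    fold_change,
    load_counts,
    rpkm_table,
    round_half_up,
)
from .genome import extract_promoters, load_annotations, load_genome, load_tss, promoters_to_frame
from .motif import (
    IUPACConsensus,
    MotifHit,
    build_pfm,
    derive_iupac_consensus,
    hits_to_frame,
    load_sites,
    scan_promoters,
    scan_sequence,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulonCandidate:
    gene_id: str
    binding_site: str
    site_offset: int
    site_strand: str
    mismatches: int
    rpkm_wt: float
    rpkm_mut: float
    fold_change: float  # 2-dp reported value, direction-folded (>= 1)
    regulon_class: str  # repressed | activated
    product: str = ""
    genomic_start: Optional[int] = None


@dataclass(frozen=True)
class RegulonTables:
    repressed: tuple[RegulonCandidate, ...]
    activated: tuple[RegulonCandidate, ...]
    bound_no_de: tuple[RegulonCandidate, ...]


def _locus_sort_key(gene_id: str) -> tuple:
    m = re.search(r"(\d+)", gene_id)
    return (int(m.group(1)) if m else 0, gene_id)


def _best_hit(hits: Sequence[MotifHit]) -> MotifHit:
    # one reported site per gene: fewest mismatches, then leftmost, then + strand
    return min(hits, key=lambda h: (h.mismatches, h.offset, h.strand == "-"))


def infer_regulon(
    hits: Mapping[str, Sequence[MotifHit]],
    de: Union[Mapping[str, DERecord], Iterable[ExpressionRecord]],
    fc_threshold: float = 2.0,
    epsilon: float = 0.01,
    products: Optional[Mapping[str, str]] = None,
) -> RegulonTables:
    """Intersect promoter motif hits with differential expression.

    ``hits`` maps gene_id to its promoter hits; ``de`` is either per-gene
    DE records or raw expression records (fold changes are then computed
    here). Repressed = bound and up in the mutant beyond the threshold
    (strict); activated = bound and down. One site is reported per gene
    (fewest mismatches, then leftmost); tables are sorted by genomic
    position, falling back to locus-tag number when coordinates are
    unknown. Genes with hits but no expression record are excluded and
    logged. The result is invariant to input ordering.
    """
    if isinstance(de, Mapping):
        de_map = dict(de)
    else:
        de_map = {}
        for rec in de:
            de_map[rec.gene_id] = (
                rec if isinstance(rec, DERecord) else fold_change(rec, epsilon)
            )
    products = products or {}

    repressed, activated, bound_no_de = [], [], []
    for gene_id in sorted(hits, key=_locus_sort_key):
        gene_hits = hits[gene_id]
        if not gene_hits:
            continue
        if gene_id not in de_map:
            logger.warning("%s: promoter hit but no expression record; excluded", gene_id)
            continue
        rec = de_map[gene_id]
        best = _best_hit(gene_hits)
        cand = RegulonCandidate(
            gene_id=gene_id,
            binding_site=best.matched_sequence,
            site_offset=best.offset,
            site_strand=best.strand,
            mismatches=best.mismatches,
            rpkm_wt=rec.rpkm_wt,
            rpkm_mut=rec.rpkm_mut,
            fold_change=round_half_up(rec.fold_change, 2),
            regulon_class="",
            product=products.get(gene_id, ""),
            genomic_start=best.genomic_start,
        )
        if rec.fold_change > fc_threshold and rec.direction == UP:
            repressed.append(dataclasses.replace(cand, regulon_class="repressed"))
        elif rec.fold_change > fc_threshold and rec.direction == DOWN:
            activated.append(dataclasses.replace(cand, regulon_class="activated"))
        else:
            bound_no_de.append(dataclasses.replace(cand, regulon_class="bound_no_de"))

    def ordered(cands: list[RegulonCandidate]) -> tuple[RegulonCandidate, ...]:
        return tuple(
            sorted(
                cands,
                key=lambda c: (
                    (c.genomic_start,) if c.genomic_start is not None
                    else _locus_sort_key(c.gene_id)
                ),
            )
        )

    return RegulonTables(ordered(repressed), ordered(activated), ordered(bound_no_de))


def candidates_to_frame(cands: Sequence[RegulonCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in cands],
            "binding_site": [c.binding_site for c in cands],
            "site_offset": [c.site_offset for c in cands],
            "site_strand": [c.site_strand for c in cands],
            "mismatches": [c.mismatches for c in cands],
            "rpkm_wt": [c.rpkm_wt for c in cands],
            "rpkm_mut": [c.rpkm_mut for c in cands],
            "fold_change": [c.fold_change for c in cands],
            "product": [c.product for c in cands],
        }
    )


# ---------------------------------------------------------------------------
# the published-table fixture


def fixture_from_published_tables(
    consensus: str = datasets.PHAR_CONSENSUS,
    max_mismatch: int = 1,
):
    """Hits and expression records rebuilt from the packaged tables.

    Each published gene's printed 12-mer binding site is treated as a
    minimal promoter region and scanned against the consensus, and its
    printed RPKM pair becomes its expression record. Table-2 genes are
    expected up in the mutant and Table-3 genes down, so the published
    fold-change columns (mut/wt and wt/mut respectively) both fold to the
    same symmetric value recomputed here.

    Returns (hits_by_gene, expression_records, products).
    """
    df = datasets.load_regulon_tables()
    hits: dict[str, list[MotifHit]] = {}
    expr: list[ExpressionRecord] = []
    products: dict[str, str] = {}
    for row in df.itertuples():
        site_hits = scan_sequence(
            row.binding_site, consensus, max_mismatch=max_mismatch,
            both_strands=True, gene_id=row.gene_id,
        )
        if site_hits:
            hits[row.gene_id] = site_hits
        expr.append(ExpressionRecord(row.gene_id, row.rpkm_wt, row.rpkm_mut))
        products[row.gene_id] = row.product
    return hits, expr, products


# ---------------------------------------------------------------------------
# end-to-end pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genome: str
    annotations: str
    counts: str
    sites: str
    tss: Optional[str] = None
    truth: Optional[str] = None  # optional truth.json for recall reporting
    upstream: int = 200
    downstream: int = 20
    min_frequency: float = 0.25
    max_mismatch: int = 1
    both_strands: bool = True
    fc_threshold: float = 2.0
    epsilon: float = 0.01
    min_rpkm: float = 0.0
    rpkm_input: bool = False  # counts file already holds rpkm_wt/rpkm_mut
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _md5(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _provenance(config: PipelineConfig) -> list[str]:
    lines = ["# phar-regulon pipeline output"]
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        lines.append(f"# {f.name}: {value}")
        if f.name in ("genome", "annotations", "counts", "sites", "tss", "truth") and value:
            digest = _md5(value) if Path(value).exists() else "missing"
            lines.append(f"# md5({f.name}): {digest}")
    return lines


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run promoters -> consensus -> scan -> DE -> regulon, writing every
    stage's table (with a provenance header) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    results: dict = {}
    timings: list[str] = []

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc
        dt = time.perf_counter() - t0
        timings.append(f"{name}: {dt:.3f} s")
        logger.info("stage %s finished in %.3f s", name, dt)
        return value

    def _promoters():
        genome = load_genome(config.genome)
        genes = load_annotations(config.annotations, genome)
        tss = load_tss(config.tss) if config.tss else {}
        proms = extract_promoters(genes, tss, genome, config.upstream, config.downstream)
        results["genes"] = genes
        return proms

    promoters = stage("promoters", _promoters)

    def _consensus():
        sites = load_sites(config.sites)
        pfm = build_pfm(sites)
        return pfm, derive_iupac_consensus(pfm, config.min_frequency)

    pfm, consensus = stage("consensus", _consensus)

    hits = stage(
        "scan",
        lambda: scan_promoters(promoters, consensus, config.max_mismatch, config.both_strands),
    )

    def _de():
        if config.rpkm_input:
            df = pd.read_csv(config.counts, sep="\t", comment="#")
            return [
                ExpressionRecord(r.gene_id, r.rpkm_wt, r.rpkm_mut)
                for r in df.itertuples()
            ]
        return rpkm_table(load_counts(config.counts))

    expr = stage("de", _de)

    products = {g.gene_id: g.product for g in results["genes"]}
    tables = stage(
        "infer_regulon",
        lambda: infer_regulon(hits, expr, config.fc_threshold, config.epsilon, products),
    )

    results.update(
        consensus=consensus, pfm=pfm, promoters=promoters, hits=hits,
        expression=expr, tables=tables,
    )

    # --- outputs
    (outdir / "consensus.txt").write_text(
        "\n".join(prov + [str(consensus)]) + "\n"
    )
    _write_tsv(pfm.to_frame(), outdir / "pfm.tsv", prov)
    _write_tsv(promoters_to_frame(promoters), outdir / "promoters.tsv", prov)
    _write_tsv(hits_to_frame(hits), outdir / "hits.tsv", prov)

    de_rows = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in expr],
            "rpkm_wt": [round_half_up(e.rpkm_wt, 2) for e in expr],
            "rpkm_mut": [round_half_up(e.rpkm_mut, 2) for e in expr],
            "fold_change": [round_half_up(fold_change(e, config.epsilon).fold_change, 2) for e in expr],
            "direction": [fold_change(e, config.epsilon).direction for e in expr],
        }
    )
    _write_tsv(de_rows, outdir / "de.tsv", prov)
    _write_tsv(candidates_to_frame(list(tables.repressed)), outdir / "regulon_repressed.tsv", prov)
    _write_tsv(candidates_to_frame(list(tables.activated)), outdir / "regulon_activated.tsv", prov)
    _write_tsv(candidates_to_frame(list(tables.bound_no_de)), outdir / "bound_no_de.tsv", prov)

    report = prov + [
        "#",
        f"genes: {len(results['genes'])}",
        f"promoters: {len(promoters)}",
        f"consensus: {consensus}",
        f"genes_with_hits: {len(hits)}",
        f"repressed_candidates: {len(tables.repressed)}",
        f"activated_candidates: {len(tables.activated)}",
        f"bound_no_de: {len(tables.bound_no_de)}",
    ]

    if config.truth:
        from .simulate import SyntheticTruth

        truth = SyntheticTruth.from_json(config.truth)
        if truth.sites:
            recovered = 0
            for planted in truth.sites:
                gene_hits = hits.get(planted.gene_id, [])
                if any(
                    h.offset == planted.offset and h.strand == planted.strand
                    for h in gene_hits
                ):
                    recovered += 1
            recall = recovered / len(truth.sites)
            results["planted_site_recall"] = recall
            report.append(f"planted_site_recall: {recall:.4f}")

    report += ["# timings"] + [f"# {t}" for t in timings]
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return results
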