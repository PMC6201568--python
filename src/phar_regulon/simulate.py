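"""Seed-reproducible synthetic data with the structure the pipeline assumes.

Four generators mirror the four kinds of evidence the analysis consumes: a
synthetic genome with motif instances planted in promoter windows; paired
negative-binomial count tables with fold changes planted on the
site-carrying genes (repressed genes up in the mutant, activated genes
down); DNase I footprint traces with a planted protection window; and
single-site equilibrium binding curves. Every generator is a pure function
of (parameters, seed) and records its planted truth, so downstream recall,
precision and recovery error can be scored without re-reading generator
internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import BindingCurve, FootprintTrace
from .datasets import EMSA_CONCENTRATIONS_NM, PHAR_CONSENSUS
from .genome import (
    GeneAnnotation,
    GenomeSequence,
    TSSRecord,
    reverse_complement,
)
from .motif import BASES, IUPAC_SETS, IUPACConsensus, PositionFrequencyMatrix

REPRESSED = "repressed"
ACTIVATED = "activated"


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    offset: int  # 0-based within the promoter's 5'->3' sequence
    strand: str  # orientation relative to the promoter
    sequence: str  # site in promoter orientation
    genomic_start: int  # 1-based leftmost genomic coordinate


@dataclass
class SyntheticTruth:
    """Record of everything planted by the generators."""

    seed: int
    sites: list[PlantedSite] = field(default_factory=list)
    directions: dict[str, str] = field(default_factory=dict)  # gene -> repressed|activated
    fold_changes: dict[str, float] = field(default_factory=dict)
    protection_window: Optional[tuple[int, int]] = None
    protection_depth: Optional[float] = None
    kd_nM: Optional[float] = None

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["sites"] = [dataclasses.asdict(s) for s in self.sites]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["sites"] = [PlantedSite(**s) for s in payload["sites"]]
        if payload.get("protection_window") is not None:
            payload["protection_window"] = tuple(payload["protection_window"])
        return cls(**payload)


@dataclass
class GenomeBundle:
    genome: dict[str, GenomeSequence]
    annotations: list[GeneAnnotation]
    tss: dict[str, TSSRecord]
    truth: SyntheticTruth
    upstream: int
    downstream: int


def _sample_site(
    rng: np.random.Generator,
    motif: IUPACConsensus | PositionFrequencyMatrix | str,
    mismatches: int = 0,
) -> str:
    """One site: drawn from a PFM column-wise, or a uniform expansion of a
    consensus, optionally mutated at ``mismatches`` random positions."""
    if isinstance(motif, PositionFrequencyMatrix):
        freqs = motif.frequencies()
        return "".join(
            BASES[rng.choice(4, p=freqs[j])] for j in range(motif.length)
        )
    if isinstance(motif, str):
        motif = IUPACConsensus(motif)
    site = [
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
        for c in motif.code_string
    ]
    if mismatches:
        for j in rng.choice(len(site), size=mismatches, replace=False):
            outside = sorted(set(BASES) - IUPAC_SETS[motif.code_string[j]])
            if outside:
                site[j] = outside[rng.integers(len(outside))]
    return "".join(site)


def generate_genome(
    n_genes: int = 50,
    intergenic_len: int = 600,
    motif: IUPACConsensus | PositionFrequencyMatrix | str = PHAR_CONSENSUS,
    fraction_with_site: float = 0.4,
    seed: int = 0,
    gene_length: int = 900,
    upstream: int = 200,
    downstream: int = 20,
    tss_offset: int = 60,
    gc: float = 0.5,
    planted_mismatches: int = 0,
    repressed_fraction: float = 0.5,
    contig_id: str = "syncontig1",
) -> GenomeBundle:
    """Synthetic genome with motif instances planted in promoter windows.

    Genes alternate strands along a single contig with fixed intergenic
    spacing; each gene's TSS sits ``tss_offset`` bp upstream of its start
    codon. A uniform-random fraction of genes receives one site (sampled
    from the motif) at a uniform-random offset within its
    [-upstream, +downstream] promoter window, on a random strand. Planted
    genes are split into future repressed/activated classes
    (``repressed_fraction`` of them repressed) for the count simulator.
    Background bases are i.i.d. with the given GC content.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    window_len = upstream + downstream + 1
    site_len = (
        motif.length
        if isinstance(motif, PositionFrequencyMatrix)
        else len(str(motif))
    )
    if window_len < site_len:
        raise ValueError("promoter window shorter than the site")
    if intergenic_len < upstream + tss_offset + 1:
        raise ValueError("intergenic_len too small for the promoter window")

    rng = np.random.default_rng(seed)
    total_len = intergenic_len + n_genes * (gene_length + intergenic_len)
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(list(BASES), size=total_len, p=p_base)

    annotations: list[GeneAnnotation] = []
    tss: dict[str, TSSRecord] = {}
    prom_coords: dict[str, tuple[int, int, str]] = {}  # genomic start, end, strand
    cursor = intergenic_len + 1
    for i in range(n_genes):
        gid = f"sg{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + gene_length - 1
        annotations.append(GeneAnnotation(gid, contig_id, start, end, strand, "synthetic gene"))
        anchor = start - tss_offset if strand == "+" else end + tss_offset
        tss[gid] = TSSRecord(gid, anchor, strand, "experimental")
        if strand == "+":
            prom_coords[gid] = (anchor - upstream, anchor + downstream, strand)
        else:
            prom_coords[gid] = (anchor - downstream, anchor + upstream, strand)
        cursor = end + intergenic_len + 1

    n_with_site = int(round(fraction_with_site * n_genes))
    site_gene_idx = np.sort(rng.choice(n_genes, size=n_with_site, replace=False))
    truth = SyntheticTruth(seed=seed)

    for i in site_gene_idx:
        gene = annotations[i]
        p_start, p_end, strand = prom_coords[gene.gene_id]
        site = _sample_site(rng, motif, planted_mismatches)
        offset = int(rng.integers(0, window_len - site_len + 1))
        site_strand = "+" if rng.random() < 0.5 else "-"
        oriented = site if site_strand == "+" else reverse_complement(site)
        if strand == "+":
            gstart = p_start + offset
            genomic_content = oriented
        else:
            gstart = p_end - offset - (site_len - 1)
            genomic_content = reverse_complement(oriented)
        seq[gstart - 1 : gstart - 1 + site_len] = list(genomic_content)
        truth.sites.append(
            PlantedSite(gene.gene_id, offset, site_strand, site, gstart)
        )

    order = rng.permutation(len(site_gene_idx))
    n_rep = int(round(repressed_fraction * len(site_gene_idx)))
    for rank, k in enumerate(order):
        gid = annotations[site_gene_idx[k]].gene_id
        truth.directions[gid] = REPRESSED if rank < n_rep else ACTIVATED

    genome = {contig_id: GenomeSequence(contig_id, "".join(seq))}
    return GenomeBundle(genome, annotations, tss, truth, upstream, downstream)


def simulate_counts(
    truth: SyntheticTruth,
    annotations: Sequence[GeneAnnotation],
    baseline_mean: float = 500.0,
    dispersion: float = 10.0,
    fc_up: float = 8.0,
    fc_down: float = 8.0,
    library_size_factors: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count table for WT and mutant conditions.

    Site-carrying genes marked repressed get mutant mean x``fc_up``; those
    marked activated get mutant mean /``fc_down``; all other genes keep the
    baseline in both conditions. ``dispersion`` is the NB size (shape)
    parameter, variance mu + mu^2/size; ``numpy.inf`` gives the Poisson
    limit. The expected class of every gene is written back into
    ``truth.fold_changes``.
    """
    if fc_up < 1 or fc_down < 1:
        raise ValueError("fold changes must be >= 1")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    rng = np.random.default_rng(seed)

    def draw(mean: float) -> int:
        if mean <= 0:
            raise ValueError("nonpositive NB mean")
        if np.isinf(dispersion):
            return int(rng.poisson(mean))
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))

    lib_wt, lib_mut = library_size_factors
    rows = []
    for gene in annotations:
        direction = truth.directions.get(gene.gene_id)
        mu_wt = baseline_mean
        if direction == REPRESSED:
            mu_mut, fc = baseline_mean * fc_up, fc_up
        elif direction == ACTIVATED:
            mu_mut, fc = baseline_mean / fc_down, fc_down
        else:
            mu_mut, fc = baseline_mean, 1.0
        truth.fold_changes[gene.gene_id] = fc
        rows.append(
            {
                "gene_id": gene.gene_id,
                "length_bp": gene.length,
                "count_WT": draw(mu_wt * lib_wt),
                "count_MUT": draw(mu_mut * lib_mut),
            }
        )
    return pd.DataFrame(rows)


def simulate_footprint(
    length: int = 200,
    window: tuple[int, int] = (40, 51),
    depth: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
    label: str = "synthetic footprint",
) -> tuple[FootprintTrace, SyntheticTruth]:
    """Footprint trace pair with a planted protection window.

    The control is unit intensity plus truncated Gaussian noise; the bound
    channel is the control scaled by ``depth`` inside the window (1.0
    outside) plus independent noise. ``window`` is 1-based inclusive trace
    coordinates.
    """
    start, end = window
    if not (1 <= start <= end <= length):
        raise ValueError(f"window {window} outside trace of length {length}")
    if not 0 <= depth <= 1:
        raise ValueError("depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.arange(1, length + 1)
    control = np.clip(1.0 + rng.normal(0, noise_sd, length), 0, None)
    factor = np.where((positions >= start) & (positions <= end), depth, 1.0)
    bound = np.clip(control * factor + rng.normal(0, noise_sd, length), 0, None)
    trace = FootprintTrace(label, positions, control, bound)
    truth = SyntheticTruth(
        seed=seed, protection_window=(start, end), protection_depth=depth
    )
    return trace, truth


def simulate_binding_curve(
    kd_nM: float = 25.0,
    concentrations: Sequence[float] = EMSA_CONCENTRATIONS_NM,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[BindingCurve, SyntheticTruth]:
    """Single-site binding curve f = [P]/([P]+Kd) with Gaussian noise,
    clipped to [0, 1]."""
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, float)
    f = conc / (conc + kd_nM)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0, noise_sd, len(conc)), 0, 1)
    return BindingCurve(conc, f), SyntheticTruth(seed=seed, kd_nM=kd_nM)


# ---------------------------------------------------------------------------
# file emission (same formats the analysis modules consume)


def write_genome_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotations": outdir / "annotations.tsv",
        "tss": outdir / "tss.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["genome"], "w") as fh:
        for contig in bundle.genome.values():
            fh.write(f">{contig.contig_id}\n")
            for i in range(0, len(contig.sequence), 70):
                fh.write(contig.sequence[i : i + 70] + "\n")
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in bundle.annotations],
            "contig": [g.contig_id for g in bundle.annotations],
            "start": [g.start for g in bundle.annotations],
            "end": [g.end for g in bundle.annotations],
            "strand": [g.strand for g in bundle.annotations],
            "product": [g.product for g in bundle.annotations],
        }
    ).to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in bundle.tss.values()],
            "position": [t.position for t in bundle.tss.values()],
            "strand": [t.strand for t in bundle.tss.values()],
            "source": [t.source for t in bundle.tss.values()],
        }
    ).to_csv(paths["tss"], sep="\t", index=False)
    bundle.truth.to_json(paths["truth"])
    return paths
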