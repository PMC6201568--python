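"""Packaged reference data: published PhaR binding sites and regulon tables.

The package ships the published evidence needed to rebuild the PhaR
consensus and the candidate regulon tables for B. diazoefficiens USDA110
without any download: the three footprint-mapped 12-mer binding sites, the
eight printed 12-mers underlying the consensus, the published degenerate
consensus itself, the EMSA titration series, and the 70-row
repressed/activated candidate tables (gene, binding site, RPKM pair, fold
change, product).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .motif import BindingSite

#: Published degenerate PhaR-binding consensus (R=A/G, Y=C/T, S=C/G, M=A/C).
PHAR_CONSENSUS = "TGCRNYGCASMA"

#: 12-mer sites mapped by DNase I footprinting (two in the phaP1 promoter,
#: one in phaP4).
FOOTPRINT_SITES = (
    BindingSite("TGCGACGCACAA", "phaP1", "footprint"),
    BindingSite("TGCGTCGCACAA", "phaP1", "footprint"),
    BindingSite("TGCGCTGCACAA", "phaP4", "footprint"),
)

#: The eight printed 12-mer sites behind the consensus derivation: the three
#: footprint sites plus the sites reported for phaP5, phaZ1, phaZ3, cyoA and
#: the exoZ-operon gene blr2367. (The original alignment also included the
#: phaR promoter region, whose site sequence was not printed.)
CONSENSUS_INPUT_SITES = FOOTPRINT_SITES + (
    BindingSite("TGCATCGCACAA", "phaP5", "table"),
    BindingSite("CGCATCGCAGCA", "phaZ1", "table"),
    BindingSite("TGCAGTGCAGCA", "phaZ3", "table"),
    BindingSite("TGCGGCGCAGCA", "cyoA", "table"),
    BindingSite("TGCACCGCAGCA", "blr2367", "table"),
)

#: EMSA protein titration series, nM.
EMSA_CONCENTRATIONS_NM = (0.0, 1.72, 3.44, 6.88, 13.8, 27.5, 55.0, 110.0)


def load_regulon_tables() -> pd.DataFrame:
    """The 70 published regulon candidate rows (28 repressed, 42 activated).

    Columns: gene_id, gene_name, regulon_class, binding_site, rpkm_wt,
    rpkm_mut, fold_change, product. RPKM columns are wild type (USDA110)
    and the phaR deletion mutant; the printed fold change is mut/wt for
    repressed genes and wt/mut for activated genes, both >= 1.
    """
    ref = resources.files("phar_regulon").joinpath("data/regulon_tables.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df


def published_sites() -> list[BindingSite]:
    """All 70 binding sites from the published candidate tables."""
    df = load_regulon_tables()
    return [
        BindingSite(row.binding_site, row.gene_id, "table")
        for row in df.itertuples()
    ]
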