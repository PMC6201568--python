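#!/usr/bin/env python
"""Rebuild the repressed/activated regulon candidate tables.

Takes the packaged published evidence (each gene's printed binding site as
its promoter hit, its printed RPKM pair as its expression record), recomputes
every fold change from the RPKM pairs, and intersects binding with
differential expression at the strict twofold threshold.

Outputs: results/regulon_repressed.tsv, results/regulon_activated.tsv
"""

from pathlib import Path

from phar_regulon import fixture_from_published_tables, infer_regulon
from phar_regulon.regulon import candidates_to_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    hits, expr, products = fixture_from_published_tables(max_mismatch=1)
    tables = infer_regulon(hits, expr, fc_threshold=2.0, products=products)

    candidates_to_frame(list(tables.repressed)).to_csv(
        OUT / "regulon_repressed.tsv", sep="\t", index=False
    )
    candidates_to_frame(list(tables.activated)).to_csv(
        OUT / "regulon_activated.tsv", sep="\t", index=False
    )

    print(f"repressed candidates (up in the deletion mutant): {len(tables.repressed)}")
    print(f"activated candidates (down in the deletion mutant): {len(tables.activated)}")
    top = max(tables.repressed, key=lambda c: c.fold_change)
    print(f"strongest derepression: {top.gene_id} ({top.product}), "
          f"fold change {top.fold_change}")


if __name__ == "__main__":
    main()
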