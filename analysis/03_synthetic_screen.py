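#!/usr/bin/env python
"""Benchmark the genome-wide screen on synthetic data with planted truth.

Generates a synthetic genome (50 genes, 40% carrying an exact-consensus
site in their promoter window), simulates negative-binomial counts with
8-fold planted changes, runs the full file-based pipeline, and scores
planted-site recall, background false positives against the analytic
expectation, and fold-change recovery across 20 seeds.

Outputs: results/synthetic_run/ (one full pipeline run),
         results/synthetic_benchmarks.tsv
"""

import argparse
from pathlib import Path

import pandas as pd

from phar_regulon import (
    ExpressionRecord,
    PHAR_CONSENSUS,
    PipelineConfig,
    classify_de,
    consensus_match_probability,
    extract_promoters,
    generate_genome,
    run_pipeline,
    scan_promoters,
    simulate_counts,
    write_genome_bundle,
)
from phar_regulon.datasets import CONSENSUS_INPUT_SITES

OUT = Path(__file__).resolve().parents[1] / "results"


def one_pipeline_run(seed: int) -> None:
    workdir = OUT / "synthetic_run"
    indir = workdir / "inputs"
    bundle = generate_genome(n_genes=50, fraction_with_site=0.4, seed=seed)
    paths = write_genome_bundle(bundle, indir)
    counts = simulate_counts(bundle.truth, bundle.annotations, seed=seed)
    counts.to_csv(indir / "counts.tsv", sep="\t", index=False)
    with open(indir / "sites.txt", "w") as fh:
        for s in CONSENSUS_INPUT_SITES:
            fh.write(s.sequence + "\n")
    cfg = PipelineConfig(
        genome=str(paths["genome"]), annotations=str(paths["annotations"]),
        tss=str(paths["tss"]), counts=str(indir / "counts.tsv"),
        sites=str(indir / "sites.txt"), truth=str(paths["truth"]),
        fc_threshold=2.0, seed=seed,
    )
    res = run_pipeline(cfg, workdir)
    tables = res["tables"]
    print(f"pipeline run (seed {seed}): planted-site recall "
          f"{res['planted_site_recall']:.2f}; "
          f"{len(tables.repressed)} repressed / {len(tables.activated)} activated "
          f"candidates at twofold -> {workdir}")
    print("(with 40% of genes planted, RPKM library normalization compresses "
          "mutant-up fold changes — composition bias, negligible at genome scale)")


def seed_sweep(seed: int, n_seeds: int) -> None:
    p1 = consensus_match_probability(PHAR_CONSENSUS, 1)
    rows = []
    for i in range(n_seeds):
        s = seed + i
        bundle = generate_genome(n_genes=50, fraction_with_site=0.4, seed=s)
        proms = extract_promoters(
            bundle.annotations, bundle.tss, bundle.genome,
            bundle.upstream, bundle.downstream,
        )
        hits = scan_promoters(proms, PHAR_CONSENSUS, max_mismatch=1)
        planted = {t.gene_id: t for t in bundle.truth.sites}
        recall = sum(
            any(h.offset == t.offset and h.strand == t.strand
                for h in hits.get(t.gene_id, []))
            for t in bundle.truth.sites
        ) / len(bundle.truth.sites)
        fp = sum(
            1
            for g, hl in hits.items()
            for h in hl
            if not (g in planted and abs(h.offset - planted[g].offset) < 12)
        )
        window = bundle.upstream + bundle.downstream + 1
        fp_expected = 50 * 2 * (window - 11) * p1

        counts = simulate_counts(
            bundle.truth, bundle.annotations,
            baseline_mean=500, dispersion=10, fc_up=8, fc_down=8, seed=s,
        )
        recs = [ExpressionRecord(r.gene_id, r.count_WT, r.count_MUT)
                for r in counts.itertuples()]
        out = classify_de(recs, 4)
        up = {d.gene_id for d in out["up"]}
        down = {d.gene_id for d in out["down"]}
        de_rec = sum(
            (g in up) if d == "repressed" else (g in down)
            for g, d in bundle.truth.directions.items()
        ) / len(bundle.truth.directions)
        rows.append(
            {"seed": s, "site_recall": recall, "false_positive_hits": fp,
             "fp_expected": round(fp_expected, 3), "de_recovery": de_rec}
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "synthetic_benchmarks.tsv", sep="\t", index=False)
    print(f"{n_seeds}-seed sweep: mean site recall {df.site_recall.mean():.3f}, "
          f"total FP {df.false_positive_hits.sum()} vs expected "
          f"{df.fp_expected.sum():.1f}, mean DE recovery {df.de_recovery.mean():.3f}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=20)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)
    one_pipeline_run(args.seed)
    seed_sweep(args.seed, args.n_seeds)


if __name__ == "__main__":
    main()
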