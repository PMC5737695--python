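"""Last-exon differential-expression statistics on a synthetic exon-level
DE table: Fisher enrichment of DE among last vs internal exonic parts,
up/down direction summary, and the per-position (from the 3' end)
fold-change profile.

Uses a 300-gene annotation so the exonic-part table has enough last
exons for the enrichment test to be informative."""

import json

from common import RESULTS

from clipscape.pipeline import stage_exonstats
from clipscape.simulate import SimConfig, simulate_gene_models


def main():
    cfg = SimConfig(seed=0, n_genes=300, genome_len=1_500_000)
    ann, _ = simulate_gene_models(cfg)
    de, enr, dirs = stage_exonstats(cfg, ann, RESULTS)
    (a, b), (c, d) = enr.table
    print(f"exonic parts: {len(de)} ({int(de.is_last.sum())} last exons)")
    print(f"last-exon DE enrichment: table [[{a},{b}],[{c},{d}]], "
          f"OR = {enr.odds_ratio:.1f}, Fisher p = {enr.p:.2e}")
    print(f"direction (|log2FC| >= 0.5, FDR < 0.05): "
          f"last exons {dirs['last']['up']} up / {dirs['last']['down']} down; "
          f"internal {dirs['internal']['up']} up / {dirs['internal']['down']} down")
    print(f"tables: {RESULTS / 'exon_de.tsv'}, "
          f"{RESULTS / 'position_profile.tsv'}, {RESULTS / 'exonstats.json'}")


if __name__ == "__main__":
    main()
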