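"""Build the synthetic study fixture: a 12-gene ~100 kb genome, three
CLIP and three input replicates of 50k aligned reads, 16 planted 8-fold
binding clusters with crosslink deletions carrying a pyrimidine-rich
5-mer, and ground-truth BED/JSON manifests."""

import json

from common import FIXTURES, get_fixture


def main():
    ref, exp = get_fixture()
    manifest = json.loads((FIXTURES / "manifest.json").read_text())
    print(f"fixture written to {FIXTURES}")
    print(f"  genes: {manifest['n_genes']} "
          f"({sum(1 for g in manifest['genes'].values() if g['biotype'] == 'mRNA')} mRNA)")
    print(f"  planted clusters: {manifest['n_planted_clusters']} "
          f"(fold {manifest['config']['fold_enrichment']})")
    print(f"  crosslink sites: {manifest['n_xlink_sites']}, "
          f"motif {manifest['motif']!r} at "
          f"{manifest['config']['motif_site_fraction']:.0%} of sites")
    print(f"  CLIP replicates: {len(exp.clip_bams)} x "
          f"{manifest['config']['library_size_clip']} reads; "
          f"input: {len(exp.input_bams)} x "
          f"{manifest['config']['library_size_input']}")


if __name__ == "__main__":
    main()
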