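"""Trans-band detection and category enrichment of hotspot members.

Scatters background trans-eQTL over the 203-bin WS220 genome, plants one
hotspot of 55 co-mapping trans-eQTL, flags bins exceeding the Poisson
null, and runs a hypergeometric enrichment of the hotspot's member genes
against synthetic functional categories.
"""

import numpy as np
import pandas as pd

from crypteqtl import (
    CategoryTable,
    EQTLRecord,
    WS220_CHROM_LENGTHS,
    count_trans_per_bin,
    enrich,
    genome_bins,
    poisson_transbands,
)

rng = np.random.default_rng(5)
chroms = list(WS220_CHROM_LENGTHS)


def record(spot, chrom, pos):
    return EQTLRecord(
        spot_id=spot, gene_id=f"gene_{spot}", peak_marker="m", chromosome=chrom,
        position_bp=pos, neg_log10_p=4.5, effect=0.8, variance_explained=0.3,
        ci_left_bp=max(1, pos - 250_000), ci_right_bp=pos + 250_000,
        qtl_type="trans", treatment="gld1_rnai",
    )


records = [
    record(f"bg{i}", c := chroms[rng.integers(6)],
           int(rng.integers(1, WS220_CHROM_LENGTHS[c] + 1)))
    for i in range(180)
]
records += [record(f"hot{i}", "IV", int(2_500_001 + rng.integers(500_000)))
            for i in range(55)]

bins = genome_bins()
counts, members = count_trans_per_bin(records, bins)
bands = poisson_transbands(counts, bins, members, alpha=1e-4)
lam = counts.sum() / len(bins)
print(f"{len(bins)} bins, {counts.sum()} trans-eQTL, lambda = {lam:.2f}/bin")
for b in bands:
    print(f"trans-band {b.chromosome}:{(b.start_bp - 1) / 1e6:.1f}-"
          f"{b.end_bp / 1e6:.1f} Mb with {b.count} trans-eQTL "
          f"(Poisson P = {b.p_poisson:.2e})")

# enrichment of the band members against synthetic categories; category
# "stress_response" contains 30 of the hotspot genes
band_genes = set(bands[0].genes)
categories = {"stress_response": [f"gene_hot{i}" for i in range(30)]
              + [f"gene_bg{i}" for i in range(10)],
              "cuticle": [f"gene_bg{i}" for i in range(20, 60)]}
rows = [(c, "synthetic", g) for c, gs in categories.items() for g in gs]
table = CategoryTable(pd.DataFrame(rows, columns=["category_id", "source", "gene_id"]))
universe = {r.gene_id for r in records}
for res in enrich(band_genes, table, universe):
    print(f"category {res.category_id}: {res.overlap}/{res.category_size} members "
          f"in the band, P = {res.p_value:.2e} (Bonferroni {res.p_adj:.2e})")
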