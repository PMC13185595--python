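#!/usr/bin/env python
"""OGT-associated gene discovery on the synthetic gene matrix.

Runs the extreme-pair screen (within-genus high-vs-low OGT contrasts)
and the psychrophile screen, Bonferroni-corrects them, selects the top
50 genes from each, and checks how many planted OGT-coupled orthologs
were recovered. A block pathway map demonstrates the hypergeometric
over-representation step.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermolag import io
from thermolag.genes import (
    extract_extreme_pairs,
    fisher_screen,
    pathway_enrichment,
    psychrophile_screen,
    select_top_genes,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"
SCRATCH = ROOT / "scratch"


def main() -> None:
    matrix = io.read_tsv(SCRATCH / "gene_matrix.tsv", index_col="species_id")
    curated = io.read_tsv(OUT / "curated.tsv")
    taxonomy = io.read_tsv(OUT / "taxonomy.tsv")
    gene_info = io.read_tsv(OUT / "gene_info.tsv")
    ogt = curated.set_index("species_id")["ogt"]
    matrix = matrix.loc[matrix.index.intersection(ogt.index)]

    pairs = extract_extreme_pairs(ogt, taxonomy)
    sp = fisher_screen(matrix, pairs.high_group, pairs.low_group)
    ss = psychrophile_screen(matrix, ogt)
    top = select_top_genes(sp, ss, 50)
    io.write_tsv(sp.head(60), OUT / "screen_pairs_top.tsv")
    io.write_tsv(ss.head(60), OUT / "screen_psychrophiles_top.tsv")
    (OUT / "top_genes.txt").write_text("\n".join(top) + "\n")

    coupled = set(gene_info.loc[gene_info["coupling_mode"] != "none", "gene"])
    print(f"{len(pairs.pairs)} extreme pairs across genera")
    print(f"pair screen best gene: {sp.iloc[0]['gene']} (p={sp.iloc[0]['p']:.2e}, "
          f"Bonferroni={sp.iloc[0]['p_bonferroni']:.2e}, m={sp.iloc[0]['m']})")
    print(f"psychrophile screen best: {ss.iloc[0]['gene']} (p={ss.iloc[0]['p']:.2e})")
    print(f"{len(coupled & set(top))} of {len(coupled)} planted coupled genes in the top list")

    # block pathway map: 20 pathways of 25 genes; the first block holds
    # every planted gene, so it should dominate the enrichment table
    universe = list(matrix.columns)
    pw = pd.DataFrame(
        {"gene": universe, "pathway": [f"PW{int(i // 25):02d}" for i in range(len(universe))]}
    )
    enr = pathway_enrichment(top, pw, universe)
    io.write_tsv(enr, OUT / "pathway_enrichment.tsv")
    print(enr.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
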