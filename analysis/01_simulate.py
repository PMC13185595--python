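#!/usr/bin/env python
"""Generate the standard 200-species synthetic study.

Writes the tree, taxonomy, true/lagged OGT, gene matrix and noisy OGT
databases under results/synthetic/ (small tables) and the genome FASTA
bundles under scratch/genomes/ (bulky, regenerable).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermolag import io, synthetic
from thermolag.synthetic import SimConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed)
    tree, taxonomy = synthetic.simulate_tree(cfg)
    history = synthetic.simulate_ogt(tree, cfg)
    bundles, truth = synthetic.simulate_genomes(tree, history, cfg)
    matrix, events, gene_info = synthetic.simulate_gene_content(tree, history, cfg)
    sources, meta = synthetic.simulate_ogt_sources(tree, history, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    tree.write(OUT / "tree.nwk")
    io.write_tsv(taxonomy, OUT / "taxonomy.tsv")
    io.write_tsv(truth, OUT / "ogt_truth.tsv")
    io.write_tsv(gene_info, OUT / "gene_info.tsv")
    io.write_tsv(events, SCRATCH / "gene_events.tsv")
    io.write_tsv(matrix, SCRATCH / "gene_matrix.tsv", index=True)
    io.write_tsv(meta, OUT / "metadata.tsv")
    for i, src in enumerate(sources, 1):
        io.write_tsv(src, SCRATCH / f"ogt_source_{i}.tsv")
    io.write_bundles(bundles, SCRATCH / "genomes")

    n_jump = len(history.jump_branches)
    print(f"simulated {cfg.n_tips} species; tree height {tree.height():.2f}")
    print(f"{n_jump} OGT jump branches; {len(events)} gene gain/loss events")
    print(f"tables -> {OUT}; genomes and bulky tables -> {SCRATCH}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
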