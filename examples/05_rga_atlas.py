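"""Resistance-gene-analog atlas: physical clusters, divergent paired
NLRs, and the pan-RGA occupancy partition.

Genes of one family within 200 kb of each other chain into clusters;
paired NLRs are adjacent NBS genes in head-to-head (-,+) orientation
with facing promoters.
"""

import numpy as np
import pandas as pd

from pankiwi.model import FamilyMatrix
from pankiwi.rga import cluster_genes, paired_nlr, paired_nlr_rates, pan_rga, pan_rga_summary
from pankiwi.simulate import SimulationConfig, simulate_rga_geneset

cfg = SimulationConfig(seed=42)
genes, truth = simulate_rga_geneset(cfg)

clusters = cluster_genes(genes, max_gap=200_000)
print(f"{len(clusters)} clusters called; planted {len(truth['clusters'])} "
      f"(sizes {[len(c) for c in clusters]})")

pairs = paired_nlr(genes, max_gap=20_000)
rates = paired_nlr_rates(genes, pairs)
print(f"{len(pairs)} paired NLRs; planted {len(truth['pairs'])}; "
      f"decoy tail-to-tail pairs rejected: {len(truth['decoys'])}")
print(f"{rates['genes_in_pairs_pct']}% of NBS genes sit in pairs")

# pan-RGA: occupancy partition of an RGA-restricted family matrix
rng = np.random.default_rng(42)
counts = pd.DataFrame(rng.integers(0, 3, size=(60, 15)),
                      index=[f"R{i:03d}" for i in range(60)],
                      columns=[f"asm{j + 1:02d}" for j in range(15)])
counts = counts[counts.sum(axis=1) >= 1]
classes = {f: ["NBS", "RLK", "RLP", "TM-CC"][i % 4]
           for i, f in enumerate(counts.index)}
result, per_class = pan_rga(FamilyMatrix(counts), class_of_family=classes)
print("\npan-RGA composition:")
print(pan_rga_summary(result).to_string(index=False))
print("\nper-class occupancy shares (%):")
print(per_class.to_string(index=False))
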