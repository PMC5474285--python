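#!/usr/bin/env python
"""Organ-localization of target genes on a synthetic expression atlas.

Generates a seeded 84-tissue log-normal atlas over the packaged target
symbols, plants 8x overexpression for a subset of genes in panel tissues,
computes strict above-gene-mean calls, and ranks the 17 immunity-related
panel organs by call frequency.

Finding: every planted (gene, organ) pair is recovered. Because a
log-normal baseline is right-skewed, many unplanted cells also exceed
the gene mean by chance, so the frequency ranking mixes planted signal
with that background - a property the strict above-mean rule shares
with its use on real atlas data.
"""

from pathlib import Path

import numpy as np

from herbnet import core_io
from herbnet.organ_expression import (above_average_calls,
                                      build_organ_network,
                                      genes_in_at_least_k_organs,
                                      organ_frequency)
from herbnet.synthetic import gen_expression_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
N_TISSUES = 84


def main() -> None:
    panel = core_io.load_organ_panel()
    symbols = sorted({t.gene_symbol for t in core_io.load_target_fixture()})
    extra = [f"Other tissue {j + 1:02d}" for j in range(N_TISSUES - len(panel))]
    tissues = panel + extra
    rng = np.random.default_rng(SEED)
    planted = set()
    for g in rng.choice(symbols, size=60, replace=False):
        for t in rng.choice(panel, size=3, replace=False):
            planted.add((str(g), str(t)))
    matrix, truth = gen_expression_matrix(
        len(symbols), tissues, set(), boost=8.0, sigma=0.5, seed=SEED)
    matrix.values.index = symbols
    for g, t in planted:
        matrix.values.at[g, t] *= 8.0

    calls = above_average_calls(matrix, organ_panel=panel)
    freq = organ_frequency(calls)
    recovered = sum(1 for g, t in planted if bool(calls.calls.at[g, t]))
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "05_organ_frequency.tsv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("tissue\tn_genes\n")
        for tissue, count in freq:
            fh.write(f"{tissue}\t{count}\n")
    net = build_organ_network(calls)
    core_io.write_network(net, RESULTS / "05_organ_network.sif", "sif")
    print(f"genes profiled            : {len(symbols)} over {N_TISSUES} tissues")
    print(f"planted calls recovered   : {recovered}/{len(planted)}")
    print(f"genes with >=1 panel call : "
          f"{len(genes_in_at_least_k_organs(calls, 1))}")
    print(f"genes with >=2 panel calls: "
          f"{len(genes_in_at_least_k_organs(calls, 2))}")
    print(f"top organs by frequency   : {freq[:5]}")
    print(f"wrote {out} and 05_organ_network.sif")


if __name__ == "__main__":
    main()
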