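#!/usr/bin/env python
"""Moderated-t differential expression across six synthetic two-group
datasets, top-250 union, and intersection with the target gene set.

Each dataset plants upregulated genes (3 sigma shift, 10 samples per
group), 23 of which across the union are target symbols; the per-dataset
top-250 lists are unioned with deduplication and intersected with the
packaged 182-target table.

Finding: the planted 23-gene overlap is recovered exactly; the moderated
t with an empirical-Bayes variance prior ranks every planted gene inside
the per-dataset top lists.
"""

from pathlib import Path

import numpy as np

from herbnet import core_io
from herbnet.de_compare import (estimate_prior, intersect_targets,
                                moderated_t, top_upregulated, union_dedupe)
from herbnet.synthetic import gen_two_group_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
N_DATASETS = 6


def main() -> None:
    targets = core_io.load_target_fixture()
    symbols = sorted({t.gene_symbol for t in targets})
    rng = np.random.default_rng(SEED)
    overlap = sorted(str(g) for g in rng.choice(symbols, size=23,
                                                replace=False))
    top_lists = []
    for i in range(N_DATASETS):
        n_genes = 2000
        gene_ids = [f"G{j + 1:04d}" for j in range(n_genes)]
        # plant ~4 target symbols per dataset plus anonymous DE genes
        share = [overlap[j] for j in range(len(overlap))
                 if j % N_DATASETS == i]
        de_ids = gene_ids[:40]
        df, design, _ = gen_two_group_matrix(n_genes, 10, de_ids, 3.0,
                                             seed=SEED * 100 + i)
        # rename the first planted rows to the shared target symbols
        renames = dict(zip(de_ids[:len(share)], share))
        df = df.rename(index=renames)
        d0, s0 = estimate_prior(df.var(axis=1, ddof=1).to_numpy(), d=18)
        results = moderated_t(df, design, d0=d0, s0_sq=s0)
        top = top_upregulated(results, 250)
        top_lists.append(top)
        planted_found = sum(1 for g in share if g in top)
        print(f"dataset {i + 1}: top-{len(top)} extracted, prior "
              f"d0={d0:.1f} s0^2={s0:.2f}, "
              f"planted targets in top list {planted_found}/{len(share)}")

    union = union_dedupe(top_lists)
    common, rows = intersect_targets(union, symbols, targets)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "06_common_genes.tsv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tuniprot_id\tprotein_name\n")
        for g, acc, name in rows:
            fh.write(f"{g}\t{acc}\t{name}\n")
    print(f"union of {N_DATASETS} top lists : {len(union)} genes")
    print(f"intersection with targets : {len(common)} genes "
          f"(planted 23: {'recovered' if set(common) == set(overlap) else 'MISSED'})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
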