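"""Organ-localization of target genes from a gene x tissue expression atlas.

The localization rule is deliberately simple: for each gene, average its
expression over ALL tissues in the matrix (e.g. all 84 atlas tissues), call
the gene "overexpressed" in every tissue where expression strictly exceeds
that gene-wise mean, then count calls over a fixed immunity-related organ
panel and rank organs by frequency. A constant-expression gene is called
nowhere, and no gene can be called in every tissue of the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ExpressionMatrix
from .errors import ValidationError
from .netanalysis import BipartiteNetwork, build_bipartite


@dataclass
class OrganCallMatrix:
    """Boolean above-average calls with the per-gene means that defined them."""

    calls: pd.DataFrame           # genes x tissues, bool
    gene_means: pd.Series         # per-gene mean over all matrix tissues
    organ_panel: list[str]        # ordered tissue subset for counting

    def panel_calls(self) -> pd.DataFrame:
        missing = [t for t in self.organ_panel if t not in self.calls.columns]
        if missing:
            raise ValidationError(f"panel tissues missing from matrix: {missing}")
        return self.calls[self.organ_panel]


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: dict[str, str],
                    method: str = "max") -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    method 'max' (default; conservative for presence calls) or 'mean'.
    Probes absent from the mapping are dropped; the dropped count is
    attached as `matrix.values.attrs['n_unmapped_probes']`.
    """
    if method not in ("max", "mean"):
        raise ValidationError(f"unknown collapse method {method!r}")
    if not probe_to_gene:
        raise ValidationError("empty probe-to-gene mapping")
    df = matrix.values
    mapped = [p for p in df.index if p in probe_to_gene]
    n_unmapped = len(df.index) - len(mapped)
    sub = df.loc[mapped]
    genes = pd.Index([probe_to_gene[p].upper() for p in mapped], name="gene")
    grouped = sub.groupby(genes)
    out = grouped.max() if method == "max" else grouped.mean()
    out.attrs["n_unmapped_probes"] = n_unmapped
    return ExpressionMatrix(values=out)


def above_average_calls(matrix: ExpressionMatrix,
                        organ_panel: list[str] | None = None
                        ) -> OrganCallMatrix:
    """Call each (gene, tissue) where expression strictly exceeds the
    gene's mean over all tissues in the matrix."""
    df = matrix.values
    if df.shape[0] == 0:
        raise ValidationError("empty expression matrix")
    if df.shape[1] < 2:
        raise ValidationError(
            "above-average calls need at least two tissues (with one tissue "
            "each gene's value equals its mean)")
    means = df.mean(axis=1)
    calls = df.gt(means, axis=0)
    panel = list(organ_panel) if organ_panel is not None else list(df.columns)
    return OrganCallMatrix(calls=calls, gene_means=means, organ_panel=panel)


def organ_frequency(calls: OrganCallMatrix) -> list[tuple[str, int]]:
    """Per-panel-organ count of genes called there, descending; ties
    broken lexicographically by tissue label."""
    if not calls.organ_panel:
        raise ValidationError("empty organ panel")
    pc = calls.panel_calls()
    counts = pc.sum(axis=0)
    return sorted(((t, int(counts[t])) for t in calls.organ_panel),
                  key=lambda x: (-x[1], x[0]))


def genes_in_at_least_k_organs(calls: OrganCallMatrix, k: int) -> set[str]:
    """Genes with >= k above-average calls within the panel."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    pc = calls.panel_calls()
    per_gene = pc.sum(axis=1)
    return set(per_gene.index[per_gene >= k])


def genes_in_all_panel_organs(calls: OrganCallMatrix) -> set[str]:
    """Genes called above average in every panel tissue."""
    if not calls.organ_panel:
        raise ValidationError("empty organ panel")
    pc = calls.panel_calls()
    return set(pc.index[pc.all(axis=1)])


def build_organ_network(calls: OrganCallMatrix) -> BipartiteNetwork:
    """Organ-gene bipartite network over the panel; genes (and organs)
    without any panel call are omitted entirely."""
    pc = calls.panel_calls()
    edges = [(t, g) for g in pc.index for t in calls.organ_panel
             if bool(pc.at[g, t])]
    organs_with_calls = [t for t in calls.organ_panel
                         if any(t == e[0] for e in edges)]
    genes_with_calls = sorted({g for _t, g in edges})
    return build_bipartite(edges, left_ids=organs_with_calls,
                           right_ids=genes_with_calls)
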