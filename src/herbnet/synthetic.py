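"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here so all stages are
testable without any database download. Generators are pure functions of
their arguments including the seed, and they force values to the intended
side of each screening threshold rather than sampling and hoping, so
planted counts are exact and tests never flake. Distribution choices
(log-normal expression baselines, shifted-geometric target degrees) are
pragmatic emulations of atlas and interaction data, not claimed to be
statistically faithful to any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (CompoundRecord, ExpressionMatrix, InteractionEdge,
                      TargetRecord)
from .de_compare import CONTROL, DISEASE, GroupDesign
from .errors import ValidationError

DEFAULT_THRESHOLDS = (15.0, -0.4, 0.18)  # OB%, Caco-2, DL


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream assertions."""

    seed: int
    pass_ids: set[str] = field(default_factory=set)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_calls: set[tuple[str, str]] = field(default_factory=set)
    planted_de_genes: set[str] = field(default_factory=set)
    planted_overlap: set[str] = field(default_factory=set)


def gen_compound_table(n: int, frac_pass: float, seed: int
                       ) -> tuple[list[CompoundRecord], GroundTruth]:
    """Compound ADME table in which exactly round(n * frac_pass) compounds
    clear the default thresholds.

    Base values are drawn log-normal (OB), normal(0.5, 0.8) (Caco-2) and
    uniform[-0.5, 0.95] (DL), then reflected to the intended side of each
    threshold. Failing compounds violate a random nonempty subset of the
    three criteria.
    """
    if not 0.0 <= frac_pass <= 1.0:
        raise ValidationError("frac_pass must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed)
    if n == 0:
        return [], truth
    n_pass = int(round(n * frac_pass))
    ob_t, caco_t, dl_t = DEFAULT_THRESHOLDS
    records = []
    for i in range(n):
        cid = f"S{i + 1:03d}"
        ob = float(rng.lognormal(mean=2.5, sigma=0.8))
        caco = float(rng.normal(0.5, 0.8))
        dl = float(rng.uniform(-0.5, 0.95))
        if i < n_pass:
            ob = ob_t + abs(ob - ob_t)
            caco = caco_t + abs(caco - caco_t)
            dl = dl_t + abs(dl - dl_t)
            truth.pass_ids.add(cid)
        else:
            fail_axes = rng.choice(3, size=rng.integers(1, 4), replace=False)
            ob = ob_t + abs(ob - ob_t)
            caco = caco_t + abs(caco - caco_t)
            dl = dl_t + abs(dl - dl_t)
            # margin keeps the value strictly below the threshold after
            # rounding to 4 decimals
            if 0 in fail_axes:
                ob = max(0.0, ob_t - abs(ob - ob_t) - 0.01)
            if 1 in fail_axes:
                caco = caco_t - abs(caco - caco_t) - 0.01
            if 2 in fail_axes:
                dl = dl_t - abs(dl - dl_t) - 0.01
        records.append(CompoundRecord(compound_id=cid, name=f"synthetic-{cid}",
                                      ob_percent=round(ob, 4),
                                      caco2=round(caco, 4), dl=round(dl, 4)))
    return records, truth


def gen_interaction_edges(compound_ids: list[str], n_targets: int,
                          mean_degree: float, seed: int,
                          dup_fraction: float = 0.3,
                          target_records: list[TargetRecord] | None = None,
                          ensure_coverage: bool = False
                          ) -> tuple[dict[str, list[InteractionEdge]],
                                     list[TargetRecord], GroundTruth]:
    """Compound-target edge tables split across three synthetic 'sources'.

    Per-compound distinct-target counts follow a geometric law with the
    given mean (support >= 1), capped at n_targets. dup_fraction of the
    deduplicated edges are copied into a second source file to exercise
    cross-source merging. An existing target table may be passed via
    target_records (n_targets then defaults to its length); with
    ensure_coverage every target receives at least one edge. Returns
    (per-source edge tables, target table, truth with the deduplicated
    pair set).
    """
    if mean_degree < 1:
        raise ValidationError("mean_degree must be >= 1")
    if target_records is not None:
        targets = list(target_records)
        n_targets = len(targets)
    else:
        targets = [TargetRecord(uniprot_id=f"P{90000 + i:05d}",
                                protein_name=f"Synthetic protein {i + 1}",
                                gene_symbol=f"SYG{i + 1:03d}")
                   for i in range(n_targets)]
    if n_targets < mean_degree:
        raise ValidationError("n_targets must be >= mean_degree")
    rng = np.random.default_rng(seed)
    accs = [t.uniprot_id for t in targets]
    truth = GroundTruth(seed=seed)
    pairs: list[tuple[str, str]] = []
    for cid in compound_ids:
        k = min(int(rng.geometric(1.0 / mean_degree)), n_targets)
        chosen = rng.choice(n_targets, size=k, replace=False)
        for j in chosen:
            pairs.append((cid, accs[j]))
    if ensure_coverage:
        covered = {u for _c, u in pairs}
        for acc in accs:
            if acc not in covered:
                cid = compound_ids[int(rng.integers(0, len(compound_ids)))]
                pairs.append((cid, acc))
    truth.planted_edges = set(pairs)
    sources = ["TCMSP", "SEA", "BINDINGDB"]
    tables: dict[str, list[InteractionEdge]] = {s: [] for s in sources}
    for c, u in sorted(truth.planted_edges):
        primary = sources[int(rng.integers(0, 3))]
        tables[primary].append(InteractionEdge(
            compound_id=c, uniprot_id=u, sources=frozenset({primary})))
        if dup_fraction > 0 and rng.random() < dup_fraction:
            other = sources[int(rng.integers(0, 3))]
            if other != primary:
                tables[other].append(InteractionEdge(
                    compound_id=c, uniprot_id=u, sources=frozenset({other})))
    return tables, targets, truth


def gen_expression_matrix(n_genes: int, tissues, planted, boost: float,
                          sigma: float = 0.5, seed: int = 0
                          ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-normal baseline (log-mean 5) with planted tissue overexpression.

    `tissues` is a list of labels or an int count; `planted` is a set of
    (gene, tissue) pairs whose cells are multiplied by `boost` (> 1).
    """
    if boost <= 1:
        raise ValidationError("boost must be > 1")
    if isinstance(tissues, int):
        tissues = [f"Tissue{j + 1:02d}" for j in range(tissues)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gset, tset = set(genes), set(tissues)
    for g, t in planted:
        if g not in gset or t not in tset:
            raise ValidationError(f"planted pair ({g!r}, {t!r}) references "
                                  "unknown gene or tissue")
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=5.0, sigma=sigma, size=(n_genes, len(tissues)))
    df = pd.DataFrame(vals, index=genes, columns=list(tissues))
    for g, t in planted:
        df.at[g, t] *= boost
    truth = GroundTruth(seed=seed, planted_calls=set(planted))
    return ExpressionMatrix(values=df), truth


def gen_two_group_matrix(n_genes: int, n_per_group: int, de_genes,
                         effect_sd: float, seed: int
                         ) -> tuple[pd.DataFrame, GroupDesign, GroundTruth]:
    """Two-group matrix: control cells N(0,1); planted genes shifted by
    +effect_sd (in baseline-sd units) in the disease group."""
    if n_per_group < 2:
        raise ValidationError("need at least 2 samples per group")
    if effect_sd < 0:
        raise ValidationError("effect_sd must be >= 0")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    de = {g.upper() for g in de_genes}
    unknown = de - set(genes)
    if unknown:
        raise ValidationError(f"de_genes not in gene ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    ctrl_cols = [f"ctrl{j + 1:02d}" for j in range(n_per_group)]
    dis_cols = [f"dis{j + 1:02d}" for j in range(n_per_group)]
    x = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_group))
    df = pd.DataFrame(x, index=genes, columns=ctrl_cols + dis_cols)
    for g in de:
        df.loc[g, dis_cols] += effect_sd
    design = GroupDesign(labels={**{s: CONTROL for s in ctrl_cols},
                                 **{s: DISEASE for s in dis_cols}})
    truth = GroundTruth(seed=seed, planted_de_genes=de)
    return df, design, truth


def gen_de_lists_with_overlap(target_genes, m_overlap: int, n_lists: int,
                              list_size: int, seed: int
                              ) -> tuple[list[list[str]], GroundTruth]:
    """Per-dataset DE gene lists whose union overlaps the target set in
    exactly m_overlap symbols (decoy symbols are disjoint from targets)."""
    targets = sorted({g.strip().upper() for g in target_genes})
    if m_overlap > len(targets):
        raise ValidationError("m_overlap exceeds target set size")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(targets, size=m_overlap, replace=False))
    lists: list[list[str]] = []
    decoy_counter = 0
    for i in range(n_lists):
        lst = [chosen[j] for j in range(len(chosen)) if j % n_lists == i]
        while len(lst) < list_size:
            decoy_counter += 1
            lst.append(f"DECOY{decoy_counter:05d}")
        rng.shuffle(lst)
        lists.append(lst)
    truth = GroundTruth(seed=seed, planted_overlap=set(chosen))
    return lists, truth
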