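"""Two-group differential expression with an empirical-Bayes moderated t.

Mirrors the limma-style analysis behind GEO two-group comparisons: per-gene
pooled variances are shrunk toward a prior (d0, s0^2) fitted by method of
moments on log variances under a scaled-F model, the moderated t gets
d0 + d degrees of freedom, the top N genes upregulated in the disease group
are extracted per dataset, dataset lists are unioned with deduplication,
and the union is intersected with the herb's target gene set.

With d0 = 0 the statistic reduces exactly to the ordinary pooled two-sample
t; with d0 -> infinity every posterior variance collapses to s0^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import TargetRecord
from .errors import ValidationError

CONTROL, DISEASE = "control", "disease"


@dataclass(frozen=True)
class GroupDesign:
    """sample label -> group ('control' or 'disease'); >= 2 samples each."""

    labels: dict[str, str]

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - {CONTROL, DISEASE}
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        for grp in (CONTROL, DISEASE):
            if len(self.samples(grp)) < 2:
                raise ValidationError(f"need >= 2 samples in group {grp!r}")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]


@dataclass(frozen=True)
class DEResult:
    """One gene's two-group comparison (disease minus control)."""

    gene: str
    mean_diff: float
    t_stat: float
    p_value: float
    rank: int


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, limma-style)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior(variances, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Under the scaled-F model s_g^2 ~ s0^2 F(d, d0), log s^2 has variance
    trigamma(d/2) + trigamma(d0/2) and a mean shifted by digamma terms.
    Matching both moments recovers the prior. When the observed variance of
    log s^2 does not exceed trigamma(d/2) the moments are inconsistent with
    any finite d0; the fit falls back to (d0=4, s0^2 = mean variance) with a
    notice. d0 is capped at 100.
    """
    v = np.asarray(variances, dtype=float)
    if v.size < 10:
        raise ValidationError("need at least 10 genes to fit the variance prior")
    if np.all(v == 0):
        raise ValidationError("all variances are zero")
    if d < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    pos = v[v > 0]
    z = np.log(pos)
    e_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return 4.0, float(np.mean(v))
    d0 = min(2.0 * _trigamma_inverse(excess), 100.0)
    # E[log s^2] = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    log_s0 = (e_z - special.digamma(d / 2.0) + np.log(d / 2.0)
              + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(np.exp(log_s0))


def moderated_t(matrix: pd.DataFrame, design: GroupDesign,
                d0: float = 0.0, s0_sq: float | None = None
                ) -> list[DEResult]:
    """Moderated two-sample t per gene (disease minus control).

    Posterior variance s~^2 = (d0 s0^2 + d s_g^2) / (d0 + d) with
    d = n1 + n2 - 2; t = mean_diff / (s~ sqrt(1/n1 + 1/n2)); two-sided p
    from Student t with d0 + d degrees of freedom. Ranks are 1-based by
    ascending p (ties by |t| descending, then gene symbol).
    """
    if d0 < 0:
        raise ValidationError("d0 must be >= 0")
    if d0 > 0 and (s0_sq is None or s0_sq <= 0):
        raise ValidationError("s0_sq must be > 0 when d0 > 0")
    ctrl = design.samples(CONTROL)
    dis = design.samples(DISEASE)
    missing = [s for s in (*ctrl, *dis) if s not in matrix.columns]
    if missing:
        raise ValidationError(f"design samples missing from matrix: {missing}")
    n1, n2 = len(ctrl), len(dis)
    d = n1 + n2 - 2
    x1 = matrix[ctrl].to_numpy(dtype=float)
    x2 = matrix[dis].to_numpy(dtype=float)
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d
    if d0 == 0:
        if np.any(s2 == 0):
            raise ValidationError(
                "zero pooled variance with d0=0; supply a variance prior")
        post = s2
    else:
        post = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    genes = list(matrix.index)
    order = sorted(range(len(genes)),
                   key=lambda i: (p[i], -abs(t[i]), genes[i]))
    rank = {i: r + 1 for r, i in enumerate(order)}
    return [DEResult(gene=str(genes[i]), mean_diff=float(diff[i]),
                     t_stat=float(t[i]), p_value=float(p[i]), rank=rank[i])
            for i in range(len(genes))]


def top_upregulated(results: list[DEResult], n: int) -> list[str]:
    """Top n genes upregulated in the disease group, by ascending p.

    Only genes with mean_diff > 0 qualify; ties on p break by |t|
    descending then gene symbol. Fewer than n positives yields a shorter
    list.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    up = [r for r in results if r.mean_diff > 0]
    up.sort(key=lambda r: (r.p_value, -abs(r.t_stat), r.gene))
    return [r.gene for r in up[:n]]


def union_dedupe(lists) -> set[str]:
    """Symbol-normalized union of per-dataset gene lists."""
    out: set[str] = set()
    for lst in lists:
        out.update(g.strip().upper() for g in lst)
    return out


def intersect_targets(de_union, target_genes,
                      target_table: list[TargetRecord] | None = None):
    """Sorted intersection of the DE union with the target gene set.

    When a target table is supplied, returns (genes, annotation rows)
    where each row carries the UniProt accession and protein name.
    """
    de = {g.strip().upper() for g in de_union}
    tg = {g.strip().upper() for g in target_genes}
    common = sorted(de & tg)
    if target_table is None:
        return common
    by_sym: dict[str, TargetRecord] = {}
    for t in target_table:
        by_sym.setdefault(t.gene_symbol, t)
    rows = [(g, by_sym[g].uniprot_id if g in by_sym else "",
             by_sym[g].protein_name if g in by_sym else "")
            for g in common]
    return common, rows
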