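"""ADME screening: Tanimoto drug-likeness and the three-threshold filter.

Active compounds are those whose predicted oral bioavailability (OB),
Caco-2 permeability and drug-likeness (DL) all clear fixed thresholds
(defaults OB >= 15%, Caco-2 >= -0.4, DL >= 0.18). Compounds failing the
thresholds but carrying literature-reported bioactivity can be rescued via
an explicit id list, so the retained set is `passed | rescued`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import CompoundRecord, DescriptorVector
from .errors import ValidationError


@dataclass(frozen=True)
class FilterThresholds:
    """Screening thresholds; `inclusive` selects >= (default) vs strict >."""

    ob_min: float = 15.0
    caco2_min: float = -0.4
    dl_min: float = 0.18
    inclusive: bool = True


@dataclass
class FilterReport:
    """Partition of the screened compound ids.

    passed, rescued and the keys of excluded are disjoint and their union
    is the full input id set; excluded maps each failing, unrescued
    compound to the list of criteria it violated.
    """

    passed: list[str] = field(default_factory=list)
    rescued: list[str] = field(default_factory=list)
    excluded: dict[str, list[str]] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return self.passed + self.rescued


def dl_tanimoto(a: DescriptorVector, b: DescriptorVector) -> float:
    """Tanimoto similarity of two descriptor vectors.

    F(A, B) = A.B / (|A|^2 + |B|^2 - A.B). Symmetric; equals 1 for
    identical nonzero vectors; lies in [0, 1] for componentwise
    nonnegative inputs (it can leave that interval for mixed-sign
    vectors, which is why stored DL indices are not re-bounded).
    """
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if va.shape != vb.shape:
        raise ValidationError(
            f"descriptor length mismatch: {va.size} vs {vb.size}")
    dot = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - dot
    if denom == 0.0:
        raise ValidationError(
            "Tanimoto similarity undefined for two all-zero vectors")
    return dot / denom


def _violations(c: CompoundRecord, t: FilterThresholds) -> list[str]:
    def ok(value: float, cutoff: float) -> bool:
        return value >= cutoff if t.inclusive else value > cutoff

    out = []
    if not ok(c.ob_percent, t.ob_min):
        out.append("ob_percent")
    if not ok(c.caco2, t.caco2_min):
        out.append("caco2")
    if not ok(c.dl, t.dl_min):
        out.append("dl")
    return out


def apply_adme_filter(compounds: list[CompoundRecord],
                      thresholds: FilterThresholds | None = None,
                      rescue_ids: list[str] | None = None) -> FilterReport:
    """Screen compounds against the thresholds with a literature-rescue list.

    A compound passes iff all three values clear their cutoffs. Failing
    compounds listed in rescue_ids land in `rescued`; other failures in
    `excluded` with every violated criterion named. Rescue ids absent from
    the input are rejected (guards typos in config files).
    """
    thresholds = thresholds or FilterThresholds()
    rescue = set(rescue_ids or [])
    ids = {c.compound_id for c in compounds}
    unknown = rescue - ids
    if unknown:
        raise ValidationError(
            f"rescue id(s) not present in compound table: {sorted(unknown)}")
    report = FilterReport()
    for c in compounds:
        bad = _violations(c, thresholds)
        if not bad:
            report.passed.append(c.compound_id)
        elif c.compound_id in rescue:
            report.rescued.append(c.compound_id)
        else:
            report.excluded[c.compound_id] = bad
    return report


def filter_monotonicity_check(compounds: list[CompoundRecord],
                              t1: FilterThresholds,
                              t2: FilterThresholds) -> bool:
    """True iff the pass set under the stricter thresholds t2 is contained
    in the pass set under t1 (t2 must be componentwise at least as strict)."""
    if (t2.ob_min < t1.ob_min or t2.caco2_min < t1.caco2_min
            or t2.dl_min < t1.dl_min):
        raise ValidationError("t2 must be componentwise at least as strict as t1")
    p1 = set(apply_adme_filter(compounds, t1).passed)
    p2 = set(apply_adme_filter(compounds, t2).passed)
    return p2 <= p1
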