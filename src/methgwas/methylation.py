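"""Methylation phenotyping from per-cytosine calls.

Turns allc-style per-cytosine read counts into per-feature weighted
methylation levels, per-line trait values, transposon target-class
assignments (RdDM vs CMT2), and the mutant-vs-wild-type differential test.

Coordinate conventions: feature annotations are 0-based half-open (BED);
cytosine positions are 1-based (allc), so a cytosine at position ``p``
belongs to feature ``[start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylationCallRecord",
    "FeatureAnnotation",
    "TETargetSets",
    "weighted_methylation",
    "feature_levels",
    "line_average",
    "classify_te_targets",
    "differential_methylation_test",
]

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class MethylationCallRecord:
    """One cytosine: read counts in one sequence context."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    mc: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.mc <= self.total):
            raise ValueError(f"need 0 <= mc <= total, got mc={self.mc} total={self.total}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic feature (TE or gene) with a 0-based half-open interval."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str = "TE"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"feature {self.id}: start must be < end")


@dataclass
class TETargetSets:
    """Transposons classified by which mutant erases their methylation."""

    rddm_ids: set = field(default_factory=set)
    cmt2_ids: set = field(default_factory=set)
    threshold: float = 0.1


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "strand": [c.strand for c in calls],
            "context": [c.context for c in calls],
            "mc": [c.mc for c in calls],
            "total": [c.total for c in calls],
        }
    )


def weighted_methylation(calls, feature: FeatureAnnotation, context: str | None = "CHG"):
    """Weighted methylation level of one feature: sum(mc) / sum(total).

    Both strands are pooled.  ``context=None`` pools all contexts.  Returns
    ``None`` (undefined, never 0) when no read covers the feature in the
    requested context.
    """
    df = _calls_frame(calls)
    sel = (df["chrom"] == feature.chrom) & (df["pos"] > feature.start) & (df["pos"] <= feature.end)
    if context is not None:
        sel &= df["context"] == context
    total = int(df.loc[sel, "total"].sum())
    if total == 0:
        return None
    return float(df.loc[sel, "mc"].sum()) / total


def feature_levels(calls, features, context: str | None = "CHG") -> dict:
    """Weighted methylation per feature id (``None`` where uncovered)."""
    return {f.id: weighted_methylation(calls, f, context=context) for f in features}


def line_average(per_feature_levels: dict) -> float:
    """Per-line trait value: unweighted mean over features with coverage.

    Features with undefined (no-coverage) levels are excluded, not
    zero-filled, mirroring averaging over all transposons with at least one
    mapped read.
    """
    defined = [v for v in per_feature_levels.values() if v is not None]
    if not defined:
        raise ValueError("no feature has a defined methylation level")
    return float(np.mean(defined))


def classify_te_targets(
    wt_levels: dict,
    cmt2_levels: dict,
    drm1drm2_levels: dict,
    threshold: float = 0.1,
    allow_overlap: bool = False,
) -> TETargetSets:
    """Assign TEs to CMT2- or RdDM-target classes from mutant methylation loss.

    A TE is CMT2-targeted if ``wt - cmt2 > threshold`` and RdDM-targeted if
    ``wt - drm1drm2 > threshold`` (strict inequalities).  When a TE exceeds
    the threshold in both mutants and ``allow_overlap`` is False (default),
    it is assigned to the class with the larger difference; ties go to the
    RdDM class.  TEs with an undefined level in any of the three samples are
    left unclassified.
    """
    out = TETargetSets(threshold=threshold)
    for te in wt_levels:
        wt = wt_levels.get(te)
        cm = cmt2_levels.get(te)
        dr = drm1drm2_levels.get(te)
        if wt is None or cm is None or dr is None:
            continue
        d_cmt2 = wt - cm
        d_rddm = wt - dr
        is_cmt2 = d_cmt2 > threshold
        is_rddm = d_rddm > threshold
        if allow_overlap:
            if is_cmt2:
                out.cmt2_ids.add(te)
            if is_rddm:
                out.rddm_ids.add(te)
        elif is_cmt2 and is_rddm:
            (out.cmt2_ids if d_cmt2 > d_rddm else out.rddm_ids).add(te)
        elif is_cmt2:
            out.cmt2_ids.add(te)
        elif is_rddm:
            out.rddm_ids.add(te)
    return out


def differential_methylation_test(
    group_a_levels: dict,
    group_b_levels: dict,
    alpha: float = 0.01,
    delta: float = 0.1,
) -> pd.DataFrame:
    """Mutant-vs-wild-type differential methylation per feature.

    A feature is flagged when a two-tailed Welch's t-test on the replicate
    levels gives p < ``alpha`` AND the absolute mean difference (a - b)
    exceeds ``delta``.  Features with fewer than two replicates in either
    group are skipped with a warning.

    Parameters are replicate level maps ``feature id -> sequence of
    fractions``.  Returns a frame with columns ``feature, mean_a, mean_b,
    diff, t, p, flagged``.
    """
    rows = []
    for fid in group_a_levels:
        if fid not in group_b_levels:
            continue
        a = np.asarray([v for v in group_a_levels[fid] if v is not None], dtype=float)
        b = np.asarray([v for v in group_b_levels[fid] if v is not None], dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"feature {fid}: <2 replicates, skipped", stacklevel=2)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        diff = float(a.mean() - b.mean())
        flagged = bool(p < alpha and abs(diff) > delta)
        rows.append(
            {
                "feature": fid,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "diff": diff,
                "t": float(t),
                "p": float(p),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "mean_a", "mean_b", "diff", "t", "p", "flagged"])
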