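"""Per-sample mtDNA quantification and the coverage-depth relationship.

mtDNA content — the ratio of mitochondrial reads to total reads in a sample —
doubles as a contamination screen: leukocytes degrading during whole-blood
transit release mtDNA (and nuclear DNA that dilutes the foetal fraction), so
elevated content flags compromised samples.  The expected covered fraction at
mean depth c follows the standard Poisson (Lander-Waterman) approximation
1 - exp(-c), used here for QC expectations only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MtReference
from .simulate import AlignedFragment, TruthSample


@dataclass
class SampleQC:
    """Per-sample mtDNA quantification."""

    sample_id: str
    total_reads: int
    mt_reads: int
    mt_content: float
    coverage_fraction: float
    mean_depth: float
    tube_type: str = ""
    transport_days: int = 0
    foetal_fraction: float = float("nan")
    mt_content_class: str = ""


def compute_qc(
    fragments: Sequence[AlignedFragment],
    total_reads: int,
    ref: MtReference,
    truth: TruthSample | None = None,
) -> SampleQC:
    """Exact mtDNA content, covered fraction and mean depth for one sample."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if len(fragments) > total_reads:
        raise ValueError("more mitochondrial fragments than total reads")
    L = ref.length
    diff = np.zeros(L + 1, dtype=np.int64)
    for frag in fragments:
        start = (frag.start - 1) % L
        end = start + frag.length
        if end <= L:
            diff[start] += 1
            diff[end] -= 1
        else:
            diff[start] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[end - L] -= 1
    depth = np.cumsum(diff[:-1])
    sample_id = fragments[0].sample_id if fragments else (truth.sample_id if truth else "")
    return SampleQC(
        sample_id=sample_id,
        total_reads=int(total_reads),
        mt_reads=len(fragments),
        mt_content=len(fragments) / total_reads,
        coverage_fraction=float((depth > 0).mean()),
        mean_depth=float(depth.mean()),
        tube_type=truth.tube_type if truth else "",
        transport_days=truth.transport_days if truth else 0,
        foetal_fraction=truth.foetal_fraction if truth else float("nan"),
    )


def expected_coverage(mean_depth: float) -> float:
    """Expected covered fraction at mean depth c: 1 - exp(-c)."""
    if mean_depth < 0:
        raise ValueError("mean depth must be >= 0")
    return 1.0 - math.exp(-mean_depth)


def classify_mt_content(
    cohort: Sequence[SampleQC],
    cutoffs: tuple[float, float] | None = None,
) -> list[SampleQC]:
    """Assign each sample a low/medium/high mtDNA-content class.

    Default cutoffs are the cohort tertiles of mt_content; explicit
    ``cutoffs = (c1, c2)`` override them.  Ties fall to the lower class; an
    all-equal cohort is classed "medium" throughout.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    values = np.array([s.mt_content for s in cohort])
    if cutoffs is None:
        if np.all(values == values[0]):
            for s in cohort:
                s.mt_content_class = "medium"
            return list(cohort)
        cutoffs = (float(np.quantile(values, 1 / 3)), float(np.quantile(values, 2 / 3)))
    c1, c2 = cutoffs
    for s in cohort:
        if s.mt_content <= c1:
            s.mt_content_class = "low"
        elif s.mt_content <= c2:
            s.mt_content_class = "medium"
        else:
            s.mt_content_class = "high"
    return list(cohort)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups: returns (H, p).

    H is tie-corrected; p comes from the chi-square approximation with
    ``len(groups) - 1`` degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
    result = stats.kruskal(*groups.values())
    return float(result.statistic), float(result.pvalue)


def qc_table(cohort: Sequence[SampleQC]) -> pd.DataFrame:
    """QC report, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "total_reads": [s.total_reads for s in cohort],
            "mt_reads": [s.mt_reads for s in cohort],
            "mt_content": [s.mt_content for s in cohort],
            "coverage_fraction": [s.coverage_fraction for s in cohort],
            "mean_depth": [s.mean_depth for s in cohort],
            "tube_type": [s.tube_type for s in cohort],
            "transport_days": [s.transport_days for s in cohort],
            "foetal_fraction": [s.foetal_fraction for s in cohort],
            "mt_content_class": [s.mt_content_class for s in cohort],
        }
    ).set_index("sample_id")
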