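"""Cohort-level variant analyses.

Population frequency spectra, the 1-kb genome-bin distribution of distinct
variants, regional Venn intersections, variant-count normalisation by mtDNA
content, pairwise shared-variant counts, and frequency-ranked top-variant
tables with ancestral-variant exclusion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MtVariant, VariantKey, hgvs_name


@dataclass
class CohortTable:
    """Presence matrix (samples x distinct variants) plus per-sample metadata."""

    presence: pd.DataFrame  # index sample_id, columns VariantKey, values bool
    metadata: pd.DataFrame  # index sample_id: region, tube_type, days, mt_content

    @classmethod
    def from_calls(
        cls,
        calls: Mapping[str, Sequence[MtVariant | VariantKey]],
        metadata: pd.DataFrame | None = None,
    ) -> "CohortTable":
        keys_per_sample = {
            sid: {v.key if isinstance(v, MtVariant) else v for v in vs}
            for sid, vs in calls.items()
        }
        all_keys = sorted({k for ks in keys_per_sample.values() for k in ks})
        presence = pd.DataFrame(
            [[k in keys_per_sample[sid] for k in all_keys] for sid in keys_per_sample],
            index=list(keys_per_sample),
            columns=all_keys,
            dtype=bool,
        )
        if metadata is None:
            metadata = pd.DataFrame(index=presence.index)
        return cls(presence=presence, metadata=metadata.loc[presence.index])

    @property
    def n_samples(self) -> int:
        return len(self.presence)

    def sample_variants(self, sample_id: str) -> set[VariantKey]:
        row = self.presence.loc[sample_id]
        return set(row.index[row])


@dataclass
class VennResult:
    """Exact set-algebra intersection cells over per-region variant sets."""

    region_sets: dict[str, set[VariantKey]]
    cells: dict[frozenset, int] = field(default_factory=dict)
    total_distinct: int = 0

    def cell(self, *regions: str) -> int:
        """Count of variants present in exactly the given regions."""
        return self.cells.get(frozenset(regions), 0)

    @property
    def common_all(self) -> int:
        return self.cell(*self.region_sets)


def frequency_spectrum(cohort: CohortTable) -> pd.Series:
    """Per-variant population frequency: fraction of samples carrying it."""
    if cohort.n_samples == 0:
        raise ValueError("cohort has no samples")
    return cohort.presence.mean(axis=0)


def spectrum_bins(
    freqs: pd.Series, edges: Sequence[float] = (0.01, 0.05, 0.10, 0.15, 1.0)
) -> pd.Series:
    """Histogram of the frequency spectrum over (0, e1], (e1, e2], ... bins."""
    labels, counts, lo = [], [], 0.0
    for hi in edges:
        labels.append(f"({lo:g},{hi:g}]")
        counts.append(int(((freqs > lo) & (freqs <= hi)).sum()))
        lo = hi
    return pd.Series(counts, index=labels)


def genome_bins(
    variants: Sequence[VariantKey], bin_size: int = 1000, n_bins: int = 16
) -> pd.Series:
    """Distinct-variant counts per 1-kb genome section.

    Bin b = ceil(pos / bin_size), capped at ``n_bins`` so the last section
    absorbs the reference tail (positions 15,001-16,569 for the defaults).
    """
    counts = pd.Series(0, index=range(1, n_bins + 1))
    for key in set(variants):
        b = min((key.pos + bin_size - 1) // bin_size, n_bins)
        counts[b] += 1
    return counts


def region_intersection(cohort: CohortTable, regions: Sequence[str]) -> VennResult:
    """All 2^k - 1 exclusive intersection cells over per-region variant sets."""
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    region_sets: dict[str, set[VariantKey]] = {}
    for region in regions:
        sids = cohort.metadata.index[cohort.metadata["region"] == region]
        if len(sids) == 0:
            raise ValueError(f"region {region!r} has no samples")
        sub = cohort.presence.loc[sids]
        region_sets[region] = set(sub.columns[sub.any(axis=0)])
    universe = set().union(*region_sets.values())
    cells: dict[frozenset, int] = {}
    for key in universe:
        members = frozenset(r for r, s in region_sets.items() if key in s)
        cells[members] = cells.get(members, 0) + 1
    return VennResult(region_sets=region_sets, cells=cells, total_distinct=len(universe))


def normalize_variant_count(n_variants: int, mt_content: float) -> float:
    """Variant count normalised to mtDNA content (simple division)."""
    if mt_content <= 0:
        raise ValueError("mt_content must be positive")
    return n_variants / mt_content


def shared_variants(
    sample_a: Sequence[MtVariant | VariantKey], sample_b: Sequence[MtVariant | VariantKey]
) -> int:
    """|A n B| on (pos, ref, alt) variant keys."""
    def keys(vs):
        return {v.key if isinstance(v, MtVariant) else v for v in vs}
    return len(keys(sample_a) & keys(sample_b))


def load_ancestral_variants(path: str | Path | None = None) -> set[VariantKey]:
    """The packaged (editable) ancestral variant list."""
    if path is None:
        with importlib.resources.as_file(
            importlib.resources.files("cfmito") / "data" / "ancestral_variants.tsv"
        ) as p:
            return load_ancestral_variants(p)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        VariantKey(int(r.pos), r.ref, r.alt, r.variant_type)
        for r in df.itertuples(index=False)
    }


def top_variants(
    cohort: CohortTable,
    k: int = 5,
    variant_types: Sequence[str] | None = None,
    exclude_ancestral: bool = False,
    ancestral: set[VariantKey] | None = None,
    per_region: bool = False,
) -> pd.DataFrame:
    """Frequency-ranked variant table (optionally excluding ancestral variants).

    With ``per_region``, adds one frequency column per region (fraction of
    that region's samples carrying the variant).
    """
    freqs = frequency_spectrum(cohort)
    if variant_types is not None:
        allowed = set(variant_types)
        freqs = freqs[np.array([key.vtype in allowed for key in freqs.index], bool)]
    if exclude_ancestral:
        if ancestral is None:
            ancestral = load_ancestral_variants()
        freqs = freqs[np.array([key not in ancestral for key in freqs.index], bool)]
    order = sorted(freqs.index, key=lambda key: (-freqs[key], key.pos, key.alt))[:k]
    out = pd.DataFrame(
        {
            "variant": [hgvs_name(key) for key in order],
            "n_carriers": [int(cohort.presence[key].sum()) for key in order],
            "frequency": [float(freqs[key]) for key in order],
        }
    )
    if per_region and "region" in cohort.metadata.columns:
        for region in sorted(cohort.metadata["region"].unique()):
            sids = cohort.metadata.index[cohort.metadata["region"] == region]
            sub = cohort.presence.loc[sids]
            out[f"freq_{region}"] = [float(sub[key].mean()) for key in order]
    return out
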