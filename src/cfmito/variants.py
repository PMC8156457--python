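"""Pileup construction, permissive variant calling and the filtration cascade.

Low-pass cf-mtDNA sequencing yields shallow (1-40x) mitochondrial coverage, so
the screening strategy is a deliberately permissive frequency-based caller
followed by explicit filters that carry all the thresholds that matter:

* depth filter — site depth < 5 is unreliable at this coverage;
* homopolymer filter — semiconductor sequencing concentrates indel errors in
  homopolymer runs, so variants in (or, for indels, adjacent to) runs of
  length >= 4 are removed (>= 3 in the stricter indel-reporting mode);
* alternative-allele support filter — fewer than 4 reads supporting the
  alternative allele is compatible with scattered sequencing error.

Heteroplasmy is then classified from the surviving allele counts: a variant
supported exclusively by the alternative allele is homoplasmic; under the
approximate rule, fewer than 4 reference reads (themselves compatible with
sequencing error) also count as homoplasmic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reference import HomopolymerTrack, MtReference, position_in_run, run_length_at

SNV, DEL, INS = "SNV", "del", "ins"

LOW_DEPTH = "LOW_DEPTH"
HOMOPOLYMER = "HOMOPOLYMER"
LOW_ALT_SUPPORT = "LOW_ALT_SUPPORT"

HOMOPLASMIC = "homoplasmic"
HETEROPLASMIC = "heteroplasmic"
UNCLASSIFIED = "unclassified"


class VariantKey(NamedTuple):
    """Identity of a mitochondrial variant.

    ``pos`` is 1-based. Deletions are represented at the first deleted base
    (``ref`` = deleted base, ``alt`` = ''); insertions are anchored to the
    preceding base (``ref`` = '', ``alt`` = inserted sequence).
    """

    pos: int
    ref: str
    alt: str
    vtype: str


def hgvs_name(v: VariantKey) -> str:
    """HGVS-style name: m.15326A>G, m.9906delG, m.9808insT."""
    if v.vtype == SNV:
        return f"m.{v.pos}{v.ref}>{v.alt}"
    if v.vtype == DEL:
        return f"m.{v.pos}del{v.ref}"
    if v.vtype == INS:
        return f"m.{v.pos}ins{v.alt}"
    raise ValueError(f"unknown variant type {v.vtype!r}")


def parse_hgvs(name: str) -> VariantKey:
    """Inverse of :func:`hgvs_name`."""
    body = name.removeprefix("m.")
    if "del" in body:
        pos, ref = body.split("del")
        return VariantKey(int(pos), ref, "", DEL)
    if "ins" in body:
        pos, alt = body.split("ins")
        return VariantKey(int(pos), "", alt, INS)
    if ">" in body:
        left, alt = body.split(">")
        i = 0
        while i < len(left) and left[i].isdigit():
            i += 1
        return VariantKey(int(left[:i]), left[i:], alt, SNV)
    raise ValueError(f"cannot parse variant name {name!r}")


@dataclass
class MtVariant:
    """One called mitochondrial variant with its allele counts and filter state."""

    key: VariantKey
    depth: int
    alt_reads: int
    ref_reads: int
    homopolymer_run_length: int = 0
    filter_flags: set[str] = field(default_factory=set)
    heteroplasmy_class: str = UNCLASSIFIED
    heteroplasmy_fraction: float | None = None

    @property
    def pos(self) -> int:
        return self.key.pos

    @property
    def vtype(self) -> str:
        return self.key.vtype

    @property
    def hgvs(self) -> str:
        return hgvs_name(self.key)

    @property
    def passed(self) -> bool:
        return not self.filter_flags


@dataclass
class PileupSite:
    """Allele read counts at one reference position (non-reference alleles only)."""

    pos: int
    ref_base: str
    depth: int
    alt_counts: dict[VariantKey, int] = field(default_factory=dict)


# ------------------------------------------------------------------ pileup


def build_pileup(fragments: Sequence, ref: MtReference) -> tuple[list[PileupSite], np.ndarray]:
    """Per-position depth and allele counts from aligned fragments.

    Returns the sites that carry at least one non-reference allele, plus the
    full per-position depth array (index 0 = m.1).  Fragments may wrap the
    circular origin; insertions are keyed to the preceding position.
    """
    L = ref.length
    diff = np.zeros(L + 1, dtype=np.int64)
    alt_counts: dict[int, dict[VariantKey, int]] = defaultdict(lambda: defaultdict(int))
    for frag in fragments:
        start = (frag.start - 1) % L  # 0-based
        if frag.length <= 0 or frag.length > L:
            raise ValueError(f"fragment length {frag.length} outside reference")
        end = start + frag.length
        if end <= L:
            diff[start] += 1
            diff[end] -= 1
        else:  # wraps the origin
            diff[start] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[end - L] -= 1
        for key in frag.alleles:
            alt_counts[key.pos][key] += 1
    depth = np.cumsum(diff[:-1])
    sites = []
    for pos in sorted(alt_counts):
        sites.append(
            PileupSite(
                pos=pos,
                ref_base=ref.base(pos),
                depth=int(depth[pos - 1]),
                alt_counts=dict(alt_counts[pos]),
            )
        )
    return sites, depth


def call_variants(sites: Iterable[PileupSite], min_alt_call: int = 2) -> list[MtVariant]:
    """Emit one variant per (site, non-reference allele) with minimal support.

    Deliberately permissive: all thresholds that control the analysis live in
    the downstream filters, not here.  ``ref_reads`` is the count of reads
    carrying the reference allele (site depth minus all alternative alleles).
    """
    out = []
    for site in sites:
        total_alt = sum(c for k, c in site.alt_counts.items() if k.vtype != INS)
        ref_reads = max(site.depth - total_alt, 0)
        for key, count in sorted(site.alt_counts.items()):
            if count < min_alt_call:
                continue
            # reads carrying an insertion also carry the anchor reference base,
            # so the insertion's reference support is depth minus its own count
            rr = max(site.depth - count, 0) if key.vtype == INS else ref_reads
            out.append(
                MtVariant(
                    key=key,
                    depth=int(site.depth),
                    alt_reads=int(count),
                    ref_reads=int(rr),
                )
            )
    return out


# ------------------------------------------------------------------ filters


def filter_depth(variants: Iterable[MtVariant], min_depth: int = 5) -> list[MtVariant]:
    """Flag variants at sites with total depth below ``min_depth`` (default < 5)."""
    variants = list(variants)
    for v in variants:
        if v.depth < min_depth:
            v.filter_flags.add(LOW_DEPTH)
        else:
            v.filter_flags.discard(LOW_DEPTH)
    return variants


def filter_homopolymer(
    variants: Iterable[MtVariant],
    snv_track: HomopolymerTrack,
    indel_track: HomopolymerTrack | None = None,
    length: int | None = None,
) -> list[MtVariant]:
    """Flag variants within homopolymer runs.

    SNVs use ``snv_track`` (runs >= 4 by default); indels use ``indel_track``
    when given (the stricter >= 3 mode used for indel reporting), otherwise
    the SNV track.  Indels also count when immediately adjacent to a run.
    """
    variants = list(variants)
    indel_track = indel_track or snv_track
    for v in variants:
        track = snv_track if v.vtype == SNV else indel_track
        L = length or max(getattr(track, "length", 0), 16_569)
        if position_in_run(track, v.pos, v.vtype, length=L):
            v.filter_flags.add(HOMOPOLYMER)
            v.homopolymer_run_length = run_length_at(track, v.pos, v.vtype)
        else:
            v.filter_flags.discard(HOMOPOLYMER)
            v.homopolymer_run_length = 0
    return variants


def filter_alt_support(variants: Iterable[MtVariant], min_alt: int = 4) -> list[MtVariant]:
    """Flag variants supported by fewer than ``min_alt`` alternative-allele reads."""
    variants = list(variants)
    for v in variants:
        if v.alt_reads < min_alt:
            v.filter_flags.add(LOW_ALT_SUPPORT)
        else:
            v.filter_flags.discard(LOW_ALT_SUPPORT)
    return variants


def classify_heteroplasmy(
    variant: MtVariant, min_ref_reads: int = 4, approximate: bool = False
) -> MtVariant:
    """Classify a variant as homoplasmic or heteroplasmic from allele counts.

    Strict rule: homoplasmic iff no reference reads remain.  Approximate rule:
    reference support below ``min_ref_reads`` is treated as residual
    sequencing error, so such variants also count as homoplasmic.
    """
    if variant.alt_reads == 0:
        raise ValueError("not a variant: zero alternative-allele reads")
    variant.heteroplasmy_fraction = variant.alt_reads / (variant.alt_reads + variant.ref_reads)
    cut = min_ref_reads if approximate else 1
    variant.heteroplasmy_class = HOMOPLASMIC if variant.ref_reads < cut else HETEROPLASMIC
    return variant


# ------------------------------------------------------------------ cascade


@dataclass
class FilterReport:
    """Variant counts (total / indel / SNV) at each stage of the cascade."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, label: str, variants: Sequence[MtVariant]) -> None:
        n_indel = sum(1 for v in variants if v.vtype in (DEL, INS))
        n_snv = sum(1 for v in variants if v.vtype == SNV)
        self.stages.append((label, n_indel + n_snv, n_indel, n_snv))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "total", "indels", "snvs"]
        ).set_index("stage")


def run_cascade(
    variants: Sequence[MtVariant],
    snv_track: HomopolymerTrack,
    indel_track: HomopolymerTrack | None = None,
    min_depth: int = 5,
    min_alt: int = 4,
    apply_alt_support: bool = True,
    ref_length: int = 16_569,
) -> tuple[list[MtVariant], FilterReport]:
    """Apply depth -> homopolymer (-> alt-support) filters in order.

    The flags are independent predicates, so the surviving set does not depend
    on the order; the order only shapes the staged counts in the report.
    """
    report = FilterReport()
    report.add("total", variants)
    variants = filter_depth(variants, min_depth=min_depth)
    survivors = [v for v in variants if LOW_DEPTH not in v.filter_flags]
    report.add("depth", survivors)
    variants = filter_homopolymer(variants, snv_track, indel_track, length=ref_length)
    survivors = [v for v in survivors if HOMOPOLYMER not in v.filter_flags]
    report.add("homopolymer", survivors)
    if apply_alt_support:
        variants = filter_alt_support(variants, min_alt=min_alt)
        survivors = [v for v in survivors if LOW_ALT_SUPPORT not in v.filter_flags]
        report.add("alt_support", survivors)
    kept = [v for v in variants if v.passed]
    return kept, report
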