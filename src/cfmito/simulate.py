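"""Synthetic cf-mtDNA cohort generator with known truth.

Emulates the mixture structure of the mitochondrial fraction of maternal
plasma cfDNA in an NIPT setting:

* a maternal mitochondrial haplotype drawn from a haplogroup tree (the foetal
  haplotype is identical by maternal inheritance unless de-novo variants are
  configured);
* leukocyte mtDNA leaking into the cell-free pool while whole blood is in
  transit — flat over time for EDTA tubes (plasma is separated before
  shipping) and growing past a 72-h threshold for Streck whole-blood tubes;
* foetal-fraction dilution by the nuclear DNA co-released from degrading
  leukocytes;
* mostly homoplasmic truth variants (a configurable ~95% of them at
  heteroplasmy 1.0, the residue Beta(2,2));
* platform-like sequencing error: uniform substitutions plus indel errors
  concentrated in homopolymer runs, at a rate non-decreasing in run length.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .haplogroup import HaploTree
from .reference import MtReference, find_homopolymers
from .variants import DEL, INS, SNV, VariantKey

MATERNAL_CF, FOETAL_CF, LEUKOCYTE = "maternal_cf", "foetal_cf", "leukocyte"

REGIONS = ("Central", "Northwestern", "Volga-Ural", "Yakutia", "Others")

#: Mutational hot-spot ranges (1-based, inclusive): the 3-5, 11-13 and
#: 15-16 kb sections, the last covering the control region.
HOTSPOT_RANGES = ((2001, 5000), (10001, 13000), (14001, 16569))

#: Cohort composition: sample proportions, transit-time means (days) and
#: illustrative haplogroup superclade priors per region of origin.
REGION_WEIGHTS = {
    "Northwestern": 0.615, "Central": 0.186, "Volga-Ural": 0.098,
    "Yakutia": 0.076, "Others": 0.025,
}
REGION_DAY_MEAN = {
    "Northwestern": 1.5, "Central": 3.5, "Volga-Ural": 5.0,
    "Yakutia": 9.0, "Others": 6.0,
}
#: EDTA plasma is separated locally shortly after collection, while Streck
#: whole-blood tubes are the shipping standard, so remote regions are
#: predominantly Streck.
REGION_TUBE_STRECK = {
    "Northwestern": 0.5, "Central": 0.7, "Volga-Ural": 0.9,
    "Yakutia": 0.9, "Others": 0.8,
}
_EUROPEAN_PRIOR = {
    "H": 0.45, "U": 0.12, "J": 0.10, "T": 0.06, "K": 0.03, "C": 0.05,
    "D": 0.04, "M": 0.02, "N": 0.04, "W": 0.03, "B": 0.02, "I": 0.04,
}
REGION_CLADE_PRIOR = {
    "Northwestern": _EUROPEAN_PRIOR,
    "Central": _EUROPEAN_PRIOR,
    "Volga-Ural": {**_EUROPEAN_PRIOR, "H": 0.35, "U": 0.18, "C": 0.07, "D": 0.05},
    "Yakutia": {"C": 0.45, "D": 0.33, "M": 0.10, "H": 0.06, "U": 0.06},
    "Others": {**_EUROPEAN_PRIOR, "H": 0.30, "C": 0.10, "D": 0.09, "M": 0.06},
}


def default_homopolymer_indel_rate(run_length: int) -> float:
    """Per-fragment indel error probability in a homopolymer run.

    Non-decreasing in run length and capped below 0.5, mimicking the
    length-dependent error mode of semiconductor sequencing.
    """
    return min(0.01 * max(run_length - 2, 0), 0.45)


@dataclass(frozen=True)
class LeakageParams:
    """Leukocyte mtDNA leakage: baseline relative mass ``w0``, a transit-time
    change-point (72 h by default), an exponential post-threshold rate and a
    saturation cap ``w_max`` (the leukocyte pool is finite, so leakage cannot
    grow without bound)."""

    w0: float = 0.1
    threshold_days: float = 3.0
    growth_rate: float = 0.9
    w_max: float = 10.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 200
    seed: int = 0
    tube_mix: dict | None = None  # None: region-dependent (REGION_TUBE_STRECK)
    region_weights: dict = field(default_factory=lambda: dict(REGION_WEIGHTS))
    fragment_mean_len: int = 170
    fragment_len_sd: float = 25.0
    base_depth_range: tuple[float, float] = (1.0, 6.0)  # pre-leakage, log-uniform
    total_reads_mean: float = 3.5e6
    total_reads_sd: float = 4e5
    # the foetal fraction emulated here is the gestation-age-scaled quantity,
    # hence the modest between-sample spread
    foetal_fraction_mean: float = 0.10
    foetal_fraction_sd: float = 0.015
    leakage: LeakageParams = field(default_factory=LeakageParams)
    substitution_error_rate: float = 2e-3
    homopolymer_indel_rate: Callable[[int], float] = default_homopolymer_indel_rate
    error_track_min_len: int = 3
    homoplasmic_fraction: float = 0.95
    n_leukocyte_private: int = 12
    n_cf_private: int = 3
    n_de_novo_foetal: int = 0
    # fraction of private variant positions drawn from the hot-spot sections
    hotspot_fraction: float = 0.315

    def validate(self) -> None:
        if not 0 <= self.homoplasmic_fraction <= 1:
            raise ValueError("homoplasmic_fraction must be in [0,1]")
        if self.leakage.threshold_days < 0:
            raise ValueError("threshold_days must be >= 0")
        for rl in (3, 4, 6, 10, 20):
            if self.homopolymer_indel_rate(rl) >= 0.5:
                raise ValueError("homopolymer_indel_rate must stay below 0.5")
        rates = [self.homopolymer_indel_rate(rl) for rl in range(2, 25)]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("homopolymer_indel_rate must be non-decreasing")


@dataclass
class TruthSample:
    """Simulator ground truth for one cohort sample."""

    sample_id: str
    region_label: str
    tube_type: str
    transport_days: int
    haplogroup: str
    maternal_variants: frozenset[VariantKey]
    foetal_variants: frozenset[VariantKey]
    leukocyte_private: frozenset[VariantKey]
    cf_private: frozenset[VariantKey]
    heteroplasmy: dict[VariantKey, float]
    mixture_weights: tuple[float, float, float]  # (maternal_cf, foetal_cf, leukocyte)
    foetal_fraction: float  # true, after dilution by leaked nuclear DNA
    mean_depth: float
    total_reads: int

    def haplotype(self, origin: str) -> frozenset[VariantKey]:
        if origin == MATERNAL_CF:
            return self.maternal_variants | self.cf_private
        if origin == FOETAL_CF:
            return self.foetal_variants
        if origin == LEUKOCYTE:
            return self.maternal_variants | self.leukocyte_private
        raise ValueError(f"unknown origin {origin!r}")


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned cfDNA fragment; may wrap the circular origin."""

    sample_id: str
    start: int  # 1-based
    length: int
    alleles: tuple[VariantKey, ...]
    origin: str


# ------------------------------------------------------------------ mechanisms


def leakage_weight(tube_type: str, transport_days: float, params: LeakageParams) -> float:
    """Relative leukocyte mtDNA mass after transit.

    EDTA plasma is separated before shipping, so the weight stays at the
    baseline ``w0``; Streck whole blood holds at ``w0`` up to the change-point
    and grows exponentially beyond it.
    """
    if transport_days < 0:
        raise ValueError("transport_days must be >= 0")
    if tube_type == "EDTA":
        return params.w0
    if tube_type == "Streck":
        excess = max(transport_days - params.threshold_days, 0.0)
        return min(params.w0 * math.exp(params.growth_rate * excess), params.w_max)
    raise ValueError(f"unknown tube type {tube_type!r}")


def dilute_foetal_fraction(ff0: float, leaked: float) -> float:
    """Foetal fraction after dilution by leaked nuclear DNA (relative mass)."""
    if not 0 <= ff0 <= 1:
        raise ValueError("ff0 must be in [0,1]")
    if leaked < 0:
        raise ValueError("leaked mass must be >= 0")
    return ff0 / (1.0 + leaked)


def draw_haplotype(tree: HaploTree, haplogroup_name: str, ref: MtReference) -> frozenset[VariantKey]:
    """SNV set defined by the root-to-node path of a haplogroup."""
    pairs = tree.cumulative(haplogroup_name)
    return frozenset(VariantKey(pos, ref.base(pos), alt, SNV) for pos, alt in pairs)


# ------------------------------------------------------------------ cohort truth


def _choice(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _leaves_under(tree: HaploTree, clade: str) -> list[str]:
    children = {n.parent for n in tree.nodes.values() if n.parent}
    leaves = []
    for node in tree.nodes.values():
        if node.name in children:
            continue
        anc = node
        while anc.parent is not None and anc.parent != tree.root:
            anc = tree.nodes[anc.parent]
        if anc.name == clade:
            leaves.append(node.name)
    return sorted(leaves)


def _draw_private(
    rng: np.random.Generator,
    n: int,
    ref: MtReference,
    excluded: set[int],
    hotspot_fraction: float = 0.315,
) -> frozenset[VariantKey]:
    out = set()
    while len(out) < n:
        if rng.random() < hotspot_fraction:
            lo, hi = HOTSPOT_RANGES[rng.integers(len(HOTSPOT_RANGES))]
            pos = int(rng.integers(lo, hi + 1))
        else:
            pos = int(rng.integers(1, ref.length + 1))
        if pos in excluded:
            continue
        excluded.add(pos)
        base = ref.base(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        out.add(VariantKey(pos, base, alt, SNV))
    return frozenset(out)


def _draw_heteroplasmy(rng: np.random.Generator, cfg: SimConfig) -> float:
    if rng.random() < cfg.homoplasmic_fraction:
        return 1.0
    return float(np.clip(rng.beta(2.0, 2.0), 1e-3, 1.0))


def make_truth_sample(
    cfg: SimConfig,
    ref: MtReference,
    tree: HaploTree,
    rng: np.random.Generator,
    sample_id: str,
    region: str | None = None,
    tube_type: str | None = None,
    transport_days: int | None = None,
    haplogroup: str | None = None,
    mean_depth: float | None = None,
) -> TruthSample:
    """Draw one sample's ground truth under the configured study conditions."""
    region = region or _choice(rng, cfg.region_weights)
    if tube_type is None:
        mix = cfg.tube_mix
        if mix is None:
            p = REGION_TUBE_STRECK[region]
            mix = {"Streck": p, "EDTA": 1 - p}
        tube_type = _choice(rng, mix)
    if transport_days is None:
        transport_days = int(np.clip(1 + rng.poisson(REGION_DAY_MEAN[region] - 1), 1, 14))
    if haplogroup is None:
        clade = _choice(rng, REGION_CLADE_PRIOR[region])
        leaves = _leaves_under(tree, clade) or [clade]
        haplogroup = leaves[rng.integers(len(leaves))]
    maternal = draw_haplotype(tree, haplogroup, ref)
    excluded = set(tree.informative_positions)
    hf = cfg.hotspot_fraction
    leuk_private = _draw_private(rng, cfg.n_leukocyte_private, ref, excluded, hf)
    cf_private = _draw_private(rng, cfg.n_cf_private, ref, excluded, hf)
    de_novo = _draw_private(rng, cfg.n_de_novo_foetal, ref, excluded, hf)
    foetal = maternal | de_novo
    heteroplasmy = {
        v: _draw_heteroplasmy(rng, cfg)
        for v in maternal | foetal | leuk_private | cf_private
    }

    params = cfg.leakage
    w = leakage_weight(tube_type, transport_days, params)
    ff0 = float(np.clip(rng.normal(cfg.foetal_fraction_mean, cfg.foetal_fraction_sd), 0.02, 0.25))
    leaked = max(w - params.w0, 0.0)
    true_ff = dilute_foetal_fraction(ff0, leaked)
    weights = ((1 - ff0) / (1 + w), ff0 / (1 + w), w / (1 + w))

    lo, hi = cfg.base_depth_range
    if mean_depth is None:
        base = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        mean_depth = base * (1 + w) / (1 + params.w0)
    total_reads = int(max(rng.normal(cfg.total_reads_mean, cfg.total_reads_sd), 1e5))
    return TruthSample(
        sample_id=sample_id,
        region_label=region,
        tube_type=tube_type,
        transport_days=transport_days,
        haplogroup=haplogroup,
        maternal_variants=maternal,
        foetal_variants=foetal,
        leukocyte_private=leuk_private,
        cf_private=cf_private,
        heteroplasmy=heteroplasmy,
        mixture_weights=weights,
        foetal_fraction=true_ff,
        mean_depth=float(mean_depth),
        total_reads=total_reads,
    )


# ------------------------------------------------------------------ fragments


class _ErrorModel:
    """Pre-indexed homopolymer runs for fast per-fragment error injection."""

    def __init__(self, ref: MtReference, cfg: SimConfig):
        self.cfg = cfg
        self.ref = ref
        track = find_homopolymers(ref, cfg.error_track_min_len)
        self.runs = track.runs
        self.run_index = np.full(ref.length + 1, -1, dtype=np.int32)
        for i, run in enumerate(self.runs):
            if run.start <= run.end:
                self.run_index[run.start : run.end + 1] = i
            else:
                self.run_index[run.start :] = i
                self.run_index[1 : run.end + 1] = i
        self.rates = np.array([cfg.homopolymer_indel_rate(r.run_length) for r in self.runs])

    def errors(self, rng: np.random.Generator, start: int, length: int) -> list[VariantKey]:
        cfg, ref = self.cfg, self.ref
        out: list[VariantKey] = []
        n_sub = rng.binomial(length, cfg.substitution_error_rate)
        for _ in range(n_sub):
            pos = (start - 1 + int(rng.integers(length))) % ref.length + 1
            base = ref.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            out.append(VariantKey(pos, base, alt, SNV))
        # homopolymer indel errors: one Bernoulli draw per distinct run overlapped
        span = np.arange(start, start + length)
        span = (span - 1) % ref.length + 1
        run_ids = np.unique(self.run_index[span])
        for rid in run_ids:
            if rid < 0:
                continue
            run = self.runs[rid]
            if rng.random() >= self.rates[rid]:
                continue
            inside = [p for p in span if self.run_index[p] == rid]
            pos = int(inside[rng.integers(len(inside))])
            if rng.random() < 0.5:
                out.append(VariantKey(pos, run.base, "", DEL))
            else:
                out.append(VariantKey(pos, "", run.base, INS))
        return out


def simulate_sample(
    cfg: SimConfig,
    truth: TruthSample,
    ref: MtReference,
    rng: np.random.Generator,
    error_model: _ErrorModel | None = None,
) -> list[AlignedFragment]:
    """Draw one sample's aligned fragments from the truth mixture.

    Fragment count is ``mean_depth * L / fragment_mean_len``; each fragment's
    tissue of origin follows the mixture weights and it carries each truth
    variant of that tissue overlapping its span with probability equal to the
    variant's heteroplasmy, plus injected sequencing errors.
    """
    cfg.validate()
    if truth.mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if error_model is None:
        error_model = _ErrorModel(ref, cfg)
    L = ref.length
    n_frags = max(int(round(truth.mean_depth * L / cfg.fragment_mean_len)), 1)
    origins = [MATERNAL_CF, FOETAL_CF, LEUKOCYTE]
    weights = np.asarray(truth.mixture_weights)
    haplos = {
        o: sorted(truth.haplotype(o), key=lambda v: (v.pos, v.vtype, v.alt))
        for o in origins
    }
    positions = {o: np.array([v.pos for v in hs]) for o, hs in haplos.items()}
    origin_draws = rng.choice(3, size=n_frags, p=weights / weights.sum())
    starts = rng.integers(1, L + 1, size=n_frags)
    lengths = np.clip(
        np.round(rng.normal(cfg.fragment_mean_len, cfg.fragment_len_sd, size=n_frags)),
        60, 400,
    ).astype(int)
    fragments = []
    for i in range(n_frags):
        origin = origins[origin_draws[i]]
        start, length = int(starts[i]), int(lengths[i])
        end = start + length  # exclusive, may exceed L (wrap)
        alleles: list[VariantKey] = []
        pos_arr = positions[origin]
        if pos_arr.size:
            in_span = (pos_arr >= start) & (pos_arr < end)
            if end > L:
                in_span |= pos_arr < end - L
            for j in np.nonzero(in_span)[0]:
                v = haplos[origin][j]
                if rng.random() < truth.heteroplasmy[v]:
                    alleles.append(v)
        # at most one event per position per fragment; truth beats errors
        by_pos = {v.pos: v for v in error_model.errors(rng, start, length)}
        by_pos.update({v.pos: v for v in alleles})
        fragments.append(
            AlignedFragment(
                sample_id=truth.sample_id,
                start=start,
                length=length,
                alleles=tuple(sorted(by_pos.values())),
                origin=origin,
            )
        )
    return fragments


# ------------------------------------------------------------------ cohort


@dataclass
class SimulatedSample:
    truth: TruthSample
    fragments: list[AlignedFragment]


@dataclass
class SimulatedCohort:
    config: SimConfig
    samples: list[SimulatedSample]

    @property
    def truths(self) -> list[TruthSample]:
        return [s.truth for s in self.samples]


def simulate_cohort(
    cfg: SimConfig, ref: MtReference, tree: HaploTree, **truth_overrides
) -> SimulatedCohort:
    """Generate a full cohort; bit-reproducible under a fixed ``cfg.seed``."""
    cfg.validate()
    error_model = _ErrorModel(ref, cfg)
    samples = []
    for i in range(cfg.n_samples):
        rng = np.random.default_rng([cfg.seed % (2**31), i])
        truth = make_truth_sample(cfg, ref, tree, rng, f"S{i:04d}", **truth_overrides)
        frags = simulate_sample(cfg, truth, ref, rng, error_model)
        samples.append(SimulatedSample(truth=truth, fragments=frags))
    return SimulatedCohort(config=cfg, samples=samples)


def simulate_buffy_pair(
    truth: TruthSample,
    cfg: SimConfig,
    ref: MtReference,
    rng: np.random.Generator,
    buffy_depth: float | None = None,
) -> tuple[list[AlignedFragment], list[AlignedFragment]]:
    """Matched (cfDNA, buffy coat) fragment sets for one individual.

    The buffy-coat sample is drawn purely from the leukocyte haplotype; the
    cfDNA sample from the usual mixture.  Shared variant counts after
    identical calling and filtering are higher for Streck than EDTA samples
    because leaked leukocyte mtDNA carries its private variants into the
    cell-free pool.
    """
    cf = simulate_sample(cfg, truth, ref, rng)
    buffy_truth = TruthSample(
        sample_id=truth.sample_id + "_buffy",
        region_label=truth.region_label,
        tube_type=truth.tube_type,
        transport_days=truth.transport_days,
        haplogroup=truth.haplogroup,
        maternal_variants=truth.maternal_variants,
        foetal_variants=truth.foetal_variants,
        leukocyte_private=truth.leukocyte_private,
        cf_private=frozenset(),
        heteroplasmy=truth.heteroplasmy,
        mixture_weights=(0.0, 0.0, 1.0),
        foetal_fraction=0.0,
        mean_depth=buffy_depth if buffy_depth is not None else truth.mean_depth,
        total_reads=truth.total_reads,
    )
    buffy = simulate_sample(cfg, buffy_truth, ref, rng)
    return cf, buffy


# ------------------------------------------------------------------ coverage model


def simulate_coverage_fraction(
    mean_depth: float,
    n_samples: int,
    rng: np.random.Generator,
    fragment_len: int = 170,
    ref_len: int = 16_569,
) -> np.ndarray:
    """Covered fraction of the circular reference under uniform fragment placement.

    Places ``round(mean_depth * ref_len / fragment_len)`` fragments of fixed
    length uniformly at random for each of ``n_samples`` replicates and
    returns the per-replicate fraction of positions covered at depth >= 1.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    n_frags = int(round(mean_depth * ref_len / fragment_len))
    out = np.empty(n_samples)
    for i in range(n_samples):
        diff = np.zeros(ref_len + 1, dtype=np.int32)
        starts = rng.integers(0, ref_len, size=n_frags)
        ends = starts + fragment_len
        wrap = ends > ref_len
        np.add.at(diff, starts, 1)
        np.add.at(diff, np.where(wrap, ref_len, ends), -1)
        diff[0] += int(wrap.sum())
        np.subtract.at(diff, ends[wrap] - ref_len, 1)
        depth = np.cumsum(diff[:-1])
        out[i] = float((depth > 0).mean())
    return out
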