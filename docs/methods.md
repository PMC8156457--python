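# Methods

## Scope and model

`cfmito` analyses the mitochondrial fraction of low-pass cfDNA sequencing
from pregnant women. The quantities it manipulates are simple but their
interactions are not: per-sample mtDNA content is simultaneously a
biological signal, a QC covariate and a contamination marker; variant calls
at 1–40× depth are dominated by platform error unless filtered; and
haplogroup assignment must tolerate heavy variant dropout. The package
couples each analysis stage to a synthetic cohort generator with known
truth, so every stage is testable end-to-end without access to patient
data.

## Reference and annotations

The packaged reference (`data/chrM_synthetic.fa`) is a **synthetic**
16,569-bp circular sequence with human-mtDNA-like base composition and a
few salted long C-runs; it is a stand-in, not the rCRS, and is labelled as
such. All fixed annotations are genuine mitochondrial coordinates: the
D-loop control region m.16024–m.576 (wrapping the origin), HV1
m.16024–m.16383, HV2 m.57–m.372. Coordinates are 1-based inclusive
throughout, matching HGVS `m.POS` naming; the BED export converts to
0-based half-open.

Homopolymer runs are maximal single-nucleotide repeats; a run touching both
ends of the circular sequence is merged into one origin-wrapping run
(the D-loop itself wraps, so origin-spanning features are first-class). A
variant is "within" a run when its position lies inside it; insertions and
deletions additionally count when immediately adjacent to a run boundary,
because left-aligned indels seeded by a run are conventionally placed at
its edge. The adjacency choice for indels is a design decision, not an
observation.

## Variant calling and filtration

Calling is deliberately permissive — one record per (site, non-reference
allele) with ≥ 2 supporting reads, populated from a pileup with circular
wrap and insertions keyed to the preceding position. Every threshold that
matters lives in the filter cascade:

| filter | default | rationale |
| --- | --- | --- |
| site depth | < 5 removed | low-pass mtDNA; lower than nuclear thresholds because heteroplasmy spreads variants over few reads |
| homopolymer | runs ≥ 4 (SNV and indel) | semiconductor-platform indel error mode |
| homopolymer, indel-strict mode | runs ≥ 3 for indels | separate reporting mode for frequent-indel tables |
| alt support | < 4 alt reads removed | isolated alt reads compatible with scattered error |

The flags are independent predicates, so the surviving set is
order-invariant; the order (depth → homopolymer → alt-support) only shapes
the staged counts in the `FilterReport`. Multi-allelic sites emit one
record per alternative allele; `ref_reads` counts reference-allele reads
only, except for insertions, whose carriers also carry the anchor base, so
their reference support is depth minus their own count.

Heteroplasmy fraction is `alt / (alt + ref)`. The strict homoplasmy rule
requires zero reference reads; the approximate rule treats < 4 reference
reads as residual error, by symmetry with the alt-support filter. The two
rules differ exactly on sites with 1–3 reference reads.

## Haplogroup assignment

The packaged tree (`data/haplogroup_tree_synthetic.tsv`) is a synthetic
~50-node reduction covering superclades H, U, J, T, K, C, D, M, N, W, B, I
at 2–4 levels, with 14–18 defining SNVs per node so that leaf paths carry
~45–55 variants; users may supply a fuller tree in the same TSV schema
(name, parent, comma-separated `POS`+`ALT` tokens). Scoring uses the
Kulczynski measure over (pos, alt) pairs, with the sample set restricted to
positions informative anywhere in the tree so private variants do not
dilute confidence. Ties break toward the deeper node, then lexicographic
name. Calls with confidence ≤ 0.5 are discarded; empirically this is the
regime of samples presenting fewer than ~40 variants.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed and are
not fitted quantities. Each sample draws:

- **region of origin** with weights 0.615 / 0.186 / 0.098 / 0.076 / 0.025
  (Northwestern, Central, Volga-Ural, Yakutia, Others) and a region-linked
  haplogroup prior (Yakutia weighted to C/D/M; the priors are
  illustrative);
- **tube type** region-linked (Streck probability 0.5–0.9; EDTA plasma is
  separated locally, Streck whole blood is the shipping standard for
  remote sites) and **transit days** 1–14 (1 + Poisson, regional means
  1.5–9 days);
- **leukocyte leakage**: relative leukocyte mtDNA mass `w` is the baseline
  `w0 = 0.1` for EDTA at any time and for Streck up to the 72-h
  change-point, then grows as `w0·exp(0.9·(days − 3))` capped at
  `w_max = 10` (the leukocyte pool is finite). The cap and rate were chosen
  so enrichment saturates around the observed envelope of low-pass NIPT
  mtDNA yields (~16–5,500 mitochondrial reads per 3–4 M total, mean depth
  1–40×) rather than estimated from data;
- **mixture weights** (maternal cf, foetal cf, leukocyte) =
  `((1−ff₀)/(1+w), ff₀/(1+w), w/(1+w))`; the foetal haplotype equals the
  maternal one (maternal inheritance; de-novo foetal variants are a config
  knob, default 0);
- **foetal fraction**: baseline ff₀ ~ N(0.10, 0.015) (this emulates the
  gestation-age-scaled quantity, hence the modest spread), diluted by
  leaked nuclear mass to `ff₀ / (1 + (w − w0))`;
- **truth variants**: the haplogroup path plus 12 leukocyte-private and 3
  cf-private SNVs at positions drawn with weight 0.315 from the 3–5,
  11–13 and 15–16 kb hot-spot sections (which yields ≈ ⅔ of variants in
  hot spots, since those sections already cover 51.7% of the genome);
  95% of truth variants are homoplasmic, the residue Beta(2, 2);
- **fragments**: `depth · L / 170` fragments of N(170, 25) bp (cfDNA-scale;
  fragment length is not modelled beyond this), uniform circular starts;
  each fragment carries each truth variant of its origin tissue with
  probability equal to the variant's heteroplasmy. Pre-leakage depth is
  log-uniform on 1–6×, multiplied by `(1+w)/(1+w0)`;
- **errors**: substitutions at 2×10⁻³ per base; per overlapped homopolymer
  run, an indel error with probability `min(0.01·(run−2), 0.45)` —
  non-decreasing in run length. At most one event per position per
  fragment; truth beats error.

All randomness flows from one seed (per-sample child generators), so
cohorts are bit-reproducible.

What the generator does **not** emulate: base qualities, strand bias, PCR
duplicates, GC-coverage bias, NUMT mis-mapping, back-mutations, and any
real phylogenetic structure beyond the packaged toy tree. Passing tests
therefore demonstrate the pipeline's internal correctness and its
behaviour under the modelled mixture/error structure — not calling
performance on real Ion Torrent data.

## Coverage–depth model

Expected covered fraction at mean depth `c` uses the Poisson
(Lander–Waterman) approximation `1 − e^(−c)`: with `N = c·L/ℓ` fragments
of length `ℓ` placed uniformly on a circle of length `L`, per-position
coverage is Binomial(N, ℓ/L) ≈ Poisson(c). The model is used only for QC
expectations and the acceptance computation, never for inference. Under
it, 2× mean depth covers ~86.5% (> 75%), 4× covers ~98.2% (> 95%), and
99.9% mean coverage first occurs at integer depth 7 — the simulation in
`scripts/acceptance.py` confirms all three with 200–500 replicates per
depth.

## Statistics

Group comparisons use the Kruskal–Wallis rank test (tie-corrected H,
chi-square p with g−1 df) via `scipy.stats.kruskal`; p-values are reported
per comparison without multiple-testing correction, matching per-figure
testing practice. mtDNA-content classes default to cohort tertiles (ties
to the lower class; an all-equal cohort is "medium") since no published
boundaries exist; explicit cutoffs override. Variant-count normalisation
is plain division by mtDNA content — the minimal faithful reading of
"normalised to mtDNA content".

## Numerical / degenerate-input choices

- Distinct-variant identity is (pos, ref, alt, type); deletions are
  represented at the first deleted base and insertions anchored to the
  preceding base (`m.9808insT` convention). The VCF layer converts to
  anchored REF/ALT and back lossily only for an origin-adjacent deletion
  at m.1 (right-anchored instead).
- A sample with no tree-informative variants scores 0 (with a warning) and
  is discarded; its superclade is left empty.
- Depth filtering uses **total** site depth, not alt depth — depths
  reported for called variants can therefore fall below the
  alternative-allele count only through deletions; observed depth ranges
  (1 to several hundred) support total-depth semantics.
- The frequent-indel notation `POSXY>Y` sometimes seen for 1-bp deletions
  is not produced; deletions are always named `m.POSdelREF`.
- Genome bins are `ceil(pos/1000)` capped at 16, so bin 16 spans
  m.15001–m.16569.

## Test scale

The suites simulate cohorts of 12–645 samples at 1–30× depth; the largest
(the transport/contamination suite) uses 645 samples — the cohort scale the
generator's regional weights describe — and runs in well under a minute.
Coverage acceptance uses 200–500 replicates per depth. All stochastic
tests fix seeds; property tests (hypothesis) are derandomised.

## Known limitations

- The packaged reference/tree/annotation table are synthetic stand-ins;
  conclusions about real haplogroup frequencies or pathogenicity cannot be
  drawn from them.
- The caller has no base-quality or strand-bias model, so it should not be
  pointed at real BAMs without recalibrated expectations; the filtration
  cascade is the part designed to transfer.
- Kulczynski confidence here is analogous to, but not numerically
  comparable with, HaploGrep-style quality scores.
- The leakage change-point and growth rate are scenario parameters, not
  estimates of any study's biology.
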