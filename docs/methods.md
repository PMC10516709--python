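# Methods

## The audit model

A sample's analyzable genome is covered exactly once by three disjoint
element catalogs: active CRMs, non-active CRMs (both from a genome-wide CRM
catalog whose per-sample states come from the functional-state caller or
from user labels) and non-CRMs. Crossing this three-way cover with STARR
peak overlap yields six exclusive base-level categories A–F. The partition
assumes the catalogs are genuinely disjoint and jointly cover the
analyzable regions; violations are a hard error listing offending
intervals, not a warning.

Two overlap semantics coexist deliberately:

* **Base labels** use direct base intersection (a peak base inside an
  active CRM is C, however small the mutual overlap fraction). Only this
  reading makes the base-share ratios C/(C+D+E) and C/(B+C) internally
  consistent with the conservation identities Σ(A..F) = analyzable bases,
  C+D+E = in-region peak bases, B+C = active-CRM bases, A+D =
  non-active-CRM bases, E+F = non-CRM bases — all asserted at run time on
  every partition.
* **Element pairing** uses the inclusive 50% reciprocal-overlap predicate,
  and feeds the containment (full/partial) and peaks-per-CRM statistics.

A `strict_element_rule` mode restricts C/D base labels to reciprocally
matched peak∩CRM bases as a sensitivity analysis; its counts intentionally
break the peak-base sum identity and are reported without it.

Peak bases outside the analyzable regions are counted as `unassessed` and
excluded from category totals, never dropped silently.

## Fold enrichment — one definition everywhere

Features, peak signal strengths and profile matrices share one per-base
definition: `fe = (signal/L_s) / (input/L_i)` with library sizes `L` equal
to total track mass unless supplied. At zero-input bases a pseudocount of
one read-equivalent enters numerator and denominator
(`fe = ((s+1)/L_s)/((1)/L_i)`), keeping fold enrichment bounded; where the
input is positive no pseudocount is applied, so scaling a track and its
library size together leaves features unchanged exactly.

## Functional-state caller

Four features per CRM — log1p of the mean fold enrichment of ATAC,
H3K4me1, H3K4me3, H3K27ac — are z-standardized (means/scales frozen into
the model) and fed to a logistic regression fit by maximum likelihood with
a small L2 ridge (`ridge=1e-4`, i.e. C=1e4) so separable data keeps finite
weights. The probability cutoff defaults to 0.5 and classification is
inclusive at the threshold. Models serialize to JSON (weights, intercept,
standardization, threshold, feature order) so externally trained weights
can be supplied. Zero-variance features are retained with unit scale and a
warning.

## Complexity, enrichment, association, profiles

* **Complexity** = `log(N_TFBS × D + 1)`, natural log by default
  (configurable; any base preserves ordering). `N_TFBS` is hits per 100 bp;
  hits map into an element by ≥1 bp overlap and count once; `D` averages
  network degree over the element's *unique* hit motifs; motifs absent from
  the network contribute degree 0 and are flagged.
* **Enrichment** = `(N − M)/M`. Backgrounds reproduce the foreground's
  length multiset exactly per draw, placed uniformly over chromosomes
  proportional to length, rejecting placements crossing chromosome ends or
  an exclusion set; GC matching (±0.02 absolute, 10 000 attempts per
  template) rejects against a sequence source. `M` averages over
  `n_draws=10` by default; `n_draws=1` reproduces single-background
  behavior. `M=0` yields NaN with a warning. Length mode counts covered bp
  (ChromHMM states); count mode counts annotation elements overlapping by
  ≥1 bp (transposable elements).
* **Association**: a gene's TSS distance to an element is edge distance
  (0 inside; the gap to the interval boundary otherwise); ties break by
  lexicographically smaller gene id. Within a category a gene counts once;
  genes may appear under several categories. Expression units are taken as
  provided. The Mann–Whitney U p-value is exact (scipy) when the smaller
  sample has ≤8 values and no ties exist; with ties and ≤20 total values it
  enumerates all label assignments over midranks (this makes identical
  samples give p = 1.0 exactly); otherwise the normal approximation with
  tie and continuity corrections. KS is scipy's two-sample test.
* **Profiles**: windows (default 6 kb) center on element midpoints (lower
  median base for even lengths) and tile into non-overlapping 100-bp bins —
  binning, not a rolling mean. Bins extending past a chromosome end are
  masked and excluded from column means; a fully masked column is NaN.
  Row sampling per category: all of C, D, E; up to 10 000 uniform for A and
  B; F downsampled to |E|; all deterministic given a seed.

## Preprocessing

CRMs reciprocally overlapping (≥50% both lengths) a silencer or CTCF peak
are removed, then CRMs with any TSS within 1000 bp of the nearest element
edge (distance 0 inside). The retained set is order-independent; the
removal report counts each element once in silencer → CTCF → promoter
precedence. Replicate peak consensus is the base intersection of each
first-replicate peak with the union of its ≥1-bp-overlap partners,
folded sequentially over additional replicates, so every consensus base is
present in all replicates.

## Synthetic scenarios

The generator plants exactly the structure the audit measures, all from one
RNG seed (byte-identical bundles on re-run):

* **Geometry.** Default 4 × 1.2 Mb chromosomes; a 2% tail per chromosome
  lies outside the analyzable regions. 1200 CRMs with log-normal lengths
  (mean 1181 bp, σ=0.4) alternate with non-CRM gaps that are split into
  elements (log-normal, median 1 kb); CRMs and non-CRMs partition the
  analyzable regions exactly. 30% of CRMs are active.
* **Peaks.** 1000 peaks, log-normal lengths (median 500 bp), each placed
  fully inside a distinct host element of the category drawn from the
  target base-share mixture C:D:E = 0.23:0.28:0.49; ~1.2% of E-like peaks
  straddle the analyzable margin to exercise the unassessed count. Hosts
  are drawn without replacement, so peaks never overlap.
* **Tracks** are piecewise constant per 10 bp. The noise floor is
  gamma(shape 4, scale 0.25) — mean 1 with shape > 2 so per-base
  fold-enrichment ratios have finite variance when the track serves as
  input. Active CRMs carry Gaussian bumps of ATAC (narrow, σ = len/8),
  H3K4me1, H3K4me3 and H3K27ac (broad, σ ≈ len/3.3); E-like peaks carry
  H3K9me3; non-active CRMs carry mild H3K27me3; STARR signal bumps sit on
  all peaks (C strongest). Conservation is Gaussian noise with a +1 shift
  inside CRMs only — E-like peaks stay neutral.
* **Genes/expression.** TSSs sit inside non-CRM elements; TPM is
  log-normal (median 10). The planted effect multiplies by 4 the TPM of
  genes that active CRMs are closest to — the association the audit later
  recovers — rather than genes near any CRM, so the boost concentrates in
  categories B and C.
* **TFBS/network.** A motif graph with preferential attachment (early
  motifs are hubs). Peak-hosting active CRMs draw hits at 6/kb from the hub
  pool; other CRMs 3/kb from all motifs; E-like non-CRMs 2/kb and
  background 0.5/kb from the low-degree half — giving C the highest
  complexity while E-like peaks still exceed random non-CRMs in raw TFBS
  density.
* **ChromHMM-like/TE.** Background 2-kb state tiles; heterochromatin
  ("Het") covers the central 60% of every E-like peak, with the background
  tile rate solved so genome-wide Het density is 10% exactly — hence the
  analytic enrichment expectation (0.6−0.1)/0.1 = 5. LTR elements are
  additionally placed inside half the E-like peaks.
* **Null scenarios** keep the geometry but zero every effect: flat marks,
  no expression boost, no conservation shift, uniform TFBS rates and
  motif pools, no Het planting.

What the generator does **not** emulate: read-level noise, mappability,
repeat structure beyond planted TE-like intervals, chromatin-domain
correlation in background placement, multi-TSS genes. Passing tests
therefore demonstrate the pipeline's correctness and calibration on data
with the assumed statistical structure, not performance on real genomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default 4.8 Mb scenario
for mixture recovery and planted-Het enrichment, a 0.6 Mb scenario for
state-caller recovery and planted-effect orderings, 200 scenarios of
0.25 Mb for Mann–Whitney type-I calibration (sized so category gene sets
reach the asymptotic branch of the test), 20 null scenarios for AUROC
calibration, 100 background-vs-background simulations with 1000 × 1 kb
foregrounds for enrichment null calibration, and 500 random ≤10 kb genomes
for the per-base partition oracle. Derived ratios re-derive from stored
base counts within 1e−12. Degenerate inputs: empty categories are reported
empty, not errors; all-N sequences give NaN GC; zero-length element sets
raise.

## Known limitations

* The functional-state caller ships as a trainer plus model format; no
  pretrained multi-cell-type weights are bundled, so real-data use needs
  labeled training elements or external weights.
* Consensus peak semantics ("overlap in replicates") follow the documented
  intersection rule; other reasonable definitions (union, score-weighted
  merge) would change peak lengths slightly.
* Enrichment reports fold changes without significance; the matched
  backgrounds are not chromatin-domain-preserving shuffles.
* BED input must already be 0-based half-open; chromosome-name dialects
  are only reconciled through an explicit alias map.
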