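# Methods

## Model

For a peptide backbone *p* carrying glycoform *x*, the relative retention
time is RRT(x) = tr(x,p) / tr(A2G2,p), the ratio of the glycoform's
retention time to that of the bi-antennary digalactosylated asialo
glycoform (A2G2) of the same peptide in the same run. The model's central
assumption is backbone invariance: the peptide moiety shifts absolute
HILIC retention multiplicatively, so RRT depends (to good approximation)
only on the glycan. RRTs of one glycoform are therefore pooled across
peptides and summarized by their median and standard deviation; the window
is `median ± k·σ` with k = 3, covering 99.7% of a Gaussian. Given an
anchor glycopeptide identified with high confidence at retention time *a*,
the absolute window of glycoform *x* is `a·[median − kσ, median + kσ]`,
linear in *a* and hence invariant under a common rescaling of a peptide's
retention times.

Isobaric glycan isomers (e.g. α2,3- vs α2,6-linked sialic acid, core vs
arm fucose) can give several chromatographic peaks for one glycoform. No
per-isomer windows are fitted: every peak enters the pool as its own
observation, so one window spans all isomeric species, and an assignment
with several peaks passes validation if *any* peak is inside the window.
This deliberately trades specificity for a lower false-negative rate.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 3.0 | window half-width in σ units (dimensionless); 3 ↔ 99.7% Gaussian coverage |
| `anchor` | `A2G2` | anchor glycoform; its RRT is identically 1 |
| `ddof` | 1 | sample-sd denominator (n−1); training pools are small |
| `anchor_tie_break` | none (error) | `first_eluting` or `most_intense` when a run shows several anchor peaks |

Reporting rounds minutes half-up to 0.1 min; verdicts are always decided
on unrounded endpoints, and window boundaries are inclusive (a measurement
exactly at median ± kσ validates, consistent with the coverage intent).

## The packaged reference model

The shipped model (`data/reference_window_model.json`) transcribes the
window parameters fitted on glycopeptides of haptoglobin, hemopexin and
sex hormone-binding globulin: ten glycoforms (A2G2F1 … A3G3S3) with their
median RRT and ±3σ limits relative to A2G2. Observation counts behind the
fit were not published, so `n_obs` is null; σ is back-computed as
(upper − median)/3 and inherits the rounding of the printed limits, which
is also why the stored limits are not exactly symmetric about the median
(e.g. A2G2F1: 1.027 / 1.032 / 1.034). Prediction uses the stored limits
directly — never median ± kσ recomputed from σ — so the transcribed
windows reproduce exactly as printed. Freshly fitted models are symmetric
by construction, and the raw training retention times are not available,
so the reference parameters are a fixed input, not a reproducible output.

### Known inconsistencies in the reference validation table

The fetuin validation fixture (`data/fetuin_assignments.csv`, measured
RTs; `data/fetuin_published_windows.json`, the windows published alongside
them) contains cells that do not equal anchor RT × reference limits:

* the RPTGEV… A2G2S2 window as published (66.2–72.0) matches the A2G2S2F1
  parameter row, not A2G2S2 (which gives 67.4–69.8 and excludes the
  measured 67.1); likewise the published RPTGEV… A3G3S1 window (50.7–52.3)
  matches the A2G2S1F1 row;
* several endpoints differ by 0.1 min from the recomputation (e.g. LCPDC…
  A3G3 lower 32.5 vs 32.4), consistent with windows having been computed
  from unrounded anchor times before rounding.

The package follows the parameter table as printed; the published windows
are kept as a separate fixture for comparison and are never merged into
the model. Validating the 11 windowed fetuin records against recomputed
windows yields 10 `within` and the one A2G2S2 outlier above.

## Synthetic data generator

`simulate_dataset` emulates the assumed data-generating process: each
peptide draws an anchor retention time uniformly on 25–40 min (the range
the training backbones span); each glycoform draws a true RRT from
Normal(median, σ) once per peptide (backbone invariance taken literally;
an optional per-peptide perturbation term, default 0, lets tests probe
violations); every replicate injection then measures each species with
multiplicative noise `(1 + ε)`, ε ~ Normal(0, RSD) with RSD = 0.006, the
replicate reproducibility reported for the reference measurements.
Defaults are the reference study's conditions: the ten modeled glycoforms
with their transcribed medians/σ as truth and four injections. Isomer
peaks are deterministic RRT offsets — enough to exercise the pooling rule,
not a mixture model. Not simulated: peak shapes, intensities, gradient
effects, co-elution, missing anchors. Passing closed-loop tests therefore
shows the estimator and filter are correct under the model's own
assumptions, not that real chromatography satisfies them.

Two numerical notes. First, a fitted σ estimates the spread of *observed*
RRTs, which includes the replicate ratio noise (≈ √2·RSD·median) on top of
the configured glycoform scatter; recovery tests compare against that
observation-level σ. Second, the transcribed σ of the least variable
glycoforms (A2G2F1: 0.0007) is smaller than 0.6% replicate RSD alone would
produce — a tension internal to the source parameters that does not affect
medians and is left as-is.

## Replicates and anchors

Replicate injections each carry their own anchor measurement, and an RRT
is only meaningful within one injection, so the observation CSV dialect
includes an optional `replicate` column (default 1) and the fit forms RRTs
within each (peptide, replicate) group before pooling. Within a group,
several anchor *peaks* are an error unless a tie-break is configured —
silently guessing the anchor would corrupt every window derived from it.
A glycoform absent from the model gets verdict `no_window`, not `outside`:
the model makes no claim about glycoforms it has not seen. Degenerate
single-observation windows (σ = 0, zero width) are retained but flagged;
no artificial minimum width is imposed.

## Numerical choices

* Sample standard deviation (ddof = 1); median of an even-sized pool is
  the midpoint of the two central values (numpy conventions).
* Half-up rounding via `decimal` on the shortest float repr, so 39.25 →
  39.3 (not banker's rounding).
* Noise-free closed-loop recovery is asserted at 1e-9 absolute: the float
  round-trip (a·m)/a is not bit-exact.
* Monoisotopic constants: glycan residues HexNAc 203.07937, Hex 162.05282,
  Fuc 146.05791, NeuAc 291.09542 Da; proton 1.007276, water 18.010565,
  carbamidomethyl +57.02146 Da (default-on for Cys, overridable). Peptide
  residue masses come from pyteomics.
* Explicit zero counts in glycoform codes (`A2G2S0`) are rejected so that
  parse → format round-trips to the identical string.
* Sequon counting includes Asn within two residues of the C-terminus
  (motif truncated by the cleavage site); peptides with more than one
  potential sequon trigger a warning in the mass utilities, which assume a
  single attached glycan.

## Problem sizes in the test suite

Closed-loop acceptance checks run at the reference design point — 50
peptides × 4 injections (200 observations per glycoform) for median
recovery to ±0.01 — and coverage is measured on 10,000 fresh observations
(250 peptides × 4 injections × 10 glycoforms) against the fitted 3σ
windows, with tolerance 0.997 ± 0.004 (binomial 3σ at n = 10,000 plus σ̂
estimation error at 200 training observations). Invariant sweeps use 100
small random datasets.

## Limitations

* The model transfers across peptide backbones, not across chromatographic
  conditions: a substantially different gradient slope changes RRTs,
  especially for late-eluting sialylated glycoforms, and requires refitting
  on a model glycopeptide set.
* Highly sialylated glycoforms show the largest RRT variability, hence the
  widest windows — exactly where retention shifts are largest.
* Windows validate composition-level assignments only; they do not resolve
  which isobaric isomer a peak is, and no confidence score is defined for
  borderline distances from a window edge.
* The method needs an anchor: a peptide whose A2G2 glycoform was not
  identified cannot be validated (`resolve_anchor` fails loudly).
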