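# Methods

## The measurement problem

A lentiviral gene-therapy product is a mixture: a fraction *p* of cells
carries one or more integrated vector copies, the rest carry none. Bulk qPCR
measures the average copies per cell over the whole mixture (bulk VCN); flow
cytometry with branched-DNA mRNA probes measures *p* per cell. Neither alone
answers the safety-relevant question — how many copies sit in each modified
cell — but the ratio does:

    real VCN = bulk VCN / p.

This identity is exact whenever the negative population truly carries zero
copies; sorted-negative fractions with small nonzero VCN (sorter impurity)
bias the reconstruction, which is why the package also computes the sorted
mixture reconstruction Σ fᵢ·vᵢ and a consistency check between the two
routes rather than adjudicating one.

## Deconvolution conventions

* **Percent handling.** Fractions above 1 (and ≤ 100) are treated as
  percentages and divided by 100 with a warning. Published tables print
  percentages; formulas need proportions; silent mixing of the two is the
  dominant failure mode for this arithmetic, so the conversion is loud.
* **Rounding.** Internal math is full precision. Outputs compared against
  printed tables are rounded half-up — 2 decimals for table rows, 1 for
  headline figures — because that is how such tables are typeset; Python's
  default banker's rounding would disagree on exact ties.
* **Sorted fractions are used as reported.** Sort losses mean the positive
  and negative gate fractions need not sum to 1 (e.g. 19.1% + 80.1%);
  renormalizing would hide the loss, so it is opt-in
  (`reconstruct_bulk_vcn(..., renormalize=True)`).
* **Consistency tolerance.** `consistency_check` passes at a relative
  discrepancy of ≤ 0.15 by default — wide enough to absorb the combined
  qPCR and counting error of a well-run concordance experiment, tight enough
  to flag a ~25% gap.
* **Uncertainty.** `bootstrap_real_vcn` resamples the positive count as
  Binomial(n, p̂) and the bulk VCN as a zero-truncated Normal(v̂, se), and
  takes percentile 95% bounds of the ratio. Coverage is validated by
  simulation at known truth (93–97% over 500 experiments). This treats the
  two assays as independent, which they are (different aliquots, different
  chemistry).

## qPCR model

VCN = ploidy · E^−(meanCt_WPRE − meanCt_PTBP2) with amplification efficiency
E per cycle. Defaults: E = 2 (perfect doubling, overridable per target or
calibrated from a standard dilution series, efficiency = 10^(−1/slope)), and
ploidy = 2, i.e. VCN is reported per cell against a diploid reference locus.
The ploidy convention is stored on every estimate because per-haploid-genome
reporting is equally common; all downstream math is convention-independent as
long as one convention is used throughout. Standard errors are first-order
propagations of the replicate Ct SDs: se = VCN · ln E · √(sd²_t/n_t +
sd²_r/n_r). With triplicates, the SDs carry only 2 degrees of freedom each,
so a correct 95% interval needs a t critical value at Welch–Satterthwaite
degrees of freedom rather than 1.96 — the test suite demonstrates this.
Replicates are aggregated as the arithmetic mean of Ct; no automatic outlier
rejection. Undetectable targets are explicit censored values: a censored
vector target yields VCN 0 (flagged), a censored reference makes the sample
unquantifiable (error).

## Gating model

The threshold is the nearest-rank empirical quantile of a non-transduced
control, default 0.9999, putting the control's own false-positive rate at or
below 0.01%. The rule is deterministic and anchored to the control — no
mixture model is fitted, matching how such assays are gated in practice
against their negative panels. Events exactly at the threshold are negative
(strict `>`), a fixed tie-break. MFIs are geometric means by default
(fluorescence is log-distributed; the geometric mean makes the MFI ratio
invariant to instrument gain), with an arithmetic option. A warning fires
when the control has fewer than 1/(1−q) events, where the extreme quantile
degenerates to the sample maximum. Hierarchical marker gating
(`gate_with_marker`) applies rectangular gates on surface-marker channels
(e.g. CD34/CD90) before the transgene gate; empty sub-populations are
flagged, not estimated.

## Single-hit Poisson model

Integrations per cell ~ Poisson(λ) gives p(λ) = 1 − e^(−λ) and the
zero-truncated mean m(λ) = λ/(1 − e^(−λ)); the two satisfy m·p = λ
(conservation of copies). λ is identified with the measured bulk VCN when
classifying a product — the convention under which "VCN 1 should give 63%
positives". m(λ) is computed from the series 1 + λ/2 + λ²/12 below λ = 1e−8
to avoid cancellation in 1 − e^(−λ). Classification uses a ±10% band on
observed/expected; the band is pragmatic (no formal test is implied by the
comparison). Titrations are fitted on the saturating curve
p(d) = 1 − e^(−αd) by bounded 1-D least squares bracketed by the per-point
exact solutions — at 1000 particles/cell observed fractions sit far outside
the linear regime, so a straight-line fit would be wrong; the low-dose linear
slope (points with p < 0.1) is reported alongside as a cross-check.

## Synthetic data: what it emulates and what it does not

The generator provides ground truth for validation in place of instrument
data:

* **Copy numbers.** Poisson(λ), or a two-component permissiveness mixture
  for sub-Poisson products: a fraction π of cells draws Poisson(λ/π), the
  rest get zero, preserving mean λ exactly. The mixture is the simplest
  mechanism that reproduces ~40% positives at bulk VCN 1, and it is
  identifiable from (bulk VCN, fraction) pairs alone; a beta-Poisson
  continuum of permissiveness is deliberately not modelled.
* **Fluorescence.** Log-normal autofluorescence background (median 10 a.u.,
  log-SD 0.25) plus mfi_per_copy per integrated copy with multiplicative
  log-normal noise (CV 0.25), additive on the linear scale; an optional
  saturation copy count caps the per-cell signal (probe-set saturation).
  Zero-copy cells are distributionally identical to the control — the model
  has no pseudotransduction. The log-normal choice is a field convention,
  not a measured distribution. Branched-DNA amplification yields brightly
  separated populations; the defaults reflect that, so gating error at the
  control threshold is negligible next to counting error.
* **Promoter presets** set mfi_per_copy only (PGK 17, EFS 25, UCOE 35,
  MND 57), calibrated so a λ = 1 sample gated against the default control
  lands near the reported promoter MFI ratios (MND ≈ 8.9, PGK ≈ 3.1); EFS
  and UCOE are intermediate placeholders with no published anchor.
  Transcription kinetics are not modelled. A side effect worth knowing: dim
  presets lose a visible share of single-copy cells below the gate, so at
  equal VCN a PGK-like construct shows a genuinely lower positive fraction —
  matching what is observed with weak promoters.
* **qPCR.** Ct = ct_ref − log_E(quantity) + Normal(0, sd_ct) per replicate,
  triplicates by default; quantity 0 returns a censored measurement.
* **Designs.** Serial dilution replaces cells with background-only cells at
  rate 1 − d, carrying surviving positive events over verbatim (so the MFI
  of positives is exactly dilution-invariant by construction); sorting
  assigns each event to its gated side with probability = purity; titration
  sets λ = α·dose per sample with independent child seeds.

All generators take one seed and are exactly reproducible. What passing
tests on these data show is that the estimators are correct under the stated
generative model; they do not show robustness to spectral spillover, doublet
contamination, pseudotransduction, instrument drift, or non-log-normal
backgrounds, none of which are simulated.

## Problem sizes and numerical choices

Validation simulations use 10⁵ cells for recovery and dilution properties
and 10⁶ for the tightest fraction checks (binomial SE ≈ 5·10⁻⁴ at λ = 1),
sizes at which counting error dominates model error while a full suite run
stays in seconds. Bootstrap intervals default to 2000 resamples. The
nearest-rank quantile, strict-inequality gate, and half-up rounding are all
fixed tie-break conventions chosen for determinism.

## Known limitations

* FCS container files are not read or written; event tables interchange as
  CSV (a channel map handles instrument column names). No compensation,
  logicle/arcsinh transforms, doublet exclusion or viability gating.
* The deconvolution treats the positive population as homogeneous; clonal
  decomposition beyond positive/negative, and integration-site analysis, are
  out of scope.
* real VCN inherits the qPCR ploidy convention; comparing against a
  per-haploid pipeline requires halving.
* The Poisson comparison assumes the flow assay detects every cell with ≥ 1
  integrated, expressed copy; silenced integrants would depress p and
  inflate the apparent real VCN.
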