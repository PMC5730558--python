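# Methods

`gliomaprofiler` re-implements, as a tested and reusable pipeline, the
computational workflow of a rat C6 glioma immune-microenvironment study:
flow-cytometry quantification of immune populations, two-group differential
expression with a plug-in FDR, rank-based GO enrichment, and a cross-species
comparison that ranks human glioblastoma (GBM) subtypes by transcriptomic
similarity to the rat model.  Because the raw cytometry and array data of
such a study are not redistributable at desk scale, every analysis runs
against a seeded synthetic-data module that plants known ground truth; the
estimators never see the ground-truth records, which are written to sidecar
files only.

## Flow-cytometry simulation and gating

**Fluorescence model.** Each panel is a finite mixture over named
populations; within a population, channels are independent log-normals
(FACS dot plots are conventionally viewed on log axes, and log-normal
components are the standard first-order model for cytometry intensity
clusters).  Canonical levels, in natural-log intensity units: negative
(autofluorescence) log-mean 3.0 (log-sd 0.3); positive markers log-mean 7.0
(log-sd 0.5); CD45-low (microglia) 5.5 and CD45-high (peripheral immune
cells) 8.5, both log-sd 0.45, a 3-unit gap that makes the low/high boundary
learnable.  The isotype control is drawn from its own distribution with
log-mean 0.2 above the negative population (log-sd 0.4): isotype antibodies
exhibit low-level nonspecific binding above pure autofluorescence.  This
offset matters quantitatively — it keeps the false-positive leak of the
99th-percentile positivity rule on truly negative events to ≈10⁻⁴, so
recovered fractions are binomially consistent with the planted ones even at
10⁶ events.

**Default population fractions** are the percentages the emulated study
reports: sham brain 13% microglia; day-21 glioma brain 28% microglia, 4%
macrophages, 20% leukocytes; Tregs (FOXP3+) 8.2%, Th (CD4+) 2.8%; MDSCs
(CD11b+Gr1+) 3.99% in glioma brain (1.05% sham) and 6.30% in glioma blood
(2.11% sham).  Values the study does not print (sham T-cell subsets, Tc
fraction, the CD11b+Gr1− companion pool) are modest defaults consistent
with its direction of effect and are configurable.  T-cell populations are
marker-exclusive (each positive on exactly one channel); real Tregs are
CD4+FOXP3+, so the simulator understates marker co-occurrence — fine for
single-marker gating, not a model of full multi-colour compensation.

**Gating.** θ_pos per channel is the 0.99 quantile of the isotype-control
distribution (the study defines background by isotype controls but states
no quantile; 99% is the common practice default and configurable).  The
CD45 low/high split θ_split is the minimum-density point between the two
dominant modes of log-CD45 among CD45-positive stained events, from a
Gaussian KDE on a 512-point grid.  Two numerical guards make mode detection
robust: local maxima below 5% of the global density maximum are ignored,
and a candidate mode pair is accepted only when the valley between the
peaks drops below 0.8 × the smaller peak (KDE estimates of genuinely
unimodal samples often carry a twin-bump at the apex that would otherwise
be read as bimodality).  When no prominent pair exists — e.g. sham brains,
which lack CD45-high cells — the split is flagged as underivable and must
be supplied; the pipeline learns it on the glioma panel of the same batch
and freezes it for sham (whether the original analysis fixed the boundary
per sample or per batch is not stated; per-sample derivation with an
optional frozen override is the default).

Events exactly equal to a threshold are classified negative (strict
inequalities throughout).  All population percentages use all gated events
as denominator; the MDSC view additionally reports Gr1+ within CD11b+,
since both conventions appear in practice.  The simulator generates only
analyzable events — no debris/doublet pre-gate, spillover, or logicle
transform is modelled.

**Group comparisons** report Welch's t and the two-sided Mann-Whitney U
(exact null for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise), with significance flagged on the Mann-Whitney p
at 0.05 — the "t test followed by Mann-Whitney" reporting convention.

## Differential expression

Per-gene Welch two-sided t-tests on log2 expression, tumor vs control,
default group sizes 4 control vs 3 tumor.  Discoveries are p < α at a
uniform α (default 0.01), and the headline FDR is the plug-in estimate
FDR̂ = m·α/k (expected false positives over observed discoveries).  BH
q-values are attached per gene for transparency but are not the selection
rule.  Genes with zero variance in both groups get t = 0, p = 1 when means
are equal (±∞, p = 0 otherwise), avoiding NaN propagation.

Operating characteristics at these tiny group sizes are worth knowing: the
null simulation in the test suite measures an empirical type-I error of
≈0.007 at nominal α = 0.01 — the Welch–Satterthwaite approximation is
conservative at ~5 degrees of freedom — and power for a 2-log2-unit effect
at noise sd 0.5 is ≈0.64 at α = 0.01 versus ≈0.94 at α = 0.05.  The
planted-effect recovery test therefore evaluates sensitivity at the 0.05
level, which the emulated study also uses as an alternative selection
filter; composable post-hoc filters (`apply_filters`) reproduce the
"fold change window plus p cutoff" style of selection.

"Strongest regulation" ranking is |log2fc| descending among discoveries
(ties: smaller p, then lexicographic gene id; p-ranking available by flag).
Marker-panel reports print the signed linear fold-change convention
(−2 means halved).  Probe-level matrices are collapsed by keeping only
uniquely mapping probes and averaging them per gene.

## GO enrichment

Input is the full gene → signed log2fc list.  Each term's genes are
compared against all remaining input genes with a two-sided rank-sum
(Mann-Whitney) test on the fold-change ranks; the originating tool's
default is labelled a "Wilcoxon signed-rank" test, but for a two-set rank
comparison the rank-sum form is the applicable statistic, and output
headers state the statistic actually used.  Exact null for combined n ≤ 20
without ties, tie-corrected normal approximation above; average ranks for
ties; min_term_size 3; BH correction across tested terms.  Direction is
the term's median fold change relative to the global median.  Annotations
are consumed flat (no GO-graph propagation); a ">2-fold upregulated"
pre-filter can be applied upstream by the caller.  Because the statistic
is rank-based, any strictly increasing transform of the fold changes leaves
all p-values unchanged (property-tested).

## Cross-species subtype similarity

**Assignment.** For each human tumor sample, all G genes are ranked within
the sample (rank 1 = highest expression, average ranks for ties) and
normalized as r/(G+1).  For each subtype, the normalized ranks of its
signature genes are tested against Uniform(0,1) with the one-sample KS
statistic; an over-expressed signature concentrates near 0, measured by the
upward-signed D⁺ = sup(ECDF − uniform).  The sample is assigned the
subtype with the largest D⁺; all four D and exact two-sided p values are
always emitted so alternative decision rules can be audited, and samples
where no subtype shifts upward are flagged low-confidence but still
assigned.  Whether the original analysis applied the KS test to ranks,
z-scores or another transform is unstated; normalized ranks versus uniform
is the default here because it is scale-free per sample.

**Similarity.** Rat genes map to human symbols through a one-to-one-filtered
ortholog table (ambiguous pairs dropped, not expanded).  Fold changes are
log2 differences against the mean of normals/controls; rat replicates keep
per-sample vectors (default 3, matching the study design), human references
are per-subtype means over assigned samples.  Spearman's ρ is computed per
rat replicate × subtype over the mapped signature genes; subtypes are
ranked by mean ρ and compared pairwise with two-sided Mann-Whitney tests.
With 3 replicates per group the exact two-sided Mann-Whitney p cannot fall
below 0.1, which the result carries as an explicit small-sample warning.
The Neural subtype is retained in assignment even when few samples land on
it; subtypes with no assigned samples are excluded from the ranking and
flagged.

**Cohort simulator.** 4 × 210 disjoint signature genes plus 1160 background
genes; tumors add a +1.5 log2 centroid shift on their own subtype's
signature; per-sample noise sd 1.0 on a gene baseline of sd 2.0; 20 tumors
per subtype, 10 normals.  The ortholog map retains exactly
round(retention × 840) signature genes (default 660/840) and all background
genes; the rat study's 3 tumor replicates carry the target subtype's shift
attenuated by 0.7 through the mapped genes.  The attenuation models
imperfect cross-species conservation of the expression program; under it
the target subtype's mean ρ is ≈0.25 against ≈0 for the others, so winner
recovery is driven by ranking, not by large absolute correlations — as in
real cross-species comparisons.

## Reproducibility and problem sizes

Everything flows from one integer seed; sub-streams derive via
`SeedSequence(seed, spawn_key=(k,))` with fixed purpose indices, so adding
a generator call never perturbs existing streams.  Identical seed + config
gives byte-identical outputs.  Default problem sizes — 5×10⁴ events for
myeloid panels, 10⁶ for the intracellular-FOXP3 panel, 10⁵ for MDSC
panels, 10⁴ genes for the null calibration, 100-seed batteries for the
recovery properties — mirror the emulated study's stated scales while
keeping a full run on a single CPU in seconds to a couple of minutes.

## Known limitations

* No FCS binary format, compensation/spillover, biexponential transforms,
  doublet exclusion or clustering-based auto-gating.
* No RMA/CEL preprocessing, batch correction or moderated-variance testing;
  the pipeline starts at probe- or gene-level matrices.
* GO annotations are flat gene sets; no DAG propagation or Fisher mode.
* The subtype signature and ortholog map are consumed as input files; no
  subtype discovery, ssGSEA or live database access.
* Synthetic data are Gaussian/log-normal with independent channels and
  genes; passing recovery tests demonstrates estimator correctness under
  these conditions, not robustness to real-data artefacts (correlated
  genes, heavy tails, batch structure).
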