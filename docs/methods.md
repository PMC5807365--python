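# Methods

## The experimental system being modeled

The analysis targets footprinting experiments in which a dCas9 fused to
the DNMT3A catalytic domain is expressed in a methylation-depleted,
maintenance-competent ES cell background: de novo methyltransferases are
knocked out, DNMT1 was transiently repressed to erase the methylome
(global CpG methylation ~0.04), and re-expressed DNMT1 then propagates
whatever the fusion enzyme deposits. Against this blank background every
catalytic engagement of the enzyme is recorded, so on-target activity
(sgRNA-directed) and off-target activity (ubiquitous nuclear enzyme) can
be quantified separately. The package implements both the analysis of
such data and a generative model of the system.

## Analysis model

**Per-CpG observations.** A call is (chrom, dyad position, methylated
reads, total reads); the dyad coordinate is the plus-strand C, 0-based.
Calls from the two strands of a dyad are merged onto that coordinate by
default (an optional strand column supports per-strand tables). CpGs
need ≥5 reads to enter any summary and ≥10 reads (in both samples) to
enter a paired test.

**Tile testing.** 200 bp grid tiles; within a tile, CpGs present and
test-covered in both samples are paired positionally and the statistic is
the paired *t* on the per-CpG differences, t = mean(d)·√n / sd(d) with
n−1 df, two-sided. Tiles with <3 shared CpGs are excluded (no p value).
Degenerate sd(d)=0 takes the continuous limit: all-zero differences give
p=1; a nonzero mean with zero spread gives p=0 and t=±∞. The BH family is
all tested tiles genome-wide per comparison (the procedure is one
genome-wide scan, not per chromosome). Significance is the dual rule
adjusted-p < 0.05 AND |Δ| > 0.10; for CGIs the Δ cutoff is waived. Δ is
two-sided by default; `gain_only` restricts to gains. Tile means are
unweighted means of per-CpG levels — coverage weighting is available
behind `read_weighted` but the unweighted form matches the "mean
methylation for matched CpGs" convention.

**On/off-target.** "Downstream" of a protospacer is 3′ on the
protospacer's strand (configurable to always-rightward); the window is
the literal 200 bp span, not snapped to the tile grid, while the matched
background uses grid tiles with WT mean within ±0.05 of the window's WT
mean, excluding the window itself. Error bars for the contrast are the
SD across background tiles per clone and across clones when several are
supplied. Gain curves hold the CpG set fixed across all days and clones
so the curve reflects methylation change, not coverage drift. Top-k
ranking is by mean descending with (chrom, start) tie-break; only tiles
qualifying in every sample are eligible.

**H3K4me3 scores.** ChIP reads per CGI divided by CGI length; the
99th-percentile density (nearest rank) maps to 100 and larger values are
capped. Nearest-rank was chosen because the percentile convention of the
original scaling is unstated; any interpolation scheme differs only in
the single anchor value.

**Read-level classification.** A read belongs to a window only if ≥1 of
its CpG dyads lies inside (mere interval overlap carries no evidence and
would dilute the fraction); "none" means all in-window calls
unmethylated, "some" means at least one methylated. The pooled fraction
carries a Wilson score 95% CI (the source convention is unstated; Wilson
behaves well near 0/1).

**Smoothing.** Loess with degree-2 local polynomials, tricube weights
over the ⌈span·n⌉ nearest neighbors by coordinate distance, span 0.4, no
robustness iterations. The SD band is the square root of the same
smoother applied to squared residuals, floored at zero — a pragmatic
band for genomic tracks, not a formal variance estimate. Smoothing never
crosses region boundaries.

## Generative model

**Genome.** One synthetic chromosome (default 2 Mb). CpG dyads are
placed on a 2 bp candidate lattice: each even position starts a dyad
with probability 2× the per-bp rate of its compartment (0.01/bp
background, 0.08/bp in CGIs), so dyads never overlap and the dyad count
per compartment is exactly binomial — a closed form the placement tests
use. CGIs are 40 disjoint intervals of 500–2000 bp; 5% of non-CGI 200 bp
tiles are labeled enhancer-like. The base sequence is uniform ACGT with
CG stamped at dyads and accidental CG dinucleotides removed, so sequence
and annotation agree exactly.

**Wild-type landscape.** Per-dyad baselines: bulk Beta(8.5, 1.5)
(mean 0.85), enhancer-like Beta(5, 5) (intermediate), hypomethylated
CGIs Beta(2, 38) (mean 0.05). A minority of CGIs (default 10%, the
approximate genome-wide share of WT-methylated islands) is forced
hypermethylated, Beta(27, 3). Per-CGI H3K4me3 density is
1 − (island WT mean) + N(0, 0.03), clipped to [0,1] — anti-correlated
with methylation, as at promoters. In depleted mode all baselines are
scaled to a global mean of 0.04; the **unscaled** WT baseline is retained
because it, not the depleted state, encodes each locus's potential to
become methylated. Cells start strand-symmetric (mm with probability =
baseline, else uu).

**Dynamics.** Per day, per cell, per strand, an unmethylated CpG gains
methylation with probability 1 − exp(−rate), where

    rate(x) = r_off · s(x) + Σ_g max(0, r_on − r_off) · p_K4(x) · exp(−d(x,g)/λ) · [d ≤ 1 kb]

with susceptibility s(x) = 0.1 + 0.9·WT(x), multiplied inside CGIs by the
protection factor p_K4(x) = 1 − 0.8·(normalized K4 density). The guide
term is parameterized as the *excess* of the on-target rate over the
background process: at r_on = r_off a guide contributes exactly nothing,
so the on-target window is statistically exchangeable with its
methylation-matched background (the null the discrimination test needs),
and at an unprotected protospacer the total rate approaches r_on. The
spreading decay is exponential with λ = 250 bp inside a 2 kb window
centered on the protospacer. Gains precede division each day.

**Division and maintenance.** Each cell's chromosome is one DNA
molecule, so a division inherits a single parental strand per cell
(chosen at random); the complementary strand is synthesized unmethylated
and maintenance then converts hemimethylated dyads to full with fidelity
0.95. This per-molecule inheritance is what leaves unmaintained
hemimethylation on a *consistent* strand within each cell — the state in
which half of strand-uniform reads carry methylation and half carry
none, the read-level signature the package quantifies. Non-CpG
methylation is not a maintenance substrate and dilutes ~2× per division.

**Contexts.** `cpg_only` (catalytic-domain behavior) deposits on CG
dyads exclusively; `cpg_and_cpa` (full-length-enzyme behavior)
additionally methylates CpA cytosines at 0.3× the off-target rate —
enough, against dilution, to hold CpA ~4× above the conversion-noise
floor. Non-CG cytosines are tracked on the plus strand only and observed
by reads of either strand; strand-resolved state is reserved for CG
dyads, where hemimethylation is the object of study.

**Observation layer.** Reads draw (cell, strand, start) uniformly;
read count = coverage·L/read length (default 30× / 150 bp). A methylated
cytosine reads methylated with probability 0.995 (protection); an
unmethylated one with probability 0.005 (conversion failure). Per-site
counts merge dyad strands. There is no PCR duplication, fragment-length
model or quality-score model: the analysis consumes call tables, and
those artifacts act upstream of calls.

**Rate defaults.** No quantitative off-target rate is published for this
system; r_off = 0.05/day and r_on = 1.0/day were chosen once so that the
depleted landscape roughly reproduces the qualitative behavior of the
induction time course (rapid, widespread global gain over days; strong
on-target saturation inside the 2 kb guide window) and were not revisited.

## Rate recovery

`fit_off_target_rate` inverts a deterministic forward model that tracks,
per dyad, the distribution over the number of methylated strands (0/1/2)
under the same gain and division/maintenance rules (one-daughter
marginal: p0′ = q0 + q1/2; p1′ = (1−f)(q1/2 + q2); p2′ = f(q1/2 + q2)).
Observations are first corrected for the bisulfite error model
(E[obs] = t·0.995 + (1−t)·0.005) and the rate is fit by bounded scalar
least squares. Susceptibility enters as a known covariate field — in the
real assay it is the measurable wild-type methylation landscape.

## What the simulator does and does not show

The simulator reproduces the statistical structure the analysis relies
on — a bimodal landscape, susceptibility tied to prior methylation
state, strand-resolved maintenance, binomial read sampling with
conversion noise — so passing tests demonstrate that the pipeline's
statistics are correct and calibrated under that structure. It does not
model sequence-dependent enzyme preference, chromatin accessibility
beyond the H3K4me3 proxy, RRBS fragment selection, mappability, or
cell-cycle asynchrony; agreement on synthetic data therefore does not
certify effect-size estimates on real libraries, where those factors add
dispersion the binomial model lacks. The read-level analysis cannot, by
construction, distinguish true hemimethylation from a mixed population
of fully methylated and unmethylated cells — it quantifies only the
observable "some" fraction, as in the underlying assay.

## Problem sizes and numerical choices

Validation experiments run at the system's native scale: 2 Mb genome,
200 cells, 30× coverage (≈23,000 dyads; ≈400,000 reads per sample). The
null false-discovery check uses 20 independent re-sequencings of
wild-type-level methylomes (depleted ones make most tiles degenerate and
the check vacuous); rate recovery uses days 0–3 at three true rates × 5
seeds; discrimination uses a single bulk-compartment guide per run so
matching bands are well populated. Ties in the top-k ranking break by
coordinate; histogram bins are left-closed with edge values assigned
rightward (an epsilon guard absorbs floating-point edge error); loess
neighborhoods at boundary-distance ties are weight-zero and therefore
tie-break invariant. All randomness flows from one seed through
explicitly passed generators; fixed seed gives byte-identical outputs
(manifest checksums are asserted in tests).
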