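# Methods

## Partition pipeline

Stranded nascent reads are assigned to fixed 1-kb bins by fragment midpoint
(the midpoint is symmetric with respect to strand and bin boundaries; 5′-end
assignment would shift the two strands in opposite directions). Each strand
array is scaled to counts per million using the library's total retained
target reads — normalizing per strand would erase the asymmetry being
measured — then smoothed with a uniform blur over the 30 neighboring bins on
each side. At chromosome edges the blur window truncates and renormalizes
over the bins actually present, so constant tracks are exact fixed points.
The matched input is processed through the identical CPM and blur stages and
subtracted per strand, with negative values clipped to zero; bins whose
corrected signal falls below 0.3 CPM on **both** strands are masked and
propagate as absent values (never zeros) downstream. The stage order is
fixed (raw → CPM → blur → subtract → filter) and enforced at run time.
Partition is (F − R)/(F + R) per unmasked bin, multiplied by −1 when the
library chemistry sequences the complementary strand.

## IZ orientation and the leading-strand fraction

Initiation-zone midpoints define fork direction: downstream of a midpoint
the fork moves rightward and the leading nascent strand is the forward
genome strand; upstream the assignment swaps. Windows within ±flank
(default 250 kb) of each midpoint contribute one row each; upstream windows
are multiplied by −1 so leading-strand enrichment pools as positive
oriented partition. Offset-0 windows carry no fork direction and are
excluded from pooled statistics.

The leading-strand fraction maps the mean oriented partition P to
100·(P + 1)/2. Windows with |offset| ≤ 31 bins are excluded by default:
the 61-bin blur mixes the two fork directions across the midpoint, so
leading/lagging identity is undefined inside the smoothing window. A
bootstrap CI resamples IZs (1000 draws, seeded).

Condition comparisons use a two-sided Wilcoxon signed-rank test on paired
(IZ, offset) bins, dropping zero differences. The null distribution is
enumerated exactly (dynamic programming over doubled midranks) for ≤ 25
nonzero pairs and approximated normally with continuity and tie corrections
above; the implementation is cross-checked against an independent library
routine on tie-free data in the test suite.

## Spike-in calibration (RRPM)

With a constant proportion of exogenous chromatin in every library, the
scale factor α = (input spike fraction)/(IP spike fraction) converts RPM to
reference-adjusted RPM. α = 1 when IP and input have identical spike
composition, and a genome-wide loss of target material lowers α in
proportion, which is what makes treated/control totals comparable. The
bar-plot statistic (target/spike in the IP, normalized to input) equals
total genome-wide RRPM mass up to a constant. The formula lives in a single
function so alternative spike-normalization conventions can be swapped.

Consensus peaks concatenate and sort all replicates' peaks, merge intervals
separated by ≤ 500 bp (gap distance, not center distance), and keep merged
intervals that overlap ≥ 1 bp of at least one peak from **every**
replicate. Quantification takes every 1-kb bin overlapping ≥ 1 bp of any
retained peak; the bin set depends only on the peaks, so vectors from
different conditions align bin-for-bin. Efficiency change is
100·(1 − Σtreated/Σcontrol); positive values are losses.

## MS relative abundance

Relative abundance of a site state is the summed MS1 area of all
peptidoforms carrying it over the backbone's total area, charge states
summed; over the exhaustive state set of one site the values sum to 100%.
Missing backbones report as missing, never as 0%. Isobaric coeluters are
split before this step: the averaged per-ion ratio r of analogous MS2
fragments assigns total·r/(1+r) to the first species. The arithmetic mean
of per-ion ratios is the default ("averaged ratio" is ambiguous between
mean types); a geometric-mean option is provided.

## The simulator

One parental nucleosome sits every 200 bp (mononucleosomal MNase spacing).
Behind the fork each is recycled in place to the leading daughter with
probability `p_lead` (among non-evicted histones) or the lagging daughter;
with probability `evict_frac` it is evicted, then redeposited with
probability `redeposit_frac` onto a free nascent slot — strand drawn fairly,
position uniform, restricted to non-domain positions under the
`outside_domains` rule — or lost to the soluble pool. Every unoccupied
daughter slot receives a new histone, so nucleosome density is conserved
across conditions (matching the unchanged nascent-chromatin accessibility
the readouts assume). Conservation (recycled + redeposited + lost =
parental) is exact per realization and asserted in the truth record.
Redeposited histones retain their marks by default (`retain_marks_on_
redeposit`); this is what makes the genome-wide H3K27me3 loss (15%) smaller
than the in-domain loss (20%) under the double-deficient preset.

Presets (all with spike fraction 0.0005 = 0.05% of chromatin):

| preset | p_lead | evict | redeposit | rationale |
|---|---|---|---|---|
| `wt` | 0.50 | 0 | – | symmetric recycling |
| `dpole4` | 0.42 | 0 | – | moderate lagging bias (design value; no published number) |
| `mcm2-2a` | 0.85 | 0 | – | strong leading bias (design value) |
| `dpole4-mcm2-2a` | 0.80 | 0.20 | 0.25 outside domains | 0.8 in-domain and 0.8 + 0.2·0.25 = 0.85 genome-wide retention |

Geometry: 8 chromosomes × 20 Mb with one IZ each (midpoint at 10 Mb),
sized so the default depths (2×10⁶ IP, 1×10⁶ input reads) run the full
study in seconds per library while leaving seed-to-seed scatter of the
recovered leading fraction at ~0.2 percentage points. Mark domains are
40 kb tiles every 400 kb (10% of the genome) with a seeded phase offset.

Two deliberate idealizations:

* **SCAR sampling is restricted to nascent windows (±310 kb) around IZs.**
  The EdU pulse labels chromatin near active origins; concentrating the IP
  there gives the ~30-fold local enrichment over the genome-wide input
  under which subtract-and-clip input correction is benign. With a
  genome-uniform IP, CPM-scale IP and input coincide in expectation for a
  genome-wide mark, and subtraction would clip one strand to zero in every
  window, saturating partition at ±1. ChOR sampling is genome-wide: its
  quantification is strand-blind and needs no defined fork direction.
* **Spike-in read counts are set to their expectations** (depth × spike
  share) rather than binomially resampled. At desk-scale depth, binomial
  spike noise alone would be ±4–6 percentage points on the efficiency
  estimate — noise the real protocol (tens of thousands of spike reads,
  replicated) does not carry. All other read sampling is stochastic.

What the simulator does not emulate: sequence content (reads are
coordinates, not bases), stochastic origin firing and replication timing
(one deterministic fork basin per position; the measured quantities are
expectations over strand assignment, not firing dynamics), GC/mappability
bias, PCR duplicates, IZ-distal Okazaki-scale structure, and read–write
spreading of marks after deposition. Passing recovery tests therefore shows
the pipeline's estimators are correct under the segregation model, not that
they are robust to every artifact of real libraries.

## Expected recoveries

Under the `dpole4-mcm2-2a` preset the leading-strand fraction of all
*remaining* parental histones is (0.8·0.8 + 0.05·0.5)/0.85 ≈ 78%: the
recycled 80% are leading-biased, the redeposited 5% are strand-symmetric.
The pipeline recovers ≈ 78.3% ("about 80%"), 50% on `wt`, and 20%/15%
in-domain/genome-wide H3K27me3 losses, each within ±2 points at default
depth.

## Numerical choices

* Coordinates are 0-based half-open everywhere; overlap is ≥ 1 bp.
* Bins with zero corrected coverage are masked regardless of the CPM
  threshold; division by zero cannot occur.
* bedGraph output carries 6 decimals; round trips are lossless at 1e-6.
* All randomness flows from a single seed through named, documented
  streams; identical config + seed gives byte-identical outputs.
* Exact Wilcoxon enumeration switches to the normal approximation above 25
  nonzero pairs (2·rank DP stays integral under midrank ties).
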