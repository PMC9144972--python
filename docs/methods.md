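# Methods

`phagekit` re-implements, as tested library code, the quantitative
procedures used to characterize a temperate *Burkholderia* podophage
(JC1): kill-curve virulence indexing, one-step growth analysis,
host-range/EOP scoring, adsorption and serum-survival normalizations,
proteomic virion-association filtering, genome summary statistics and
attachment-site analyses.  A seeded population simulator generates
synthetic data with the statistical structure each analysis assumes, so
the full pipeline runs and is validated with no external data.

## Virulence indexing

Local virulence at one multiplicity of infection (MOI) is

    v = 1 - AUC_phage / AUC_control

where AUC is the trapezoidal area under the OD600 curve from inoculation
to the onset of stationary phase in the uninfected control.  The global
virulence index (GVI) is the trapezoidal area under v versus log10(MOI)
divided by the log-MOI range.  For decade-spaced MOIs the divisor equals
(number of MOIs − 1) — 6 for log MOI −3..3 — but the range form also
normalizes correctly for non-decade ladders.  GVIs are comparable only
between experiments using the same MOI ladder.

Design choices:

- **No clamping.** Local virulence below zero is reported as-is; it flags
  outgrowth of the infected culture past the control, which clamping
  would silently hide.
- **Window selection.** Published analyses fix the window by inspecting
  the control curve; both an explicit window (`onset=<hours>`) and
  automatic detection are provided.  Detection smooths the control with a
  centered 3-point moving average and returns the earliest time after the
  maximum slope at which the slope stays below 5% of the maximum for 3
  consecutive intervals; a curve that never settles returns the last time
  point, flagged.
- **Baseline subtraction off by default**; an opt-in mode subtracts the
  OD at the window start and floors negatives at zero.

## One-step growth analysis

Burst size is P/I: the maximum titer after lysis over the phage initially
added.  The latent period is read off the titer curve as the last sampled
time before the titer first exceeds `rise_factor` (default 2) times the
baseline (mean of the first two samples) — deliberately conservative and
limited by the sampling resolution, because that is how the quantity is
read off a 30-minute-resolution curve.  P is the maximum observed titer
(not a plateau mean), and I defaults to the measured initial titer when
not supplied.  A factor of 2 is the smallest rise robust to counting
noise at a few hundred plaques per spot.

## Population model

    S'  = r S (1 − N/K) − a S V
    I1' = (1 − p_lys) a S V − (n/τ) I1
    Ij' = (n/τ)(I_{j−1} − I_j)          j = 2..n
    L'  = p_lys a S V + r_L L (1 − N/K)
    R'  = m S + r R (1 − N/K)
    V'  = β (n/τ) I_n − a S V − δ V,    N = S + ΣI + L + R

Susceptible cells S grow logistically (rate `r`/h, capacity `K` CFU/mL)
and are infected by free phage V at rate `a` mL/(cell·h).  Infections
lysogenize with probability `p_lys`; the rest pass through `n` latency
compartments (Erlang(n) lysis-time distribution with mean `τ` hours) and
release `β` virions.  Lysogens L and resistant cells R are phage-inert
and grow logistically; resistant cells emerge from the susceptible pool
as a slow flow `m` per hour (written as a source term in R', not a debit
on S', which is negligible at the default m = 1e-8/h).  Observed OD600 is
`c_od·N` plus additive Gaussian noise (σ = 0.01, typical plate-reader
noise) floored at zero; observed titers are Poisson plate counts
(triplicate 5 µL spots at the tenfold dilution giving 300–3000 expected
plaques, mirroring titration in technical triplicate).

**Integration.** The system is stiff when a dense culture collapses: with
a = 1e-8 and V near β·K the adsorption rate a·V reaches ~10³/h while
growth rates are of order 1/h, which is far outside the stability region
of explicit fixed-step methods at any step that finishes a 48 h panel in
reasonable time.  The model is therefore integrated with LSODA
(stiffness-switching, rtol 1e-8), which is deterministic for identical
inputs — the same parameters and seed reproduce output bit-for-bit on a
given platform, which the test suite asserts.  State is floored at zero
in the right-hand side and the output.  Two bookkeeping accumulators
(cells ever infected, phage ever released) are co-integrated so the
budget identity "phage released ≤ β × cells infected" can be checked to
integrator tolerance.

**Defaults and presets.** The defaults describe the microplate kill-curve
experiment on a *Burkholderia*-like host: inoculum 1e6 CFU/mL, growth
rate 0.35/h (stationary onset in the low tens of hours, as plate-reader
cultures show), K = 1.5e9 CFU/mL, τ = 1.5 h and β = 296 (the measured
one-step values), n = 5 latency stages, and OD conversion 1e-9 OD per
CFU/mL.  Temperature is not mechanistic; two presets encode the observed
contrast as infection-parameter differences chosen once to embody it:
`PRESET_37C` (defaults: a = 1e-8, β = 296, p_lys = 0.01) collapses the
culture at every MOI before the control plateaus, giving local virulence
> 0.75 everywhere and GVI ≈ 0.85; `PRESET_30C` (r = 0.3, K = 1.8e9,
a = 1e-10, β = 100, p_lys = 0.5) leaves growth nearly intact (GVI ≈
0.14).  The cultures under the lytic preset regrow by 48 h through the
lysogen/resistant classes, reproducing the late outgrowth such
experiments show.

**Synchronized one-step assay** (`one_step_assay`): 3e7 CFU/mL infected
at MOI 0.1 with efficient adsorption (a = 3e-7; 99% of phage adsorbed in
the 30 min adsorption period), after which the adsorption constant is
zeroed — the model analogue of the large dilution every synchronized
protocol uses to stop readsorption of progeny.  Without that step the
progeny are adsorbed as fast as the primary inoculum and neither the
burst plateau nor the latent period is observable in the free titer.
Lysis timing within a synchronized single cycle is sharp, so this assay
uses n = 120 stages (CV ≈ 9%); the 5-stage kill-curve default is far too
dispersed for a threshold read-off of the latent period — with n = 5,
about 1% of the total burst is already released by τ/3, which would trip
any rise detector hours early.  Lysogenization and phage decay are
negligible on the 6 h assay time scale and are set to zero.

**Genome generator.** Non-overlapping genes with known start/stop codons
and strands are planted on an i.i.d. background of the requested G+C
fraction; the first `terminal_repeat` bases are copied onto the end,
producing the direct terminal repeat characteristic of headful-packaged,
circularly permuted assemblies.  The truth record (exact coding density,
codon tallies, G+C, repeat length) makes every genome statistic testable
against construction.  Genes never wrap the origin: the printed
coordinate dialect reserves start > end for the minus strand, so wrapped
genes are unrepresentable and unsupported (a documented limitation).

**Dose–response generator.** Deaths are Binomial(n, p) with
p = 1/(1 + (LD50/dose)^hill); dose = LD50 gives p = 0.5 by construction.

**What the simulator does not emulate:** lag phase and diauxie in growth
curves, aggregation/biofilm effects on OD, MOI-dependent adsorption
saturation, burst-size variability between cells beyond Erlang lysis
timing, spatial structure, and genuine mutational (stochastic) resistance
— the resistant flow is deterministic.  Green tests on synthetic data
show the estimators are correct for data matching these assumptions, not
that any particular real culture satisfies them.

## Host range, EOP and screening computations

EOP is the titer on a test strain over the titer on the reference host,
computed only where plaques formed; strains clearing without plaques are
scored "+/++/+++" by the lowest titer still clearing (1e10/1e9/1e8
PFU/mL; the three-decade scale is closed and other titers are rejected).
"Not detected" is represented as absence, never as EOP 0.  EOPs print
with two significant figures; the raw value is retained.

The proteomic virion-association filter keeps proteins with ≥ 2 unique
medium-to-high-quality peptides and returns the rest flagged
"unconfirmed" rather than dropping them.  Peptide quality tiers upstream
of the printed counts are not reproducible and are not modeled.

LD50 defaults to linear interpolation of death fraction against log10
dose between the two doses bracketing 0.5 — parameter-free and robust for
sparse decade ladders; a two-parameter log-logistic least-squares fit is
available as an alternative.  Recovery is validated on the tenfold dose
ladder of the larval assay (2e2..2e6 CFU around the 2e4 LD50).  On a
plain 1e2..1e6 ladder the interpolation itself carries a ~24% systematic
bias at hill = 2 (the logistic is not linear in log dose between decades
that far from the midpoint), which is worth knowing before choosing dose
ladders.

Serum survival is the CFU count at a serum concentration over the count
in the serum-free control, as a percentage; adsorption assays are
normalized the same way to the no-cell control, and values above 100%
are reported rather than truncated.

## Genome statistics

- **Terminal repeat trimming** finds the longest exact repeat of length
  4–50 bp shared by the contig's prefix and suffix and removes one copy
  from the end.  The 4 bp floor exists because any sequence shares 1–3 bp
  ends with ~44% probability, and trimming those would make the operation
  non-idempotent; real terminal repeats are at least several bp.
- **Coding density** is the interval union of all annotated genes (both
  strands pooled; nested genes counted once) over the genome length.  The
  printed annotation's density excludes the tRNA gene, whose coordinates
  are not printed; the effect is below 0.2 percentage points.
- **G+C content** excludes ambiguity codes from numerator and
  denominator (`ambiguous_base_count` reports how many were excluded).
- **Boundary codon usage** extracts first/last codons in the printed
  dialect: minus-strand genes read reverse-complemented from the higher
  printed coordinate.
- **att-overlap search** scans every alignment diagonal with a sliding
  window for the longest equal-length substring pair with at most
  `max_mismatch` mismatches and length ≥ `min_len` (defaults 1 and 12);
  ties break toward fewer mismatches, then smaller offsets.  Offsets are
  0-based half-open internally and printed 1-based.  The implementation
  is checked exactly against exhaustive enumeration of all substring
  pairs on small inputs.
- **Frame preservation** models integration into a gene's 5′ end: the
  junction is located as the longest suffix of the hybrid sequence found
  verbatim in the reference CDS, the 30 bp upstream window is scanned for
  the nearest ATG in frame with the downstream remainder (offset to the
  junction congruent mod 3 with the junction's reference offset), and the
  first 10 codons of the rescued gene are translated (bacterial code)
  against the reference start to count changed residues.

## Problem sizes used in validation

Kill-curve panels: 7 decade MOIs, 48 h at 1 h resolution.  One-step
recovery: 20 seeded assays, 6 h at 30 min resolution.  LD50 recovery: 20
seeded cohorts, 500 larvae per dose, 5 doses.  Oracle equivalence:
per-base coding-density oracle on 1e5 bp genomes; att-overlap brute force
on 250 string pairs up to 60 nt.  These sizes make every check exact or
tight while the whole suite runs in well under a minute of simulation
time.

## Known limitations

- The latent-period estimate is biased downward by up to one sampling
  interval by construction (last pre-rise sample).
- Burst size via P/I assumes near-complete adsorption of the inoculum;
  at MOI ≳ 1 it underestimates the per-cell burst because phage beyond
  the first per cell are wasted.
- The stationary-onset detector assumes a single growth phase; diauxic
  controls will trigger on the first plateau.
- GVI values from different MOI ladders are not comparable; the code
  normalizes by log-MOI range but cannot repair a design mismatch.
- The deposited genome record is not packaged, so sequence-dependent
  statistics of the real genome (its G+C, codon tallies) can only be
  recomputed after placing the record at
  `src/phagekit/data/OM283127.fasta`.
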