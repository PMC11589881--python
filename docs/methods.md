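# Methods

## Model and scope

`memtail` analyses the insertion constraints on the C-terminal
transmembrane helix (cTM) of multispanning membrane proteins. The model
has three ingredients:

1. **Insertion route.** The Sec translocon inserts a TM cotranslationally
   only after ~45 further residues have been synthesised. A C-tail of
   fewer than 45 residues therefore implies posttranslational insertion.
   We implement the threshold as a strict `tail_len < 45` (configurable,
   `RouteParams.cotranslational_min_tail`).
2. **Orientation.** Loop sides alternate deterministically from the
   N-terminal side across each TM, so the C-terminus lies on the
   cytosolic side (C_cyt) iff the N-side flipped `n_tm` times is "in".
3. **Translocation barrier.** The hydrophilicity of a loop or tail is the
   sum of per-residue mid-membrane ΔG^app values from the biological
   hydrophobicity scale. Oxa1-family insertases translocate only short,
   relatively hydrophobic tails; for E. coli C_ext proteins the empirical
   capacity band is ΔG^app ≈ 5–6 kcal/mol, and a C_ext protein whose
   (possibly variant-extended) tail both remains < 45 residues and
   exceeds this band is flagged as a predicted misinsertion. The boolean
   flag uses the band midpoint 5.5 kcal/mol by default; the flags at both
   band edges are always reported alongside.

## ΔG^app scale and segment scoring

The scale ships as `data/biological_hydrophobicity.tsv` (`residue`,
`dg_mid` in kcal/mol, positional width `sigma` in residues), transcribed
from the published biological hydrophobicity scale; the code never
hard-codes coefficients, and downstream logic depends only on orderings
and signs. Non-standard letters are rejected explicitly; selenocysteine
(U) is substituted by Cys as a logged preprocessing step during FASTA
reading, never silently during scoring.

TM segment scoring supports two profiles:

* **mid-only (flat)** — the plain sum of mid-membrane values over the
  window; this is the form used for all loop/tail hydrophilicity sums.
* **positional (default for TM windows)** — each residue's mid value is
  weighted by a Gaussian of its offset from the window centre,
  `exp(−d²/2σ²)` with σ = 6 residues. This is this package's own
  approximation of the position-dependent insertion profile (the
  membrane-centre contribution decays towards the interfaces over roughly
  ±6 residues ≈ half the bilayer core at ~1.5 Å helical rise); it
  preserves every ordering the flat model produces on homogeneous
  windows while down-weighting edge residues. We deliberately do not
  re-derive the full published piecewise positional coefficients.

`min_dg_near_center` scans candidate helix windows of length 19–23
(default grid, configurable) whose floor-midpoint centre lies within
±`slack` residues of the annotated TM centre (default 5, option 6 — the
source description "within five to six residues" is ambiguous) and keeps
the minimal score. When no candidate window fits (a TM hard against a
terminus), the largest window that does fit is scored and returned with
`truncated=True` rather than raising. Ties between equally scoring
windows resolve to the first encountered (shorter length, then leftmost
centre); floating-point summation order can select either member of an
exact tie.

## Consensus rules

Two topologies agree when their TM counts match and every rank-paired
centre satisfies |Δcenter| ≤ `center_window/2`. The default window of 14
residues is read as a window centred on one prediction, i.e.
|Δcenter| ≤ 7; the looser ≤ 14 reading is available by doubling the
parameter. Pairing is strictly by rank order — counts are already equal,
so no assignment problem arises. Merging: three-way agreement → quality
"high" with CCTOP coordinates; else an agreeing CCTOP+TMAlphaFold pair
(CCTOP coordinates), else TMAlphaFold+PolyPhobius (TMAlphaFold
coordinates); otherwise the fallback preference PolyPhobius > CCTOP >
TMAlphaFold with quality "low". Two-way agreements are labelled "low" by
default (only the three-way case is unambiguously "high" in the source
procedure); an opt-in "medium" label exists. A CCTOP+PolyPhobius-only
agreement has no named priority and falls through to the fallback, with
the agreeing pair still recorded. TMAlphaFold predictions with fewer than
5 quality tests passed are discarded before merging; a missing
`tests_passed` value is treated as passing. The merged topology is always
one of the inputs verbatim — no coordinate averaging.

## Cohort assembly and statistics

Filters apply in a fixed, logged order: length (18–10,000 residues) → TM
count (≥3, to restrict to translocon-inserted multispanning proteins) →
organelle exclusion. Organelle exclusion is list-driven (user-supplied ID
lists, e.g. from MitoCarta-like curation) or via an organelle tag on the
record; nothing is inferred from sequence. Signal-peptide residues are
excluded from N-tail statistics but retained in the sequence so that all
coordinates stay 1-based against the full chain.

Orientation-class comparisons restrict to posttranslational proteins,
split by C_cyt/C_ext and apply a two-sided Mann–Whitney test with midrank
ties: the exact null when min(n) ≤ 8 and the pooled sample is tie-free,
the normal approximation with tie correction otherwise (the switch point
is configurable; it exists for testability, not as a statistical claim).
No multiple-testing correction is applied — comparisons are reported per
metric, as in the figure-panel convention this mirrors.

## Nonstop variants

A stop-loss variant is accepted as a coding substitution
(`c.{pos}{ref}>{alt}`) against an explicit user-supplied CDS (which must
contain the stop codon and enough 3′ sequence to reach the next in-frame
stop), or at protein level (`p.Ter{N}{Aaa}`, implying N−1 encoded
residues) with a directly supplied extension peptide. The variant must
fall inside the stop codon and abolish it; translation then proceeds in
frame to the next stop, using the standard genetic code only. No
transcript-database lookup is performed — the provided sequence is the
truth. Extended tails are re-classified exactly as wild-type tails
(additivity of ΔG^app makes `new_tail_dg = wt_tail_dg + ΔG(extension)`).

## %insertion quantification

The statistic `100·(1 − AMS/untreated)/(1 − NEM/untreated)` is applied
verbatim to per-replicate %PEGylation values. Preconditions are enforced
as errors: the untreated lane must show PEGylation, and NEM must block
some of it (the denominator controls for cysteines inaccessible in whole
cells and is otherwise meaningless). Band noise can push the raw value
outside [0, 100]; the reported value is clamped with a `clamped` flag and
the raw value retained. Densitometry calibration fits intensity versus
relative amount linearly through the origin over a geometric (two-fold)
dilution series of ≥3 points; saturation of the most-concentrated point
is detected against a fit excluding it (a through-origin fit including a
capped top band absorbs most of the deviation into the slope), firing
when the top residual exceeds twice the RMS of the remaining residuals.
Replicates aggregate as mean ± SEM (sample SD, ddof = 1); fewer than
three replicates warns, a single replicate reports SEM = NaN.

## Synthetic data: what it emulates, and what it does not

The proteome generator draws, per protein: TM count uniform in 3–12,
orientation C_ext with probability 0.5, internal loop lengths uniform in
2–25 residues, 21-residue TMs from a hydrophobic palette, and a C-tail
whose length and target summed ΔG^app come from per-orientation
distributions — C_ext: geometric lengths (p = 0.15, median ~5) with
ΔG^app targets N(3.0, 1.5²), i.e. below the 5–6 capacity band; C_cyt:
lognormal lengths (μ = 3.0, σ = 0.7, median ~20) with targets
N(12.0, 4.0²). These defaults express the qualitative study conditions —
C_ext tails short and relatively hydrophobic, C_cyt tails longer and
hydrophilic — at magnitudes consistent with the E. coli-like regime.
Tail composition is tuned by greedy single-residue swaps (the move whose
ΔG delta best cancels the residual) until the achieved sum is within
±0.5 kcal/mol of the target; this converges deterministically and fast,
unlike rejection sampling. Unreachable targets are resampled with a
logged count, then clipped into the reachable range.

The generator does **not** emulate realistic amino-acid composition
beyond ΔG targets, homology/phylogenetic structure, signal peptides, or
re-entrant/interface helices. Tests passing on this synthetic proteome
therefore demonstrate correctness of the pipeline's arithmetic and label
logic, not predictive accuracy on real proteomes — reproducing the
published cohort sizes would additionally require proteome downloads and
predictor-version parity, which is out of scope by design.

Predictor perturbation applies, independently per source: missing data
(probability `p_missing`), per-segment centre jitter (rounded Gaussian,
kept only if topology invariants survive), TM drop and spurious-TM
addition (into the largest loop able to host one). Reverse translation
uses uniform codon choice — codon bias is irrelevant to every consuming
stage — and plants a single-nucleotide stop-loss variant; amino acids not
reachable from any stop codon by one substitution (e.g. Met) are rejected
with a clear error, and `reachable_first_residues()` enumerates the valid
set. Gel generation inverts the %insertion formula (mock = 90, NEM = 9 %
PEGylation baselines) and applies mean-one lognormal noise per band at a
chosen CV.

## Numerical and interface choices

* Coordinates 1-based inclusive everywhere; TM centre = floor midpoint.
* All randomness flows through `numpy.random.default_rng` seeded from the
  spec or function argument; identical seeds give byte-identical outputs.
* The acceptance script and test suite use scaled problem sizes — 500
  proteins for label recovery, 1000 cohorts of 100 proteins for power,
  1000 random cases for each oracle-equivalence check — chosen to make
  the full run complete in well under a minute while keeping Monte-Carlo
  error far from the asserted margins.
* Errors are typed and early: unknown residues, degenerate denominators,
  non-nonstop variants, missing in-frame stops, and malformed tables
  (with line numbers) each raise distinct, named exceptions; missing
  predictor data is a value, not an error.

## Known limitations

* The Gaussian positional profile is an approximation; absolute windowed
  TM scores should not be compared against the published ΔG-predictor
  server output, though orderings are preserved.
* Two-way consensus quality ("low" vs "medium") is a policy choice, not
  derivable from the source procedure.
* The misinsertion flag is a threshold heuristic on summed tail ΔG^app;
  it ignores tail charge placement, helicity, and insertase identity.
* Exact Mann–Whitney p-values are only available for tie-free pooled
  samples; heavily tied small samples fall back to the approximation.
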