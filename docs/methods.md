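# Methods

This note documents the statistical model, the algorithms, the synthetic
benchmark generator and the numerical choices behind `seqregister`, in the
spirit of a methods appendix. Nothing here states an empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Problem and pipeline

Given a protein model, its target (reference) sequences and a density map
(or 2mFo−DFc map coefficients), the tool answers: *is each modelled
fragment assigned to the right place in the right sequence?* The pipeline
is

1. read model, sequences and density (`structure_io`);
2. compute a per-residue 20-class residue-type probability profile from
   the density (`residue_classifier`, pluggable);
3. identify each chain's sequence from its whole profile
   (`register_scanner.assign_chain`);
4. slide fixed-length windows along every continuous residue-number run,
   re-align each window gaplessly against all targets, and compare the
   best placement with the register the model implies
   (`register_scanner.scan_chain`);
5. merge and categorize disagreements into issue regions
   (`register_scanner.categorize`) and serialize a report (`cli_report`).

All coordinates are orthogonal angstroms; residue numbering is author
numbering. Maps are sigma-scaled (zero mean, unit variance over the cell)
so that downstream features are scale-free; MTZ coefficients are Fourier-
synthesized on a grid with spacing ≤ d_min/3 (auto-detected column pairs
`FWT/PHWT`, then `2FOFCWT/PH2FOFCWT`). Interpolation is trilinear with
periodic wrapping and is exact at grid nodes. Alternate conformations:
altloc blank or 'A' is kept, others dropped. Only P1 periodic
interpolation of the synthesized unit-cell map is supported — no symmetry
expansion, scaling or refinement.

## 2. Alignment score and p-value

A window of `L` probability rows `P_i` (floored at `probability_floor`,
default 1e-4, then renormalized — entries already above the floor are
unchanged, which keeps clean closed-form scores exact) is scored at offset
`o` of target `a` by `S(o) = Σ_i log(P_i(a_{o+i})/q(a_{o+i}))` in nats.
Background `q` is uniform by default (no composition estimate is imposed).
An 'X' in the target contributes zero. The best placement over all offsets
of all targets is selected; ties break to the earlier sequence, then the
lowest offset.

**Null distribution.** Under an i.i.d. background sequence the single-
offset score is a sum of `L` independent 20-atom random variables, whose
distribution is computed exactly by sparse convolution on a lattice of
`grid_step` nats (default 0.002). Atoms are binned rounding down; lattice
tails carrying < 1e-12 mass are truncated. A tail query `P(S ≥ s)`
compensates the expected accumulated rounding by shifting the threshold
L/2 steps and splits the threshold bin's mass with a geometric within-bin
model (tails decay ~exponentially, so uniform splitting would overestimate
the upper part by ~rate·step/2). With the default step the computed tails
agree with exhaustive 20^5 enumeration to well under one percent, which
matters because the best-of-M correction amplifies marginal-tail errors by
`dp/dt = M(1−t)^{M−1}`.

**Best-of-M correction.** The p-value of the best alignment over `M`
offsets is `p = 1 − (1 − θ·tail)^M`. Scores at overlapping offsets of the
same sequence are not independent: a letter shared by two placements `d`
apart is scored by rows `d` apart, so `Cov(S_o, S_{o+d})` is the sum of
same-letter cross-row covariances over the `L−d` shared positions — a
quantity computed exactly from the window. When some lag correlation is
strong (|ρ_d| ≥ 0.1), exceedances cluster and the plain independence
correction overestimates `p`; the declumping factor
`θ = Π_d (1 − q_d)`, with `q_d = P(S_d ≥ s | S_0 ≥ s)` evaluated under a
Gaussian coupling with the exact lag correlation (Owen's T function),
estimates the fraction of exceedances that start a new cluster. Weak lags
are deliberately left uncorrected: for sums of bounded atoms the Gaussian
joint tail overstates their clustering, and correcting dozens of weak lags
visibly overshoots. The correction is active only for `tail < 0.5`; with
no strong lag `θ = 1` and the formula is the familiar independence one.

The independence-with-declumping form remains an approximation above
`p ≈ 0.5`, where accumulated weak-lag clustering is real but not
correctable without exact pairwise joint distributions; the tool makes no
decisions in that regime (the operating threshold is 0.14).

**Certified screen.** For the log-odds score `E[e^S] = 1` under the null,
so `tail(s) ≤ e^{−s}` exactly (Markov at unit rate). When
`M·e^{−(s−margin)}` already clears the threshold decision (margin
`(L+2)·grid_step` dominates the lattice version), the scanner records this
certified upper bound as the window's p-value and skips the convolution.
Statuses and regions are identical to the all-exact path; this is what
keeps thousand-chain benchmarks in the minutes range.

## 3. Scanning and categorization

Windows (default length 20, stride 1, minimum chain length 10) are taken
only inside continuous residue-number runs (insertion codes break a run).
Chains of 10–19 residues are scanned as a single truncated window; shorter
chains are skipped, not failed. A chain is *assigned* when the gapless
alignment of its longest continuous run's profile reaches `p < 0.14`;
otherwise it is reported as an `unassigned_chain` region.

The register the model claims (`model_offset`) is anchored once per run by
a mismatch-tolerant ('X'-wildcard Hamming, minimum-mismatch, ties to the
lowest offset, rejected above 50% mismatches) placement of the run's
claimed one-letter sequence in the assigned target, extrapolated through
the run by numbering; a chain-level anchor is the fallback. Anchoring by
numbering rather than per-window string matching is what makes *indexing
issues* — identities right, numbering wrong — detectable at all, and what
keeps isolated point mismatches from poisoning whole windows.

A window is `shifted` when `p < 0.14` and its best placement disagrees
with `model_offset` (or the best sequence differs); `consistent` when it
agrees with `p < 0.14`; `inconclusive` otherwise. Consecutive shifted
windows with a common offset delta within `merge_gap = 5` residues merge
into one region. Region bounds trim half a window from each end (a single
shifted window collapses to its midpoint), which maps the span of shifted
windows onto the actually shifted residue span to within a few residues.
Category: `indexing_issue` if the model's residues over the region match
the target at the *detected* offset, else `register_shift`; adjacent runs
with opposite offsets stay separate regions. Isolated residues inside
consistent stretches whose claimed type disagrees with the target (or is
UNK/'X') become `sequence_mismatch` regions. Shifted groups whose register
cannot be anchored at all have an unknowable shift magnitude and yield no
region.

## 4. Baseline residue-type classifier

The classifier interface is a callable `(model, map, chain, residue) →
probability row`; `extract_profile` accepts any such callable or a
precomputed tab-separated profile table (columns `chain`, `resnum`,
`icode`, then the 20 types in alphabetical one-letter order). Rows for
unclassifiable residues (missing backbone) are uniform and flagged.

The built-in baseline measures, in radial shells around the side-chain
anchor (CB, or an ideal-geometry pseudo-CB when absent; default shell
edges 0, 1.5, 2.5, 3.5, 4.5, 5.5 Å, 48 Fibonacci-lattice points per
shell), the mean of an omit-style difference density: the Gaussian density
computed from every atom that is *not* part of the residue's own side
chain (its own backbone and all neighbouring residues — their coordinates
are reliable even when the register is wrong), scaled to the map via the
mean map level at the residue's backbone atoms, is subtracted point by
point. Sample points within 3 Å of another chain's atoms or within 1.2 Å
of a non-side-chain atom are masked, and each shell mean is multiplied by
its surviving-point fraction so it stays comparable to a full spherical
average. Subtracting the *computed* local model density rather than a
constant backbone level is essential: backbone atoms sit on density
maxima, and a constant-offset baseline buries the inter-type shell
differences under a residue-independent ramp.

Templates `μ[a,k]` are the Gaussian-smeared (σ = 1 Å, closed-form
spherical average) contributions of type `a`'s side-chain heavy atoms at
ideal distances from CB (heavy-atom counts per type: G 0, A 1, S/C 2,
T/V/P 3, N/D/I/L/M 4, E/Q/K 5, H 6, R/F 7, Y 8, W 10; distances beyond
the outermost edge are clipped into the last shell). Each template is
fitted by a least-squares scale clamped to [0.05, 20] —
`score(a) = −Σ_k (f_k − s·μ[a,k])²`, glycine's empty template scoring the
features' total squared mass — and probabilities are
`softmax(score/0.25)`, floored and renormalized. The positive lower clamp
makes an all-zero feature vector rank glycine strictly first. The
classifier is deterministic; no learned model is trained or shipped.

## 5. Synthetic benchmark generator

`synthetic` produces ground-truth benchmarks without any downloads:

- **Targets** are i.i.d. draws from the background.
- **Profiles** emulate a classifier of accuracy `alpha`: per residue a
  predicted label is drawn (the true type with probability `alpha`,
  otherwise from a confusion kernel — uniform by default, or
  similarity-weighted within D/N, E/Q, V/T/I, F/Y), and the row places
  mass `alpha` on the *label*, so the row argmax equals the truth with
  frequency `alpha`. Rows are then multiplied by log-normal jitter
  (default scale 0.3) and renormalized: real posteriors vary continuously
  from residue to residue, and without jitter every row would share one
  value multiset, collapsing window null distributions onto a coarse
  21-atom lattice that no actual classifier produces and making p-values
  artificially discrete. `alpha = 1` still yields exactly degenerate rows.
- **Errors**: register shifts (density at `i+offset`, claim at `i`),
  indexing shifts (identities follow the density, numbering does not),
  numbering gaps (a properly numbered unmodelled loop — *not* an error),
  point mismatches and UNK residues. Sequence positions are 1-based; a
  positive offset means the true position exceeds the claimed one.
- **Fragment sampling** draws up to three continuous fragments of each
  requested length (default 10 and 20) per chain uniformly, then rejects
  fragments containing UNK residues or insertion codes, or whose residue
  count does not match the difference between flanking residue numbers;
  rejection may leave fewer fragments than requested.
- **Toy structures and maps** for the density path: an idealized extended
  chain (3.5 Å per residue, side chains alternating sides) with
  pseudo-side-chain atoms at the template distances from CB, rendered as
  periodic Gaussian-atom density (σ = 1 Å, 0.6 Å grid) in an orthorhombic
  P1 box.
- **Scoring**: a detected region matches a true region iff category and
  offset agree and the overlap covers ≥ 50% of the true span; boundary
  error is the larger endpoint discrepancy.

What the generator does *not* emulate: crystallographic noise, model bias,
resolution dependence, rotamer variability, or realistic confusion
structure — `alpha` is an abstract accuracy knob. Passing benchmarks
therefore demonstrate the correctness and calibration of the *statistics
and bookkeeping*, not end-to-end performance on real maps; the toy-map
classifier test is likewise a self-consistency check (the generator places
side-chain mass at the same ideal distances the templates assume), not a
measurement of accuracy on experimental density.

## 6. Benchmark studies (tests and `scripts/acceptance.py`)

Problem sizes were chosen to exercise each claim at desk scale: boundary
localization on 200 chains (length 300, one +2 shift over residues
121–180, accuracy 0.9, window 20, threshold 0.14, median boundary error
required ≤ 5 residues); p-value calibration on 20,000 null windows
(L = 20, accuracy 0.8, unrelated 300-residue targets; fraction below t
within ±0.02 at t = 0.05, 0.14, 0.5); Monte-Carlo oracle agreement on 20
windows of L ∈ {5, 10, 20} probed at the 0.14 operating threshold against
10^5-draw best-score frequencies (each probe's deviation is ~N(0,1)
binomial SE when the p-value is correct, so one excursion beyond 3 SE
among 20 probes is statistically expected and allowed, hard-capped at
4.5 SE), plus deterministic enumeration oracles (L = 2 identity, L = 5
full 20^5 tails); offset recovery at ±1, ±2, ±5, ±10 over a 60-residue
span (detection ≥ 95%, recovered offset exact everywhere) with a
false-positive check on 1,000 shift-free chains (≤ 1%); noise-free
correctness at accuracy 1.0; fragment-sampler conformance; and the
classifier top-5 smoke test on a 50-residue toy map.

## 7. Known limitations

- Gapless alignment only: insertions/deletions are located indirectly via
  shifted flanking registers, not by gapped alignment.
- The best-of-M p-value is approximate above ~0.5 (see §2); decisions are
  made far below that.
- Region boundaries are resolved to about half a window near run edges.
- The baseline classifier is a transparent stand-in; on real maps a
  learned classifier (plugged in through the profile contract) will be
  substantially more accurate.
- Chain-to-sequence assignment uses the longest continuous run; heavily
  fragmented chains with no sizable run may go unassigned.
- No nucleic-acid chains, no per-residue map-model correlation metrics,
  and no automatic model correction.
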