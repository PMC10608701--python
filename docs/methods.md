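# Methods

## The labeled-reference credentialing model

`isocred` implements annotation of untargeted LC-MS metabolomics data
against a *dual-isotope labeled reference*: a microbial culture (the
motivating design uses *S. cerevisiae*) grown in four media — unlabeled,
U-¹³C, U-¹⁵N, and U-¹³C+¹⁵N — for enough generations that labeling is
effectively complete. A metabolite with *c* carbons and *n* nitrogens then
appears as four ions whose m/z values differ by exact, known amounts:

    Δm(13C) = c · (m(¹³C) − m(¹²C)) = c · 1.0033548 Da
    Δm(15N) = n · (m(¹⁵N) − m(¹⁴N)) = n · 0.9970349 Da
    Δm(dual) = Δm(13C) + Δm(15N)

Two things follow. First, any peak lacking the predicted partners in the
labeled conditions is not a metabolite of the organism (solvent clusters,
media components, instrument artifacts) and is discarded — this is the
*credentialing* filter. Second, the shifts read the carbon and nitrogen
counts directly off the spectrum, which collapses the combinatorial
ambiguity of molecular-formula assignment.

Assumptions: full isotopic enrichment (no partial isotopologue envelopes;
partial labeling is out of scope), one ion form per polarity
([M−H]⁻ / [M+H]⁺ by default), and a single chromatographic method so that
one RT scale and one co-elution tolerance apply everywhere.

## Quartet matching

For each unlabeled peak (neutral mass M from the ion m/z and the
configured adduct), candidate assignments are enumerated over
c ∈ [0, min(c_max, ⌊M/12⌋)] and n ∈ [0, min(n_max, ⌊M/14⌋)]. For each
(c, n) the best-matching partner (smallest |ppm|) is sought in each
labeled condition within:

- `mz_tol_ppm` (default 5 ppm) of the predicted partner m/z,
- `rt_tol` (default 0.5 min) of the unlabeled peak's RT,
- labeled/unlabeled intensity ratio within `intensity_ratio_bounds`
  (default 0.2–5; a fully labeled culture expresses the same metabolite at
  comparable abundance).

A candidate is admissible only when **both** atom counts are evidenced:
c by the ¹³C or dual partner, n by the ¹⁵N or dual partner. A lone
single-label partner would leave the other count completely
unconstrained, so no quartet is emitted for it. Support levels are
`full` (all three partners), `triad` (two), and `pair` (dual partner
only). Candidates are ranked by (support, worst-partner ppm error); an
exact tie between distinct (c, n) at the top flags the quartet
*ambiguous*.

Unlabeled peaks are processed in descending intensity and each labeled
peak may be claimed by at most one quartet; a later quartet whose best
partner is already claimed is emitted but flagged `conflict`. The
*credentialed* set — what proceeds to formula prediction — is
support=full, unambiguous, conflict-free. Intensity-greedy claiming was
chosen over global assignment because it is deterministic, linear-time,
and matches how the strongest signal dominates in practice.

The windowed binary-search implementation is verified against an
exhaustive enumeration over all (u, ¹³C, ¹⁵N, dual, c, n) combinations in
the test suite; outputs are identical, including tie-breaks and flags.

Defaults: `c_max` 40 and `n_max` 10 comfortably cover CHNOPS metabolites
below m/z 1000. The electron mass is carried in the proton-mass
correction: at m/z 70 it amounts to ~7.8 ppm, larger than the matching
tolerance, so it cannot be neglected.

## Formula prediction under labeling constraints

`decompose(M, c, n, tol_ppm, bounds)` enumerates oxygen, phosphorus and
sulfur counts over their bounds and *solves* hydrogen from the mass
residual, h = round((M − mass(C_c N_n O_o P_p S_s)) / m(H)), reducing the
enumeration from O(H·O·P·S) to O(O·P·S). Equivalence with the full
nested loop is a tested invariant, not an assumption. Accepted candidates
satisfy:

- |ppm error| ≤ tol_ppm (default 5 ppm),
- RDBE = C + 1 + (N+P)/2 − H/2 within [0, 25] **and integer-valued**
  (neutral even-electron molecules; this subsumes the nitrogen rule),
- H within [0, 80], O within [0, 20], P and S within [0, 4],
- H/C within [0.1, 6.0] when C > 0.

The H/C default is the *extended* range of the common golden-rules
heuristics rather than the narrower [0.2, 3.1] "common" range: N-rich
small metabolites central to this problem domain — urea (H/C = 4),
guanidine, methylamine — fall outside the common range, and the labeling
constraint already carries most of the filtering power. All bounds are
config-exposed.

`constrained_gain` quantifies that filtering power by comparing the
candidate count with (c, n) fixed against the conventional label-free
search over the same bounds; the constrained set is a subset by
construction. On random CHNOPS formulas above 300 Da at 10 ppm the median
reduction is roughly 60–70-fold.

## Annotation tiers

Library entries are admissible for a quartet only if the entry's formula
has exactly the labeling-inferred C and N counts and its neutral mass is
within `mass_tol_ppm`. Evidence then sets the tier:

1. `standard_confirmed` — RT within `rt_tol` (default 0.5 min, the same
   scale as co-elution) of an authenticated standard's RT;
2. `ms2_matched` — MS2 cosine ≥ `ms2_threshold` (default 0.7);
3. `putative_formula` — mass/formula evidence only;
4. `unannotated` — no formula candidate at all.

MS2 similarity is a greedy one-to-one fragment-matched cosine (closest
m/z pairs first, each fragment used once, `frag_tol_mz` default 0.01 Th)
over square-root-scaled intensities; sqrt scaling tempers the dominance
of base peaks, and the score is 1 exactly when the spectra coincide
within tolerance up to global scaling.

## Database merging

Annotations from the four runs (ESI±, APCI±) are merged on an identity
key — the best-tier name when identified, otherwise the top candidate's
Hill formula — with greedy RT clustering (`rt_tol` 0.5 min, seeded by the
first row in canonical sort order). Merged entries keep the union of
detecting runs, the best tier, and per-run intensities (not averaged, so
source-coverage heat maps remain reconstructible). Rows are canonically
sorted before clustering, making the merge provably order-independent;
unannotated quartets carry no usable identity and are excluded from the
database. Distinct identities at the same mass and RT are never
collapsed.

## The synthetic-data generator

`sample_library` rejection-samples distinct CHNOPS formulas inside the
plausibility box with neutral mass in 72–980 Da (both ion polarities then
stay inside the m/z 70–1000 scan range), RT uniform on the 1–20 min
usable window of the gradient, and a random fragment spectrum per
compound. `simulate_quartets` plants, per compound and detectable run,
the four condition peaks at their exact shifts, then applies:

- multiplicative mass noise, m/z × (1 + ε·10⁻⁶), ε ~ N(0, `ppm_noise_sd`)
  per peak (default 2 ppm, typical for well-calibrated 120k-resolution
  Orbitrap data);
- RT jitter ~ N(0, `rt_jitter_sd`), default 0.05 min;
- independent per-condition partner dropout (default 10%);
- log-normal intensities with labeled/unlabeled ratio noise clipped to
  [0.25, 4], inside the default ratio bounds;
- unlabeled-only decoys (default one per compound per run) at uniform
  m/z and RT — the media/background class credentialing removes;
- S/N drawn above the picking threshold (peak lists model already-picked
  peaks).

The source/polarity design assigns each compound one polarity (67%
negative) and ESI-only / APCI-only / shared status (55% / 35% / 10%),
mirroring the strong source exclusivity of HILIC metabolite coverage.
`degrade_library` splits simulator knowledge into realistic annotation
inputs: the library keeps each entry's RT and MS2 spectrum with
probability 0.6 each, and "acquired" query MS2 spectra exist for 70% of
compounds with 10% intensity noise.

What the generator does **not** emulate: chromatographic peak shapes,
isotopologue fine structure and natural-abundance satellites, adduct and
in-source-fragment multiplicity, partial labeling, correlated mass-axis
drift, and intensity-dependent mass error. Passing tests therefore show
the algorithmic chain is correct under the stated noise model, not that
real data will reach the same recovery.

### Recovery accounting

With 10% per-condition dropout only ~73% of compounds retain all three
partners, so recovery is reported two ways: `recovery_rate` — the
fraction of all planted compounds whose emitted quartet (any support
level) carries the correct (c, n), the headline sensitivity of atom-count
inference — and `credentialed_recovery_rate`, restricted to compounds
with a fully planted quartet and to credentialed output. At the default
conditions (1000 compounds, 2 ppm noise, 5 ppm tolerance) partner-match
errors are ~2.8 ppm r.m.s. (two independent 2 ppm draws), so ~92% of
individual partners fall inside the window; the measured rates (~94% and
~82–85%) follow directly from that arithmetic. Decoys are never
credentialed in any tested run because a decoy would need three
co-eluting, ratio-compatible, unclaimed partners at one consistent (c, n)
— a coincidence with probability ≈ 10⁻⁸ per decoy at the default peak
densities.

## Numerical choices and degenerate inputs

- Atomic masses are CODATA/IUPAC monoisotopic values; ¹²C = 12 exactly.
- Candidate ordering tie-breaks: formula candidates by (|ppm|,
  heteroatom count, Hill string); quartet candidates by (support, worst
  ppm, c, n); matches by (tier, score, name). All orderings are total, so
  identical inputs give byte-identical outputs.
- Empty peak tables are valid (warning, empty outputs, exit 0); rows with
  non-numeric fields are collected and reported by index, never dropped.
- The S/N filter is strict (> 5), matching the picking convention;
  filtering is idempotent.
- Problem sizes in the test suite and acceptance script (1000-compound
  simulations, 100-formula oracle sweeps, ≤20-peak exhaustive instances)
  were chosen so the full chain and its brute-force oracles run
  comfortably on a single CPU while keeping binomial noise on measured
  rates below about one percentage point.

## Known limitations

- One adduct per polarity during matching; alternative adducts (e.g.
  ammonium from the mobile phase) affect only the neutral-mass arithmetic
  and are config-selectable for decomposition, not searched in parallel.
- No isotopologue-envelope fitting: a compound must be fully labeled or
  it will not pair.
- Greedy partner claiming can demote a true quartet when two compounds'
  partners genuinely collide within tolerance; the demoted quartet is
  retained in the output with its `conflict` flag for inspection.
- The element alphabet is fixed to CHNOPS; halogenated or metal-containing
  species require extending `ElementBounds` and the mass table.
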