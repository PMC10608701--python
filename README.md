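# isocred

Dual-isotope (¹³C/¹⁵N) credentialing, mass-shift-constrained formula
prediction, and tiered annotation for untargeted LC-MS metabolomics.

## The problem

Untargeted metabolomics peak lists are dominated by features that are not
metabolites — media components, solvent clusters, adducts of contaminants
— and even for genuine metabolites an accurate mass alone rarely pins
down a molecular formula. A *labeled reference* solves both problems at
once: grow a reference organism in four media (unlabeled, U-¹³C, U-¹⁵N,
U-¹³C+¹⁵N) until labeling is complete, and every true metabolite with
*c* carbons and *n* nitrogens appears as a **quartet** of co-eluting
peaks at mass shifts

    +c·Δ¹³C,   +n·Δ¹⁵N,   +c·Δ¹³C + n·Δ¹⁵N
    (Δ¹³C = 1.0033548 Da, Δ¹⁵N = 0.9970349 Da)

Background peaks have no labeled partners and are discarded
(*credentialing*); for the survivors the shifts read (c, n) directly off
the spectrum, collapsing formula ambiguity — typically by one to two
orders of magnitude above 300 Da. `isocred` implements the full chain for
peak tables acquired with ESI and APCI ion sources in both polarities:

1. **peak I/O & filters** — CSV/TSV peak tables, S/N > 5 and scan-range
   filters, reference libraries (TSV + MSP spectra), optional mzML;
2. **quartet matching** — co-elution + ppm windows + intensity-ratio
   bounds, atom-count inference, greedy partner claiming, credentialing;
3. **formula engine** — CHNOPS decomposition with (c, n) fixed, RDBE and
   H/C plausibility filters, hydrogen solved from the mass residual;
4. **annotation** — library matching gated on (c, n) consistency, tiers
   `standard_confirmed` (RT match) > `ms2_matched` (spectral cosine) >
   `putative_formula`;
5. **database building** — merging across ion sources and polarities with
   per-run detection provenance and counts;
6. **synthetic data** — a ground-truthed generator of four-condition
   experiments (mass noise, RT jitter, dropout, decoys) used by the test
   suite and the acceptance script.

See `docs/methods.md` for the model, defaults, and limitations.

## Worked example

```python
from isocred import (SimConfig, sample_library, simulate_quartets,
                     match_quartets, credential, decompose,
                     neutral_mass, recovery_report)

lib = sample_library(5, seed=42)          # 5 synthetic metabolites
runs, truth = simulate_quartets(lib, SimConfig(n_compounds=5, seed=42))

c = runs[("APCI", "negative")]            # one source/polarity run
quartets = match_quartets(c["U"], c["C13"], c["N15"], c["C13N15"])
for q in credential(quartets):
    top = decompose(neutral_mass(q.u), q.c, q.n, tol_ppm=5.0)[0]
    print(f"u_mz={q.u.mz:.5f} rt={q.u.rt:.2f} c={q.c} n={q.n} "
          f"support={q.support} ppm={q.ppm_residual:.2f} top={top.formula}")
```

prints

```
u_mz=494.23302 rt=5.32 c=32 n=1 support=full ppm=2.99 top=C32H33NO4
```

one credentialed quartet: an unlabeled [M−H]⁻ ion at m/z 494.23302
whose ¹³C, ¹⁵N and dual partners were all found (support `full`) within
2.99 ppm at worst, implying 32 carbons and 1 nitrogen — and the formula
engine's top candidate under those constraints, C32H33NO4, is the planted
compound. Compounds whose quartets were degraded by simulated dropout
remain matchable at lower support but are not credentialed.

From the shell, the same chain end to end:

```sh
isocred simulate --out sim/ --seed 42 --n-compounds 200
isocred build-db --input sim/ --library sim/library.tsv \
    --msp sim/library.msp --query-msp sim/queries.msp --out db/
```

which writes per-run quartet and annotation tables, `database.tsv` (one
row per distinct metabolite with its tier and the runs that detected it)
and `summary.tsv` (per-source/polarity counts plus the distinct total).
`isocred --print-config` emits every tunable default as YAML.

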