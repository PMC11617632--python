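# cspfit

Chemical-shift-perturbation (CSP) analysis and dissociation-constant
extraction for protein–ligand NMR titrations, built for methyl-HMQC (or
amide-HSQC) data of the kind used to map nucleotide binding to DEAD-box
helicase RecA domains: a weakly bound nucleotide in fast exchange whose peaks
drift with saturation, and a tightly bound one in slow exchange whose free
and bound peaks trade volume.

## What it computes

**Composite CSP.** Per probe (an Ile/Leu/Val methyl or a backbone amide),
shift changes in the two dimensions are combined as

    Δδ = sqrt(ΔδH² + (s_X·ΔδX)²),    s_C13 = 0.18, s_N15 = 0.15.

Perturbed residues are classified against the 10%-trimmed mean of all
composite CSPs (and trimmed mean + 1 SD), a residue counting as perturbed if
at least one of its methyls crosses the threshold.

**Binding isotherm.** For protein at total concentration [P]_T and ligand at
molar ratio x = [L]_T/[P]_T, exact 1:1 mass action gives the bound fraction

    f(x) = ½[(1 + K_D/[P]_T + x) − sqrt((1 + K_D/[P]_T + x)² − 4x)].

*Fast exchange*: each probe's merged peak obeys Δδ(x) = Δδ_max·f(x); (K_D,
Δδ_max) are fitted per probe by nonlinear least squares.  *Slow exchange*:
f(x) is estimated per probe and point from peak volumes — from the free peak
as 1 − I_P(x)/I_P(0), from the bound peak as I_PL(x)/I_PL(x_max) — with each
route used only when its volume errors pass a threshold, the two averaged
when both survive, and K_D fitted to the combined f(x).  Per-probe K_D
values are aggregated to a mean ± SD with the selection rule recorded in the
report.

**Two-ligand fingerprint comparison.** If two ligands induced identical
bound-state shifts, per-probe CSP magnitudes of one endpoint against the
other would fall on a line with slope equal to the ratio of the two
saturation fractions.  The package fits that line (slope, intercept, R²),
flags magnitude outliers (robust-line residuals beyond a
multiplicity-calibrated MAD cutoff) and direction reversals (negative cosine
between the two s_X-scaled CSP vectors, subject to a noise floor).

**Kinetics.** Exchange-regime classification of k_ex against the
shift-difference timescale Δν, the implied bounds k_off ≪/≫ Δν and
k_on = k_off/K_D, and ATP-turnover rates from 1D integral time series.

**Synthetic data.** Seeded generators emulate fast- and slow-exchange
titrations, paired two-ligand CSP endpoints with programmed outliers and
reversals, and hydrolysis time courses — every analysis stage is testable
against known ground truth.

## Worked example

Simulate a slow-exchange titration (true K_D = 53 µM, 160 µM protein,
ratios 0–16, 5% volume noise) and fit it back:

```bash
$ cspfit simulate --regime slow --kd 53 --protein-conc 160 \
      --n-probes 20 --seed 11 --out adp_sim
$ cspfit fit adp_sim/manifest.yaml --out adp_fit
K_D fit summary — ligand synthetic-slow (slow exchange)
  probes fitted   : 20 (0 skipped)
  probes selected : 20 (rule: all probes)
  mean K_D        : 53.3 µM
  SD K_D          : 10.92 µM
```

The per-probe average recovers the generating K_D (53.3 vs 53 µM); the SD
reflects the 5% multiplicative volume noise propagated through the
volume-ratio estimates.

The same from Python, statsmodels-style — a model built from data whose
`fit()` returns a results object:

```python
from cspfit import SyntheticConfig, SlowExchangeModel, simulate_slow_titration

series = simulate_slow_titration(SyntheticConfig(kd=53, protein_conc=160, seed=11))
results = SlowExchangeModel(series).fit()
print(results.mean_kd, results.sd_kd)   # per-probe aggregate, µM
results.to_report("kd_fits.tsv")        # deterministic TSV report
```

Comparing two ligands sharing a common structural response (B = 0.17 × A)
with 8 programmed magnitude outliers and 5 programmed direction reversals:

```python
import numpy as np
from cspfit import SyntheticConfig, TwoLigandConfig, simulate_two_ligand, CSPComparison

base = SyntheticConfig(n_probes=70, bound_shift_scale=0.05, seed=1)
noise = float(np.hypot(base.shift_noise_sd_h, 0.18 * base.shift_noise_sd_x))
cfg = TwoLigandConfig(base=base, gradient=0.17, n_outliers=8, n_reversals=5,
                      outlier_displacement=10 * noise)
a, b, truth = simulate_two_ligand(cfg)
print(CSPComparison(a, b, ligand_a="ADP", ligand_b="ATP").fit().summary())
```

```
CSP comparison — ATP vs ADP (70 probes, free intercept)
  gradient  : 0.1243
  intercept : 0.005122 ppm
  R²        : 0.244
  magnitude outliers  : V143b, I212, I272, I281, V301a, I320, L323a, L338a
  direction reversals : L160b, L224a, I321, I349
```

The eight flagged outliers are exactly the eight programmed ones.  Four of
the five programmed reversals are flagged; the fifth (L163b) has a reversed
vector whose magnitude sits at the 0.005 ppm noise floor, where a direction
is not measurable and the floor rule correctly withholds the flag.  The
fitted gradient (0.124) sits below the programmed 0.17 because at this
gradient the B-side CSPs are comparable to the shift noise — the same
regression attenuation that afflicts real weak-ligand endpoints.

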