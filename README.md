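# ryrcicr

Quantitative analysis of ryanodine-receptor (RyR) Ca²⁺ sensitivity.

Ryanodine receptors are the Ca²⁺-release channels of the sarcoplasmic
reticulum. They are activated by cytoplasmic Ca²⁺ itself (Ca²⁺-induced Ca²⁺
release, CICR), and small shifts in their Ca²⁺ sensitivity — caused by
caffeine, or by disease mutations in the Ca²⁺- and caffeine-binding sites —
translate into large changes in resting Ca²⁺ leak and in cellular phenotype.
This package implements the quantitative machinery used to characterize such
shifts, for researchers analyzing [³H]ryanodine binding assays, Ca²⁺ imaging
of RyR-expressing cells, and cryo-EM coordinate models of the channel.

## The model

Channel activity measured by [³H]ryanodine binding (which binds only the open
channel) follows a biphasic dependence on free Ca²⁺, modeled as occupancy of a
high-affinity activating site (A-site) and a low-affinity inactivating site
(I-site):

```
A([Ca²⁺]) = A_max · f_A · (1 − f_I)

f_A = [Ca²⁺]^n_A / ([Ca²⁺]^n_A + K_A^n_A)
f_I = [Ca²⁺]^n_I / ([Ca²⁺]^n_I + K_I^n_I)
```

with dissociation constants `K_A`, `K_I` (mol/L) and Hill coefficients `n_A`,
`n_I` held fixed during fitting (one shared pair per mutant panel, chosen by
maximizing the summed R² of the fits; 2.0 and 1.0 are the canonical values).
The readouts are **pCa₅₀ = −log₁₀ K_A** (Ca²⁺ sensitivity), the caffeine
shift **ΔpCa₅₀**, and the extrapolated **resting activity** A(pCa 7) whose
mutant/wild-type ratio quantifies arrhythmogenic leak potential.

## What's in the package

| module | purpose |
| --- | --- |
| `ryrcicr.model_core` | closed-form biphasic model, pCa₅₀, resting-activity fold change |
| `ryrcicr.binding_fit` | Scatchard Bmax analysis, B/Bmax normalization, fixed-Hill curve fitting, ΣR² Hill-coefficient selection, sensitization tables |
| `ryrcicr.buffer_chem` | EGTA/BAPTA free-Ca²⁺ calculator (forward, inverse, pCa ladders) |
| `ryrcicr.trace_analysis` | (F−Fmin)/(Fmax−Fmin) normalization, oscillation detection, ER upper-level envelope, caffeine EC₅₀ dose–response |
| `ryrcicr.structure_compare` | PDB/mmCIF loading, Kabsch superposition, domain displacement, residue contacts, binding-pocket size proxy |
| `ryrcicr.synthetic_data` | seed-deterministic generators for every input the pipeline consumes |
| `ryrcicr.io` / `pipeline` / `cli` | file formats, simulate→fit→summarize orchestration, `ryrcicr` command |

## Worked example

Run the full synthetic pipeline — generate a mutant panel, fit every curve,
summarize sensitization:

```
$ ryrcicr run --seed 5 --out demo
simulate: ok
fit: ok
summarize: ok
$ cat demo/summary.tsv
genotype        pCa50_control  pCa50_caffeine  delta_pCa50  resting_fold_vs_wt  SE_control  R2_control  status
WT              4.74927        5.81818         1.06892      1                   0.0225131   0.984509    ok
W4644A-like     5.61167        5.58934         -0.0223309   54.1592             0.0195686   0.988174    ok
I4925A-like     5.77537        6.77805         1.00268      113.008             0.0170887   0.990547    ok
F3713A-like     4.93509        5.37696         0.441869     1.43736             0.0340077   0.966813    ok
C4192W-like     5.72031        6.7069          0.986585     87.5495             0.0222853   0.983894    ok
```

Reading the table: the wild-type channel has pCa₅₀ ≈ 4.75 and caffeine
left-shifts it by ~1 pCa unit; the W4644A-like genotype is sensitized but
caffeine-blind (ΔpCa₅₀ ≈ 0); the C4192W-like genotype carries an eightfold
K_A shift, which the resting-activity extrapolation amplifies to a ~90-fold
increase in modeled activity at resting (100 nM) Ca²⁺ — the quadratic lever
(K-ratio)^n_A that makes modest sensitivity shifts arrhythmogenic.

Designing the assay buffer (10 mM EGTA, apparent K_d 10⁻⁷ M):

```
$ ryrcicr freeca buffer.json --ladder 8,7,6,5
pCa  free_Ca_M  total_Ca_M   status
8    1e-08      0.000909101  ok
7    1e-07      0.0050001    ok
6    1e-06      0.00909192   ok
5    1e-05      0.00991072   ok
```

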