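# kmeopl

Analysis toolkit for methyllysine-oriented peptide library (Kme-OPL)
profiling of methyllysine "reader" domains and Kme-specific antibodies.

Lysine methylation (Kme0–Kme3 on the side-chain ε-amine) is read by protein
modules — chromo, Tudor, MBT, PHD, TTD domains — whose binding depends on
both the methyl order and the amino acids flanking the methylated lysine.
A Kme-OPL is a degenerate library of seven-mer peptides oriented around a
central methyl-lysine: within each methyl order the library comprises 114
*sets*, each fixing one of 19 residues (cysteine excluded) at one of the six
flanking positions P−3…P+3 while the remaining flanks are an equimolar
degenerate mixture; a *pool* combines all 114 sets of one methyl order.
Screening a GST-tagged reader against pools calls its preferred methyl
order, and screening the 114 sets yields a 6 × 19 matrix of GST-subtracted
fluorescence signals — the reader's binding profile.

This package implements the downstream computation:

- **`kmeopl.library`** — combinatorics of the library: sets, pools,
  degenerate composition, membership of concrete seven-mers.
- **`kmeopl.signal`** — plate fluorescence → GST-subtracted pool results and
  normalized 6 × 19 reader profiles; methyl-order calls; specificity
  histograms separating sequence-specific from promiscuous readers.
- **`kmeopl.lob`** — proteome-wide **Lowest-Bin (LoB) scoring**: every
  lysine-centered seven-mer `x₋₃x₋₂x₋₁ K x₊₁x₊₂x₊₃` in a FASTA proteome is
  scored

  `LoB(x) = min over p ∈ {−3,−2,−1,+1,+2,+3} of S(p, x_p)`

  where `S` is the raw GST-subtracted profile, so one disfavored residue
  vetoes the motif (minimizing false positives); motifs are ranked,
  normalized to the scan maximum, and can be annotated with protein copy
  numbers to weigh detectability against abundant competitors such as
  histones. Optimal and poorest-binding sequences are read off the profile
  by per-position argmax/argmin.
- **`kmeopl.fp`** — fluorescence-polarization validation: mP → anisotropy
  (`A = 2P/(3−P)`), 20-mP anchor scaling, and non-linear least-squares
  fitting of specific binding with Hill slope,
  `A(x) = baseline + (A_max − baseline)·xʰ/(K_dʰ + xʰ)`.
- **`kmeopl.simulate`** — a latent reader model (independent multiplicative
  position weights, per-order multipliers) with closed-form set/pool
  expectations, plus generators for noisy plates, proteomes with planted
  motifs, and FP titrations, so the whole pipeline is testable end to end.

## Worked example

A promiscuous Kme2 reader versus a sequence-specific Kme3 reader that
prefers KAK(Kme3)TGK:

```python
from kmeopl import *

# 1. Promiscuous Kme2 reader: bright pools, high specificity index
promiscuous = uniform_model(preferred_order=2, noise_sd=50.0)
plate = simulate_plate(promiscuous, n_replicates=4, seed=10)
pools = summarize_pools(plate.pools)
print(pools.round(1))
print("preferred methyl order:", call_methyl_order(pools).orders)
h = specificity_histogram(build_profile(plate.set_measurements(2)))
print(f"specificity index: {h.specificity_index:.3f} ({h.label})")

# 2. Sequence-specific Kme3 reader
specific = one_hot_model("KAKKTGK", epsilon=0.05, peak_set_signal=800.0, noise_sd=50.0)
plate3 = simulate_plate(specific, n_replicates=4, seed=11)
print("Kme3 pool signal (specific reader): "
      f"{summarize_pools(plate3.pools).loc[3, 'subtracted']:.0f} RFU")
profile = build_profile(plate3.set_measurements(3))
h3 = specificity_histogram(profile)
print(f"specificity index: {h3.specificity_index:.3f} ({h3.label})")
print("best sequence: ", predict_optimal_sequence(profile).sequence)
print("worst sequence:", predict_worst_sequence(profile).sequence)

# 3. Proteome-wide LoB scan with a planted optimal motif
records, manifest = generate_proteome(n_proteins=100, planted_motifs=["KAKKTGK"], seed=12)
results = score_proteome(profile, records)
print(results.head(3)[["protein_id", "k_position", "window",
                       "lob_score", "norm_score", "rank"]].round(2).to_string(index=False))

# 4. FP validation of the predicted best peptide
best = simulate_fp_titration(0.84, 1.0, 0.1, 0.02, noise_sd=0.002, seed=13)
fit = fit_series(best)
print(f"best-peptide Kd: {fit.kd:.2f} +/- {fit.kd_se:.2f} uM (Hill {fit.hill:.2f})")
```

Output:

```
              reader_mean  gst_mean  subtracted  n    sd
methyl_order
0                   246.8     141.3       105.6  4  58.9
1                   265.4     114.8       150.6  4  41.8
2                  2131.6     132.2      1999.4  4  21.3
3                   250.0     131.9       118.1  4  35.3
preferred methyl order: (2,)
specificity index: 1.000 (promiscuous)
Kme3 pool signal (specific reader): 54 RFU
specificity index: 0.053 (specific)
best sequence:  KAKKTGK
worst sequence: ITNKAMG
 protein_id  k_position  window  lob_score  norm_score  rank
synprot0020         177 KAKKTGK     770.57        1.00   1.0
synprot0030          94 EMTKRHQ      61.99        0.08   2.0
synprot0001         129 LWLKMDF      60.53        0.08   3.0
best-peptide Kd: 0.74 +/- 0.09 uM (Hill 0.99)
```

The promiscuous reader lights up its whole pool (~2,000 RFU subtracted,
specificity index 1.0) while the specific reader, diluted across the
degenerate mixture, gives a dim pool (~54 RFU) yet a sharply specific
profile (index 0.053: 6 of 114 sets above half-maximum). The LoB scan
recovers the planted optimal motif at rank 1 with roughly a 13-fold margin
over the best background seven-mer, and the Hill fit recovers the simulated
peptide's sub-micromolar dissociation constant.

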