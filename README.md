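# histoquant

Label-free relative quantification of combinatorial histone post-translational
modifications (PTMs) from bottom-up LC-MS of propionylated histone peptides,
with deconvolution of co-eluting positional isomers and pulldown-vs-input
enrichment statistics.

## Who this is for

Chromatin proteomics groups that quantify histone acetylation/methylation
states on the standard tryptic backbone peptides (H3 9–17, 18–26, 27–40,
73–83; H4 4–17; the H2A 12–17 variant pair) and compare affinity-pulldown
histones — for example histones crosslinked to a bromodomain protein or an
oncogenic fusion such as BRD4-NUT — against genomic input.

## The model

**Derivatization and mass arithmetic.** Histones are propionylated before and
after trypsin digestion: every peptide N-terminus and every unmodified or
mono-methylated lysine carries a propionyl group (+C3H4O, 56.0262 Da);
acetylated, di- and tri-methylated lysines do not.  Consequently
Kac = Kun − CH2 in mass, and positional isomers with the same PTM multiset
(H3K18ac vs H3K23ac; the four H4 tri-acetyl isoforms) are strictly isobaric.

**Relative abundance.** For each backbone family, the chromatographic peak of
every modified form is integrated (trapezoidal, flat median baseline) and
normalized to the summed area of all forms of that backbone:

    f_i = A_i / Σ_j A_j ,   Σ_i f_i = 1  per sample and backbone.

**Positional-isomer deconvolution.** Co-eluting isobaric isoforms share one
precursor peak; their mixing fractions θ are estimated from the
intensity-weighted average MS/MS across the peak.  With indicator matrix `Z`
(which isoforms produce each discriminating b/y ion) and shared-ion scale
`s`, the estimator solves

    θ̂ = argmin_{θ ≥ 0, Σθ = 1} ‖ I_obs − s·Zθ ‖²

which for two isomers reduces to θ₁ = I₁/(I₁+I₂) over unique-ion intensity
sums.  The class-level abundance is then split as f_isoform = f_class · θ̂.

**Statistics.** Technical variability is bounded by the H2A T16/S16
variant-pair recovery ratio: threshold = 2 × (max deviation of the ratio
from its mean, relative to the mean); a 20% spread yields the 0.4 fold-change
threshold.  Each group is tested with Shapiro–Wilk; pulldown vs input means
are compared with an unpaired two-sample Welch t-test
(Welch–Satterthwaite df; input passed first, so enrichment gives t < 0).
Whole-sample PTM patterns are compared by Pearson r with Fisher-z 95% CIs.

## Worked example

```python
import numpy as np
from histoquant import (default_config, simulate_run, average_spectrum,
                        resolve_isoforms, simulate_replicates,
                        variability_threshold, fold_change_table)
from histoquant import histone_model as hm

cfg = default_config(seed=42)                 # input n=4, pulldowns n=4 / n=2
traces, spectra, truth = simulate_run(cfg)    # one synthetic LC-MS run

# deconvolve the H3 18-26 mono-acetyl peak (K18ac vs K23ac co-elute)
cid = "H3_18-26:ac"
cls = [s for s in spectra if s.precursor_id == cid]
trace = {t.trace_id: t for t in traces}[cid]
avg = average_spectrum(cls, weights=[trace.intensity_at(s.rt_min) for s in cls])
iso = hm.group_isobaric(hm.enumerate_forms("H3_18-26"))[cid]
est = resolve_isoforms(avg, iso)
print(est.isoform_ids, np.round(est.theta, 4))
# ('H3_18-26:K18ac', 'H3_18-26:K23ac') [0.1429 0.8571]

table, _ = simulate_replicates(cfg)           # replicate abundance table
thr = variability_threshold(table)
enr = fold_change_table(table, [("input", "BRD4short")], threshold=thr.threshold)
row = enr[enr["form"] == "H3_18-26:K18acK23ac"].iloc[0]
print(round(row.fold_change, 2), round(row.t, 2), round(row.df, 2), f"{row.p:.2e}")
# 3.12 -10.44 3.38 1.09e-03
```

The mixing fractions (0.143, 0.857) are the latent truth of the generator
(5% of the family is K18ac, 30% K23ac → θ = 0.05/0.35, 0.30/0.35): the
averaged-MS/MS estimator recovers them exactly at zero noise.  The
enrichment row says the di-acetylated form is 3.1-fold higher in the
pulldown than input, with Welch t = −10.44 (negative = enriched in
pulldown), df = 3.38, p ≈ 1.1e−3, and exceeds the technical-variability
threshold.

## Command line

```bash
histoquant run --config examples/demo.yaml        # simulate → quantify → stats → report
histoquant simulate --outdir results --seed 7     # individual stages
```

Outputs are plain text (`xic_*.tsv`, `ms2_*.tsv`, `abundance.csv`,
`enrichment.csv`, `correlations.csv`) plus a `manifest.json` with the seed,
config hash and SHA-256 of every artifact; the same seed reproduces every
file byte-for-byte.

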