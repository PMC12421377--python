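# pasbind

Quantitative tools for studying how the mammalian polyadenylation machinery
recognizes polyadenylation-signal (PAS) hexamers. The canonical signal
AAUAAA and its second-most-common variant AUUAAA account for ~75% of
annotated human poly(A) signals; the rest are rare (<3%) single-nucleotide
variants whose binding to the mammalian polyadenylation specificity factor
(mPSF) is much weaker. `pasbind` implements the two quantitative pillars of
that picture for experimentalists and annotation analysts:

1. **Binding affinity** — exact one-site equilibrium models for direct and
   competition fluorescence-anisotropy assays, and nonlinear least-squares
   Kd estimation from replicated titration curves, including residual
   bootstrap uncertainties and identifiability flags.
2. **Annotation frequency** — a census of annotated poly(A)-signal hexamers
   in genome annotation (GFF3 + FASTA, or GenBank flat files), stratified by
   each signal's position among its transcript's signals, plus the log–log
   frequency-versus-affinity correlation that ties the two together.

A synthetic-data layer generates both kinds of input — simulated titrations
at the standard assay designs and annotated genome corpora with planted
signals — so the entire pipeline is testable without any download.

## The models

**Direct assay.** A receptor R (mPSF) is titrated against a fixed
fluorescent probe L. With totals R_t, L_t and dissociation constant K_d,
the bound probe fraction follows the depletion-aware quadratic isotherm

    FB = ((R_t + L_t + K_d) − sqrt((R_t + L_t + K_d)² − 4 R_t L_t)) / (2 L_t),

which reduces to the hyperbola R_t/(R_t + K_d) as L_t → 0.

**Competition assay.** An unlabeled competitor I (totals I_t, constant
K_d2) displaces the probe (K_d1). Eliminating the complexes leaves a cubic
in the free receptor concentration R,

    R³ + aR² + bR + c = 0,
    a = K_d1 + K_d2 + L_t + I_t − R_t,
    b = K_d2 (L_t − R_t) + K_d1 (I_t − R_t) + K_d1 K_d2,
    c = −K_d1 K_d2 R_t,

whose unique root in [0, R_t] is taken in trigonometric closed form and
verified against a brute-force bisection oracle to ≤ 1e−9 relative. The
observed anisotropy is the intensity-weighted mix
r = (Q·FB·r_b + (1−FB)·r_f) / (Q·FB + (1−FB)) with Q = 1 by default.
Fits run over (log10 K_d, r_f, r_b) with multi-start Gauss–Newton.

## Worked example

```bash
python examples/fit_titration_curves.py
```

prints (seed 42):

```
direct fit:      Kd =    19.9 nM (+/- 1.3), r_free = 0.050, r_bound = 0.203, converged = True
competition fit: Kd =   494.4 nM (+/- 37.9), flags = none
truncated range: Kd =    4349 nM, flags = ['lower_bound_only']
```

The direct fit recovers the probe Kd (true value 19 nM) from a noisy
triplicate receptor titration; the competition fit recovers an unlabeled
oligo's Kd (true 520 nM) given that probe Kd; the third fit shows the
failure mode of an under-ranged competitor series — the signal never drops
below 90% of its upper plateau, so only a lower bound on the Kd is
claimed, and the result is flagged rather than reported as a converged
estimate.

The other examples cover the equilibrium arithmetic
(`equilibrium_basics.py`), the corpus generator and stratified census
(`census_synthetic_corpus.py`), and the hexamer taxonomy, fold-change
ratios and log–log correlation on the packaged 18-hexamer reference panel
(`frequency_affinity_correlation.py`), which ends with

```
log-log regression over 16 hexamers with measured Kd:
  Pearson r = -0.833, slope = -0.671
  Spearman rho = -0.694
```

— the inverse frequency–affinity relationship: rarer signals bind mPSF more
weakly.

A thin CLI mirrors the library (`pasbind simulate-assay | simulate-corpus |
fit | census | report`); run `pasbind --help` for the options.

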