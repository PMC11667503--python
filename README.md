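# tmtpipe

QC, harmonization and diversity analysis for multi-site TMT proteomic
cohorts.

Large brain-proteome studies quantify ~10,000 proteins across ~1,000 donors
by multiplexing samples into 16-channel TMT batches processed at several
contributing sites. Before any biology can be read out, batch effects —
which can explain >90% of raw per-protein variance — must be removed, failed
samples dropped, and the cleaned matrix interrogated for what donor traits
(sex, race, AD diagnosis, age) actually explain. `tmtpipe` implements that
stack as a tested, reusable library plus CLI:

- **QC** (`tmtpipe.qc`): strict 50% missingness filter, sample-loading
  normalization, log2 transform, iterative PCA outlier removal (|score −
  mean| > 4 SD on PC1/PC2, repeated until a fixed point), and per-protein
  batch regression (residuals + grand mean).
- **Harmonization** (`tmtpipe.harmonize`): two-way median polish of log2
  ratios to each batch's pooled internal standard (GIS), and bootstrap
  age/sex residualization.
- **Variance partitioning** (`tmtpipe.varpart`): per protein, REML variance
  components for y = μ + sex + race + diagnosis [+ batch] + ε, reported as
  fractions of total variance; fixed-effects SS mode as cross-check.
- **Association** (`tmtpipe.association`): biweight midcorrelation (bicor,
  c = 9) screens against anchor proteins (APP/MAPT-style), one-way ANOVA +
  Tukey HSD across the four race×diagnosis groups, DAP group classification
  (shared up/down vs race-specific), cross-race fold-change concordance,
  volcano tables, stage trends.
- **Targeted quantification** (`tmtpipe.targeted`): APOE ε4 carrier calls
  from the allele-specific peptide LGADMEDVR (exact 1-D 2-means, midpoint
  threshold) with genotype concordance reporting; peptide-to-domain roll-up
  for tau (N-terminal 1–126, PRD 127–242, MTBR 243–369, C-terminal 370–441
  on P10636-8) and C-terminus-defined Aβ40/Aβ42 species.
- **Synthetic cohorts** (`tmtpipe.simulate`): a multi-site TMT cohort
  generator with recorded ground truth — site-structured batch effects,
  sex/race/AD effect proteins, planted whole-sample outliers, MNAR+MCAR
  missingness, GIS channels, and an APOE ε4 peptide with a planted
  genotype-record error rate — so every stage is testable without
  restricted data.

See `docs/methods.md` for the models, estimators and design choices.

## Worked example

```python
import tmtpipe as tp

# a 1000-protein, 600-donor cohort in 40 TMT batches across 4 sites
dataset, truth = tp.simulate_cohort(tp.SimConfig(seed=42))

clean, report = tp.run_qc(dataset)
print(report.outlier_ids, truth.outlier_ids)
# ['S0088', 'S0113', 'S0139'] ['S0088', 'S0113', 'S0139']

from tmtpipe.varpart import VarianceModelSpec, fit_variance_partition
spec = VarianceModelSpec(include_batch=True)
print({k: round(v, 4) for k, v in fit_variance_partition(clean, spec).medians().items()})
# {'batch': 0.0, 'sex': 0.0, 'race': 0.0, 'diagnosis': 0.0, 'residual': 0.9932}
# (batch medians ~0.91 on the *pre*-regression matrix)

from tmtpipe.association import anova_tukey, fc_concordance
result = anova_tukey(clean)            # 4-group ANOVA + Tukey, race x diagnosis
r, n, scatter = fc_concordance(result)
print(round(r, 3), n)
# 0.869 220
```

The QC report lists exactly the three planted whole-sample outliers; after
batch regression the median batch variance fraction is indistinguishable
from zero while the residual dominates; and the AD fold changes estimated
separately in White and African American donors correlate at ~0.87 — the
generator plants them with correlation 0.9, so the concordance statistic
recovers the planted value up to selection and estimation noise.

The same pipeline is scriptable from the shell:

```bash
tmtpipe simulate --seed 42 --out-dir sim/
tmtpipe qc --matrix sim/matrix.tsv --traits sim/traits.tsv --out-dir qc/
tmtpipe diff --matrix qc/matrix_qc.tsv --traits qc/traits_qc.tsv --out-dir diff/
tmtpipe proteotype --matrix qc/matrix_qc.tsv --traits qc/traits_qc.tsv --out-dir pt/
```

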