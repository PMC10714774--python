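# oralmicro

Longitudinal analysis of multi-site **oral microbiota dynamics in
allogeneic hematopoietic stem-cell transplant (allo-HSCT) recipients**.

Allo-HSCT is one of the most drastic perturbations a human microbiome can
experience: conditioning chemotherapy, aplasia, broad-spectrum antibiotics
and immune reconstitution compress years of ecological change into weeks.
This package implements the processed-data analysis chain for cohorts
sampled at three oral sites — gingival crevicular fluid (GCF), oral mucosa
(OM) and supragingival biofilm (SB) — at five timepoints anchored to the
stem-cell infusion: preconditioning (P), aplasia (A), engraftment (E), and
30/75 days after engraftment (E30/E75). It is aimed at microbiome
bioinformaticians who have genus- or ASV-level count tables, a rooted
phylogeny, antibiotic charts and clinical outcomes, and want the full chain
from depth normalization to competing-risks survival association — with a
synthetic cohort generator supplying ground truth so everything is testable
without patient data.

## What it computes

* **Depth filtering and SRS normalization.** Samples below a minimum
  sequencing depth (default 3,000 reads) are excluded with a report;
  libraries are then scaled to a common depth `C_min` by *scaling with
  ranked subsampling*: counts scaled by `C_min/total`, integer parts kept,
  remaining units assigned by descending fractional part (seeded
  tie-breaking).
* **Alpha diversity and ecological indices.** Gini-Simpson diversity
  `D = 1 − Σ pᵢ²`, summarized per patient-site as
  *resistance* `D_E/D_P`, *resilience* `(D_E30 − D_E)/(day_E30 − day_E)`
  and *stability* `D_E30/D_P`.
* **Weighted UniFrac** `W(p,q) = Σ_b l_b |P_b − Q_b|` (normalized to [0,1]
  by default), PCoA ordination, seeded one-way **PERMANOVA**
  (`pseudo-F = (SS_B/(k−1))/(SS_W/(n−k))`, add-one permutation p),
  distance-to-centroid via the Gower identity, all-against-all dispersion,
  minimum between-site distances, per-day compositional shift rates, and
  compositional stability `1 − d(P, E30)`.
* **Blooms and antibiotics.** A *bloom* is a taxon rising from <1% relative
  abundance at P to ≥30% at a later timepoint (a maximal run of dominant
  timepoints is one event). Antibiotic exposure is summarized as LOT
  (distinct days under any therapy) and DOT (agent-days) over the P→E30
  window, prophylaxis excluded; classes used by ≥20% of patients are tested
  against blooming with Fisher's exact test (conditional-MLE odds ratio,
  Bonferroni adjustment), plus Mann-Whitney and chi-square comparisons.
* **Recovery and outcomes.** A patient-site *recovers* when
  `d(P, E30) < 0.5` on the bounded UniFrac scale. Recovery is associated
  with survival through landmark Cox proportional-hazards fits (Efron
  ties) and **Fine-Gray** subdistribution-hazard fits for competing risks,
  with univariate-screened multivariate adjustment, Kaplan-Meier and
  Aalen-Johansen curves.

## Worked example

```python
import oralmicro as om

cfg = om.CohortConfig(n_patients=30, seed=1)     # study-sized cohort
bundle = om.generate_cohort(cfg)

counts, report = om.filter_min_depth(bundle.counts, min_reads=3000)
sub = bundle.meta[bundle.meta.site == "OM"]
dm = om.unifrac_distance_matrix(counts.subset_samples(sub.sample_id), bundle.tree)

calls = om.classify_recovery(dm, sub)
calls = calls[calls.evaluable]
merged = bundle.outcomes.merge(calls[["patient", "recovered"]], on="patient")
merged["recovered"] = merged["recovered"].astype(bool).astype(int)

fit = om.cox_univariate(merged, "recovered", landmark_days=44.0)
print(f"OM recovery: HR={fit.hr:.2f} ({fit.ci_low:.2f}-{fit.ci_high:.2f}), p={fit.p:.3f}")
```

Output (seed 1):

```
OM recovery: HR=0.14 (0.03-0.70), p=0.017
```

i.e. patients who regained their preconditioning oral-mucosa composition by
E30 carry roughly one seventh the death hazard of non-recoverers in this
synthetic cohort (in which true non-recovery multiplies the hazard by 5),
with the Wald 95% CI excluding 1.

The same pipeline is scriptable from the shell:

```bash
oralmicro simulate --seed 1 --outdir cohort/
oralmicro validate --counts cohort/counts.tsv --metadata cohort/metadata.csv
oralmicro blooms --counts cohort/counts.tsv --metadata cohort/metadata.csv --out blooms.tsv
```

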