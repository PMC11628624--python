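# notchsig

Quantitative analytics for NOTCH-pathway activity in triple-negative breast
cancer (TNBC) cohorts: gene-signature curation and patient scoring,
survival comparison, ChIP-seq summit co-localization, motif co-occurrence,
and drug-screen synergy scoring — with synthetic-data generators so every
stage can be exercised and validated without any external downloads.

Intended for computational biologists who want the bespoke statistics of a
NOTCH/SOX2 plasticity analysis as tested, reusable library functions
rather than one-off scripts.

## What it computes

**Signature scoring and stratification.** A signature score for patient
*s* counts, over the signature genes *g* present in the cohort matrix, the
HIGH calls

&nbsp;&nbsp;score(s) = Σ_g 1[ x_gs > median_s′(x_gs′) ]

where medians are taken within the scored cohort (HIGH is strictly above
the median; even *n* uses the midpoint of the central order statistics).
Cohorts are then cut into three equal-sized tertiles
(LOW / INT / HIGH) by ascending score with deterministic sample-ID
tie-breaks; single genes (e.g. *SOX2*) are dichotomized by the bottom/top
⌊n/3⌋ of expression. The packaged `TNBC_NOTCH_77` signature (77 genes,
*ACTBL2* … *ZNF750*) ships as data.

**Survival.** Follow-up is capped at 120 months (later times censored at
the cap), survival is estimated by the Kaplan–Meier product-limit
estimator, and groups are compared with the k-sample log-rank test: at
each distinct event time the expected events per group come from the
hypergeometric model, giving χ² = (O−E)ᵀV⁻¹(O−E) with k−1 degrees of
freedom. Both are implemented from first principles and validated against
brute-force oracles and `lifelines`.

**Peak co-localization.** Two ChIP-seq peaks co-localize when their
single-bp summits lie strictly closer than 500 bp on the same chromosome.
Enrichment over positions resampled uniformly from enhancer regions is
tested with the two-sided Fisher exact test (probability-mass definition,
verified exhaustively against hypergeometric enumeration). A minimal PWM
scanner (JASPAR counts → log-odds with background-distributed pseudocount
0.8; threshold as a fraction of the maximum attainable score) supports
motif co-occurrence within co-localized peak pairs.

**Drug screens.** Z′-factor plate QC, four-parameter logistic (4PL)
dose–response fits with a strict Hill-slope window (0.5 < h < 5), and
highest-single-agent (HSA) synergy: per combination cell the excess
inhibition over max(monotherapy A, monotherapy B), averaged over all
combination cells, in percentage points.

## Worked example

```python
from notchsig import *

sig = load_packaged_signature("TNBC_NOTCH_77")        # 77 genes
cfg = CohortSimConfig(n_samples=300, active_fraction=1/3, effect=1.5,
                      hazard_ratio=2.5, censoring_fraction=0.3, seed=42)
expr, clinical, truth = simulate_cohort(cfg, sig)

sv = signature_score(expr, sig)                       # coverage 1.0
groups = stratify_equal_groups(sv)                    # 100 LOW / 100 INT / 100 HIGH

merged = clinical.assign(group=clinical["sample"].map(groups.labels))
merged = merged[merged["group"].isin(["LOW", "HIGH"])]
res = logrank_test(cap_followup(merged, cap=120.0))
print(f"chi2={res.statistic:.2f}, df={res.df}, p={res.p_value:.2e}")
```

prints

```
chi2=20.73, df=1, p=5.30e-06
```

The simulated cohort plants one third of samples as signature-active
(each signature gene shifted up 1.5 log2 units) with a proportional
hazard ratio of 2.5; the pipeline recovers every planted-active sample in
the HIGH tertile and the log-rank test detects the survival split between
the HIGH and LOW tertiles at p ≈ 5×10⁻⁶.

The same objects drive the shell interface, e.g.:

```sh
notchsig simulate cohort --seed 42 -o sim/
notchsig score --expr sim/expression.tsv -o sim/scores.tsv
notchsig stratify --scores sim/scores.tsv -o sim/labels.tsv
notchsig survival --clinical sim/clinical.tsv --groups sim/labels.tsv -o sim/km.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — cohort
simulation → scoring → tertile stratification → capped log-rank; peak-pair
simulation → co-localization → resampled background → Fisher enrichment;
4PL fitting and HSA scoring on a planted dose matrix — and writes its JSON
summary to the given path:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/notchsig/signatures.py` — DE-table thresholding, set-algebra curation, packaged signature
- `src/notchsig/stratify.py` — median dichotomization, scoring, tertiles, cross-stratification, NOTCH alteration calls
- `src/notchsig/survival.py` — follow-up capping, Kaplan–Meier, log-rank
- `src/notchsig/peaks.py` — summit distances, co-localization, background resampling, Fisher test
- `src/notchsig/motifs.py` — PWM construction, window scanner, pair co-occurrence
- `src/notchsig/drug.py` — Z′, 4PL, Hill filter, HSA
- `src/notchsig/simulate.py` — synthetic cohort / peak / dose-matrix generators, tumor-volume formula
- `src/notchsig/io.py`, `src/notchsig/cli.py` — format readers/writers and the `notchsig` CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
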