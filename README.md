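# corsistudy

A computerized **Corsi block-tapping test (CBT)** — the classic visuospatial
working-memory span task — together with the full statistical pipeline used
to compare musicians who read music with non-musicians, including the
analysis of how accurately each group judges its own visuospatial ability
(*metacompetence*).

The package is aimed at researchers in cognitive psychology / psychometrics
who want to (a) administer and score CBT sessions with partial credit,
(b) simulate realistic cohorts of respondents to validate the inferential
machinery, and (c) run the complete group-comparison analysis (ANCOVA with
sex and age covariates, assumption checks, correlations, self-assessment
contingency analysis) from plain data files.

## The task and its score

Sequences of blocks light up on a 10-block board (20 × 15 cm window, 1 s
highlight, 0.5 s inter-block interval). Sequences start at two blocks and
grow by one every three trials; the participant advances only by
reproducing at least one of the three sequences perfectly, and the session
ends at the first failed level. Each trial earns one *item credit* per
block recalled in its correct serial position. With `L` the highest (last)
level administered and `avLevelScore` the mean item credit over the trials
at that level, the session score is

```
FinalResult = L − 1 + avLevelScore / L        ∈ [L − 1, L]
```

Worked example: failing level 3 with item credits (2, 2, 1) gives
`avLevelScore = (2+2+1)/3 = 1.67` and `FinalResult = 3 − 1 + 1.67/3 = 2.56`.

Synthetic respondents carry a latent span `s` and recall each item of a
length-`k` sequence independently with probability
`(1 − lapse) · logistic((s − k)/τ)`; latent spans follow a linear model
over group, sex and age, and self-assessment is a noisy read-out of one's
own span. The shipped defaults are calibrated so simulated group score
distributions match the study conditions (musicians ≈ 7.04 ± 0.78,
non-musicians ≈ 6.30 ± 1.10, a ≈ 0.7-point male advantage, no age effect).

## Worked example

```sh
$ python analysis/01_simulate_study.py
wrote 60 participants to results/study/ (seed 20240)
group score summary:
              mean   std  count
group
musician      6.99  0.79     31
non_musician  6.21  1.02     29

$ python analysis/02_analyze_study.py
analyzed 51 participants (9 excluded as normal/unable)
ANCOVA group term: F(1,47) = 6.09, p = 0.017, eta_p^2 = 0.115
  claim-good cell musician|good-good: 54.84%
  ...
```

The first script simulates one study cohort (31 musicians, 29
non-musicians) and writes `participants.csv`, `sessions.jsonl` and
`scores.csv`. The second joins and analyzes them: participants who
answered "normal"/"unable" at the self-assessment interview are excluded,
the ANCOVA compares groups controlling sex and age (here: a significant
musician advantage with partial η² ≈ 0.12), and the claim-good cells show
the share of the claim-good subsample in each group × performance cell
(performance "good" = score ≥ 7). The remaining drivers check generator
calibration at n = 10 000/group (`03`), estimate the ANCOVA type-I error
and power over replicate studies (`04`), and quantify the metacompetence
asymmetry — musicians' claim-good accuracy beats non-musicians' in ~96% of
replicates (`05`).

The same pipeline is scriptable via a CLI:

```sh
corsistudy simulate --seed 11 --out results/study
corsistudy score results/study/sessions.jsonl --out rescored.csv
corsistudy analyze --scores results/study/scores.csv \
    --participants results/study/participants.csv --out results/analysis
corsistudy power --seed 2 --replicates 200 --out power.csv
corsistudy report results/analysis/report.json
```

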