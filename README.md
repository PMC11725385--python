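# symdiv

Symbiont community analysis for coral early life stages under heat
stress: DIV-profile collapsing of ITS2 amplicon variant tables, alpha and
beta diversity with permutation inference, and Kaplan-Meier survival —
packaged with a synthetic-data generator that emulates the study
structure so the whole pipeline is testable end to end.

## The problem

Corals host dinoflagellate symbionts (Symbiodiniaceae) whose community
composition can shift under heat stress. The ITS2 marker used to profile
these communities is multi-copy: one symbiont genome contributes several
distinct sequence variants, which co-occur across samples as a "DIV
profile" (e.g. the nested *Cladocopium* family `C15`, `C15-C15dq`,
`C15-C15dq-C15dr`, `C15-C15dq-C15dr-C_1365`). Computing diversity on raw
variants over-counts taxa, while standard profile callers discard rare
background sequences (≤ 200 reads) — precisely the taxa expected to
expand under stress in a time series. `symdiv` implements the hybrid
overlay that fixes both: per sample, the member variants of its dominant
DIV profile are collapsed into one column (counts conserved exactly)
while every other variant, however rare, is retained as its own column
and merely *labelled* background.

On the collapsed table the package computes Shannon diversity (mapped to
Pielou evenness for beta regression with permutation-calibrated pairwise
contrasts), Bray-Curtis dissimilarities, NMDS (Kruskal stress-1),
PERMANOVA, ANOSIM and a betadisper-style dispersion test; survival of
interval-monitored larvae and juveniles is analysed with the
Kaplan-Meier estimator and the log-rank test. The simulated study
reproduces the system's qualitative biology: larvae under heat show an
expanded background community (higher alpha diversity, shifted beta
diversity) and die with a ~57 d median, juveniles keep their community
fixed but die faster (~20 d median).

## Worked example

The numbered drivers under `analysis/` run the study end to end and
write tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_collapse.py
python analysis/03_diversity.py
python analysis/04_survival.py
```

With seed 1 this prints (abridged):

```
dominant profiles: {'C15-C15dq-C15dr-C_1365': 78, 'C15-C15dq-C15dr': 2}
count conservation: exact
co-occurrence recovery of planted family: yes
juvenile: mean Shannon ambient=0.143 heat=0.187, contrast p_adj=0.13
larva:    mean Shannon ambient=0.166 heat=1.041, contrast p_adj=0.005
larva:    permanova statistic=8.417 p=0.001
larva:    anosim statistic=0.253 p=0.001
juvenile: permanova statistic=5.733 p=0.015
juvenile/heat: n=60, median not reached, end-of-monitoring survival 0.60
juvenile: log-rank heat vs ambient chi2=12.0, p=0.000534
larva:    log-rank heat vs ambient chi2=36.8, p=1.31e-09
```

Reading this: nearly all samples are dominated by the planted four-member
C15 profile, and collapsing conserved every read. The larval heat group's
mean Shannon diversity jumps from 0.17 to 1.04 nats (background genera
expanding under heat) with a significant evenness contrast and clear
community separation (PERMANOVA/ANOSIM p = 0.001), while the juvenile
contrast stays null (p_adj = 0.13) as designed. The juvenile PERMANOVA
p = 0.015 is a false positive at this particular seed — juveniles are
generated with *no* treatment effect, and the suite separately verifies
the test's type-I error is calibrated (≈0.04–0.05 over 500 null
replicates). Survival medians are "not reached" because the default
monitoring windows end right where heat survival hits ~50%, as in the
real experiments; the log-rank tests nonetheless separate the treatments
decisively. A `symdiv` console script offers the same stages as
subcommands (`symdiv all --seed 1 --out run/`).

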