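# metallomap

Proteome-wide prediction of metalloproteins from native chromatographic
fractionation data.

## The problem

A third or so of all proteins need a metal partner, but predicting *which*
metal a protein binds from sequence alone is unreliable. An experimental
alternative fractionates native biomass over multiple chromatography steps
and measures every fraction twice: ICP-MS quantifies metal concentrations,
and MS/MS identifies the proteins present. A protein that repeatedly
co-elutes with a metal's concentration peaks — across thousands of
fractions and many separations — is a strong metalloprotein candidate,
even if it was never purified to homogeneity.

`metallomap` is for analysts of such campaigns: it turns the raw
(fraction × metal × replicate) and (fraction × protein × peptide-count)
tables into scored, filtered, clustered metalloprotein predictions, with
per-metal estimates of how many distinct metalloproteins the data demand.

## The method

Peptide counts are reduced to Boolean presence. Per metal, contiguous runs
of ≥ 2 fractions whose concentrations stand well above the surrounding
baseline in every ICP-MS replicate are *metal peaks* (curated peak tables
are the primary path; a fold-over-local-median detector formalizes the
rule). For protein *p_i* and metal *m_j*, with *f* fractions in the
analysis universe, *f_mj* of them inside peaks of *m_j*, *f_pi* containing
*p_i*, and *f_pi,mj* in the intersection, the **Global Metal Protein
Association (GMPA)** score is the hypergeometric upper tail

    G(p_i, m_j) = Σ_{n = f_pi,mj}^{min(f_pi, f_mj)}
                  C(f_mj, n) · C(f − f_mj, f_pi − n) / C(f, f_pi)
                = P(X ≥ f_pi,mj),   X ~ Hypergeom(f, f_mj, f_pi)

— the chance of at least the observed overlap if the protein's fractions
were placed uniformly at random. Because the score depends strongly on
occurrence count, an exponential regression `score = exp(a + b·occ)` is
fit per metal in log space and scaled into a *significance curve*
`exp(a + c·b·occ)`, with the exponent ratio *c* anchored so every known
metalloprotein of the metal (seen in ≥ 10 fractions) stays below the
curve; metals without references take the mean ratio of the anchored
metals. Significant proteins are clustered by fraction co-occurrence
(Euclidean distance on presence vectors, Ward linkage, dynamic hybrid tree
cut); each cluster should contain at least one distinct metalloprotein, so
the cluster count estimates the metal's metalloprotein count, and a greedy
set cover of the metal's peaks provides the matching lower bound. An
independent InterPro keyword classifier (IPM) predicts metal-associated
domains from annotation text with per-metal regex patterns and manual
curation scores.

A synthetic-data generator plants metal peaks and metalloproteins with
known ground truth, so the entire pipeline is testable offline.

## Worked example

Simulate a default experiment (8 separations × 60 fractions, 10 metals,
5 planted metalloproteins per metal plus 300 background proteins) and run
the full pipeline, using the planted truth as the known-metalloprotein
reference list:

```sh
metallomap simulate --seed 11 --outdir demo/data
cat > demo/config.yaml <<EOF
fractions: demo/data/fractions.tsv
metals: demo/data/metals.tsv
observations: demo/data/observations.tsv
peaks: demo/data/peaks.tsv
references: demo/data/truth.tsv
outdir: demo/out
EOF
metallomap run --config demo/config.yaml
```

The run logs one line per stage:

```
INFO metallomap: load: 480 fractions, 9600 metal measurements, 5351 observation rows
INFO metallomap: filter: min_peptides=2, proteins 350 -> 335
INFO metallomap: presence: 335 proteins x 480 fractions
INFO metallomap: peaks: loaded curated regions for 10 metals
INFO metallomap: gmpa: 3350 protein-metal scores over f=480 fractions
INFO metallomap: significance: Co=5, Fe=5, Mn=5, Mo=5, Ni=5, Pb=5, U=5, V=5, W=5, Zn=5
INFO metallomap: clustering/cover: Co:1cl/1cov, Fe:1cl/1cov, ... Zn:1cl/1cov
```

15 of 350 proteins are dropped by the two-peptide identification filter.
`demo/out/gmpa_scores.tsv` holds the quadruple and score per pair; a
planted Ni protein seen in 22 fractions, 13 of them inside Ni peaks of a
480-fraction universe with 15 Ni-peak fractions, scores

```
protein_id  metal  f    f_m  f_p  f_pm  score            ln_score
MP_Ni_02    Ni     480  15   22   13    5.146959455e-18  -39.80812553
```

— co-elution that extreme cannot be chance, while background proteins with
no peak overlap score 1. `demo/out/summary.tsv` gives the per-metal
balance sheet (here for Co: all 5 known subunits observed and significant,
forming 1 cluster, with a greedy cover of 1 protein explaining all peaks
and none uncovered):

```
metal  known_subunits_total  known_observed  known_meeting_significance  proteins_clustered  clusters_total  clusters_with_known  cover_size  uncovered_peaks
Co     5                     5               5                           5                   1               1                    1           0
```

All five planted proteins per metal pass their metal's significance curve,
and they form exactly one cluster — matching the single planted co-elution
group per metal.

Every stage is also available separately (`simulate`, `validate`,
`detect-peaks`, `score`, `curves`, `ipm`, `run`); see
`metallomap --help`.

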