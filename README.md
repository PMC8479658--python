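# hicdci

Differential chromatin interaction profiling from Hi-C contact maps,
with transcriptional regulator (TR) inference from public ChIP-seq
binding compendia.

## The problem

Chromatin architecture is dynamic — across differentiation, under
perturbation, in disease — and transcriptional regulators drive much of
that dynamics. But Hi-C resolves contacts at 10⁴–10⁵ bp while TR
binding happens at 10¹–10² bp, so regulator activity cannot be read
off a contact map directly. `hicdci` is for genomics researchers who
have Hi-C (or similar 3C-derived) maps from two biological states and
want a ranked list of the regulators most associated with the observed
interaction changes, without running any new experiments.

## Method

**1. Differential chromatin interaction (DCI) profile.** Raw
intra-chromosomal counts from each condition (with optional
replicates) are distance-normalized per chromosome: each count c_ij is
divided by the mean count over all pairs at distance |i−j|, removing
the dominant distance decay and any scalar depth difference. For every
bin *i*, its *contact score array* collects the normalized contacts
with flanking bins within ±D (default D = 200 kb). With m control and
n treatment replicates, each of the m×n (control, treatment) array
pairs is compared by a paired t-test; the p-values are combined by
Fisher's method (χ² = −2Σln p, 2mn df), giving the signed per-bin
score

&nbsp;&nbsp;&nbsp;&nbsp;S_i = sign(Σ t) · (−log₁₀ p_Fisher),

positive for interactions gained in treatment.

**2. TR inference.** The profile is mapped onto a catalog of candidate
cis-regulatory elements (each CRE inherits the score of the bin
containing its midpoint). Every binding dataset in the compendium is
scored by the Mann–Whitney AUROC of its bound CREs against the
score-ranked CRE list; per TR, a Wilcoxon rank-sum (TR's AUROCs vs the
rest), a z-score and the max AUROC are each converted to rank
quantiles r ∈ (0,1], and the rank sum s = r_w + r_z + r_m is referred
to the Irwin–Hall distribution (sum of three uniforms, lower tail) for
the final p-value. Flipping the profile's sign yields the
decreased-interaction ranking, so every run reports two TR tables.

Inputs: HiC-Pro triplet matrices, `.cool` stores, or Juicer `.hic`
files (the latter via the optional `hic-straw` package); a BED CRE
catalog; a TSV binding compendium. Full model details, parameter
defaults and limitations are in [docs/methods.md](docs/methods.md).

## Worked example

The package ships a generator that builds complete synthetic inputs
with known ground truth: distance-decaying Poisson contact maps with a
gained 200 kb block per chromosome (fold change 3 in treatment), a toy
CRE catalog, and a 50-TR binding compendium in which one causal TR
binds 10× more densely inside the gained blocks.

```python
from hicdci import (SimulationConfig, simulate_contact_maps, simulate_cre_catalog,
                    simulate_compendium, compute_dci_profile, map_profile_to_cres, rank_trs)

cfg = SimulationConfig(seed=1)                      # 2 chroms x 400 bins at 5 kb
treatment = simulate_contact_maps(cfg, "treatment") # gained 200 kb block per chrom
control = simulate_contact_maps(cfg, "control")

profile = compute_dci_profile(treatment, control, D=200_000)
print("scored bins:", int((~profile.no_data).sum()))
print("top-scoring bin:", profile.to_frame().nlargest(1, "S").to_string(index=False))

catalog = simulate_cre_catalog(cfg)
compendium = simulate_compendium(cfg, catalog)
cre_profile = map_profile_to_cres(profile, catalog)
table = rank_trs(cre_profile, compendium, "increase").table
print(table.head(3).to_string(index=False))
```

Output:

```
scored bins: 800
top-scoring bin: chrom  start    end         S            p  sign  n_tests  no_data
 chr2 465000 470000 35.198877 6.325903e-36     1        4        0
  tr_name  max_auc  wilcoxon_stat  wilcoxon_p  z_score  rank_sum  irwin_hall_p  rank
TR_causal 0.737760          196.0    0.000202 5.187203      0.06      0.000036     1
    TR003 0.575123          130.0    0.233535 0.674186      0.34      0.006551     2
    TR025 0.547471          148.0    0.126263 0.515867      0.41      0.011487     3
```

The top-scoring bin (S ≈ 35, chr2:465000) sits inside the implanted
chr2 block, and the causal TR tops the increase-direction ranking with
max AUROC 0.74 and Irwin–Hall p = 3.6 × 10⁻⁵ — the decoy TRs' AUROCs
hover near the null value 0.5.

The same pipeline runs from the shell:

```bash
hicdci --treatment t_rep0.matrix t_rep1.matrix \
       --control c_rep0.matrix c_rep1.matrix \
       --file-type hicpro --bin-size 5000 --genomic-distance 200000 \
       --cre-catalog cres.bed --compendium comp --outdir results/
```

writing `dci.bedGraph`, `dci_bins.tsv`, `tr_increase.txt`,
`tr_decrease.txt` and `run.log`.

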