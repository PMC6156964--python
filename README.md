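# blocklik

Composite-likelihood inference of multi-population demographic history — and a
genome-wide recombination rate — from the **distribution of blockwise site
frequency spectra (bSFS)**.

## The problem

The plain site frequency spectrum (SFS) is a function only of expected branch
lengths, and very different histories can produce nearly identical spectra.
Partitioning the genome into short fixed-length blocks and recording the
*joint* SFS vector of each block (the bSFS — "a histogram of histograms")
retains short-range linkage information and is a much richer summary, at the
cost that exact likelihoods exist only for tiny samples and no recombination.

`blocklik` approximates the bSFS likelihood by Monte Carlo for **arbitrary**
demographies (population splits, size changes, exponential growth, continuous
migration, admixture pulses) with intra-block recombination as a free
parameter. For a sample of `b_x` genomes from each of `X` populations, the
branches of a genealogy fall into mutation classes `i = (i_1, ..., i_X)` (the
joint-SFS site types); a block's configuration is the count vector `k` over
those classes. Conditional on one sampled ancestral recombination graph (ARG)
with span-weighted class lengths

    t_{i,A} = (1/L) * sum_p w_p * t_{i,p}

the configuration probability is a product of Poissons,
`p(k | t) = prod_i Poisson(k_i; theta_block * t_{i,A})`, and the model
probability is the average over `M` simulated ARGs:

    p_hat(k | Theta) = (1/M) sum_d p(k | t_d),
    ln L(Theta) = sum_k n_k * ln p_hat(k).

Every simulated ARG contributes to every configuration, which makes the
approximation cheap and accurate even for modest `M`. Capping per-class
counts at `k_max` (lumping the tail) closes the configuration space so the
probability table sums to one. A *composite* bSFS (cbSFS) pools subsamples of
a larger sample, scaling the method to arbitrarily many genomes. Maximization
uses a noisy-objective two-stage search (population-based global search, then
replicate simplex refinements), and confidence intervals come from a
parametric bootstrap over linked stretches of sequence.

Who this is for: population geneticists with whole-genome or genome-wide
multi-locus data (VCF + callable-sites BED) who want demographic parameter
estimates beyond what the SFS alone can identify.

## Worked example

Simulate 5,000 unlinked 2-kb blocks for two genomes from each of two
populations that split `T = 2.5` (units of `4*N_A` generations) ago, with
daughter sizes 22,000 and 8,600 and ancestral size 1,400, then re-fit the
four demographic parameters:

```python
import blocklik as bl
from blocklik import templates

model, pmap = templates.m2(n_a=1400, n_s=22000, n_b=8600, t=2.5,
                           r=2e-8, free_r=False)
layout = bl.SampleLayout(sizes=(2, 2), block_length=2000)
table = bl.simulate_bsfs(bl.SimulationSpec(model=model, layout=layout,
                                           num_blocks=5000, seed=21))
print(table.total_blocks, table.num_configs)

schedule = [
    bl.SearchSpec(stage="global", args_per_eval=100, replicates=2,
                  eval_budget=160, seed=101),
    bl.SearchSpec(stage="local", args_per_eval=400, replicates=2,
                  eval_budget=100, seed=102, reuse_draws=True),
]
result = bl.fit(table, model, pmap, schedule, final_args=2000)
print({n: round(float(v), 1) for n, v in zip(pmap.names, result.best_params)})
print(round(result.best_loglik, 1))
```

prints (seeds as above):

```
5000 153
{'N_A': 756.9, 'N_S': 20274.8, 'N_B': 8885.9, 'T': 2.9}
-17574.1
```

The 5,000 blocks span 153 unique configurations; the search recovers the
daughter sizes and split time well, while the ancestral size — the hardest
parameter, informed only by deep coalescences — is within a factor of two at
this data size (`-17574.1` is the maximized composite log-likelihood). The
test suite runs the 20,000-block version of this experiment with a
parametric bootstrap, where all four parameters land within two bootstrap
SDs of the truth.

The same machinery is exposed on the command line:

```sh
blocklik enumerate --pops 2,2 --fold --kmax 4 --no-recombination   # -> 396
blocklik tabulate --vcf data.vcf --bed callable.bed \
    --pop S:sample1,sample2 --pop B:sample3,sample4 \
    --block-length 2000 --out table.tsv
blocklik fit --table table.tsv --model-config m6.json --scale 0.01 \
    --seed 1 --out fit.json
```

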