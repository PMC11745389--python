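# epiland

Analysis toolkit for combinatorially complete fitness landscapes over
biallelic sites: epistasis-model inference with spectral denoising,
ruggedness and heterogeneity statistics, NK reference landscapes,
evolutionary dynamics (adaptive-walk Markov chains and spatially
structured Wright–Fisher simulation), mutational-path statistics, and 2D
embeddings.

## What's inside

| module | contents |
| --- | --- |
| `epiland.landscape` | genotype encoding, complete landscapes, local-optima census, sublandscape projection |
| `epiland.inference` | Walsh–Hadamard transform, order-truncating band-pass denoising, cross-validated least-squares fit of the specific (h, J, K) model, global-epistasis fit (additive latent trait + monotone nonlinearity) |
| `epiland.stats` | directed gamma correlations of fitness effects, generalized gamma(n, d) over pinned subspaces, slope-to-roughness ratio, local fitness-effect distributions |
| `epiland.nk` | NK landscape generator and topography-constrained rejection-sampled ensembles |
| `epiland.dynamics` | absorbing Markov chain of fitness-increasing walks, absorbing probabilities, ring-lattice Wright–Fisher simulation with migration radius `r`, success-rate measurement |
| `epiland.paths` | lines of descent, path weights, scaled path entropy, mutation-ordering matrices, stepwise fitness-effect distributions |
| `epiland.viz` | fitness-similarity graphs, seeded force-directed layouts, rigid layout alignment, t-SNE path embedding |
| `epiland.synthetic` | packaged hotspot-structured L=10 fixture landscape (frozen, machine-verified constraints) and Gaussian replicate noise model |
| `epiland.io` / `epiland.cli` | plain-text genotype tables, coefficient files, run manifests, `epiland` command line |

## Command line

```sh
epiland synth fixture --out fixture.tsv          # packaged L=10 fixture
epiland synth replicates --landscape fixture.tsv --sigma 0.2 --n-rep 2 --seed 1 --out reps.tsv
epiland infer --data reps.tsv --cv-folds 10 --seed 1 --out coeffs.json
epiland denoise --landscape fixture.tsv --max-order 3
epiland gamma --landscape fixture.tsv            # directed gamma matrix
epiland ruggedness --landscape fixture.tsv -n 1 -d 1
epiland synth nk -l 10 -k 2 --seed 7 --out nk.tsv
epiland sswm --landscape fixture.tsv             # absorbing probabilities
epiland wf --landscape fixture.tsv --npop 500 --mu 1e-3 -r 2 --tmax 2000 \
           --threshold 0.5 --replicates 100 --seed 1
epiland paths --landscape fixture.tsv --walks 1000 --seed 1
epiland embed --landscape fixture.tsv --seed 1
```

Each command writes tidy tab-separated output plus a JSON manifest
(parameters, seeds, output checksums). Exit codes: 0 success, 2 config
error, 3 data error.

## Genotype-table format

Tab-separated with a header; `genotype` holds the L-character 0/1 string
(site 0 first, matching the order of the optional
`# site_labels: ...` comment line) and either one `fitness` column or
replicate columns `rep1`, `rep2`, ... Rows are ordered by the integer
encoding of the bitstring (site 0 = least significant bit).

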