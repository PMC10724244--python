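# hplus

Scale-agnostic, balance-unbiased cluster discordance, with fast estimators.

## The problem

After clustering `n` observations (cells, samples, patients, ...) you often
need to judge how well a label vector `L` fits a dissimilarity matrix
`D (n x n)` *without* ground truth.  Classical internal metrics (silhouette,
within-cluster sums of squares) depend on the magnitude of the
dissimilarities, so they cannot be compared across metrics such as Euclidean
vs. Manhattan vs. Canberra.  Rank-based *discordance* fixes that: split the
`N_d = n(n-1)/2` pairwise dissimilarities into within-cluster (`D_W`) and
between-cluster (`D_B`) sets and count

```
s = #{ (w, b) in D_W x D_B : w > b }
```

the number of times a within-cluster distance strictly exceeds a
between-cluster one.  Its classical normalisation

```
G+ = s / (N_d (N_d - 1) / 2)
```

has a serious flaw: writing `alpha = |D_W| / N_d` (which is determined by
the group balance `b` via `alpha = (1/(n-1)) sum_j b_j (n b_j - 1)`),

```
E[G+] = (N_d / (N_d - 1)) * 2 alpha (1 - alpha) * P(w > b),
```

so G+ changes with cluster-size balance and the number of clusters even when
the data-generating process is identical (a balanced null gives G+ = 0.25,
a 90/10 null gives G+ ~ 0.14).  Renormalising by the number of cross pairs,

```
H+ = s / (|D_W| |D_B|),     E[H+] = P(w > b),
```

yields an unbiased, balance-free estimate of the probability that a
within-cluster distance exceeds a between-cluster one: 0 for perfectly
tight, separated clusters, 0.5 under the null, independent of `alpha`.
H+ is a normalised Mann-Whitney statistic between the two distance sets.

Exact computation is cheap here (the counter sorts one set and binary-searches
the other), but materialising all `N_d` distances is not.  Two scalable
estimators are provided:

* **HPE** (quantile sketch): compress each distance set to `p + 1`
  percentiles and compare sketches — brute force `O(p^2)` or a monotone
  grid walk `O(p)` — with a deterministic guarantee `|H+ - H_e| < 1/p`.
  The walk also certifies factorisations `H+ ~ gamma_W * gamma_B`
  ("`100*gamma_W`% of within distances exceed `100*gamma_B`% of between
  distances").
* **HPB** (stratified bootstrap): average exact H+ over `r` resamples of
  size `t` drawn with replacement proportionally to cluster balance,
  never building the full `n x n` matrix.

## Worked example

```python
import numpy as np
from hplus import (MixtureConfig, gaussian_mixture, compute_dissimilarity,
                   discordance, hpe, hpb, BootstrapConfig)

X, labels = gaussian_mixture(MixtureConfig(n=300, f=50, b=0.7, delta=0.8, seed=42))
D = compute_dissimilarity(X, "euclidean")

res = discordance(D, labels)
print(res.s, round(res.g_plus, 4), round(res.h_plus, 4), round(res.alpha, 4))
# 78185276 0.0777 0.1594 0.5786

est = hpe(D, labels, p=101)
print(round(est.h_e, 4), round(est.bound, 4))
# 0.1601 0.0099

boot = hpb(X, labels, BootstrapConfig(r=30, t=100, seed=42))
print(round(boot.h_b, 4), round(boot.sd, 4))
# 0.1604 0.0222
```

Reading: with a 0.8-SD mean shift on every one of 50 features, about 16% of
within-cluster distances exceed a between-cluster distance (H+ = 0.159) —
moderately concordant clusters.  G+ (0.078) is not comparable across
balances; the sketch estimate at `p = 101` lands within its guaranteed
0.0099 of the exact value, and the 30-replicate bootstrap lands within 0.001
of it without needing the full distance matrix.

The same operations are available from the shell:

```sh
hplus discordance --dissimilarity D.csv --labels labels.txt
hplus hpe --dissimilarity D.csv --labels labels.txt --p 101 --gammas
hplus hpb --data X.csv --labels labels.txt --r 150 --t 100 --seed 1
hplus alpha --n 1000 --balance 0.9,0.1
hplus simulate mixture --n 1000 --f 500 --b 0.5 --seed 1 \
      --data-out X.csv --labels-out labels.txt
hplus evaluate --dissimilarity D.csv --labels k2.txt --labels k3.txt --truth truth.txt
```

Results print as JSON (or CSV for tables) on stdout; logs go to stderr.
Exit codes: 0 success, 1 degenerate partition, 2 input error.

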