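# rcnet

Weighted rich-club analysis of brain functional-connectivity networks
under transient unilateral disruption.

Resting-state fMRI studies of focal, reversible brain "silencing" (e.g.
intracarotid barbiturate injection, the animal analogue of the clinical
Wada test) ask how a hemisphere-wide perturbation reorganizes the brain's
hub structure. `rcnet` implements the full analysis chain for such
experiments: ROI time series → pairwise Pearson functional connectivity
(FC) → positive-weight networks → weighted rich-club curves with a
reshuffle null model → paired permutation comparison of pre- vs
post-disruption curves — plus band-wise interhemispheric EEG
synchronization as an independent electrophysiological readout. Because
studies of this kind rarely deposit raw data, the package ships a
synthetic-data generator that emulates the relevant statistical structure
(bilateral block covariance, a planted hub club, a disruption effect)
with known ground truth, so every stage is testable end to end.

It is intended for systems-neuroscience researchers analyzing small-cohort
rs-fMRI/EEG experiments, and for methodologists who need a tested,
seeded reference implementation of the weighted rich-club statistic.

## The statistic

Node *strength* is the sum of FC weights on a node's edges,
s_i = Σ_j w_ij. For a strength threshold *s*, the *club* is the set of
nodes with s_i > s. With E_>s the number of edges joining club members
and W_>s the sum of their weights, the weighted rich-club ratio is

    phi_w(s) = W_>s / Σ_{l=1..E_>s} w_l^rank ,

where w_1^rank ≥ w_2^rank ≥ … are the edge weights of the whole network
in descending order: the fraction of weight the club carries relative to
the most it could carry if its members were joined by the globally
strongest connections. Because high-strength nodes share strong edges
partly by chance, phi_w is normalized by its average over topology-
preserving null networks in which the weights are globally reshuffled
(1000 draws by default):

    rho_w(s) = phi_w(s) / ⟨phi_w_random(s)⟩ .

rho_w(s) > 1 indicates a positive weighted rich-club effect. Pre/post
curves are compared with a paired sign-flip permutation test at the
animal level (exact enumeration when 2^n ≤ the permutation budget),
two-sided p per threshold, α = 0.01.

## Worked example

```python
import numpy as np
from rcnet.synthetic import CohortConfig, simulate_cohort
from rcnet.fc_network import compute_fc, average_fc, to_network
from rcnet.richclub import rho_w, prominence_ranking

cfg = CohortConfig(seed=1)                      # 3 animals x 2 conditions x 64 ROIs
cohort, truth = simulate_cohort(cfg)

fcs = [compute_fc(cohort[(a, "pre")].window(0, 500))
       for a in ("rat01", "rat02", "rat03")]
net = to_network(average_fc(fcs))               # negative correlations dropped
print(f"network: {net.n_nodes} nodes, {net.E} positive edges")

ranking = prominence_ranking(net, k=10)
hits = set(ranking.top_k) & set(truth.club_nodes["pre"])
print("top-5 strength:", ", ".join(ranking.node_ids[:5]))
print(f"planted club members in top-10: {len(hits)}/8")

curve = rho_w(net, n_null=1000, seed=1)
for i in np.flatnonzero(curve.defined)[-4:]:
    print(f"s = {curve.thresholds[i]:5.1f}   rho_w = {curve.rho[i]:.3f}")
```

prints

```
network: 64 nodes, 1868 positive edges
top-5 strength: contra:Hip, ipsi:Cg1, contra:S1J, contra:S1FL, contra:PtPR
planted club members in top-10: 8/8
s =  21.8   rho_w = 1.064
s =  23.5   rho_w = 1.160
s =  25.2   rho_w = 1.368
s =  26.9   rho_w = 1.490
```

All eight planted hub regions are recovered among the ten most prominent
nodes, and rho_w rises above 1 at high strength thresholds — a positive
weighted rich-club effect. Re-running with the same seed reproduces the
numbers exactly.

The command-line interface wraps the same pipeline:

```sh
rcnet simulate --seed 1 --out data/          # write a synthetic cohort as CSV
rcnet run --seed 1 --out results/ --n-null 1000 --n-perm 999
rcnet eeg --seed 1 --out eeg_sync.csv        # band-wise interhemispheric sync
```

`rcnet run` emits FC and SD matrices, prominence rankings, rich-club
curves for the whole brain and each hemisphere, and permutation
comparisons, all as plain CSV/JSON.

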