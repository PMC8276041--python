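# kfpm

Essential-protein prediction on a heterogeneous protein–domain network.

Essential proteins are those an organism cannot survive without; screening
for them experimentally is slow, so computational ranking from
protein–protein interaction (PPI) data is standard practice. Pure network
centrality (the centrality–lethality rule) only goes so far because PPI
maps are incomplete. `kfpm` implements a fusion method: it builds a
two-layer network of proteins and protein domains, scores each protein on
three biological channels — orthology (conservation), co-expression with
interaction partners, and subcellular localisation enrichment — fuses the
channels with CRITIC objective weights, blends in a topology score, and
propagates the result with a random walk with restart. Proteins are
returned ranked by final score.

## The method in brief

* PPI edges are weighted by `|NG(u) ∩ NG(v)|² / ((|NG(u)|+1)(|NG(v)|+1))`;
  domains link to the proteins that carry them, and domain pairs are
  weighted by their normalised shared-protein count. The blocks form one
  symmetric (N+M)×(N+M) adjacency, `NWPD = [[WPP, WPD], [WPDᵀ, WDD]]`.
* Feature fusion uses CRITIC weights `W_j ∝ σ_j Σ_i (1 − |r_ij|)`
  (contrast × conflict) on min–max scaled feature columns, giving
  `BIO(p)`; with the topology score `TOP(p)` the initial score is
  `S0(p) = θ·BIO(p) + (1−θ)·TOP(p)`, θ = 0.7. Domains inherit
  max-normalised sums of their members' scores.
* Each weight block is dampened, row-normalised and biased by the target's
  initial score to give the transition matrix NDPM (rows renormalised to
  stochastic), and scores iterate to the fixed point of
  `S ← α·NDPMᵀ·S + (1−α)·S0`, α = 0.5, ε = 1e−6.

See `docs/methods.md` for the full model, parameter rationale and
limitations.

## Worked example

No downloads are needed: the package generates complete synthetic input
bundles whose planted essential proteins carry the signals the method
exploits.

```sh
kfpm synth --seed 3 --out demo/
kfpm rank --ppi demo/ppi.tsv --domains demo/domains.tsv \
          --expr demo/expr.tsv --ortho demo/ortho.tsv \
          --subcell demo/subcell.tsv --essential demo/essential.txt \
          --out demo/ranking.tsv
kfpm evaluate --ranking demo/ranking.tsv --essential demo/essential.txt \
              --out demo/metrics.json
```

The ranking file starts:

```
#rank	protein	score	essential
1	P0003	0.019495	1
2	P0002	0.010236	0
3	P0001	0.009804	1
```

and `kfpm evaluate` prints:

```json
{
  "auc": 0.8145,
  "topk_accuracy_percent": {
    "1": 80.0,
    "5": 68.0,
    "10": 68.0,
    "15": 61.33,
    "20": 54.0,
    "25": 45.6
  }
}
```

Read this as: on this 500-protein bundle (20% of proteins planted
essential), 80% of the top-1% ranked proteins are truly essential, 68% of
the top-10% are, and the ranking separates essential from non-essential
proteins with ROC AUC 0.81 — far above the 20% base rate and the 0.5
chance AUC. The same pipeline is available from Python via
`kfpm.run_pipeline(...)`, which returns the ranking together with every
intermediate artefact (weight matrices, CRITIC weights, initial scores,
transition matrix, convergence diagnostics).

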