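# motorgraph

Graph-theoretical analysis of motor-network reorganization from
resting-state fMRI ROI time series.

Rehabilitation studies in chronic stroke ask whether an intervention
reorganizes the motor network — whether regions cluster more tightly,
whether information routes shift toward ipsilesional motor cortex — and
whether those changes track behavioral recovery. `motorgraph` implements
that analysis end to end for paired (pre/post) designs:

1. **Connectivity** — per session, the absolute Fisher z of the Pearson
   correlation between the 20 motor-network ROI signals:
   `z_ij = |atanh(r_ij)|`.
2. **Graphs** — proportional thresholding at density *s* anchored on the
   maximum-spanning-tree backbone, so every graph keeps
   `max(N−1, round(s·N(N−1)/2))` edges and is always connected.
3. **Measures** — weighted clustering `C_i = Σ_{(j,k)}(W_ij + W_ik) / (S_i (K_i−1))`
   over closed neighbor pairs (segregation), characteristic path length on
   1/weight shortest paths (integration), binary degree centrality, and
   mean-normalized betweenness centrality `BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st`
   (hubness).
4. **Statistics** — exact two-sided Wilcoxon signed-rank tests (zeros
   dropped, midranks, full sign-assignment null distribution) across
   subjects, Benjamini–Hochberg FDR per test family, trend flagging at raw
   p < 0.07, and Pearson correlation of metric changes with ARAT / 9-HPT
   changes.
5. **Synthetic cohorts** — a seeded generator of block-correlated,
   AR(1)-smoothed Gaussian ROI time series with injectable pre→post
   connectivity effects and behavior coupled to the realized network change,
   so the whole pipeline is testable without scanner data.

See `docs/methods.md` for conventions, defaults, and limitations.

## Worked example

Simulate a 13-subject cohort in which all edges of right (ipsilesional)
primary motor cortex strengthen by Δr = 0.25 after therapy, then run the
full analysis:

```python
import motorgraph as mg

atlas = mg.load_atlas()                      # 20-ROI motor network
spec = mg.CohortSpec(
    effect_edges=mg.node_effect_edges(atlas, "M1_R", 0.25), seed=7
)
cohort = mg.generate_cohort(spec)

config = mg.AnalysisConfig(sparsity_grid=(0.12, 0.24, 0.36, 0.42),
                           out_dir="results/demo")
bundle = mg.run_all(config, sessions=cohort.sessions,
                    behavior=cohort.behavior)

reg = bundle.regional
m1 = reg[(reg.region == "M1_R") & (reg.metric == "BC")].iloc[0]
print(f"M1_R betweenness: W={m1.W:g}, p={m1.p:.4f}, "
      f"q={m1.q:.4f}, flag={m1.flag}")
```

prints

```
M1_R betweenness: W=91, p=0.0002, q=0.0024, flag=significant
```

W = 91 is the maximal positive-rank sum at n = 13 — every subject's
betweenness at M1_R increased — so the exact two-sided p is 2/2¹³ ≈ 0.0002
and survives FDR across the 20-region family. The sweep table in the same
bundle shows the clustering coefficient rising at the upper mid densities
(`delta_median > 0`, significant at 0.36 and 0.42) while path length is
unchanged, the signature of increased segregation without loss of
integration.

The same pipeline is available as a CLI:

```sh
motorgraph simulate --out-dir cohort/ --seed 7 --effect-node M1_R
motorgraph all --data-dir cohort/ --out-dir results/ --density 0.42
motorgraph stats            # exact Wilcoxon on the packaged behavioral table
```

The last command prints

```
ARAT: n=11 (effective 7), W=28, exact two-sided p=0.0156
9-HPT: n=13 (effective 13), W=0, exact two-sided p=0.0002
```

On the packaged clinical table, 11 of 13 subjects completed the ARAT; the
7 nonzero changes are all improvements, giving the exact p = 2/2⁷ = 0.0156.
All 13 subjects sped up on the 9-HPT (W = 0: no positive ranks), giving
p = 2/2¹³ ≈ 0.0002.

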