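# coralmeta

Analysis toolkit for the coral larval meta-organism under nitrate
enrichment: the coral host, its Symbiodiniaceae (dinoflagellate algal
symbionts), and its prokaryotic associates treated as one system. The
package is aimed at researchers studying how elevated nitrate reshapes
cross-compartment associations in the holobiont, and at methodologists who
want the full analysis chain exercisable on synthetic data with known
ground truth.

It implements, as a tested and reusable pipeline:

- **Synthetic tri-compartment data** — five nitrate levels (ambient control
  ≈ 2.5 µM plus 5, 10, 20, 40 µM) × replicate aquaria; negative-binomial
  expression counts with planted differentially expressed transcripts
  (DETs), planted cross-compartment correlated pairs, and Symbiodiniaceae
  physiology (cell density, net photosynthesis P_N, dark respiration R_D)
  driven by named transcripts plus an aquarium-level random intercept.
- **Differential expression** — counts per million (CPM), pairwise
  treatment-vs-control tests per compartment; a transcript is significant
  when `logFC > 1` or `logFC < −1` **and** `p ≤ 1e−4` (coral,
  Symbiodiniaceae) or `p ≤ 1e−3` (prokaryotes); DET union, Venn region
  counts and up/down tallies; the ordination transform
  `sqrt(log2(CPM + 1))` with Bray–Curtis dissimilarities.
- **Photophysiology** — oxygen-slope regression over a 10-min window with
  blank correction, per-larva rates, the identity `P_G = P_N + R_D`,
  haemocytometer symbiont densities, one-way ANOVA per treatment.
- **Cross-compartment co-expression networks** — Spearman ρ with two-sided
  p-values for every coral–algal, algal–prokaryotic and coral–prokaryotic
  DET pair; edges kept at `p ≤ 0.05`; hub ranking by *size-adjusted
  betweenness* (raw shortest-path betweenness divided by the number of
  transcripts in the network); top-20 core transcripts.
- **Penalized mixed-model selection** — repeated random-subset
  L1-penalized random-intercept regression of each physiology response on
  blocks of 10 transcripts, 100 runs; transcripts whose estimates beat the
  fit's random-effect magnitude in more than 95 (coral) or 70 (prokaryote)
  runs are retained, with signs.
- **Symbiosis dynamics** — a tripartite Lotka–Volterra-type model

  ```
  dH/dt = r·H·(1 − H/(K + γ₁S + γ₂SB)) − a₁SH − a₂BH
  dS/dt = g₁HS·(1 + b₁B) − d₁S·(1 + e₁S + c₁B)
  dB/dt = g₂HB·(1 + b₂S) − d₂B·(1 + e₂B + c₂S)
  ```

  with adaptive integration, equilibrium finding (analytic Jacobian,
  stability classification), the boundary closed form
  `λᵢ = (1/eᵢ)·((gᵢ/dᵢ)·H̄ − 1)`, nullclines, and regime labels:
  mutualism vs parasitism (coral biomass with symbionts above or below the
  symbiont-free capacity K) and partner coexistence vs exclusion.

## Worked example

```python
import numpy as np
import coralmeta as cm

design = cm.generate_design(n_reps=4, seed=7)
mats, truth = cm.generate_counts(design, de_fraction=0.1, seed=7)
cpms = {c: cm.cpm(m) for c, m in mats.items()}

dets = {}
for comp in mats:
    tables = {t: cm.pairwise_de(cpms[comp], design, t) for t in ("5", "10", "20", "40")}
    dets[comp] = cm.call_dets(tables, comp)
    print(f"{comp}: {len(dets[comp].union)} DETs (planted {len(truth.de_union(comp))})")

order = design["sample_id"].tolist()
la = np.log2(cpms["coral"].data.loc[sorted(dets["coral"].union), order] + 1)
lb = np.log2(cpms["symbiodiniaceae"].data.loc[sorted(dets["symbiodiniaceae"].union), order] + 1)
edges, n_pairs = cm.correlate_pairs(la, lb)
net = cm.build_network(edges, n_pairs, name="coral-algal")
print(f"coral-algal network: {net.n_significant} of {net.n_pairs_tested} pairs "
      f"significant ({net.percent_significant:.2f}%)")
```

prints

```
coral: 30 DETs (planted 30)
symbiodiniaceae: 9 DETs (planted 12)
prokaryote: 5 DETs (planted 5)
coral-algal network: 168 of 270 pairs significant (62.22%)
```

Planted coral DETs are fully recovered at the strict coral threshold; the
weaker-powered Symbiodiniaceae compartment recovers 9 of 12. The DETs
share the nitrate-response structure, so far more of their cross-compartment
pairs correlate than the 5% a null expects — that excess is exactly what the
network stage quantifies.

The dynamic model, from the shipped illustrative parameter sets:

```python
from coralmeta import EXAMPLE_PARAMS, classify_regime
for name in ("mutualism", "parasitism"):
    rep = classify_regime(EXAMPLE_PARAMS[name])
    e = max((q for q in rep.equilibria if q.stability == "stable"), key=lambda q: q.H)
    print(f"{name}: coral-algal={rep.coral_algal}; stable H*={e.H:.3f}, "
          f"S*={e.S:.3f}, B*={e.B:.3f} (K=1.0)")
```

```
mutualism: coral-algal=mutualism; stable H*=5.500, S*=10.000, B*=0.000 (K=1.0)
parasitism: coral-algal=parasitism; stable H*=0.857, S*=0.714, B*=0.000 (K=1.0)
```

With a net symbiont benefit the coral equilibrates far above its
symbiont-free capacity (mutualism); with pure cost it is pushed below K
(parasitism). In both cases the surviving partner's density equals the
closed-form λ evaluated at the equilibrium coral biomass.

A command-line interface mirrors the stages
(`coralmeta simulate-data | de | ordination | network | select |
model-simulate | model-equilibria | run-all`); `run-all` writes every stage
output plus a manifest with the seed and config digest so reruns are
byte-identical.

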