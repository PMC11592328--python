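# infinet

Three-state Ising spin cascades on directed networks: Google-matrix ranking,
asynchronous Monte Carlo dynamics, and Erdös-barrage intervention.

## The problem

In a directed interaction network — for instance a protein–protein
interaction (PPI) network, where a link j → i records a documented action of
protein j on protein i — a small panel of permanently *activated* nodes can
drive a cascade that converts most of the network into the activated state
(the setting this package targets is fibrosis progression driven by a
TGF-β-stimulated activator panel).  `infinet` models that cascade, quantifies
it, and searches for small sets of *repressor* seed nodes that suppress it.

Each node i carries a spin σᵢ ∈ {−1, 0, +1} ("blue"/healthy,
"white"/neutral, "red"/activated).  Nodes in the red (blue) panel are pinned
to +1 (−1) forever.  From the column-normalized adjacency S̃
(S̃ᵢⱼ = Aᵢⱼ/Σₗ Aₗⱼ, zero columns at dangling nodes) the symmetric coupling
W = S̃ + S̃ᵀ defines a local field

    Zᵢ = Σ_{j≠i} (S̃ᵢⱼ + S̃ⱼᵢ) σⱼ ,

and an asynchronous Monte Carlo sweep visits the variable nodes in a fresh
random permutation, setting σᵢ ← sign(Zᵢ) (unchanged when Zᵢ = 0), each
update immediately visible to later ones.  R independent realizations yield
the per-node red-outcome fraction fr(i) and its average fr over the Nv
variable nodes.  The package also provides:

- **PageRank / CheiRank** (indices K, K*) from the Google matrix
  G = αS + (1−α)/N with α = 0.85, computed matrix-free by power iteration;
- **Erdös barrage**: the set of nodes at symmetrized distance 1 from the red
  panel, ranked by frc(i) — the network-average red outcome when node i is
  the single initial blue seed (index Kfr) — plus conditional estimates from
  random-placement ensembles, exhaustive subset evaluation of small blocker
  groups, and rank-sum group selection;
- **outcome statistics**: normalized histograms, exact empirical CCDF
  P(fr), empirical median, and least-squares power-law tail exponents;
- **synthetic networks**: a preferential-attachment generator emulating the
  gross structure of large curated PPI networks (sparse, heavy-tailed,
  mean out-degree ≈ 7.3, a hub-unreachable fraction ≈ 0.18, a modest-degree
  red activator panel whose Erdös shell contains the top hubs), so every
  stage is testable without proprietary data.

## Worked example

```
python examples/03_erdos_barrage.py
```

prints, for a seeded 1,000-node synthetic network with 10 pinned red and
6 pinned blue nodes:

```
Erdos set: 184 candidates around the 10 pinned red nodes
 n_ib  fr (Erdos)  fr (anywhere)
    0      0.7994         0.7953
    2      0.6754         0.7572
    5      0.5039         0.6509
   10      0.2220         0.4793
   20      0.0286         0.1947
```

Reading: with no repressor seeds, ~80% of variable nodes end activated
(the hub-unreachable ~18% stay white).  Seeding n_ib initial blue nodes
lowers fr monotonically, and placing them inside the Erdös shell of the
activator panel (middle column) suppresses the cascade far faster than
scattering the same number anywhere (right column) — with 20 well-placed
seeds the activated fraction drops by a factor ≈ 28 versus ≈ 4 for random
placement.  `examples/04_optimal_group.py` goes further and shows a 3-node
blocker group found by Kfr rank-sum driving fr from 0.81 to ≈ 0.

The other examples cover ranking (`01`), the plain cascade ensemble (`02`)
and distributional summaries (`05`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — synthetic benchmark network,
PageRank/CheiRank, the baseline cascade ensemble, and the Erdös-barrage
decay scan — printing a run log and writing the recomputed-targets JSON to
`--out`.  All randomness derives from `--seed`.

## Layout

- `src/infinet/network.py` — edge-list/SIF ingestion, panels, A, S̃, S, W
- `src/infinet/ranking.py` — Google operator, PageRank, CheiRank, rank index
- `src/infinet/dynamics.py` — spin configurations, sweeps, realizations,
  ensembles (`src/infinet/_kernels.py` holds the compiled sweep)
- `src/infinet/barrage.py` — Erdös set, frc rankings, subsets, group choice
- `src/infinet/stats.py` — histograms, CCDF, tail fits, scan grids
- `src/infinet/synthetic.py` — generator and exactly solvable fixtures
- `src/infinet/workflows.py` — end-to-end runners, manifests, replay
- `docs/methods.md` — model assumptions, parameters, numerical choices
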