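# Methods

## Problem setting

A biomedical interaction network is an undirected simple graph; observed
edges are trusted positives and the remaining pair space is unlabelled.
Link prediction ranks unobserved pairs by a likelihood score `S_ij`.
Bipartite data (drug–target, disease–gene, drug–disease) enter through
the biadjacency matrix `B` and are expanded to the symmetric adjacency
`[[0, B], [Bᵀ, 0]]`; partition membership is retained so candidate
generation and negative sampling can be restricted to cross-partition
pairs. Node labels are mapped to contiguous 0-based indices by first
appearance and the map travels with every result.

A structural consequence worth knowing: on an expanded bipartite graph
every pure common-neighbour index is identically zero on cross-partition
pairs (a drug's neighbours are targets, a target's neighbours are drugs),
so only indices that use even-length path information (Katz, RWR, LRW,
SimRank, ACT, ...) carry signal there. This mirrors the degenerate
behaviour such indices show on real drug–target benchmarks.

## Index implementations and numerical choices

* **Logarithms** in Adamic–Adar and the naive Bayes family are natural
  logs by default (`IndexConfig.log_base`); any fixed base rescales AA
  but changes the naive-Bayes mixture, so the choice is stamped into
  every result's config snapshot.
* **Degenerate denominators**: all degree-normalised overlap indices
  define 0/0 := 0 — an isolated node contributes no overlap evidence.
* **Local naive Bayes** needs a prior odds constant `s` and a per-node
  role function `R_w`, neither of which has a standard published closed
  form in this benchmark tradition. We estimate `s` as
  (#non-adjacent pairs)/m on the training graph and
  `R_w = (N_conn + 1)/(N_disc + 1)` over the pairs of `Γ(w)` with
  add-one smoothing; both are overridable (`lnb_s`, `lnb_R`). The three
  variants weight each common neighbour by 1, `1/log k_w`, `1/k_w`.
* **Laplacian pseudoinverse** (`act`, `cos_plus`, `cosplus_vec`): dense
  eigendecomposition of `L = D − A`; eigenvalues below `1e-10·λ_max` are
  treated as null-space modes, so disconnected graphs work —
  cross-component entries of `L⁺` are exactly zero and commute-time
  scores between components collapse to 0 rather than erroring. The
  "node vector" cosine uses `v_i = √Λ⁺ Uᵀ e_i`, whose Gram matrix is
  `L⁺`; the equivalence of the two cosine routes is verified by test,
  not assumed.
* **Katz**: direct dense solve of `(I − βA)X = I`; `β ≥ 1/λ₁` is
  rejected with a configuration error before any solve. TSCN uses the
  common-neighbour kernel `K = A²` with a zeroed diagonal and a transfer
  weight defaulting to `0.5/λ₁(K)` so its Neumann series converges; a
  zero kernel short-circuits to zero scores.
* **LHN2** reads the degree matrix as diagonal (`D⁻¹` is a pseudoinverse
  with zeros for isolated nodes).
* **Random walks**: transition rows are `A_i/k_i`, isolated nodes get
  all-zero rows (no teleportation), so walk scores involving nodes with
  no training links are 0 — the known cold-start limitation of these
  models, kept deliberately. RWR solves the restart fixed point
  `(I − αMᵀ)P_i = (1−α)e_i` by power iteration (tol 1e-9, ≤1000
  iterations) for all sources at once; LRW uses the degree-proportional
  initial configuration `q_i = k_i/2m`; SRW sums LRW over steps `1..t`.
  SimRank iterates `S ← C·MSMᵀ` with unit diagonal from `S = I`
  (contraction rate ≤ C; tol 1e-6, ≤100 sweeps; refuses n > 5000).
* **HOPE embedding**: deterministic full SVD of the Katz matrix,
  truncated to `min(embed_rank, n)`; source/target vectors scaled by
  √singular values, pair scores symmetrised. At full rank it reproduces
  Katz exactly, giving a strong internal consistency check; the default
  rank is 64.
* Everything is solved densely: the package targets desk-scale networks
  (10²–10³ nodes), matching its synthetic benchmark sizes.

## Evaluation protocol

Edges are split by uniform k-fold partition (or a single fractional
holdout); each fold's training graph keeps the full node set. Negatives
are sampled uniformly without replacement from non-adjacent pairs at a
1:1 ratio per positive by default — test negatives first, then train
negatives excluding them, so the two sets never overlap and no negative
is an observed edge; on expanded bipartite graphs only cross-partition
pairs are eligible. On tiny dense graphs the requested counts are capped
at the available non-edge universe.

Scores are compared by rank only. AUROC is the Mann–Whitney concordance
(ties ½, via mid-ranks). AUPR is step-wise average precision over
distinct score thresholds, under which a constant scorer yields the
prevalence (trapezoidal PR interpolation, which overestimates, is
deliberately not used). F1 needs an operating point: the default is
balanced top-k with k = #test positives, ties broken by ascending pair
index; evaluation pairs are ordered lexicographically so tie-breaking
cannot correlate with the label. Both the standard `2PR/(P+R)` and the
`PR/(P+R)` variant (seen in some published tables) are available; the
convention used is stamped into every report.

Model comparison across datasets uses the Friedman test on AUROC error
(1 − AUROC): mid-ranks within each dataset, the chi-square statistic
with the standard tie correction, p-value from χ²(k−1). The chi-square
reference is asymptotic in the number of blocks; the test suite validates
it against an exact permutation null at a block count where the
asymptotics hold.

The pipeline derives every cell's seed from a SHA-256 hash of the
top-level seed and the cell identity, so any model×dataset cell can be
reproduced in isolation and a rerun of the same config writes
byte-identical CSV output.

## Synthetic data: what it emulates and what it does not

The generators produce stochastic block models (monopartite, and
bipartite with matched row/column blocks): within-block probability
`p_in` exceeds cross-block `p_out`, so neighbourhood overlap and short
paths are genuinely predictive of held-out links. Default scale is the
canonical suite — 2 blocks of 100 nodes, `p_in = 0.3`, `p_out = 0.02`,
10% holdout, 1:1 negatives, 5 replicate seeds — roughly the real
pharmacological benchmark datasets scaled down tenfold.

Limits of the emulation, hence of what a green test establishes: SBM
edges are conditionally independent given block membership, so within a
block a held-out edge and a non-edge are statistically indistinguishable
to *any* score. That puts a hard ceiling on achievable AUROC under
uniform negative sampling: on the canonical suite the Bayes-optimal
block oracle reaches ≈ 0.75, and the implemented indices cluster just
below it (CN/RA/Katz/LRW ≈ 0.75) — recovery *above chance* is the
meaningful signal, not high absolute AUROC. The generator also has no
degree heterogeneity (so preferential attachment is uninformative by
design, a useful negative control), no transitivity beyond blocks, and
no weighted edges. Commute-time scores are additionally degree-dominated
on near-regular graphs (effective resistance ≈ 1/k_i + 1/k_j), which is
why ACT trails the overlap indices here while leading on heterogeneous
real data.

## Known limitations

* Dense linear algebra throughout: not intended beyond a few thousand
  nodes (SimRank refuses n > 5000 outright).
* No weighted or multi-relational graphs; simple undirected graphs only,
  with self-loops and duplicates dropped at ingest.
* Nodes with no training edges receive zero walk/overlap scores — new
  drugs or targets without any known interaction cannot be ranked.
* Skip-gram / large-scale factorisation embeddings are out of scope; the
  Katz-SVD embedding is the one representative whose construction is
  fully determined by quantities already in the package.
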