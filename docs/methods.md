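# Methods

`spermnet` analyses directed, signed molecular-interaction networks of the
kind curated for sperm capacitation and acrosome-reaction (AR) signaling:
nodes are molecules or cellular events, edges are activation or inhibition
interactions with a direction (source → target). This note records the
models and conventions the package implements, the choices made where the
design was genuinely open, and what its synthetic data do and do not show.

## Network model

A network is a set of labels plus a set of `(source, target, sign)`
triples. Duplicate table rows (e.g. one row per literature reference)
collapse to a single edge at graph construction, never at read time, so
curation provenance is preserved in the record list. Antiparallel edges
(A→B and B→A) are distinct, as are edges between the same ordered pair
with different signs — the schema is per-interaction. Self-loops are
allowed but never count toward neighbourhoods or clustering. Labels are
trimmed of surrounding whitespace only; case and internal punctuation are
preserved, because tokens such as `[Ca2+]i` and phrases such as
`membrane fusion` denote distinct biological entities and aggressive
normalisation would silently merge them.

An optional exclusion list drops currency species (H₂O, CO₂, Pi, …) whose
edges would otherwise short-circuit every pathway; excluding an endpoint
removes the whole edge.

## Topological statistics

* **Degrees** count signed-edge multiplicity; **neighbour counts** are
  direction-blind and distinct. The two differ precisely when antiparallel
  pairs, self-loops or sign-duplicate edges exist, which is why the mean
  neighbour count can fall slightly below `2E/N`.
* **Clustering** uses the undirected formula `CI = 2nI/(kI(kI−1))`, with
  `nI` the number of unordered neighbour pairs joined by at least one edge
  in either direction, even though the networks are directed — this is the
  convention of the standard topological-analyzer tools for this data
  type. Nodes with fewer than two neighbours contribute `c = 0` to the
  mean; the very low mean clustering (~0.02–0.04) typical of sparse
  signaling chains is only reproducible with this zero-inclusive
  averaging. A directed variant (`nI/(kI(kI−1))`, ordered pairs) and a
  k ≥ 2-only mean are available behind flags.
* **Path statistics** follow edge direction by default (an `undirected`
  mode symmetrizes). The characteristic path length is the mean shortest
  path over *finite* ordered pairs only; unreachable pairs are dropped and
  reported via `finite_pair_count`, because a sparse directed cascade has
  many unreachable pairs and a mean over infinite distances is undefined.
  The diameter is the largest finite length, hence diameter ≥ CPL whenever
  both exist.
* **Closeness centrality** is `Cc(n) = 1/avg(L(n,m))` over the nodes
  reachable *from* n, 0 when nothing is reachable; it lies in [0, 1].
* **Hub ranking** orders nodes by total degree (in + out, with signed
  multiplicity), ties broken lexicographically so rankings are
  deterministic.

## Power-law fits

Degree histograms are fitted as `P(k) = a·k^b` by ordinary least squares
on `(log k, log count)` over the raw frequency points with `k ≥ 1` and
count > 0 — no binning, no zero class, at least three distinct degrees.
Two quality numbers are reported, mirroring the dual reporting style of
network-analyzer tools: `R²` of the log-log regression and the Pearson
`r` between observed counts and the fitted curve on the original scale.
Maximum-likelihood (Clauset-style) estimation is deliberately out of
scope: the quantity of interest here is the descriptive log-log fit.
Exact power-law inputs are recovered to machine precision (checked to
|Δb| < 1e−9 for b ∈ {−1.5, −2.0, −2.3}).

The clustering-vs-degree relation `C(k)` is fitted the same way over the
mean clustering per neighbour count, using only k ≥ 2 points with positive
mean (log of 0 is undefined). Fewer than three usable points yields an
explicit "unfittable" marker — for sparse signaling chains this is the
common and meaningful outcome (clustering carries no degree trend).

## Topology classification

Three classes are distinguished: **random** (Erdős–Rényi: Poisson degrees,
no hubs), **scale-free** (Barabási–Albert: power-law degrees, hubs), and
**hierarchical** (scale-free degrees *and* local clustering that falls
with degree as a power law). The classifier is descriptive — fit-quality
comparisons, no likelihood-ratio or information-criterion machinery — and
proceeds in this order:

1. **Random test.** Poisson-expected and power-law-expected total-degree
   counts are scored against the observed histogram on the same support
   (k ≥ 1) with an R²-style agreement on the square-root scale (a
   variance-stabilising compromise between the count scale, which ignores
   the tail, and the log scale, which over-penalises expected counts near
   zero). The power-law expectation is rescaled to the observed node total
   because the log-log OLS intercept is tail-dominated and systematically
   misses the head. The network is random when the Poisson score is ≥ 0.5
   absolutely and beats the power-law score by ≥ 0.35. This comparison
   runs *first* because thresholding the log-log r² alone cannot reject
   sparse Poisson graphs: over their short degree range the histogram is
   monotone and a log-log line often reaches r² ≥ 0.8.
2. **Scale-free test.** Both the in- and out-degree fits must reach
   r² ≥ 0.8 — a threshold that accepts fit qualities reported for real
   curated maps (R² ≈ 0.82–0.95) and rejects their degree-independent
   clustering fits (R² ≈ 0.13–0.19).
3. **Hierarchical upgrade.** A scale-free call is upgraded when the `C(k)`
   fit reaches r² ≥ 0.8 *with a negative slope* on a network whose mean
   clustering is at least 0.1: the class is defined by clustering that is
   present and falls with degree, so an excellent fit through three noisy
   near-zero points must not qualify.

The margin and floors were calibrated once on simulated ER / PA /
hierarchical populations at the study scale (n = 146, e = 197): the
ER-vs-PA score-difference distributions separate at ≈ 0.43 (ER 5th
percentile) vs ≈ 0.30 (PA 95th percentile), and 0.35 sits between them.
All thresholds are exposed in the pipeline config. Measured accuracy over
independent 50-seed populations: scale-free 88–98%, random 96–100%; the
deterministic hierarchical construction is always labelled hierarchical.

## Node-deletion experiments

"Collapse" after hub removal is operationalized as weak-component
fragmentation — the published analyses report it only visually, so the
package states its own metrics explicitly: the number of weak components
and the giant-component fraction of the surviving nodes. Targeted attacks
remove the top of the hub ranking (or explicit labels; the ATP-ADP system
is modelled as the label group {ATP, ADP}, configurable). Random attacks
remove uniformly chosen distinct nodes, with per-repetition sub-seeds
derived from one experiment seed. `compare_attacks` runs both strategies
at the same budget and reports the asymmetry (random-minus-targeted giant
fraction) and the fraction of random repetitions the targeted attack
undercuts. Default removal budget is 2 nodes (4 is the other preset).

## Synthetic generators

The curated databases behind the published topology tables were never
deposited, so the generators emulate their *reported statistics*, not
their wiring — what passing tests show is that the pipeline measures,
classifies and perturbs such networks correctly, not anything new about
sperm biology.

* **`gen_directed_er(n, e)`** — e distinct ordered pairs sampled
  uniformly, no self-loops; the Poisson benchmark.
* **`gen_directed_pa(n, e)`** — growth with one edge per new node plus
  preferential extra edges; targets are chosen ∝ (in-degree + α), sources
  ∝ (out-degree + α). The orientation `bias` (default 0.7, the probability
  that a new node's edge points into the existing network) splits the
  exponents: with initial attractiveness α = 2.0 the mean fitted exponents
  are b_in ≈ −1.7, b_out ≈ −2.2, inside the range reported for curated
  maps (−1.5 … −2.3). Node and edge counts are exact.
* **`gen_hierarchical(levels, module_size)`** — deterministic replicated
  cliques: each level copies the structure `module_size` times and wires
  the corner nodes of the replicas to the central root. Edges are oriented
  by parity of the endpoint-index sum — arbitrary but deterministic, and
  for odd module sizes the in/out histograms coincide (even sizes produce
  parity artifacts, hence the default module_size = 5, levels = 3,
  125 nodes). `C(k)` falls as a power law with r² ≈ 0.99.
* **`gen_paper_fixture(which)`** — presets `capacitation_like` (146/197),
  `ar_like` (141/191) and `intersection_like` (109/143). A chain-flavoured
  PA variant (30% of new nodes extend a chain from the previous node; 10%
  of extra edges join two one-link nodes) reproduces the published
  one-link (22–30%) and two-link (40–45%) node fractions that pure PA
  cannot reach — real capacitation/AR maps are chains of signaling events,
  and the chain moves encode exactly that. Samples are rejected (bounded
  at 200 tries, ≈13% per-try hit rate) until the one-link fraction lies in
  [0.20, 0.35] and the two-link fraction in [0.35, 0.50]. The activation
  share is pinned to 95% by exact count (round(0.05·e) inhibition edges)
  rather than per-edge coin flips, so every seed realises the ~95%/~5%
  split within ±0.02. The three top-degree nodes are relabelled
  `[Ca2+]i`, `ATP`, `ADP` in rank order, making the calcium signal the top
  hub by construction and the hub-removal presets exercisable. A matching
  record table (annotations marked as synthetic placeholders) is emitted
  and rebuilds the network exactly.

What the fixtures do **not** emulate: the actual molecule identities
beyond the three designated hubs, the published diameter (20) and
characteristic path length (6.6–7.0) — a random PA-like wiring at this
density is more compact (diameter ≈ 14, CPL ≈ 5) than the long curated
cascades — the top-hub degree (≈ 8–10 links vs the 25 reported for the
calcium signal), and any biological pathway structure. Because the chain
moves flatten the degree tail, the fixture population sits near the
random/scale-free classifier boundary and individual seeds fall on either
side; the pure `gen_directed_pa` population is the one with an
unambiguous scale-free signature.

## Numerical and degeneracy conventions

* Empty networks summarise to zeros with explicit `None` markers for path
  statistics; edgeless networks have undefined CPL/diameter, not 0.
* Fits with fewer than three support points raise (degree fits) or return
  an unfittable marker (`C(k)`).
* All stochastic functions take a seed; repetition sub-seeds come from a
  seeded `numpy` generator, and the CLI derives per-stage seeds from one
  global seed via CRC-coded stage names, so any artifact on disk can be
  reproduced from its logged seed. Seeds stay below 2³¹.
* Weak-component and hub orderings are deterministic (size-then-label,
  degree-then-label).

## Known limitations

* The classifier is a calibrated heuristic, not a hypothesis test; its
  accuracy is quantified only for the three generator families at the
  study scale (~146 nodes, ~197 edges). Very small networks (< ~30 nodes)
  rarely have enough distinct degrees for stable fits and will often be
  indeterminate.
* Intersection matches full signed triples by default; endpoint-only
  matching is available (`match_sign=False`) because whether published
  intersections matched signs is not stated.
* SIF files cannot represent labels containing tabs; such labels are
  rejected at write time rather than mangled.
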