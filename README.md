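# roiselect

Objective region-of-interest (ROI) selection for tiled whole-slide images
(WSIs).

Pathology workflows that can only afford to analyze a few regions of a
slide — tissue microarray coring, multiplexed imaging panels, manual
review — usually pick those regions by hand or at random. Both sampling
schemes misrepresent the slide: manual picks are biased toward visually
striking tissue, and random picks need dozens of regions before their
pooled cell-type composition converges to the slide's. `roiselect`
replaces them with convex optimization over tile cluster compositions: it
finds a *small* set of ROIs whose combined composition matches the whole
slide, optionally steered toward heterogeneous (biologically diverse)
tissue.

## The model

A WSI is cut into non-overlapping 256×256-px tiles; each tile carries a
composition vector on the K-simplex (the fraction of each of K cell/tissue
clusters among its contents). Candidate ROIs are square tile-aligned
windows. With

* `A` — the N×M matrix whose column *j* is the pooled composition of
  candidate ROI *j* (N clusters, M candidates),
* `b` — the slide-wide composition,
* `E` — the vector of Shannon entropies of the candidate compositions,

two selection programs are solved:

* **Sparse composition matching**
  `min ‖x‖₁  s.t.  |Ax − b| ≤ ε,  0 ≤ x ≤ 1` —
  the minimum number of ROIs reproducing the slide composition (solved
  exactly as a mixed-integer program by default, or as the continuous LP).
* **Entropy-regularized matching**
  `min ‖Ax − b‖² − λ·Eᵀx  s.t.  0 ≤ x ≤ 1, Σx = 1` (default λ = 1) —
  trades composition fit against tissue heterogeneity so the selected
  regions are diverse rather than homogeneous.

Candidates with weight `x_j > 0.01` are the selected ROIs. Selections are
scored against the slide by composition MSE, base-2 Jensen–Shannon
divergence, and mean ROI entropy, and compared with a 1,000-draw random
baseline of equally many non-overlapping windows.

The package also ships the surrounding evaluation toolkit — tile-table
I/O and background filtering, k-means tile clustering with elbow-based
model selection, cluster purity / NMI / Spearman cluster pairing /
canonical correlation analysis for comparing labelings and embeddings,
Dice-compensated SSIM for virtual-stain quality — plus a synthetic
tissue generator with known ground truth that makes the whole pipeline
testable without any slide data.

## Worked example

```python
import roiselect as rs

# a synthetic slide: 40x40 tiles of 256 px, K=7 contiguous clusters
spec = rs.SyntheticSpec(seed=0)
grid = rs.generate_tile_grid(spec)

problem = rs.SelectionProblem.from_grid(grid, roi_side_tiles=4)
result = problem.fit("entropy", lam=1.0)
print(result.summary())
```

```
ROI selection results
======================================================
method:            entropy
candidates (M):    100
clusters (N):      7
solver status:     fista:converged+refined
objective:         -1.37369
support cutoff:    0.01
selected ROIs:     1
support objective: -1.36307
lambda:            1.0
entropy_sign:      1.0
refine:            True
------------------------------------------------------
  j   weight   entropy   window
 61   0.7885   1.4739   ROIWindow(row0=24, col0=4, height_tiles=4, width_tiles=4)
```

The solver put 79% of its weight on candidate 61 — a 4×4-tile window
whose own composition entropy (1.47 nats, near the log 7 ≈ 1.95 maximum)
marks it as covering a mix of many clusters — and the discrete refinement
kept it as a single representative ROI. Scoring it against the slide and
against random sampling at the same budget:

```python
report = result.evaluate()
baseline = problem.fit("random", k=result.n_selected, n_draws=1000, seed=0)
```

```
MSE vs WSI:        0.0158
JSD vs WSI:        0.1986
mean ROI entropy:  1.4739
random 5th-pct MSE:   0.0296
random median entropy: 0.5375
```

One optimized ROI already matches the slide composition better than 95%
of random single-ROI draws (MSE 0.016 vs the random 5th percentile
0.030) while covering nearly three times more heterogeneous tissue
(entropy 1.47 vs the random median 0.54). The sparse (`method="l1"`)
program instead returns the minimal ROI set that reproduces the slide
composition within the slack ε — typically more ROIs, each more
homogeneous.

The same pipeline is available from the shell:

```bash
roiselect simulate --outdir sim --seed 0
roiselect select --input sim/tiles.csv --method entropy --lambda 1 --outdir sel
roiselect evaluate --input sim/tiles.csv --rois sel/selected_rois.csv --outdir eval
```

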