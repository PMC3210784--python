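# Methods

This note records the model behind `validtrack`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where the design was genuinely open.

## 1. Detection

Frames are illumination-corrected by subtracting a Gaussian-blurred copy
(`gauss_sigma`, default 25 px — large against a cell radius of ~6 px, small
against the shading length scale) and linearly mapped to 8 bit per frame.
Segmentation is a global Otsu threshold with foreground strictly brighter
than θ, followed by erosion (disk, radius 1), dilation (disk, radius 1) and
removal of components below `min_area` (default 20 px). Foreground
connectivity is 8-connected everywhere, including overlap computation.
θ is computed **per frame**: contrast drifts over hours-long movies.

*Robustness guard.* Otsu's between-class criterion degenerates when a frame
is nearly cell-free (unimodal histogram): the threshold drops into the
background noise and the frame floods with speckle detections. The stack
detector therefore floors the per-frame threshold at the background median
plus 4 robust standard deviations (1.4826·MAD). Sub-confluent frames are
background-dominated, so the median/MAD estimate the background regardless
of cell load, and on well-populated frames the Otsu threshold lies far
above the floor — the guard is inert there. `compute_global_threshold`
itself remains pure Otsu and is tested against an exhaustive-search oracle.

## 2. Overlap linking

Forward overlap |∩|/A_t and backward overlap |∩|/A_{t+1} must both exceed
T_fw = T_bw = 0.3 (configurable) and the pair must be unique in both
directions for a link. These defaults echo the 30% floor that the
evaluation's dual-overlap matching uses, giving one internally consistent
notion of "the same cell". Path fragments are maximal chains of unique
links; every detected cell belongs to exactly one fragment. All non-unique
overlaps with at least `candidate_floor` = 1 px of intersection are kept in
the adjacency — deliberately permissive, since validation only ever
*removes* hypotheses.

Tie-breaking where a single "largest overlap" is needed (naive tracking):
intersection pixel count, then backward overlap, then lower label —
deterministic and documented.

## 3. Features and similarity

Per-cell features: centroid, area (pixel count), mean grey value, and
compactness C = 4πA/P². P is the Crofton perimeter estimate, which is
unbiased for smooth boundaries; the chain-code estimate overestimates a
circle's perimeter by ~5% and would push the compactness of a large
rasterized disk to ~0.91 instead of ~0.99. With Crofton, a disk of radius
50 px scores 0.992.

The step difference vector is d = (Δs, ΔA, Δḡ, ΔC) with Δs the unsigned
centroid displacement — position itself carries no identity information,
only its change does. Similarity is the 4-D normal density with sample mean
µ and sample covariance Σ; a ridge ε = 10⁻⁶·trace(Σ)/4 is added to the
diagonal whenever the smallest eigenvalue falls below ε (degenerate
reference samples, e.g. a constant coordinate). The density is evaluated
from the closed form via a Cholesky factorization and cross-checked in the
tests against an independent implementation to 10 significant digits.

## 4. Mitosis detection and calibration

A division requires both (a) the Y-shape — the fragment ends into exactly
two successor fragments starting the next frame — and (b) the pre-mitotic
pattern: over the last k = 2 steps the cell loses area, gains compactness
and gains brightness. (b) is scored as Prob(d̄) > T_mit, where d̄ is the
mean of the last k difference vectors and the model is a multivariate
normal fitted to reference divisions.

Calibration runs a clean simulated movie (420², 70 frames, 14 starting
cells, 5-h mean cycle), matches detected fragment ends to true divisions by
dual overlap, fits the model on the matched terminal windows, and sets
T_mit at the 5th percentile of the training scores — 95% recall on the
calibration divisions by construction. Model and threshold are persisted as
JSON (`mitosis_model.json`) and reused.

Daughters claimed by two surviving events are treated as an unresolvable
conflict and all involved events are dropped: when in doubt, reject.

## 5. Validation

Terminus flags: `begin`/`end` at the movie boundaries; `border-begin`/
`border-end` for candidate-free termini whose centroid lies within
`border_margin` (default 30 px) of an edge; `lost-begin`/`lost-end` for the
remaining candidate-free termini; `merged` for reversed-Y successors (which
implies lost semantics on the merged region). Termini with pending
adjacency candidates carry no flag — the junction detectors decide.

*Interior-branch refinement.* The unique-link construction has two blind
spots that share one structural trace. If one daughter of a division fails
the overlap thresholds while the other passes, the parent chain continues
into a single daughter; if one partner of a merge links uniquely into the
merged region, no reversed-Y forms. In both cases an adjacency edge
connects a fragment terminus to the **interior** of a continuing fragment.
Every such interior branch splits the continuing chain at the branch point,
unconditionally: the junction becomes an explicit Y or reversed Y, the
detectors judge it, and junctions neither detector trusts stay unresolved —
rejecting the involved paths. False splits (e.g. debris grazing a cell)
only cost recall, never purity.

*Recovery of vanished cells.* A lost-end fragment triggers local
re-detection: a window (half-width 30 px) around the terminal centroid is
re-thresholded with a local Otsu in each following frame (up to
`max_gap` = 5). Already-detected foreground is excluded from the local
histogram — bright neighbours would otherwise pull the threshold above the
faint cell — and from the recovered binary. Reconnection to a re-appeared
fragment is tried first; locally bridged regions are inserted into the
masks as new labels so that downstream feature extraction and evaluation
see one uniform mask stack. Without a full bridge the fragment is left
unchanged.

*Decision tree.* Termini are classified in fixed priority order: border →
merged → mitosis → vanished (recovery attempted) → debris → unresolved.
Debris requires `lost-begin` and either a single-frame span or a span ≤ 2
frames with mean step displacement above `debris_speed_min` (15 px/frame).
A `cell-death` flag marks lost ends with sustained terminal shrinkage below
twice the minimum area — a named heuristic only; such paths are never
complete either way.

*Assembly.* A complete path is a fragment whose begin is a daughter of a
surviving mitosis, whose end is the parent of one, and which carries no
border/lost/merged flag. Accepted paths are joined through their shared
mitoses into the lineage forest; every rejected fragment carries
machine-readable reasons. Life time = (end frame − birth frame) × frame
interval, i.e. the number of inter-mitosis intervals; the same convention
is used for ground-truth cells, so the two distributions are directly
comparable.

## 6. Evaluation

Detection matching uses the dual-overlap rule: a detected cell is a true
positive iff both directional overlap ratios with exactly one reference
cell exceed 0.3 and that reference cell matches only it. FAR = FP/(TP+FP)
and FRR = FN/(TP+FN); with this choice "the detector finds 95% of the
cells" corresponds to FRR ≈ 5%. TN is not defined for detection (there is
no enumerable set of non-cells) and is not used. A cell detected with
insufficient accuracy becomes both a FP and a FN — the rates are
intentionally coupled.

A detected mitosis is correct iff a reference division of the matched
parent exists within ±1 frame (the paper-frame assignment of a division is
ambiguous by one frame). A complete path is correct iff every cell of its
span matches one and the same reference cell and both endpoint mitoses are
correct. Trustworthiness = 100 × correct/returned.

Degree of relation = number of distinct divisions on the tree path between
two cells (siblings 1, parent–child 1, first cousins 3; 0 = unrelated; the
degree of a cell with itself is a contract error). Genealogy FAR/FRR at a
frame are fractions of all related reference pairs in that frame: degree
predicted 0 → false rejection, wrong nonzero degree → false acceptance.
The predicted forest connects *fragments* (complete paths and boundary
stubs alike) through validated mitoses, since cells alive in the frame of
interest usually belong to still-open leaf paths.

## 7. Synthetic-data generator

The generator emulates what the tracking method actually consumes: bright
convex (elliptical) cell bodies of a few hundred px² on a darker
background, Brownian motion with optional drift, soft contact avoidance
(cells push apart to a 2.5-px gap, emulating adherent cells that touch but
rarely overlap), divisions with the pre-mitotic pattern — over the last 2
frames the cell's area drops by `area_drop` = 45%, its aspect ratio goes to
1 and its intensity rises by 35% — after which two small round daughters
(area conservation of the contracted cell) split in place and respread to
full size over 6 frames. Default optics: background 30, cell intensity
120 ± 8, noise σ = 6, optional linear illumination gradient; 8-bit frames.
Life times are truncated normal (floor 2 frames), by default mean 300 min
with σ = 60 min at 15-min frame intervals — a fast-cycling adherent stem
cell culture; initial cells get uniform residual life so divisions are not
synchronized.

Error scenarios are seeded as deterministic event counts: merges steer a
cell pair into deep contact over a 3-frame approach (per-frame steps small
enough to keep the overlap chain alive), hold them as one connected region
for `merge_duration` frames, then separate; dropouts scale an interior
cell's contrast to 35% of normal for 3 frames (below the global threshold,
above the local one — interior cells only, since an edge cell's vanishing
is indistinguishable from a border exit); debris are small fast blobs
(35 px/frame, straight lines) excluded from the truth masks; in open-border
mode cells may exit (logged) and scheduled entries appear at the edges.
Ground truth comprises per-frame label masks (overlap pixels to the nearer
centre), a cell registry, lineage edges and the typed event log; identical
config + seed reproduce frames and truth bit for bit.

Not emulated: phase-contrast halos and shade-off, shape dynamics beyond
ellipse jitter, cell death/apoptosis as a rendered process, 3-D culture,
and cell fusion. Passing tests therefore demonstrate the tracking and
validation logic under controlled error injection — not performance on
real phase-contrast optics, whose detection stage would face halos and
texture these renders lack.

## 8. Benchmark problem sizes

The test suite exercises two standing movies: a clean growth movie (950²
px, 100 frames, 25 → ~1400 cells, ~500 accepted complete paths) for
detection quality and the life-time no-bias check (two-sample KS,
α = 0.01), and an error-injected movie (900² px, 150 frames, 50 starting
cells, 10 merges / 8 dropouts / 6 debris / 5 border entries, open borders
with slow drift) for the purity-versus-naive comparison. These sizes give
several hundred complete paths while keeping the whole suite around two
minutes on one CPU.

## 9. Known limitations

- A division whose second daughter leaves *no* adjacency trace at all
  (zero-pixel overlap with everything) cannot be seen by the interior-
  branch refinement; the fused parent+daughter path is then accepted with
  a wrong life time. Observed rate: ~1 per 500 accepted paths on the clean
  benchmark. A spatial-proximity hypothesis could close this, at the cost
  of more false splits.
- Merged-cell *rectification* (re-assigning identities after a merge by
  feature matching) is not implemented; merges are detected and rejected.
- The genealogy FRR is intentionally high (most relations are rejected
  with their paths); the method trades recall for purity by design.
- Runtime scales roughly linearly with total cell count in practice, but
  no test asserts wall-clock behaviour.
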