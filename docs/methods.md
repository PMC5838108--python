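# Methods

## Data model

A tractometry study is stored as a `TractometryDataset`: for each
(metric, tract) pair a subject × node matrix of real values (NaN =
missing), with `n_nodes` (default 100) uniform across tracts and metrics,
plus a per-subject metadata table and a free-form parameter mapping. Row
*i* of every matrix belongs to `subject_ids[i]`; all orders (subjects,
tracts, metrics) are preserved end-to-end through every reader and writer.
FA is dimensionless in [0, 1]; diffusivities are positive, conventionally
in µm²/ms. Violations of these physical ranges are reported as warnings,
not errors — upstream tensor fits do occasionally produce them and the
data should still be convertible.

## Statistics

**Group summaries.** Per node: count of non-missing values `n`, mean,
sample SD (n−1 denominator — norms are estimated from a finite sample of
reference subjects), and SE = SD/√n. SD and SE are undefined (NaN) below
n = 2.

**Normative z-scores.** `z(v) = (x(v) − mean_ref(v)) / sd_ref(v)` node-wise.
When the indexed subject appears in the reference list it is removed
before the norms are computed. This leave-self-out default makes the
patient-vs-controls case automatically correct and avoids the bias of a
subject contributing to its own norm; it can be disabled, in which case
the reference members' z-scores average to exactly zero node-wise (a
property the tests exercise). Nodes with zero reference SD yield NaN with
a warning rather than ±inf.

**Scalar z summary.** The default reduction of a z-profile over a node
window is the *signed peak*: the signed value at the node of maximum |z|,
ties broken toward the lowest node index. A focal lesion occupies a few
nodes; a window mean dilutes it roughly in proportion to window width,
while the peak preserves both magnitude and location. A `mean` reduction
is available for diffuse effects. This choice of default was genuinely
open; the peak rule is the one under which per-tract lesion scores match
what a per-node inspection finds.

**Deviant fraction.** A group member is deviant iff its z-profile against
the (disjoint) reference crosses the threshold strictly at ≥ 1 node in the
window; direction `absolute` (default), `positive` or `negative`. The
statistic is by construction monotonically non-increasing in the
threshold. Note that with wide windows and a 1-SD threshold even null
subjects cross occasionally (maximum over many correlated nodes), so the
statistic should be read against a control-group baseline.

**Binning.** Quantile binning sorts by (value, subject ID) — the
deterministic tie-break makes group membership reproducible — and splits
into N contiguous chunks whose sizes differ by at most 1. Equal-width and
explicit-edge binning use half-open intervals [e_i, e_{i+1}) with the last
interval closed, so the maximum value is not orphaned. Categorical binning
makes one group per distinct level in sorted order. Missing metadata
values are reported as "unassigned" and excluded; silently imputing them
would corrupt group norms.

**Node ranges** are 0-based and inclusive on both ends ("nodes 50–80"
selects 31 nodes), matching how along-tract regions are reported.

## Synthetic data generator

The generator emulates the *structure* of tractometry data, not diffusion
physics. Per subject s, tract, metric:

    x_s(v) = μ(v) + δ·[s ∈ target group]·[v ∈ window] + b_s + ε_s(v)

* μ(v): a smooth tract shape — baseline plus Gaussian bumps. Default
  baselines per metric (FA 0.45; MD 0.80, RD 0.55, AD 1.30 µm²/ms) sit at
  typical adult white-matter values; `default_spec` draws 1–3 bumps per
  (metric, tract) with amplitudes up to ±25 % of baseline, giving each
  tract a distinct profile as real tracts have.
* b_s ~ N(0, τ²): a between-subject offset (default τ: FA 0.035,
  diffusivities 0.04–0.05), the dominant variance component in real
  cohorts.
* ε_s(v): stationary AR(1) node noise with marginal SD σ (default
  0.03–0.04) and lag-1 autocorrelation ρ = 0.8 — tract profiles are
  spatially smooth, so node noise is strongly autocorrelated. The
  empirical lag-1 autocorrelation over 10⁴ nodes is verified to sit within
  ±0.05 of ρ.
* Metadata generators: uniform (default age ~ U[8, 50], the span of a
  developmental cohort), normal, and categorical draws — enough to
  exercise binning and the linked-table logic.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64),
so a spec + seed fully determines the dataset across platforms.

**Lesions** are injected post hoc as
`sign · A · sd_ctrl(v) · exp(−(v−c)²/(2w²))` where `sd_ctrl` is the
per-node sample SD of a named control group. Expressing amplitude A in
control-SD units means an injected lesion of amplitude A should be
recovered as a peak z ≈ A, making recovery directly checkable: with A = 5,
w = 3 at node 50 against 30 controls, the recovered peak-z node falls in
[45, 55] in ≥ 90 % of 20 seeded replicates and the median peak z lies
within [4.0, 6.5] (the spread reflects norm-estimation noise at n = 30).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: cross-metric correlations (FA and RD are
strongly anti-correlated in reality), partial-volume and crossing-fiber
geometry, scanner/site effects, age trends in the profiles themselves, and
non-Gaussian heavy-tailed artifacts. Tests built on it validate the
statistical machinery, not any biological claim.

## File formats

**Tidy bundle.** `nodes.csv` (header `subjectID,tractID,nodeID,<metric…>`,
rows subject-major → tract → ascending node), `subjects.csv` +
`subjects.json` (identical content, checked on read), `params.json`.
CSV dialect: comma, UTF-8, LF, minimal quoting; missing = empty cell /
JSON null. Floats are written with `repr` (shortest round-trip decimal)
and read back with pandas' `round_trip` parser, so write→read is
bit-exact — the property suite checks 50 randomized datasets.

**AFQ MAT.** Both classic v7 (via scipy.io) and HDF5-backed v7.3 (via
h5py) layouts are read; field lookup is case-insensitive; matrices stored
transposed (MATLAB column-major convention) are detected by shape and
fixed. The fixture writer emits a genuine v7.3 layout: a 512-byte MATLAB
userblock followed by plain HDF5, openable by any HDF5 reader.

**TRACULA stats folders.** The published description of this input is
just "a stats folder", so the dialect here is this package's own
documented contract: one whitespace-delimited table per (tract, metric)
named `<tract>.<metric>.txt`, first column the subject ID. Differing
per-tract node counts are harmonized by linear interpolation onto the
maximum node count present (recorded in `params`); linear interpolation is
exact for locally linear profiles and introduces no overshoot.

**Viewer state.** The query-string grammar (alphabetical keys, comma
lists, `start-end` ranges, percent-encoded elements, defaults omitted) is
likewise this package's own contract; a canonical form makes states
comparable as strings and both round-trip directions property-testable.

**Site bundles** place the tidy data under `data/` next to the viewer
assets (or a placeholder page) and carry a SHA-256 manifest; publishing is
deliberately offline-only (`publish_dryrun` emits the ready-to-init
repository copy and a registry payload validated against a shipped
JSON-schema), since actual hosting/registration is network glue outside
the computational core. Payload validation uses a small built-in checker
covering the schema subset used (type/required/properties/items).

## Numerical and degenerate-input choices

* Zero reference SD → z = NaN + warning (not ±inf); all-missing windows
  raise rather than return a silent NaN.
* `n_groups` greater than the number of subjects with values is an error
  for quantile binning (empty quantile groups are never fabricated).
* Empty groups from explicit edges yield an all-missing summary with
  n = 0 rather than an error, so a grid of summaries stays rectangular.
* Strict inequality for deviance thresholds: `threshold=0` means "any
  nonzero deviation".
* Port collisions when serving fall through to the next free port with a
  warning.

## Problem sizes

The test suite and the acceptance script run on scaled synthetic studies
chosen to estimate each quantity stably: 50 randomized datasets for the
serialization round trips, 100 small datasets for the brute-force
oracle-equivalence checks, 20 seeded replicates of the 31-subject lesion
study, 48 subjects for the deviant-fraction cohort, and 400 subjects for
group-effect recovery. These sizes keep every check deterministic and
fast while leaving the estimators' sampling noise well inside the asserted
bands.

## Known limitations

* The MAT reader targets the common AFQ field layout (`vals`, `fgnames`,
  `sub_ids`, optional `metadata`/`params`); exotic or heavily customized
  structures may need pre-massaging.
* No hypothesis testing or multiple-comparison machinery is included —
  the summaries are descriptive; inferential analysis belongs downstream.
* Profiles are treated as aligned across subjects; no re-registration of
  node grids is attempted beyond the TRACULA resampling.
* The synthetic generator's realism limits are listed above.
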