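# tractprofiles

Along-tract statistics and publishable data bundles for diffusion MRI
tractometry.

Tractometry pipelines quantify white matter tissue properties by sampling
diffusion metrics — fractional anisotropy (FA), mean/radial/axial
diffusivity (MD, RD, AD) — at equidistant nodes (typically 100) along the
core trajectory of each major fiber tract. The result, per subject, is a
*tract profile* per (tract, metric), and per study a stack of
subject × node matrices plus a subject metadata table. `tractprofiles`
turns such pipeline output into a documented, tidy, text-based exchange
format and implements the statistics that researchers and clinicians run
on it: group comparisons along the tract, and normative per-node z-scores
that localize an individual patient's lesions against control norms.

It is aimed at researchers who have tractometry output (an AFQ `.mat`
structure or a TRACULA group-stats folder) and want reproducible,
scriptable group statistics, individual-versus-norm comparisons, and a
shareable data bundle — without a GUI.

## What it computes

For a group *G* of subjects and node *v* of one (tract, metric), the group
summary is

    n(v), mean(v), sd(v) (sample, n−1 denominator), se(v) = sd(v)/√n(v)

computed over non-missing values. A subject *s* is compared to a reference
group node-wise by

    z_s(v) = (x_s(v) − mean_ref(v)) / sd_ref(v)

with the subject removed from the reference before the norms are computed
(leave-self-out, the safe default for patient-vs-control comparisons). A
focal lesion is summarized by the *signed peak*: the signed z at the node
of maximum |z| within a node window. Group-level deviance is the fraction
of patients whose |z| exceeds a threshold at one or more nodes in a window
— the along-tract analogue of "what proportion of patients fall more than
1 SD outside control norms at the cerebral peduncle".

Subjects can be binned into N groups on any metadata column (quantile,
equal-width, explicit edges such as ages 8–15 / 15–30 / 30–50, or
categorical), and a view over the data — metric, selected tracts,
grouping, brushed node ranges — is serializable to a canonical URL query
string, so any view is bookmarkable and exactly reproducible.

## Worked example

Inject a synthetic focal lesion of 5 control-SD into one patient's MD
profile and recover it against 30 controls:

```python
import tractprofiles as tp
from tractprofiles.synth import LesionSpec, SyntheticSpec

spec = SyntheticSpec(n_subjects=31, tract_names=["cst"], metric_names=["md"],
                     n_nodes=100, seed=42, metadata_columns=[])
ds = tp.generate(spec)
patient, controls = ds.subject_ids[0], ds.subject_ids[1:]
lesioned = tp.inject_lesion(
    ds, LesionSpec(patient, "cst", "md", center=50, width=3.0, amplitude=5.0),
    controls)
zp = tp.subject_zscores(lesioned, patient, "cst", "md", controls)
peak, node = tp.summarize_z(zp, how="peak")
print(f"peak z = {peak:.2f} at node {node}")
```

This prints:

```
peak z = 5.00 at node 50
```

i.e. the patient's MD deviates from control norms by 5.0 standard
deviations, peaking exactly at the injected lesion center (node 50). The
amplitude of an injected lesion is specified in control-SD units, so the
recovered peak z should match it up to norm-estimation noise.

The same workflow from the shell:

```sh
tractprofiles synth --out demo_bundle --seed 3 --n-subjects 10
tractprofiles stats zscore demo_bundle \
    --subject subject_000 --tract "Left Arcuate" --metric md
tractprofiles site assemble demo_bundle --out demo_site
tractprofiles site serve demo_site --port 8080
```

`tractprofiles assemble afq.mat --out bundle` converts real AFQ output
(MAT v7 or v7.3); `--format tracula` reads a TRACULA stats folder instead.

## The tidy bundle

A bundle directory holds four plain-text files joinable on `subjectID`:

| file | content |
|---|---|
| `nodes.csv` | one row per (subject, tract, node): `subjectID,tractID,nodeID,<metric...>` |
| `subjects.csv` | subject metadata, one row per subject |
| `subjects.json` | the same metadata as JSON records |
| `params.json` | free-form analysis parameters |

Rows are ordered subject-major, then tract, then ascending 0-based
`nodeID`; numbers are written as the shortest decimal that round-trips, so
`read_tidy(write_tidy(ds))` reproduces the dataset exactly.

## Viewer-state query strings

States serialize with alphabetically ordered keys (`band`, `brush`,
`groupKey`, `metric`, `nGroups`, `sort`, `subjects`, `tracts`), comma-joined
lists, `start-end` node ranges, `tract:start-end` brush items and
percent-encoded elements; fields at their defaults are omitted. E.g.
`brush=Left%20CST:50-80&groupKey=age&nGroups=3`. `decode(encode(s)) == s`
for every valid state.

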