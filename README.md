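# ddfnc

Decentralized dynamic functional network connectivity (ddFNC) as a tested
Python library. Multiple imaging sites hold private subject data
(voxels × timepoints matrices); the full dFNC pipeline runs without any raw
data crossing the network:

1. **Decentralized group ICA (`ddfnc.dgica`)** — per-subject PCA
   preprocessing on each site, a two-stage decentralized PCA that passes
   only scaled eigenvector packages site-to-site (serial round-robin or a
   recursive cluster-parallel variant, `ddfnc.dpca`), then whitening +
   infomax ICA at an aggregator site and a broadcast of the group spatial
   maps.
2. **Back-reconstruction** — each site recovers subject timecourses from
   the broadcast maps (GICA1).
3. **Sliding-window connectivity (`ddfnc.dfnc`)** — windowed component
   correlations (window *w* spans timepoints *w..w+t*; 162 timepoints at
   *t* = 22 give exactly 140 windows) and exemplar windows at local maxima
   of the connectivity-variance timecourse.
4. **Decentralized K-means (`ddfnc.dkmeans`)** — multishot Lloyd's with
   count-weighted centroid averaging (exactly the pooled update, label-
   identical to pooled K-means under a shared initialization), a multishot
   gradient-descent variant, and a single-shot nearest-centroid merge; all
   under correlation distance, orchestrated as exemplar-stage → full-stage
   two-stage clustering with silhouette-based run selection.
5. **Evaluation (`ddfnc.evaluation`)** — Moreau–Amari ISI, Hungarian
   component/centroid matching, reference-subset selection, subject-median
   state matrices and two-sample t-test group contrasts.

The consortium itself is simulated in-process (`ddfnc.consortium`): sites
exchange statistics only through a message channel that enforces a
whitelist (raw subject data is unrepresentable), copies payloads, and logs
all traffic so each run's communication volume can be reconstructed and
audited (`privacy_audit`). `ddfnc.synthetic` generates all test inputs:
unstructured Gaussian matrices and multi-subject mixtures of Laplacian
spatial sources whose timecourses switch among planted connectivity states.

## CLI

```bash
ddfnc simulate --out data/ --subjects 8 --states 5 --seed 0   # synthetic subjects
ddfnc run -c config.yaml --out results/ [--data data/]        # full pipeline
ddfnc cluster --variant lloyd --k 5 --n-init 20 --seed 0      # clustering stage only
ddfnc experiments --which pca_equivalence                     # stage-level comparisons
```

`config.yaml` is a flat YAML mapping of `ddfnc.interface.PipelineConfig`
fields (defaults: r=100 spatial components, k1=120 subject components,
k2=5·r site rank, window 22, k=5 states, 200 clustering initializations).
Every run writes its config, centroids, labels, spatial maps and traffic
log to the output directory; re-running from the stored config reproduces
centroids bit-exactly.

Input formats: per-subject 4-D NIfTI (optionally masked) or flat
tab-delimited voxels × timepoints matrices; outputs are delimited text.

## Library example

```python
from ddfnc.interface import PipelineConfig, run_ddfnc

cfg = PipelineConfig(seed=0, site_subject_counts=[10, 10], r=10, k1=60,
                     k2=50, d=2000, T=160, n_states=5, n_init=20, k=5)
run = run_ddfnc(cfg)                # synthetic consortium, full pipeline
run.clusters.C                      # k x pairs state centroids
run.clusters.labels                 # per-window state assignments
run.consortium.channel.to_table()   # audited traffic log
```
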