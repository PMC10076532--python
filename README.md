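# dmnconn

Inter-subject metabolic covariance network analysis of the default mode
network (DMN). Given MNI-space PET volumes (or a pre-extracted subject ×
VOI uptake table) with a group label per subject, the package:

1. extracts mean normalized uptake in 14 DMN volumes of interest
   (packaged atlas of region centers; spherical masks by default, or a
   user-supplied integer parcellation),
2. builds one 14×14 weighted undirected Pearson correlation network per
   group, computed **across** subjects, with its Fisher-z transform,
3. characterizes each network with weighted graph measures — global
   efficiency, characteristic path length, nodal efficiency, degree
   centrality (strength) — using reciprocal weight→length mapping and
   Dijkstra shortest paths,
4. compares groups with a subject-relabeling permutation test (edgewise
   Fisher-z differences with Benjamini–Hochberg FDR over the 91 edges;
   metric-wise tests with BH over the 14 nodes for regional metrics), and
5. simulates synthetic two-group cohorts with planted correlation
   differences (and optional rendered voxel volumes) so the whole
   pipeline is testable without any data download.

## Python API

```python
import dmnconn as dc

spec = dc.SimulationSpec(n_a=40, n_b=41,
                         planted_edges=[("HIP.L", "PCG.L", -0.5)], seed=1)
patients, controls, truth = dc.generate_cohorts(spec)

net_p = dc.intersubject_correlation(patients)   # GroupNetwork: R, Z, W
report = dc.compute_metrics(net_p.W, net_p.voi_names)

cfg = dc.PermutationConfig(n_permutations=10_000, seed=1)
res = dc.edgewise_permutation_test(patients, controls, cfg)
print(res.significant_labels())
```

## CLI

```sh
dmnconn simulate --out run/sim --seed 1            # cohort.tsv + ground truth
dmnconn extract  --manifest subjects.csv --out run/ex --fwhm 8
dmnconn analyze  --cohort run/sim/cohort.tsv --out run/an \
                 --permutations 10000 --seed 1
dmnconn demo     --out run/demo --seed 1           # simulate + analyze
```

`extract` takes a CSV manifest (`file, subject_id, group`) of NIfTI or
Analyze volumes already in MNI space; per-subject failures are logged,
not fatal. `analyze` writes per-group R/Z/W matrices (TSV), graph-metric
reports (JSON/TSV), edgewise and metric-wise permutation results, and a
run summary; every output directory archives the effective config and
seed, and reruns with the same seed are byte-identical. The default
permutation count is 1000 for interactive runs; pass
`--permutations 10000` for the full protocol.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria. One criterion
(single planted-edge recovery at 1000 permutations under BH-FDR across
91 edges with ≥80% sensitivity) is left deliberately failing: the
smallest attainable add-one permutation p-value at 1000 permutations is
1/1001, whose BH q-value over 91 edges is 91/1001 ≈ 0.091 > 0.05, so a
lone discovery is arithmetically impossible at that permutation count —
the test documents the defect rather than hiding it.

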