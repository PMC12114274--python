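# hbq

Hydrogen-bond distance descriptors and subset regression for
channel-blocker structure–activity analysis.

`hbq` links minimized ligand–protein–water complex structures to percent
channel inhibition (I%):

1. **structure_io** — parse PDB-style atom records and partition atoms into
   protein / ligand / water roles with polar-atom (N, O, S) typing.
2. **hbond_features** — detect direct and water-bridged hydrogen bonds at a
   3 Å distance cutoff and assemble a chain-agnostic, residue-keyed
   bond-length feature matrix (absent bonds filled with the cutoff;
   water-bridged variables carry a `W` prefix).
3. **pose_clustering** — leader-cluster docking poses by RMSD (no
   re-superposition) at a 10 Å threshold and select best-energy
   representatives of the largest clusters until ≥ 70 % of poses are
   covered.
4. **qsar_ga_mlr** — OLS multiple linear regression (R², in-fit RMSE,
   coefficient-sign interpretation) plus a genetic algorithm over
   fixed-size variable subsets with R² as fitness, validated against an
   exhaustive-search oracle.
5. **pharm_stats** — the one-parameter dose–response model
   `Y = 100/(1 + X/IC50)`, IC50 least-squares fitting, mean ± SEM group
   summaries, and percent cyst-size reduction.
6. **synthetic_data** — seeded generators for every input above (toy
   complexes with planted bond geometry, feature matrices with planted
   sparse linear structure, jittered pose sets, noisy dose–response
   curves), so the whole pipeline is testable offline.

## CLI

```sh
hbq parse complex.pdb --ligand-res LIG --summary
hbq features --complex-dir complexes/ --activity activities.tsv -o matrix.tsv
hbq cluster poses.tsv --threshold 10 --coverage 0.70
hbq select matrix.tsv --k 8 --seed 42 --generations 200 --pop 100
hbq fit matrix.tsv --vars V8,V19,V24,V27,V17,V26,V11,V10
hbq ic50 dr.tsv
hbq cysts groups.tsv --control vehicle
hbq synth features|complex|dr --seed 1 -o out
```

`features` expects one `.pdb` file per ligand conformation (names like
`12e_2.pdb` or `12b-.pdb` map to parent compound `12e` / `12b` in the
activity table) and a TSV with `ligand_id` and `I_percent` columns.
Pose files are TSV: `pose_id  energy  x1 y1 z1 x2 y2 z2 ...`.

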