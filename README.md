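# membind

Analysis of peripheral membrane-protein binding in particle-based
simulation trajectories.

Soluble lipid-binding domains — the motivating case is a DysF domain that
recognizes phosphatidic acid (PA) in coarse-grained and atomistic bilayer
simulations — bind a planar membrane transiently: the trajectory alternates
between bound poses, where part of the protein dips into the lipid head-group
region, and unbound excursions into solvent.  `membind` turns such
trajectories into the standard quantitative read-outs of that behaviour:

- **Minimum-distance traces** — per frame, the minimum over all protein
  bead / membrane bead pairs of the minimum-image Euclidean distance
  d(t) = min_{a∈protein, b∈membrane} ‖r_a − r_b‖ under the orthorhombic box,
  with periodic boundaries on all axes, the xy plane only, or none.
- **Bound-state classification and binding percentage** — a frame is bound
  when d(t) ≤ d_c (default d_c = 0.7 nm).  A Gaussian kernel density
  estimate of the pooled distances is bimodal for a binder; the first valley
  of the KDE, located from the sign changes of its first derivative, can
  replace the fixed cutoff.  The binding percentage of a condition is
  100 · mean_r(f_r) over replicas r, where f_r is the bound fraction of
  replica r (frame count or KDE mass below d_c), with the standard error
  s(f_r)/√R computed across the R independent replicas.
- **Per-residue lipid-interaction frequency** — residue i is in contact in a
  frame when min over its beads of the distance to any membrane bead is
  < 0.5 nm; its frequency is the contact-frame count pooled over all
  replicas divided by the pooled frame count.  Ranking and contiguous-run
  segmentation of the profile yield the membrane-binding regions.
- **Insertion depth** — per residue, the signed distance below (+) or above
  (−) the membrane surface (mean phosphate-bead z of the proximal leaflet),
  time-averaged over a window, in nm internally and Å at output; comparing
  the first and last window of a run quantifies binding-mode drift.
- **Liposome-flotation quantification** — for a four-fraction sucrose
  gradient, bound fraction = I_top / Σ_k I_k from band intensities, with
  per-sample mean and SD across replicates.

Because published simulation data of this kind is rarely deposited, the
package ships a first-class synthetic trajectory generator
(`membind.synthetic`): a lattice bilayer with configurable lipid composition
(e.g. 60% DOPC / 40% DOPA), a multi-residue protein cloud placed 2.5 nm
above the membrane, and a two-state Markov binding process with exact,
recorded ground truth (state sequence, interface residue set, insertion
depths).  Every analysis is validated by parameter recovery against that
ground truth.

## Worked example

Simulate four replicas of a 10-residue binder with a true stationary bound
occupancy of 0.6 above a 60/40 PC/PA bilayer, then analyse them:

```sh
membind simulate --out demo/sim --replicas 4 --frames 2000 \
    --occupancy 0.6 --n-residues 10 --seed 42
membind binding   demo/sim/replica_*.gro --out demo/binding
membind interface demo/sim/replica_*.gro --out demo/interface
membind depth     demo/sim/replica_0.gro --out demo/depth
```

which prints

```text
wrote 4 replicas to demo/sim
binding: 58.8% +/- 2.5% (threshold 0.700 nm, fixed)
top residues: [2, 3, 4, 5, 1]; regions >=50% of max: [(2, 5)]
max per-residue drift: 0.078 nm
```

The four generated replicas happened to have true occupancies
{0.607, 0.570, 0.528, 0.647} (mean 58.8%): the reported binding percentage
recovers the replica-mean occupancy exactly, with the ±2.5 percentage-point
replica standard error reflecting the chain-to-chain spread.  The interface
residues configured in the generator (2–5 for this small protein) are
recovered as the top-ranked contiguous binding region, and the sub-0.1 nm
first-versus-last-window drift identifies the binding mode as stationary.
Each output directory contains TSV/JSON results plus a metadata block with
the seed and a configuration hash; results computed under different
thresholds refuse to aggregate unless forced.

The same operations are available as library calls
(`membind.simulate_replicas`, `membind.summarize_binding`,
`membind.residue_contact_frequency`, `membind.compare_windows`, …) on
trajectories read from multi-frame GRO or multi-MODEL PDB files.

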