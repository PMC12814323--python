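# microswitch

Analysis of how side-chain "microswitch" rotamers couple to backbone
conformational microstates in molecular-dynamics ensembles of membrane
receptors (e.g. GPCRs), with a ground-truth synthetic generator so the
whole pipeline is testable without trajectory downloads.

## Who this is for

Computational structural biologists with several MD trajectory replicas
per binding state (apo, agonist-bound, ...) who want to ask: *which side
chains' rotameric states are statistically coupled to the backbone's
conformational substates, and what would that coupling do to ligand
binding kinetics?*

## What it computes

1. **Shared-basis backbone PCA.** One PCA is fitted to the pooled,
   superposed backbone (C′, Cα, N) coordinates of *all* ensembles, so
   per-frame scores are directly comparable across binding states.
2. **Microstates.** Each ensemble's frames are clustered (k-means on the
   first 5 PCs, k ∈ {4,5,6} chosen by silhouette) into microstates, with
   populations, medoid frames, PC histograms and inter-cluster RMSDs.
3. **Rotamer states.** Side-chain χ1/χ2 dihedrals are discretized into
   rotameric states (valine 3, leucine 9, tryptophan 6; Ala/Gly/Pro are
   excluded), with populations, circular-mean angles, and single-state
   dwell segments.
4. **Entropy-based cross-correlation (ECC).** For backbone microstate
   series *BB* and rotamer series *SC*, with Shannon entropies
   S = −Σᵢ pᵢ ln pᵢ:

   ```
   ECC = 2 (S_BB + S_SC − S_total) / (S_BB + S_SC)
   ```

   ECC = 0 when the series are independent (S_total = S_BB + S_SC) and
   ECC = 1 when they fully determine each other
   (S_BB = S_SC = S_total).
5. **Rotamer-conditioned histograms.** PC-space histograms restricted to
   each rotamer state of a chosen residue; these sum bin-wise, exactly, to
   the unconditioned histogram. Includes 1-D histograms along an oblique
   (default 60°) axis in the PC0–PC1 plane, cross-ensemble overlays with
   overlap coefficients, and 4 Å side-chain contact shells.
6. **Conformational-selection kinetics.** A kinetic scheme in which
   binding proceeds only from "competent" microstates: under fast
   exchange k_on,eff = p_competent · k_on*, so shifting microstate
   populations tunes the on-rate; if unbinding is accelerated in
   proportion, K_d is invariant. A master-equation mode covers slow
   exchange.

The synthetic generator plants all of this structure with known ground
truth: a Markov chain over microstates, per-ensemble and per-microstate
rigid displacements of a helical segment, and rotamer emissions coupled
to the hidden microstate with tunable strength κ ∈ [0, 1] (κ = 0:
independent; κ = 1: deterministic).

## Worked example

```python
import numpy as np
import microswitch as ms

spec = ms.SyntheticSpec(
    n_ensembles=1, replicas_per_ensemble=3, n_frames=5000,
    n_residues=10,
    residue_names=["LEU", "VAL", "TRP", "LEU", "VAL", "SER", "ALA", "GLY", "ALA", "ALA"],
    n_microstates=5, coupled_residues=[(0, 1.0)], seed=1,
)
ensemble, truth = ms.simulate_ensemble(spec)

backbone = ms.superpose(ms.extract_backbone(ensemble))
model = ms.fit_shared_pca(backbone, n_components=10)
scores = ms.project(model, backbone)
clusters = ms.cluster_ensemble(scores, k_range=(4, 5, 6), n_dims=5, seed=1)
print("clusters:", clusters.k, "populations (%):", np.round(clusters.populations, 1))

scheme = ms.build_default_scheme()
chi = ms.compute_chi(ensemble, [0, 1, 2, 3, 4, 5])
rotamers = [ms.assign_states(c, scheme) for c in chi]
for r in ms.ecc_scan(clusters.assignments, rotamers):
    print(f"residue {r.residue_index} ({r.residue_name}): ECC = {r.ecc:.3f}")
```

prints

```
clusters: 5 populations (%): [22.3 22.  19.4 18.9 17.4]
residue 0 (LEU): ECC = 0.998
residue 1 (VAL): ECC = 0.000
residue 2 (TRP): ECC = 0.001
residue 3 (LEU): ECC = 0.001
residue 4 (VAL): ECC = 0.000
residue 5 (SER): ECC = 0.000
```

The clustering recovers the five planted microstates with near-equal
populations; the residue whose rotamer emission was tied to the hidden
microstate (residue 0, κ = 1) scores ECC ≈ 1 while the uncoupled
residues sit at the finite-sample floor near 0.

The same analysis runs from the shell:

```sh
microswitch run-all --config examples/config.yaml --outdir out --seed 1
```

which writes CSV/PDB/JSON artifacts for every stage plus a
`manifest.json` with SHA-256 hashes (reruns with the same config
reproduce the hashes bit-for-bit).

## Layout

- `src/microswitch/synthetic.py` — ground-truth synthetic ensembles
- `src/microswitch/trajio.py` — topology/trajectory I/O, superposition, RMSF
- `src/microswitch/rotamers.py` — χ angles, rotamer states, dwell segments
- `src/microswitch/microstates.py` — shared PCA, clustering, histograms
- `src/microswitch/ecc.py` — entropy-based cross-correlation
- `src/microswitch/conditional.py` — conditioned histograms, overlays, contacts
- `src/microswitch/kinetics.py` — conformational-selection model
- `src/microswitch/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
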