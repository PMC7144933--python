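# chromkit

Analysis toolkit for chromatosome / linker-histone molecular-dynamics
trajectories. It implements the post-processing layer of such a study as a
reusable, tested package:

- **core_io** — PDB / multi-model-PDB / frame-table CSV readers and writers,
  an atom-selection mini-language, run configuration, structured logging.
- **geometry** — β-loop orientation angles (ϕ₁/ϕ₂), the nucleosomal plane,
  signed in-plane (α) / out-of-plane (β) linker-DNA angles, end-to-end
  distances, heavy-atom contact tables (4.0 Å default), superposition RMSD.
- **dyndist** — binned joint distributions of angle series, mutual
  information / NMI (bits, geometric-mean normalization) and KL divergence
  (nats, ε-regularized) against a reference system.
- **wham** — 1-D umbrella-sampling free-energy reconstruction: statistical
  inefficiency, self-consistent WHAM (bias `k(ξ−c)²`, colvars convention;
  a flag restores the ½ factor), Monte-Carlo bootstrap errors with
  inefficiency-aware resampling, cumulative-block convergence checks.
- **pre_backcalc** — PRE intensity-ratio back-calculation from
  probe–methyl distances with the condensed
  `exp(−β(r+d)⁻⁶) / (1 + α(r+d)⁻⁶)` model (α = 4.5×10⁸, β = 3.4×10⁷,
  d = 9 Å), ensemble averaging with 80 % percentile CIs, and comparison to
  experimental tables. Note the **negative** exponent: the form sometimes
  printed with a positive sign diverges at short range and contradicts the
  underlying relaxation model; the implementation uses the physical form
  (ratio → 1 far from the probe, → 0 near it).
- **energetics** — three-trajectory MM/GBSA assembly from per-frame
  component tables (complex / receptor / ligand), ΔΔE between binding
  modes, and complexed-vs-isolated strain decomposition, all with
  quadrature-combined per-frame standard deviations.
- **clustering** — pairwise-RMSD matrices (align-once-to-reference),
  average-linkage hierarchical clustering with a distance cutoff, medoid
  representatives, and top-fraction (e.g. 90 %) cluster selection.
- **synthetic_data** — generators for every input class with machine-
  readable ground truth: toy chromatosomes with prescribed α/β angles,
  correlated umbrella windows from analytic potentials (exact marginals via
  a Gaussian-copula AR(1) stream), noisy PRE datasets, Gaussian energy
  tables, and two-state trajectories.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle- and
property-based, all on synthetic data with known truth).

## CLI

```sh
chromkit --out-dir out --seed 1 simulate chromatosome
chromkit --out-dir out angles out/chromatosome.pdb --truth out/chromatosome_truth.json
chromkit --out-dir out simulate umbrella
chromkit --out-dir out wham --meta out/meta.csv --temp 300 --bins 100 --bootstrap 100
chromkit --out-dir out gbsa --complex c.csv --receptor r.csv --ligand l.csv
chromkit --out-dir out cluster traj.pdb --fit "segid CORE and name CA" \
    --measure "segid LH and name CA" --cutoff 2.0
chromkit --out-dir out contacts traj.pdb --sel-a "segid LH" --sel-b "segid DNA"
chromkit --out-dir out dyndist --data angles.csv --reference nucleosome.csv \
    --pairs alpha_entry:alpha_exit
```

Selection grammar: `keyword value [value ...]` clauses joined with `and`;
keywords `name`, `resid` (ranges `lo-hi`), `resname`, `segid`, `element`.

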