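# oxtrsim

Analysis toolkit for the cellular consequences of the OXTR A218T receptor
variant:

* **`oxtrsim.network`** — an ODE reaction network of oxytocin-stimulated,
  Gq-mediated Ca²⁺ release from the ER (ligand–receptor binding,
  receptor/G-protein coupling, G-protein cycling, PLC activation, IP3
  production/degradation, IP3R-gated ER release with Ca²⁺ co-agonism,
  saturable SERCA-type reuptake, first-order leak). WT and A218T builds
  differ in exactly one rate constant, the receptor/G-protein coupling
  constant `kf_coupling`.
* **`oxtrsim.metrics`** — baseline, amplitude, AUC and FWHM of Ca²⁺
  transients (simulated concentration curves or Fura-2 ratio traces),
  group mean ± SEM summaries, and mutant/WT metric ratios.
* **`oxtrsim.calibration`** — bracketed single-parameter fitting of the
  coupling constant to a target amplitude, WT-vs-A218T comparison, and
  sensitivity scans.
* **`oxtrsim.crossref`** — Benjamini–Hochberg adjustment, DE-table
  filtering (padj < 0.05 strict, |log2FC| ≥ 1.5 inclusive, direction
  switch), and cross-referencing against an ASD gene-category list
  (categories 1/2/3/other with per-category counts and a top table).
* **`oxtrsim.contacts`** — fixed-column PDB parsing, side-chain-centric
  residue neighborhoods (default 5.5 Å), geometric H-bond (3.5 Å N/O
  donor–acceptor) and hydrophobic (4.5 Å apolar C–C) classification,
  ideal-geometry Ala↔Thr substitution, and inter-chain interface reports.
* **`oxtrsim.synth`** — seeded generators for imaging-like traces
  (bi-exponential transient + drift + noise, lognormal amplitudes),
  DE/gene-category tables with planted ground truth, and ideal α-helix
  PDB fixtures (single helix or two-helix dimer).

Units are nM and seconds throughout the model. ER concentrations are
expressed in ER volume; the conserved total is
`Ca_cyt + er_cyt_volume_ratio * Ca_er` (ratio 0.18 by default).

## Parameter table

The model reads a tabular parameter file with columns
`name,value,scope,units,description` (`scope` ∈ shared/wt/mut). A
documented default is shipped at `src/oxtrsim/data/params_default.csv`;
it is a calibrated stand-in reproducing the published cascade topology
and the WT→A218T single-transient behaviour, and any externally supplied
table with the same layout substitutes for it (`--params FILE`).
The shipped `kf_coupling_mut` was calibrated so the simulated A218T/WT
amplitude ratio equals the published 1.13; AUC and FWHM ratios are then
predictions of the one-parameter model (≈1.11 and ≈1.04).

## CLI

```bash
oxtrsim simulate --variant wt --oxt-nM 100 --t-on 50 --t-off 250 --ca-free --out traj.csv
oxtrsim traces   --in traces.csv --t-stim 60 --baseline-last 20 --out metrics.csv
oxtrsim fit      --target-amplitude 900 --variant a218t
oxtrsim compare  --out comparison.json
oxtrsim crossref --de de.csv --sfari sfari.csv --padj 0.05 --lfc 1.5 --direction both --top 50
oxtrsim contacts --pdb file.pdb --chain A --resnum 218 --cutoff 5.5 [--mutate ala2thr] [--interface]
oxtrsim synth traces|tables|pdb [--spec spec.yaml] --out DIR
```

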