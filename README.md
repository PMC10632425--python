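# asymcycle

Analytics for the ATP-coupled conformational cycle of heterodimeric ABC
transporters studied in lipid bilayers, built around the BmrCD exporter:

* **DEER spectroscopy** — forward modelling of four-pulse dipolar evolution
  signals and *global* Gaussian-mixture fitting across experimental
  conditions, with the number of components selected by BIC. Component
  centers and widths are shared across conditions; populations, modulation
  depth and background slope vary per condition, so conformational
  equilibria can be tracked as ligand conditions change.
* **Protein–lipid interactions** — residence fractions of lipids at basic
  surface residues, per-leaflet kernel-density occupancy maps of lipid
  phosphorus, per-lipid minimum-distance series and a side-chain
  orientation angle for Lys/Arg, quantifying which lipids are stably bound
  versus gliding along the protein surface.
* **Structural asymmetry** — Kabsch superposition, Cα RMSD with iterative
  outlier rejection, per-residue asymmetry profiles between the two
  pseudo-symmetric transporter halves, helix tilt angles between
  conformations, and ionic-latch side-chain distances.

The model at the core of the DEER strand is

    V(t) = B(t) · [ 1 − λ_c + λ_c · Σ_k w_{k,c} ∫ N(r; μ_k, σ_k) K(t, r) dr ]

with the powder-averaged dipolar kernel K(t, r) = ⟨cos[(1 − 3cos²θ) D t/r³]⟩,
B(t) = exp(−k_c t), and BIC = n·ln(RSS/n) + p·ln(n) with
p = 2K + C·(K + 1) for K shared Gaussians over C conditions.

Every strand comes with a synthetic-data generator that writes a
machine-readable ground-truth record (mixture parameters, realized Markov
bound fractions, rigid transforms), so estimator accuracy is testable
quantitatively. See `docs/methods.md` for the full model descriptions and
design choices.

## Worked example

Generate a three-condition DEER dataset from the default preset (shared
distance components at 35 and 45 Å; populations 0.8/0.2, 0.5/0.5, 0.2/0.8;
noise sd 0.005) and fit it globally:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_fit_deer.py --seed 1
```

which prints

```
BIC table:
 K      rss          bic  converged
 1 0.236154 -7366.680134       True
 2 0.021609 -9484.912057       True
 3 0.021469 -9456.723383       True
selected K = 2 (truth K = 2)

per-condition populations (fitted vs truth):
  apo            fitted [0.797, 0.203]  truth [0.8, 0.2]
  substrate      fitted [0.498, 0.502]  truth [0.5, 0.5]
  substrate-ATP  fitted [0.188, 0.812]  truth [0.2, 0.8]

shared centers: 34.96 A (sigma 1.96), 44.92 A (sigma 3.09); worst center error 0.075 A
```

BIC drops sharply from K = 1 to the true K = 2 and rises again at K = 3;
the fitted per-condition populations track the designed conformational
equilibria to a few percent and the shared centers are recovered to better
than 0.1 Å. The remaining drivers run the lipid strand
(`03_lipid_interactions.py`: residence fractions at three contact cutoffs,
leaflet density maps, angle summaries) and the structure strand
(`04_structure_asymmetry.py`: transform recovery, outlier rejection,
homodimer asymmetry profile, a constructed 12° helix tilt).
`05_deposited_models.py` downloads the deposited BmrCD coordinate models
from the RCSB (network required) and recomputes the published RMSD and
ionic-latch comparisons.

The same functionality is scriptable through one CLI:

```sh
asymcycle synth --strand deer --seed 5 --out data/
asymcycle deer --manifest data/manifest.tsv --kmax 4 --seed 7 --out results/
asymcycle lipid --config run.yaml --out results/
asymcycle structure --config run.yaml --out results/
```

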