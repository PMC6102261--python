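# smlmpipe

Two-colour single-molecule localisation microscopy (SMLM) analysis for
quantifying adhesive ligands and adhesion proteins on functionalised
surfaces — from raw camera frames to drift-corrected molecular
coordinates, cluster morphology, degree-of-colocalisation scores and
ROI-level density comparisons.  A synthetic-data module generates
blinking movies and two-colour point patterns with known ground truth, so
every stage of the chain is verifiable without microscope data.

## Who this is for

Groups doing dSTORM/PALM imaging of cell–substrate interfaces: ligand
fields (e.g. RGD peptides) imaged in one channel, adhesion proteins
(e.g. paxillin) in the other.  The pipeline answers questions such as:
what is the ligand density and the corresponding mean ligand spacing; how
are adhesion-protein clusters shaped; do molecules of the two channels
colocalise; and how do densities inside adhesive structures compare with
the rest of the cell footprint.

## The analysis chain

1. **Event detection.** Each frame is Gaussian filtered; blinking events
   are pixels whose filtered intensity `I` satisfies `I − M > k·S`, with
   `M` and `S` the frame mean and standard deviation and `k = 6`.
2. **PSF fitting.** Each event is fitted with an error-function-integrated
   2-D Gaussian (amplitude `N` photons, centre, width σ, background `b`),
   with Poisson-weighted least squares; overlapping events are fitted
   jointly.  The per-event precision is the maximum-likelihood bound

   σ²_loc = (σ²ₐ/N)·(16/9 + 8π σ²ₐ b²/(N a²)),  σ²ₐ = σ² + a²/12,

   with `a` the pixel size and `b²` background photons per pixel.
3. **Grouping.** Re-blinks of one molecule are merged: events within
   100 nm, on-runs ≤ 5 frames, dark gaps ≤ 50 frames.
4. **Drift correction.** Fiducial markers are tracked and a
   piecewise-linear drift trajectory is estimated and subtracted.
5. **Spatial statistics.** Ripley `K(r)` / `L(r) − r` with toroidal or
   isotropic edge correction; CSR density→mean-spacing conversion
   `d = 1/(2√λ)`; nearest-neighbour distances.
6. **Clustering.** DBSCAN (`r = 20 nm`, `ε = 3`) with per-cluster counts,
   convex-hull areas and densities.
7. **Colocalisation.** Per-molecule degree of colocalisation (DoC): the
   Spearman rank correlation of the two channels' local-density gradients
   over radii 10–500 nm, attenuated by the cross-channel
   nearest-neighbour distance, `DoC = ρ_s · exp(−d/R_max)`; a molecule
   counts as colocalised at `DoC ≥ 0.4`.
8. **ROI analysis.** Densities inside/outside polygonal adhesion ROIs,
   surface vs under-cell averages, and classification of local ligand
   densities against the tethering (>0.8 µm⁻²) and spreading (4–7 µm⁻²)
   thresholds.

## Worked example

```python
import numpy as np
import smlmpipe as sp

window = sp.Window(0, 0, 10_000, 10_000)          # 10 x 10 um, in nm

# ligand field at 60 molecules/um^2 with nanoscale clustering, and a
# protein channel colocalised with it up to 20 nm labelling jitter
ligand, protein = sp.simulate_two_color(
    "colocalized", 60.0, 20.0, window, seed=1, base="clustered")

print(f"ligand density: {ligand.intensity_per_um2:.1f} /um^2")
print(f"mean CSR spacing at 0.01 /um^2: "
      f"{sp.mean_nn_spacing_from_density(0.01)/1000:.0f} um")

curve = sp.ripley_k(ligand, edge_correction="toroidal")
peak = curve.radii_nm[np.argmax(curve.l_minus_r)]
print(f"L(r)-r peaks at {peak:.0f} nm")

result = sp.doc_scores(ligand, protein)
scored = result[~result["degenerate"]]["doc"].dropna()
print(f"mean DoC: {scored.mean():.2f}, "
      f"fraction colocalised: {sp.fraction_colocalized(result):.2f}")
```

Output:

```
ligand density: 61.4 /um^2
mean CSR spacing at 0.01 /um^2: 5 um
L(r)-r peaks at 160 nm
mean DoC: 0.85, fraction colocalised: 1.00
```

The ligand field realises its requested density; 0.01 molecules/µm²
corresponds to a 5 µm mean spacing under spatial randomness; the
`L(r) − r` peak sits at the generated cluster scale; and the jittered
copy of the ligand channel scores a mean DoC of 0.85 with essentially
every molecule above the 0.4 colocalisation threshold.

A command-line interface mirrors the library
(`smlmpipe simulate|localize|group|drift|ripley|cluster|doc|roi-stats|spacing`);
each subcommand writes its outputs plus a JSON log of parameters and
seeds.  Localisation tables are CSV with nm units
(`frame, x_nm, y_nm, photons, bkg, sigma_nm, precision_nm, channel,
group_id`); ROIs are JSON polygon lists; movies are 16-bit multi-page
TIFF.

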