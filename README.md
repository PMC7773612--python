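# nirmap

Chemometric calibration and spatial mapping of soft-tissue composition from
near-infrared (NIR) diffuse-reflectance spectra.

## The problem

Knee meniscus degeneration changes the tissue's composition — water rises,
collagen and proteoglycan fall — before gross damage is visible. NIR
spectroscopy probes overtone and combination vibrations of O–H, C–H and N–H
bonds, so an arthroscopic fibre-optic probe can, in principle, read tissue
composition at the point of contact. Turning raw reflectance spectra into
constituent contents (water, hydroxyproline as a collagen proxy, uronic acid
as a proteoglycan proxy, each as % of wet weight) takes a full chemometric
workflow:

1. **Preprocessing search** — crop to the informative wavelength windows
   (1060–1172, 1211–1366, 1560–1840 nm; the regions outside are noisy or
   saturated), correct multiplicative/additive scatter (SNV, RNV or MSC) and
   smooth/differentiate with a Savitzky–Golay filter; the best combination
   is found by exhaustive search (7 range subsets × 4 scatter options × 48
   valid SG settings = 1344 configurations).
2. **PLS1 regression by NIPALS** — latent components maximise covariance
   between centred spectra X and the constituent content y:
   `w = Xᵀy/‖Xᵀy‖`, `t = Xw`, `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, deflate, repeat;
   collapsed coefficients `b_k = W_k (P_kᵀW_k)⁻¹ q_k`.
3. **Monte Carlo cross-validation (MCCV)** — repeated random 90/10 splits;
   the component count minimising mean validation RMSE (RMSECV) is kept.
4. **Monte Carlo outlier screening** — repeated 75/25 splits collecting each
   sample's held-out residuals; samples whose mean residual exceeds the
   cohort mean by 3 SD are flagged.
5. **Wavelength selection** — five algorithms compared against the
   all-channel base model: UVE, CARS, random frog, MWPLS and IRIV.
6. **Spatial mapping** — held-out grid predictions assembled into the 9×14
   measurement lattice, unmeasured edge cells imputed as neighbour means,
   the map centred in a 20×20 zero canvas and bilinearly interpolated at
   spacing 0.01 to a 1901×1901 pixel image, with measured-vs-predicted
   percent-error maps.

Because no public NIR meniscus dataset exists, the package ships a phantom
generator (`nirmap.synthetic`) that reproduces the study design — 115
training locations measured in triplicate, a 9×14 test grid with 55
measurable cells, water 70–75%, collagen 20–22%, glycosaminoglycan 0.6–0.8%
of wet weight — with Beer–Lambert band mixtures, scatter distortions and
channel noise, so every stage is testable end to end.

## Worked example

```python
from nirmap import PhantomSpec, generate_dataset, average_replicates, fit_nipals, predict
from nirmap.preprocessing import PreprocessConfig, DEFAULT_RANGES_NM, apply_pipeline
from nirmap.pls import rmse, spearman_rho

ds = generate_dataset(PhantomSpec(), seed=11)          # study-design phantom
train = average_replicates(ds.train_spectra)           # 345 spectra -> 115
cfg = PreprocessConfig(DEFAULT_RANGES_NM, "snv", 9, 2, 0)
proc, _ = apply_pipeline(train, cfg)                   # 230 -> 83 channels
y = ds.train_references.aligned_to(list(proc.sample_ids)).values_for("water")
model = fit_nipals(proc.values, y, 5)
print(f"RMSEC {rmse(y, predict(model, proc.values)):.3f} pp,"
      f" rho {spearman_rho(y, predict(model, proc.values)):.3f}")
```

prints `RMSEC 0.149 pp, rho 0.994`: after scatter correction the calibration
recovers water content to ~0.15 percentage points over its 5-point range.

The full study analog is driven by the numbered scripts:

```bash
python analysis/01_simulate_phantom.py --seed 1        # phantom -> results/phantom/
python analysis/02_search_preprocessing.py --seed 1    # optimal-config table
python analysis/03_train_models.py --seed 1            # MCCV + outliers + fit
python analysis/04_compare_variable_selection.py --seed 1  # method comparison
python analysis/05_map_constituents.py --png           # constituent + error maps
```

At seed 1 this reports, per constituent, the winning preprocessing
configuration (all three wavelength windows win for every constituent), a
4-component model, held-out Spearman ρ of 0.98–1.00 with RMSEP 0.14 pp
(water), 0.15 bp (uronic acid) and 0.04 pp (hydroxyproline), and
measured-vs-predicted map errors between 0.01% and 0.5% per grid cell. A
single `nirmap.pipeline.run(PipelineConfig(...))` call executes the same
stages programmatically with a manifest and bit-reproducible outputs.

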