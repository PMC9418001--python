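# pyrodom

Molecular-formula assignment and pyrogenic signatures for ultrahigh-resolution
(FTICR-MS) dissolved organic matter.

Wildfire transforms soil organic matter into increasingly aromatic, condensed
compounds. Direct-infusion FTICR-MS of water-extractable organic matter
resolves thousands of peaks per sample at sub-ppm accuracy, enough to assign a
unique CHONSP molecular formula to most of them and to ask how the molecular
composition of dissolved organic matter (DOM) shifts along a burn-severity
gradient. `pyrodom` implements that analysis as a tested, reproducible
pipeline for people working on fire effects, DOM chemistry, or exact-mass
metabolomics:

1. **Peak processing** — m/z window filtering (closed interval, default
   [200, 900]), removal of peaks with a more abundant ¹³C isotopologue
   1.0033548 Da below, internal recalibration against CH₂ homologous series
   (linear ppm error model), and cross-sample alignment at 0.5 ppm.
2. **Formula assignment** — exhaustive enumeration of CHONSP formulas within
   element bounds whose mass matches the deprotonated ([M−H]⁻) neutral mass
   with |error| < 0.5 ppm, filtered by H/C and O/C windows and a non-negative
   integer RDBE, with deterministic tie-breaking.
3. **Chemical descriptors** — per formula:

   - nominal oxidation state of carbon,
     NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S − z)/C
   - aromaticity index, AI = (1 + C − O − S − 0.5H)/(C − O − S − N − P),
     plus its O-discounted modified form (AI ≥ 0.67 flags condensed
     aromatics); degenerate numerators/denominators floor at 0
   - Van Krevelen compound classes from an editable H/C × O/C rectangle table

4. **Kendrick mass defect** with the C₄H₂ base unit (benzene addition):
   KM = M × 50/50.01565, KMD = NKM − KM; homologous series are ≥ 2 formulas
   sharing a KMD with nominal Kendrick masses spaced by 50, optionally
   retained only when present across all burn-severity conditions.
5. **Severity comparison** — formula × sample presence matrix, unique-formula
   sets per (possibly merged) severity group, one-sided Welch t-tests on
   per-sample mean AI with Holm adjustment, and NOSC medians/densities of
   unique formulas.

A seeded synthetic-spectrum generator emulates negative-mode, singly charged
DOM spectra (log-normal intensities, ¹³C satellites, sub-ppm mass error,
optional calibration drift, planted aromatic enrichment by severity), so the
whole pipeline is exercised end-to-end without instrument data.

## Worked example

```python
from pyrodom import SyntheticDesign
from pyrodom.pipeline import simulate, run_pipeline, PipelineConfig

design = SyntheticDesign(n_core_formulas=400,
                         n_unique_formulas_per_condition=80, seed=1)
simulate(design, "demo")                     # peak lists + metadata + truth

cfg = PipelineConfig(peaklist_dir="demo",
                     metadata_path="demo/metadata.csv",
                     output_dir="demo_out", seed=1)
manifest = run_pipeline(cfg)
print(manifest["counts"])
print(open("demo_out/comparison.txt").read())
```

On this 21-sample severity gradient (4 control / 6 low / 5 moderate / 6 high
replicates) the run reports:

```
{'input_peaks': 18138, 'isotopologue_removed': 9069,
 'aligned_clusters': 720, 'assigned_formulas': 720,
 'kendrick_series_retained': 71}
```

— every synthetic ¹³C satellite was filtered, the surviving monoisotopic
peaks aligned into 720 clusters, all of which received a formula, and 71
C₄H₂ Kendrick series were present across all four severities. The
comparison summary shows the planted aromatic enrichment recovered as a
monotone AI gradient (every severity pair significant, e.g.
control → high: mean AI 0.097 → 0.130, Holm-adjusted one-sided
p = 3.6 × 10⁻⁷) and unique formulas in high-severity samples with a higher
NOSC median than control-unique formulas (−0.44 vs −0.84, i.e. more
oxidized, thermodynamically more favourable to oxidize).

The same stages are scriptable from the shell:

```bash
pyrodom simulate --outdir demo --seed 1
pyrodom run --peaklists demo --metadata demo/metadata.csv --outdir demo_out
```

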